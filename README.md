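# lncsig

Tools for asking whether long non-coding RNA (lncRNA) expression in gut
tissue carries enough information to tell what kind of microbes live in
the gut. Germ-free mice, mice re-conventionalized with a normal
microbiota, and gnotobiotic mice colonized with defined *E. coli* strains
differ in their intestinal lncRNA profiles; `lncsig` re-implements the
full analysis chain that turns exon-microarray data into such
lncRNA-based condition signatures, and ships a seeded synthetic-data
generator so that every step can be exercised and validated against
planted ground truth without any external download.

The pipeline has five stages:

1. **Probe re-annotation** (`lncsig.annotate`). Exon-array probes are
   filtered in a fixed cascade — probes with no genomic hit, probes with
   multiple hits, probes overlapping any protein-coding transcript span
   (either strand) — and the survivors are assigned to lncRNA transcripts
   (>200 bp mature length) by exonic containment, dropping ambiguous
   probes. Probe-level log2 intensities are averaged per transcript
   (default minimum 4 probes). Each lncRNA receives one of five
   positional categories relative to coding genes, in fixed precedence:
   *sense* (same-strand exonic overlap), *intronic* (span inside one
   intron, same strand), *antisense* (opposite-strand overlap),
   *proximity* (nearest coding span within 10 kb), *intergenic*.
2. **Differential expression** (`lncsig.diffexpr`). Two-group moderated
   t-statistics: per-feature pooled variances s²_g (df = n₁+n₂−2) are
   shrunk toward an empirical-Bayes prior (d₀, s₀²) estimated by moment
   matching on log s²_g, giving s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g) and
   t = Δmean/(s̃_g√(1/n₁+1/n₂)) on d₀+d_g df. Selection is
   fold-change-primary (linear FC > 2 or < 0.5 plus unadjusted p < 0.05),
   with Pearson chi-square category-enrichment tests and Venn partitions
   of DE sets across conditions.
3. **Promoter binding** (`lncsig.promoter`). A lncRNA counts as bound by
   a ChIP-seq factor when a peak midpoint lies within 10 kb upstream of
   its TSS, strand-aware, boundaries inclusive.
4. **Classification** (`lncsig.nsc`). A from-scratch nearest-shrunken-
   centroid classifier: standardized centroid deviations
   d_ik = (x̄_ik − x̄_i)/(m_k(s_i+s₀)) with m_k = √(1/n_k − 1/n) are
   soft-thresholded by Δ, samples are assigned by the discriminant
   δ_k(x) = Σᵢ(xᵢ − x̄′_ik)²/(sᵢ+s₀)² − 2 log π_k, and cross-validation
   sweeps a Δ grid; the operating threshold is the largest Δ attaining
   the minimal CV error — the smallest gene set immediately before the
   error rate escalates.
5. **Simulation** (`lncsig.simulate`). A toy genome with lncRNAs planted
   into each category by construction, tiled probes with decoys,
   class-structured expression with planted signature lncRNAs, and peaks
   planted upstream of a configurable fraction of TSSs.

`lncsig.pipeline` ties the stages together with a manifest (checksums,
counts, effective config) so reruns with one seed are byte-identical.

## Worked example

Generate a synthetic study and run everything:

```bash
cat > run.yaml <<EOF
seed: 5
output_dir: runs/demo
EOF
lncsig run --config run.yaml
lncsig report runs/demo
```

The report (from an actual run with seed 5) includes:

```json
"filter_report": {"input": 249, "zero_hit": 11, "multi_hit": 11,
                  "coding_overlap": 11, "retained": 216},
"category_counts": {"intronic": 25, "intergenic": 20, "antisense": 10,
                    "sense": 8, "proximity": 7},
"de_counts": {"de_RC_vs_GF": {"up": 5, "down": 5},
              "de_EC_vs_GF": {"up": 5, "down": 5},
              "de_EC_BSH_vs_GF": {"up": 5, "down": 5}},
"promoter_binding": {"n_bound": 8, "n_total": 70, "pct_bound": 11.4},
"threshold": {"delta_star": 14.675, "cv_error_at_delta_star": 0.0,
              "n_genes_at_delta_star": 5}
```

Reading it: of 249 simulated probes, the cascade discarded the 33
planted decoys (11 per rule) and kept all 216 clean probes; all 70
lncRNAs landed in their planted categories; each re-colonized condition
shows its 5 planted signature lncRNAs up against germ-free (and the
germ-free signatures down); 8 of 70 lncRNA promoters carry a planted
upstream peak; and leave-one-out cross-validation of the four-condition
nearest-shrunken-centroid model reaches error 0.0, retaining a 5-gene
signature at the selected shrinkage threshold.

Each stage is also exposed on its own (`lncsig simulate`, `lncsig
annotate`, `lncsig de`, `lncsig promoters`, `lncsig classify`) and as
plain library functions.

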