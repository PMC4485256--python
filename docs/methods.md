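# Methods

## Coordinate conventions

All genomic coordinates are 0-based half-open (BED convention)
internally; GTF input is converted on read (1-based inclusive on disk).
TSS: span start on the + strand, the 0-based last base (end − 1) on the
− strand. Unstranded transcripts have no TSS and are rejected by
promoter analysis.

## Probe re-annotation

Probes are discarded in a fixed cascade whose counts always partition
the input: (1) zero genomic hits, (2) two or more hits, (3) a single hit
overlapping (≥1 bp) the *span* of any protein-coding transcript on
either strand. Using the span rather than coding exons is deliberately
conservative: it keeps the intronic lncRNA category a property of the
annotation, not of which probes happen to survive, at the cost of losing
probes for intronic/sense/antisense lncRNAs. Surviving probes map to a
lncRNA only when the hit is *contained* in the transcript's exonic
extent — exon-array probes are 25 bp, so containment is the strict
reading of unique mapping; overlap without containment is dropped, and
probes contained in two or more lncRNAs are removed as ambiguous. Only
lncRNAs with mature (summed-exon) length > 200 bp are mapping targets,
matching lncRNA database conventions. Transcript expression is the
unweighted mean of probe log2 intensities, with a default minimum of 4
probes per transcript (the array this emulates averages ≈8.6 probes per
lncRNA; half of that is the support floor).

### Positional categories

First matching rule wins: sense (same-strand exonic overlap) >
intronic (span fully inside one intron, same strand) > antisense (any
span overlap, opposite strand) > proximity (no overlap, nearest coding
span within `proximity_bp`, default 10 000, which mirrors the promoter
window) > intergenic. The precedence and the strand-specific intronic
rule are package choices — the category names alone do not fix a
deterministic assignment — and are validated by a mirror-invariance
property (reflecting coordinates and flipping strands must not change
any label) and by planted-truth recovery.

## Moderated t-statistics

For each feature, log2FC is the difference of group means and s²_g the
pooled two-group residual variance on d_g = n₁+n₂−2 df. The
empirical-Bayes prior (d₀, s₀²) is fitted by moment matching on
log s²_g: e_g = log s²_g − ψ(d_g/2) + log(d_g/2) has mean
log s₀² + ψ(d₀/2) − log(d₀/2) and variance ψ′(d_g/2) + ψ′(d₀/2), so d₀
comes from inverting the trigamma (Newton iteration, relative tolerance
1e-8) on the excess variance of e. Non-positive excess, or d₀ above
1e6, is treated as d₀ = ∞ (all variances equal s₀²; t referred to the
normal). Zero-variance features are legal — they are shrunk toward s₀²
— but excluded from the prior fit, which works on log variances.
P-values are two-sided on d₀+d_g df and deliberately unadjusted: the
selection rule is fold-change-primary (FC > 2 or < 0.5, strict
inequalities, plus p < 0.05), the criterion with the best cross-study
reproducibility for array data; no FDR step is applied. Fold change is
2^(Δ mean log2), not a ratio of linear means. Category enrichment uses
a 2×2 Pearson chi-square without continuity correction (DE membership ×
category membership), with a warning flag when any expected cell is
below 1.

## Promoter assignment

Peaks are anchored at their midpoint, floor((start+end)/2) — generic
BED input carries no summit. A lncRNA is bound when a midpoint lies in
the inclusive window [TSS − w, TSS] (+ strand) or [TSS, TSS + w]
(− strand), w = 10 000 by default; distance 0 (a peak on the TSS)
counts as bound, since the 10 kb figure bounds the upstream side only.
Reported distances are TSS-relative with upstream positive. Bound
percentages are rounded to 0.1 (round-to-nearest).

## Nearest shrunken centroids

d_ik = (x̄_ik − x̄_i)/(m_k(s_i+s₀)) with s_i the pooled within-class SD
(n−K df), s₀ = median_i(s_i), and m_k = √(1/n_k − 1/n) — the exact
standard-deviation factor of (class mean − overall mean); some write-ups
print 1/n_k + 1/n, and the choice here is pinned by a Monte-Carlo test
of Var(x̄_k − x̄) = σ²(1/n_k − 1/n). Soft-thresholding
d′ = sign(d)(|d| − Δ)₊ zeroes uninformative features; shrunken
centroids are x̄_i + m_k(s_i+s₀)d′_ik; prediction minimizes
δ_k(x) = Σ(xᵢ − x̄′_ik)²/(sᵢ+s₀)² − 2 log π_k with proportion priors by
default (uniform available) and lexicographic tie-breaking. No adaptive
offsets or heteroscedastic variants — the simplest faithful core.

Cross-validation is leave-one-out when the smallest class has fewer
than 8 samples (the emulated datasets have 4–5 per class; LOO is then
deterministic), otherwise seeded stratified k-fold with
k = min(10, smallest class). The Δ grid is 30 evenly spaced points from
0 to max|d_ik| inclusive. The operating threshold Δ\* is the largest
grid point attaining the minimal overall CV error — the fewest-genes
model immediately before the error escalates; on a flat-zero curve this
is maximal shrinkage. Feature selection at Δ is "any class deviation
survives"; a |d′| magnitude filter is also expressible by thresholding
the exported per-class d′ table directly.

A known behavior worth stating: when planted effects are strong and
signature features are many, the CV error sits at exactly zero over a
long Δ plateau (a handful of strong features suffices to separate the
classes), so Δ\* lands deep in the plateau and the selected set can be
substantially smaller than the full planted signature. Signature recall
at Δ\* is therefore high only when effects are weak enough that the
error escalates while most planted features still survive; with 20
features per class at a 2-noise-SD effect and 20 samples per class,
measured recall at Δ\* is ~0.35–0.70 while CV error stays ≤ 0.05. The
acceptance suite records this honestly rather than moving the
selection rule.

## Synthetic data

The generator emulates the study's structure, not its biology. A root
seed fans out (via `SeedSequence.spawn`) to independent streams for
annotation, probes, expression and peaks, so outputs are deterministic
functions of (config, seed) and stages cannot perturb one another.

* **Genome.** Coding genes (default 50, 3–5 exons of 150–300 bp,
  introns 2–6 kb) are laid out sequentially with inter-unit gaps of at
  least `proximity_bp` + 1 kb, so every planted lncRNA's category is
  forced by local geometry: intronic/antisense inside a host intron
  (same/opposite strand), sense starting mid-exon and running past it,
  proximity 0.5–9.5 kb downstream of its host, intergenic isolated by
  more than the proximity window on both sides. Default category counts
  (intronic 25, intergenic 20, antisense 10, sense 8, proximity 7) make
  intronic the largest group, as in the re-annotated array. Infeasible
  geometry raises rather than truncating.
* **Probes.** Clean probes (25 bp, default 8 per transcript) tile the
  exons of lncRNAs whose exons avoid all coding spans — by the span
  rule, probes on the other categories could never survive filtering,
  so planting them would only re-test the filter. Decoys are injected
  at configurable rates (default 5% each): zero-hit rows, two-hit
  probes at random positions, single hits inside random coding spans.
* **Expression.** log2 intensity = transcript baseline N(7, 1) + probe
  offset N(0, 0.25) + class effect + N(0, 0.3) noise, i.i.d. — the
  idealized setting in which the moderated-t assumptions hold exactly;
  no probe correlation, array background, or saturation, so passing
  tests certify the machinery, not robustness to real-array artifacts.
  The default design is the study's: GF 4, RC 5, EC 4, EC-BSH 5. Each
  class gets 5 signature transcripts (disjoint blocks) at a default
  effect of 5 noise SDs = 1.5 log2 units, chosen so default runs
  produce fold-change-passing DE features as the design implies;
  recovery and null studies set their own effect sizes explicitly.
* **Peaks.** A 200 bp peak is planted with its midpoint inside the
  strand-aware upstream window of a seeded `bound_fraction` (default
  0.117) of eligible lncRNAs — eligible meaning the window fits on the
  chromosome; planted midpoints are rejection-sampled out of all other
  lncRNAs' windows and background peaks out of every window, so the
  planted bound/unbound truth is exact, not approximate.

`simulate_signature_matrix` is a genome-free shortcut producing
feature-level class-structured matrices for classifier and calibration
studies (2 000 features × 80 samples runs in ~1 s, which keeps the whole
validation suite fast at the problem sizes it states).

## Pipeline

Stage outputs are plain TSV/GTF/BED/JSON; the manifest records the
effective config, seed, row counts and SHA-256 checksums, and the
report re-derives every number from the files on disk (no report-only
computation). Partial outputs of a failing stage are deleted and the
error names the stage. Limitations: two-group comparisons against a
single reference only (no multi-factor models or FDR), no peak calling
or motif analysis, no raw-CEL processing or normalization — inputs are
a preprocessed probe intensity matrix and a precomputed probe-alignment
table.
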