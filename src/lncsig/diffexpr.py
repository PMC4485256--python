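"""Differential expression with an empirical-Bayes moderated t-statistic.

Two-group comparisons against a reference condition on log2 intensities.
Per-feature residual variances are shrunk toward a common prior estimated
by method of moments on the log variances (the classic moderated-t
construction for small-sample microarray designs). Selection is
fold-change-primary: linear fold change > ``fc_up`` or < ``fc_down`` plus
an unadjusted p-value cutoff.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

D0_CAP = 1e6  # above this the prior df is treated as infinite


@dataclass(frozen=True)
class DEConfig:
    """Fold-change-primary selection thresholds."""

    fc_up: float = 2.0
    fc_down: float = 0.5
    p_cutoff: float = 0.05

    def __post_init__(self) -> None:
        if not self.fc_up > 1:
            raise ValueError("fc_up must exceed 1")
        if not 0 < self.fc_down < 1:
            raise ValueError("fc_down must be in (0, 1)")
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must be in (0, 1)")


def _trigamma_inverse(y: float, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the monotone decreasing trigamma; the 1/x + 1/(2x^2) asymptote
    gives the start. Returns inf for y <= 0.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def estimate_prior(s2: np.ndarray, df: float, tol: float = 1e-8) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Matches mean and variance of ``log(s2)`` against the scaled-F model:
    ``e_g = log s2_g - digamma(df/2) + log(df/2)`` has mean
    ``log s0^2 + digamma(d0/2) - log(d0/2)`` and variance
    ``trigamma(df/2) + trigamma(d0/2)``. d0 above 1e6 is reported as inf.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2:
        raise ValueError("need at least 2 features to estimate the variance prior")
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - special.polygamma(1, df / 2)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    half_d0 = _trigamma_inverse(float(excess), tol=tol)
    d0 = 2 * half_d0
    if d0 > D0_CAP:
        return np.inf, float(np.exp(e_mean))
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return float(d0), s0_sq


def fit_moderated_t(
    expr: pd.DataFrame,
    labels: pd.Series,
    condition: str,
    reference: str,
    categories: pd.Series | None = None,
) -> pd.DataFrame:
    """Moderated two-group t-test of ``condition`` versus ``reference``.

    Per feature g: ``log2fc = mean(condition) - mean(reference)``; pooled
    residual variance s_g^2 on n1+n2-2 df; moderated variance
    ``s~_g^2 = (d0 s0^2 + df s_g^2) / (d0 + df)``;
    ``t = log2fc / (s~_g sqrt(1/n1 + 1/n2))`` with d0 + df degrees of
    freedom (normal reference when d0 is infinite). P-values are two-sided
    and unadjusted.
    """
    labels = labels.reindex(expr.columns)
    g1 = expr.loc[:, labels == condition]
    g2 = expr.loc[:, labels == reference]
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"need >=2 samples per group, got {n1} ({condition}) vs {n2} ({reference})"
        )
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 features")

    x1, x2 = g1.to_numpy(float), g2.to_numpy(float)
    log2fc = x1.mean(axis=1) - x2.mean(axis=1)
    df_resid = n1 + n2 - 2
    rss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = rss / df_resid

    # zero-variance features are legal (shrunk toward the prior) but are
    # excluded from the moment-matching fit, which works on log variances
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValueError("need >=2 features with positive residual variance")
    d0, s0_sq = estimate_prior(positive, df_resid)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / se, 0.0)
    t_mod = np.where((se == 0) & (log2fc == 0), 0.0, t_mod)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fc": np.exp2(log2fc),
            "s2": s2,
            "s2_tilde": s2_tilde,
            "t_mod": t_mod,
            "df": df_total,
            "p": p,
        },
        index=expr.index,
    )
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    out.attrs["comparison"] = f"{condition}_vs_{reference}"
    if categories is not None:
        out["category"] = categories.reindex(out.index)
    return out


def select_de(result: pd.DataFrame, config: DEConfig = DEConfig()) -> pd.DataFrame:
    """Partition features into up / down / unchanged (strict inequalities)."""
    up = (result["fc"] > config.fc_up) & (result["p"] < config.p_cutoff)
    down = (result["fc"] < config.fc_down) & (result["p"] < config.p_cutoff)
    out = result.copy()
    out["direction"] = np.where(up, "up", np.where(down, "down", "unchanged"))
    return out


def de_sets(selected: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(up, down) feature-id sets from a :func:`select_de` table."""
    return (
        set(selected.index[selected["direction"] == "up"]),
        set(selected.index[selected["direction"] == "down"]),
    )


def category_enrichment(
    de_set: set[str], universe_categories: pd.Series, category: str
) -> dict:
    """Pearson chi-square (no continuity correction) on a 2x2 table.

    Rows: DE membership; columns: category membership within the universe
    of all annotated lncRNAs. Returns the statistic, two-sided p on 1 df,
    the table, and a low-expected-count warning flag.
    """
    universe = set(universe_categories.index)
    if not de_set <= universe:
        raise ValueError("de_set must be a subset of the annotated universe")
    in_cat = set(universe_categories.index[universe_categories == category])
    a = len(de_set & in_cat)
    b = len(de_set - in_cat)
    c = len(in_cat - de_set)
    d = len(universe - in_cat - de_set)
    table = np.array([[a, b], [c, d]], dtype=float)
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    return {
        "category": category,
        "chi2": float(chi2),
        "p": float(p),
        "table": table,
        "de_fraction_in_category": a / max(a + b, 1),
        "low_expected": bool((expected < 1).any()),
    }


def intersect_de_sets(named_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Exclusive region counts of the Venn partition of named sets.

    One row per non-empty combination of set membership; exclusive region
    counts sum to the union size. Membership lists are kept in the
    ``members`` column for export.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least 2 named sets")
    names = sorted(named_sets)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set.union(
                set(), *(named_sets[n] for n in names if n not in combo)
            )
            exclusive = inside - outside
            rows.append(
                {
                    "region": "&".join(combo),
                    "n_sets": r,
                    "exclusive_count": len(exclusive),
                    "total_intersection": len(inside),
                    "members": ",".join(sorted(exclusive)),
                }
            )
    return pd.DataFrame(rows)
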