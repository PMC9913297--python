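"""Moderated differential expression on ΔCt values.

Two-group comparisons (2D vs 3D culture, or CD133+ vs CD133−) on the
global-mean-normalised ΔCt matrix.  With only two biological replicates per
group, per-gene variance estimates are hopeless on their own; residual
variances are therefore shrunk toward a common prior by empirical Bayes,
giving a moderated t-statistic with augmented degrees of freedom — the same
rationale as the moderated linear-model approach standard for array data.

The significance call mirrors the validation rule used for array targets:
BH-adjusted Q < 0.1, an absolute group ΔCt difference > 2 cycles, and the
gene not excluded by the Ct detection filter (Ct > 35).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .ct_model import CT_DETECTION_LIMIT, CT_HIGH_EXPRESSION, ExpressionTier

Q_CUTOFF = 0.1
DCT_CUTOFF = 2.0


@dataclass
class DEResult:
    """Per-gene two-group differential-expression result on ΔCt."""

    gene: str
    mean_dct_a: float
    mean_dct_b: float
    diff: float          # mean_dct_a − mean_dct_b; positive ⇒ more RNA in B
    t_mod: float
    p: float
    q: float = float("nan")
    excluded: bool = False
    significant: bool = False


class CtExclusionMode(enum.Enum):
    """Which population's high Ct triggers the detection-filter exclusion."""

    BOTH = "both"        # excluded when mean Ct > 35 in both groups
    GROUP_A = "group_a"  # excluded when mean Ct > 35 in group A (e.g. 2D cells)


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(y) = x by Newton iteration (x > 0)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting point for both tails
    for _ in range(60):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior to sample variances.

    Models s² ~ s0² · F(df, d0) via the moments of log s², returning
    (d0, s0²).  d0 = inf when the log-variances are no more dispersed than
    chi²/df sampling alone explains.  Nonpositive variances are ignored for
    moment estimation (they still get shrunk by the caller).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        # degenerate: no spread information; infinitely strong prior
        s0 = float(s2[ok].mean()) if ok.any() else 0.0
        return np.inf, s0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0sq = float(np.exp(e_mean))
    else:
        d0 = float(2.0 * _trigamma_inverse(excess))
        s0sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def moderated_de(
    dct_matrix: pd.DataFrame,
    groups: Mapping[str, str],
    *,
    prior_df: float | None = None,
) -> list[DEResult]:
    """Moderated two-group comparison for every gene of a ΔCt matrix.

    Parameters
    ----------
    dct_matrix
        Genes × samples ΔCt table; columns are sample ids.
    groups
        Sample id → group label.  Exactly two labels must occur; the
        lexicographically smaller one is group A (2D before 3D).
    prior_df
        Override for the prior degrees of freedom d0.  ``prior_df=0``
        disables shrinkage, recovering the ordinary pooled t-test.

    Returns per-gene results with ``q`` left NaN (apply :func:`bh_adjust` or
    :func:`apply_significance_filter` downstream).
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    a_cols = [s for s in dct_matrix.columns if groups.get(s) == labels[0]]
    b_cols = [s for s in dct_matrix.columns if groups.get(s) == labels[1]]
    if not a_cols or not b_cols:
        raise ValueError("each group needs at least one sample")
    if dct_matrix.shape[0] < 2:
        raise ValueError("need at least two genes")

    xa = dct_matrix[a_cols].to_numpy(dtype=float)
    xb = dct_matrix[b_cols].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    diff = mean_a - mean_b

    df_resid = na + nb - 2
    rss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + (
        (xb - mean_b[:, None]) ** 2
    ).sum(axis=1)
    if df_resid > 0:
        s2 = rss / df_resid
    else:
        s2 = np.zeros_like(rss)

    if prior_df is None:
        d0, s0sq = fit_f_dist(s2, df_resid) if df_resid > 0 else (np.inf, 0.0)
    else:
        d0 = float(prior_df)
        _, s0sq = fit_f_dist(s2, df_resid) if df_resid > 0 and d0 > 0 else (0.0, 0.0)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = 1e6  # effectively normal tails
    elif d0 == 0:
        s2_post = s2
        df_total = df_resid
    else:
        s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (diff != 0), np.sign(diff) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (diff == 0), 1.0, p)

    return [
        DEResult(
            gene=str(g),
            mean_dct_a=float(mean_a[i]),
            mean_dct_b=float(mean_b[i]),
            diff=float(diff[i]),
            t_mod=float(t[i]),
            p=float(min(p[i], 1.0)),
        )
        for i, g in enumerate(dct_matrix.index)
    ]


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up Q-values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def apply_significance_filter(
    results: Sequence[DEResult],
    ct_by_group: Mapping[str, tuple[float, float]],
    *,
    q_cut: float = Q_CUTOFF,
    dct_cut: float = DCT_CUTOFF,
    ct_detect: float = CT_DETECTION_LIMIT,
    mode: CtExclusionMode = CtExclusionMode.BOTH,
) -> list[DEResult]:
    """Attach Q-values and the validation-rule significance call.

    ``ct_by_group`` maps gene → (mean raw Ct in group A, mean raw Ct in
    group B).  A gene is excluded when its Ct exceeds ``ct_detect`` in both
    populations (default) or, under ``GROUP_A`` mode, in group A alone.
    Significance requires Q < ``q_cut``, |ΔCt difference| > ``dct_cut`` and
    no exclusion.
    """
    missing = [r.gene for r in results if r.gene not in ct_by_group]
    if missing:
        raise ValueError(f"genes missing from Ct table: {missing}")
    qvals = bh_adjust([r.p for r in results])
    out: list[DEResult] = []
    for r, q in zip(results, qvals):
        ct_a, ct_b = ct_by_group[r.gene]
        if mode is CtExclusionMode.BOTH:
            excluded = ct_a > ct_detect and ct_b > ct_detect
        else:
            excluded = ct_a > ct_detect
        significant = (q < q_cut) and (abs(r.diff) > dct_cut) and not excluded
        out.append(
            DEResult(
                gene=r.gene,
                mean_dct_a=r.mean_dct_a,
                mean_dct_b=r.mean_dct_b,
                diff=r.diff,
                t_mod=r.t_mod,
                p=r.p,
                q=float(q),
                excluded=excluded,
                significant=significant,
            )
        )
    return out


def volcano_table(
    results: Sequence[DEResult],
    *,
    q_cut: float = Q_CUTOFF,
    dct_cut: float = DCT_CUTOFF,
) -> pd.DataFrame:
    """Volcano-plot table: gene, ΔCt difference, Q and category.

    Positive ``diff`` (group-B ΔCt below group-A) means the gene is
    increased in the 3D population.  Categories: ``increased_3d``,
    ``decreased_3d`` and ``ns``.
    """
    if not results:
        raise ValueError("no results to tabulate")
    rows = []
    for r in results:
        if r.q < q_cut and r.diff > dct_cut and not r.excluded:
            cat = "increased_3d"
        elif r.q < q_cut and r.diff < -dct_cut and not r.excluded:
            cat = "decreased_3d"
        else:
            cat = "ns"
        rows.append({"gene": r.gene, "diff": r.diff, "q": r.q, "category": cat})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Detection-set (Venn) analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectionSummary:
    """Shared/unique detection counts between two samples' tier maps."""

    shared_detected: int
    shared_high: int
    not_detected_both: int
    unique_undetected_a: int
    unique_undetected_b: int
    panel_size: int
    percentages: dict[str, int]


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def detection_set_analysis(
    tiers_a: Mapping[str, ExpressionTier],
    tiers_b: Mapping[str, ExpressionTier],
) -> DetectionSummary:
    """Venn-style comparison of which panel genes the two populations detect.

    A gene is "detected" in a population when its tier is HIGH or EXPRESSED.
    ``shared_high`` counts genes HIGH in both.  Percentages are of panel
    size, rounded to the nearest integer (half away from zero).
    """
    if set(tiers_a) != set(tiers_b):
        raise ValueError("tier maps cover different gene panels")
    panel = sorted(tiers_a)
    n = len(panel)

    def detected(t: ExpressionTier) -> bool:
        return t is not ExpressionTier.NOT_DETECTED

    shared_detected = sum(1 for g in panel if detected(tiers_a[g]) and detected(tiers_b[g]))
    shared_high = sum(
        1
        for g in panel
        if tiers_a[g] is ExpressionTier.HIGH and tiers_b[g] is ExpressionTier.HIGH
    )
    nd_both = sum(1 for g in panel if not detected(tiers_a[g]) and not detected(tiers_b[g]))
    uniq_a = sum(1 for g in panel if not detected(tiers_a[g]) and detected(tiers_b[g]))
    uniq_b = sum(1 for g in panel if detected(tiers_a[g]) and not detected(tiers_b[g]))

    counts = {
        "shared_detected": shared_detected,
        "shared_high": shared_high,
        "not_detected_both": nd_both,
        "unique_undetected_a": uniq_a,
        "unique_undetected_b": uniq_b,
    }
    percentages = {
        k: _round_half_away(100.0 * v / n) if n else 0 for k, v in counts.items()
    }
    return DetectionSummary(panel_size=n, percentages=percentages, **counts)


def results_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    """DE results as the standard output table."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "mean_dct_2d": r.mean_dct_a,
                "mean_dct_3d": r.mean_dct_b,
                "diff": r.diff,
                "t": r.t_mod,
                "p": r.p,
                "q": r.q,
                "excluded": r.excluded,
                "significant": r.significant,
            }
            for r in results
        ]
    )
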