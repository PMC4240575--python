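"""Paired tumor-vs-control cohort comparison (Wilcoxon signed-rank).

The test is implemented from first principles because exactness matters at
the study's sample size (n = 12): zero differences are dropped (classic
Wilcoxon convention), absolute differences are ranked with midranks for
ties, and the two-sided p-value is computed by full enumeration of the
2^n sign assignments for n <= 25 (dynamic programming over rank sums),
falling back to the normal approximation with tie and continuity
correction above. ``scipy.stats.wilcoxon`` serves as an independent
cross-check in the test suite, never as the implementation.

``simulate_cohort`` draws per-subject generator parameters around the
tumor/control preset means (between-subject spread taken from the
published cohort standard deviations), grows one vessel tree per VOI and
tabulates its ground-truth morphometry — a desk-scale Monte-Carlo model of
the 12-patient study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphometry import METRICS
from .phantom import (
    PhantomSpec,
    _truncated_normal,
    control_preset,
    generate_vessel_tree,
    tumor_preset,
)

__all__ = ["TestResult", "wilcoxon_signed_rank", "compare_cohorts", "simulate_cohort"]

EXACT_MAX_N = 25


@dataclass
class TestResult:
    metric: str
    n_used: int
    w_statistic: float
    p_value: float
    significant: bool
    alpha: float
    method: str  # "exact" or "normal"


def _exact_sf_cdf(double_ranks: np.ndarray, w2: float) -> tuple[float, float]:
    """P(W+ >= w) and P(W+ <= w) under H0, on doubled-rank integer scale."""
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        counts[r:] += counts[: total + 1 - r].copy()
    denom = counts.sum()  # = 2^n
    w2i = int(round(w2))
    sf = counts[w2i:].sum() / denom
    cdf = counts[: w2i + 1].sum() / denom
    return float(sf), float(cdf)


def wilcoxon_signed_rank(
    differences,
    alpha: float = 0.05,
    metric: str = "",
    zero_method: str = "drop",
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (``zero_method='drop'``); ``'pratt'`` keeps
    them in the ranking but excludes them from the sums. W = min(W+, W-).
    """
    d = np.asarray(differences, dtype=np.float64)
    d = d[~np.isnan(d)]
    if zero_method not in ("drop", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    nonzero = d != 0
    if not nonzero.any():
        raise ValueError("all paired differences are zero: test undefined")
    if zero_method == "drop":
        d = d[nonzero]
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))  # midranks for ties
    if zero_method == "pratt":
        ranks = ranks[d != 0]
        d = d[d != 0]
    n = len(d)
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if n <= EXACT_MAX_N:
        sf, cdf = _exact_sf_cdf(np.round(2 * ranks), 2 * w_plus)
        p = min(1.0, 2.0 * min(sf, cdf))
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        # tie correction on the rank variance
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        dev = w_plus - mu
        cc = 0.5 * np.sign(dev) if dev != 0 else 0.0
        z = (w_plus - mu - cc) / math.sqrt(var)
        from scipy.stats import norm

        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
        method = "normal"
    return TestResult(
        metric=metric, n_used=n, w_statistic=w, p_value=p,
        significant=p < alpha, alpha=alpha, method=method,
    )


def _fmt(mean: float, sd: float) -> str:
    return f"{mean:.3g}±{sd:.3g}"


def compare_cohorts(table: pd.DataFrame, alpha: float = 0.05):
    """One Wilcoxon signed-rank test per metric on a paired cohort table.

    ``table`` needs columns ``tumor_<metric>`` and ``control_<metric>`` for
    each of the six metrics (missing pairs are dropped per metric, with the
    n actually used reported). Returns ``(results, report)`` where
    ``report`` is a human-readable summary. No multiple-testing correction
    is applied (single-comparison p-values, as in the original analysis).
    """
    results: list[TestResult] = []
    lines = ["Paired tumor vs control comparison (Wilcoxon signed-rank, two-sided)", ""]
    for m in METRICS:
        t = table[f"tumor_{m}"].astype(float)
        c = table[f"control_{m}"].astype(float)
        ok = t.notna() & c.notna()
        diffs = (t[ok] - c[ok]).to_numpy()
        if not (diffs != 0).any():
            # identical pairs carry no evidence of a difference
            res = TestResult(metric=m, n_used=0, w_statistic=0.0, p_value=1.0,
                             significant=False, alpha=alpha, method="degenerate")
        else:
            res = wilcoxon_signed_rank(diffs, alpha=alpha, metric=m)
        results.append(res)
        star = " *" if res.significant else ""
        lines.append(
            f"{m:28s} tumor {_fmt(t[ok].mean(), t[ok].std()):>14s}  "
            f"control {_fmt(c[ok].mean(), c[ok].std()):>14s}  "
            f"n={res.n_used:2d}  W={res.w_statistic:6.1f}  p={res.p_value:.4g}{star}"
        )
    lines += ["", f"* significant at alpha={alpha} (no multiple-testing correction applied;"
              " p-values are per-metric, as in the original analysis)"]
    return results, "\n".join(lines)


#: between-subject standard deviations of the generator-level parameters,
#: taken from the published cohort spread (branches/cm^3, mm, mm)
COHORT_SPREAD = {
    "tumor": {"density_sd": 1.8, "length_sd": 1.5, "diameter_sd": 0.117},
    "control": {"density_sd": 0.6, "length_sd": 2.8, "diameter_sd": 0.146},
}

# VOI grids matching the published mean VOI volumes (9.8 vs 13.0 cm^3)
_TUMOR_GRID = (64, 64, 62)  # 9.91 cm^3 at 0.31 x 0.31 x 0.40 mm
_CONTROL_GRID = (70, 70, 69)  # 12.99 cm^3


def _truth_metrics(tree) -> dict:
    lengths = tree.segment_lengths_mm()
    voi = tree.spec.voi_volume_cm3
    total_len = float(lengths.sum())
    total_vol = tree.total_volume_mm3()
    return {
        "total_length_mm_per_cm3": total_len / voi,
        "total_surface_mm2_per_cm3": tree.total_lateral_surface_mm2() / voi,
        "total_volume_mm3_per_cm3": total_vol / voi,
        "n_branches_per_cm3": len(lengths) / voi,
        "mean_branch_length_mm": float(lengths.mean()) if len(lengths) else np.nan,
        "mean_diameter_mm": (
            2.0 * math.sqrt(total_vol / (math.pi * total_len)) if total_len > 0 else np.nan
        ),
    }


def simulate_cohort(n_subjects: int = 12, seed: int = 0) -> pd.DataFrame:
    """Simulate one paired cohort at the generator (ground-truth) level.

    Per subject, tumor and control generator parameters are drawn around
    the preset means with the published between-subject spread, one vessel
    tree is grown per VOI, and its exact morphometry is tabulated.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    seg_seeds = rng.integers(0, 2**31 - 1, size=(n_subjects, 2))
    rows = []
    for subj in range(n_subjects):
        row: dict = {"subject": subj + 1}
        for arm, preset, grid, seg_seed in (
            ("tumor", tumor_preset, _TUMOR_GRID, seg_seeds[subj, 0]),
            ("control", control_preset, _CONTROL_GRID, seg_seeds[subj, 1]),
        ):
            spread = COHORT_SPREAD[arm]
            base = preset(grid_shape=grid, seed=int(seg_seed))
            density = _truncated_normal(rng, base.branches_per_cm3_target, spread["density_sd"], 0.2)
            length = _truncated_normal(rng, base.mean_branch_length_mm, spread["length_sd"], 1.6)
            diameter = _truncated_normal(rng, base.diameter_mean_mm, spread["diameter_sd"], 0.31)
            spec = preset(
                grid_shape=grid,
                seed=int(seg_seed),
                branches_per_cm3_target=density,
                mean_branch_length_mm=length,
                diameter_mean_mm=diameter,
            )
            tree = generate_vessel_tree(spec)
            for k, v in _truth_metrics(tree).items():
                row[f"{arm}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
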