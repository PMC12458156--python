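"""Paired nonparametric method comparison on per-micrograph metrics.

For each (competitor, dataset) pair the per-micrograph metric values of a
reference method and the competitor are compared with the Wilcoxon
signed-rank test.  Effect sizes are reported in two forms: the printed
convention ``r = z / N`` and the conventional normalization
``r = z / sqrt(N)`` — the two disagree in the literature this protocol
derives from, so both are carried and labeled.  Raw p-values are adjusted
per metric family with the Benjamini-Hochberg step-up FDR procedure.

Wilcoxon details: zero differences are dropped (Wilcoxon's original
treatment; the dropped count is reported), tied absolute differences are
mid-ranked, and the two-sided p-value is exact (distribution of W+ built
by dynamic programming over rank sums) when N <= 15 with no ties,
otherwise a tie-corrected normal approximation with continuity
correction.  The z sign is positive when the first (reference) sample
tends to exceed the second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.special import ndtr
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "effect_size",
    "bh_adjust",
    "threshold_success_rate",
    "compare_methods",
]

_EXACT_N_MAX = 15


@dataclass
class WilcoxonResult:
    """Signed-rank test outcome.

    ``informative`` is False when every paired difference is zero; then no
    p-value exists (``w``, ``z`` and ``p`` are NaN) rather than a
    misleading one.
    """

    w: float  # W+ : sum of ranks of positive differences
    z: float  # normal-approximation score (continuity- and tie-corrected)
    p: float  # two-sided p-value
    n_used: int  # pairs remaining after zero-difference removal
    n_zero: int  # zero differences dropped
    method: str  # "exact" | "normal" | "none"

    @property
    def informative(self) -> bool:
        return self.method != "none"


def _exact_wplus_pvalue(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p for W+ by DP over the 2^n sign assignments.

    Ranks must be distinct integers 1..n (no ties).  The distribution of
    W+ under the null is built by polynomial multiplication; the p-value
    is ``2 * min(P(W+ <= w), P(W+ >= w))`` capped at 1.
    """
    total = int(ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    probs = counts / counts.sum()
    w = int(round(w_obs))
    lower = probs[: w + 1].sum()
    upper = probs[w:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(x, y=None) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired samples (or on differences).

    Pass two equal-length samples, or a single array of differences.
    """
    x = np.asarray(x, dtype=np.float64)
    d = x if y is None else x - np.asarray(y, dtype=np.float64)
    if d.size < 1:
        raise ValueError("need at least one paired observation")
    n_zero = int(np.count_nonzero(d == 0))
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(
            w=np.nan, z=np.nan, p=np.nan, n_used=0, n_zero=n_zero, method="none"
        )
    absd = np.abs(d)
    ranks = rankdata(absd)  # midranks for ties
    w_plus = float(ranks[d > 0].sum())

    mean = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 from the null variance
    _, tie_counts = np.unique(absd, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    dev = w_plus - mean
    if var <= 0:
        z = 0.0
    else:
        cc = 0.5 * np.sign(dev)  # continuity correction toward the mean
        z = (dev - cc) / np.sqrt(var)

    has_ties = len(tie_counts) < n
    if n <= _EXACT_N_MAX and not has_ties:
        p = _exact_wplus_pvalue(ranks, w_plus)
        method = "exact"
    else:
        p = float(min(1.0, 2.0 * ndtr(-abs(z))))
        method = "normal"
    return WilcoxonResult(
        w=w_plus, z=float(z), p=p, n_used=n, n_zero=n_zero, method=method
    )


def effect_size(z: float, n: int) -> tuple[float, float]:
    """Rank-biserial-style effect sizes from the z score.

    Returns ``(r_paper, r_conventional) = (z / N, z / sqrt(N))``: the
    first reproduces the printed convention, the second the standard
    normalization.  Neither is claimed as the uniquely correct form.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return z / n, z / np.sqrt(n)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def threshold_success_rate(values, thresholds) -> np.ndarray:
    """Fraction of per-micrograph values >= each threshold."""
    v = np.asarray(values, dtype=np.float64)
    taus = np.atleast_1d(np.asarray(thresholds, dtype=np.float64))
    if v.size == 0:
        raise ValueError("values must be non-empty")
    return np.array([(v >= t).mean() for t in taus])


def compare_methods(
    table: pd.DataFrame,
    reference: str,
    metrics=("precision", "recall"),
    method_col: str = "method",
    dataset_col: str = "dataset",
    unit_col: str = "micrograph",
) -> pd.DataFrame:
    """Paired comparison of every competitor against a reference method.

    ``table`` is long-format: one row per (method, dataset, micrograph)
    with one column per metric.  For each metric, each (competitor,
    dataset) pair yields one Wilcoxon test on the per-micrograph paired
    values (so 5 competitors x 6 datasets give 30 tests per metric);
    Benjamini-Hochberg adjustment is applied within each metric family.

    Raises if a competitor's micrograph set does not align with the
    reference's for some dataset.
    """
    if reference not in set(table[method_col]):
        raise ValueError(f"reference method {reference!r} not present in table")
    methods = [m for m in table[method_col].unique() if m != reference]
    datasets = list(table[dataset_col].unique())

    rows = []
    for metric in metrics:
        family = []
        for comp in methods:
            for ds in datasets:
                ref_rows = table[
                    (table[method_col] == reference) & (table[dataset_col] == ds)
                ].set_index(unit_col)
                comp_rows = table[
                    (table[method_col] == comp) & (table[dataset_col] == ds)
                ].set_index(unit_col)
                if set(ref_rows.index) != set(comp_rows.index):
                    raise ValueError(
                        f"micrograph sets for method {comp!r} do not align with "
                        f"reference on dataset {ds!r}"
                    )
                units = sorted(ref_rows.index)
                ref_v = ref_rows.loc[units, metric].to_numpy(dtype=float)
                comp_v = comp_rows.loc[units, metric].to_numpy(dtype=float)
                res = wilcoxon_signed_rank(ref_v, comp_v)
                if res.informative:
                    r_paper, r_conv = effect_size(res.z, res.n_used)
                else:
                    r_paper = r_conv = np.nan
                family.append(
                    {
                        "method": comp,
                        "dataset": ds,
                        "metric": metric,
                        "n_pairs": len(units),
                        "n_zero_dropped": res.n_zero,
                        "median_ref": float(np.median(ref_v)),
                        "median_comp": float(np.median(comp_v)),
                        "W": res.w,
                        "z": res.z,
                        "p_raw": res.p,
                        "r_paper": r_paper,
                        "r_conventional": r_conv,
                        "test": res.method,
                    }
                )
        fam = pd.DataFrame(family)
        informative = fam["test"] != "none"
        fam["p_adj"] = np.nan
        if informative.any():
            fam.loc[informative, "p_adj"] = bh_adjust(
                fam.loc[informative, "p_raw"].to_numpy()
            )
        rows.append(fam)
    return pd.concat(rows, ignore_index=True)
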