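"""Group comparisons, ddCT relative expression, and CV-based power analysis.

``ddct_expression`` implements relative qPCR quantitation: per-sample delta
CT against the mean of the reference genes, delta-delta CT against the
calibrator-group mean, fold change 2^(-ddCT).  ``group_compare`` dispatches
the standard designs (one-way ANOVA + Tukey, Kruskal-Wallis + Dunn,
Student's t, rank-sum).  ``power_sample_size`` converts a phenotype
difference expressed as a fraction of the mean and a coefficient of
variation into a standardized effect ``d = diff / cv`` and sizes groups via
the noncentral-t power function.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PowerSpec",
    "CompareResult",
    "ddct_expression",
    "group_compare",
    "power_sample_size",
    "power_at_n",
]

DESIGNS = ("anova_tukey", "kruskal_dunn", "t_test", "ranksum")


# ---------------------------------------------------------------------------
# ddCT
# ---------------------------------------------------------------------------


def ddct_expression(
    ct: pd.DataFrame,
    reference_genes: Sequence[str],
    calibrator: Sequence,
    targets: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Fold changes per sample x target gene by the ddCT method.

    Parameters
    ----------
    ct:
        CT table, samples as rows (index = sample ids), genes as columns.
    reference_genes:
        Reference genes; a sample's delta CT subtracts their per-sample
        arithmetic-mean CT (equivalent to a geometric mean of expression).
    calibrator:
        Sample ids forming the calibrator group; delta-delta CT subtracts
        the calibrator-group mean delta CT per gene, so the calibrator
        group's mean fold change is exactly 1.
    targets:
        Target genes; defaults to every non-reference column.
    """
    missing = [g for g in reference_genes if g not in ct.columns]
    if missing:
        raise ValueError(f"reference genes absent from table: {missing}")
    if len(reference_genes) < 1:
        raise ValueError("need at least one reference gene")
    if targets is None:
        targets = [c for c in ct.columns if c not in set(reference_genes)]
    missing = [g for g in targets if g not in ct.columns]
    if missing:
        raise ValueError(f"target genes absent from table: {missing}")
    calibrator = list(calibrator)
    if not calibrator:
        raise ValueError("calibrator group is empty")
    absent = [s for s in calibrator if s not in ct.index]
    if absent:
        raise ValueError(f"calibrator samples absent from table: {absent}")
    values = ct[list(dict.fromkeys([*reference_genes, *targets]))]
    if values.isna().any().any() or not np.isfinite(values.to_numpy()).all():
        raise ValueError("CT table contains missing or non-finite values")

    ref_mean = ct[list(reference_genes)].mean(axis=1)
    dct = ct[list(targets)].sub(ref_mean, axis=0)
    ddct = dct - dct.loc[calibrator].mean(axis=0)
    return np.power(2.0, -ddct)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompareResult:
    design: str
    statistic: float
    p_value: float
    pairwise: Optional[pd.DataFrame] = None  # all-pairs table for omnibus designs


def _dunn_pairwise(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z-tests on mean ranks with tie correction (two-sided).

    Raw p-values plus Bonferroni-adjusted ones over all pairs.
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # tie correction for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    sizes, mean_ranks, start = {}, {}, 0
    for g in names:
        k = groups[g].size
        mean_ranks[g] = float(np.mean(ranks[start : start + k]))
        sizes[g] = k
        start += k
    rows = []
    n_pairs = len(names) * (len(names) - 1) // 2
    for a, b in combinations(names, 2):
        var = (n_total * (n_total + 1) / 12.0 - tie_term) * (1 / sizes[a] + 1 / sizes[b])
        z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
        p = 2 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "statistic": z,
                     "p_value": p, "p_adjusted": min(p * n_pairs, 1.0)})
    return pd.DataFrame(rows)


def group_compare(groups: Mapping[str, Sequence[float]], design: str) -> CompareResult:
    """Compare groups under the declared design.

    ``anova_tukey`` and ``kruskal_dunn`` accept two or more groups and
    return an all-pairs post hoc table; ``t_test`` (Student, equal
    variances) and ``ranksum`` (Mann-Whitney U) require exactly two.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {DESIGNS}")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 values")
        if not np.isfinite(arr).all():
            raise ValueError(f"group {name!r} contains non-finite values")
    values = list(arrays.values())

    if design in ("t_test", "ranksum"):
        if len(arrays) != 2:
            raise ValueError(f"design {design!r} requires exactly 2 groups, got {len(arrays)}")
        if design == "t_test":
            res = sps.ttest_ind(values[0], values[1], equal_var=True)
        else:
            res = sps.mannwhitneyu(values[0], values[1], alternative="two-sided")
        return CompareResult(design=design, statistic=float(res.statistic),
                             p_value=float(res.pvalue))

    if design == "anova_tukey":
        f_res = sps.f_oneway(*values)
        tukey = sps.tukey_hsd(*values)
        names = list(arrays)
        rows = [
            {
                "group_a": names[i],
                "group_b": names[j],
                "statistic": float(tukey.statistic[i, j]),
                "p_value": float(tukey.pvalue[i, j]),
            }
            for i, j in combinations(range(len(names)), 2)
        ]
        return CompareResult(design=design, statistic=float(f_res.statistic),
                             p_value=float(f_res.pvalue), pairwise=pd.DataFrame(rows))

    kw = sps.kruskal(*values)
    return CompareResult(design=design, statistic=float(kw.statistic),
                         p_value=float(kw.pvalue), pairwise=_dunn_pairwise(arrays))


# ---------------------------------------------------------------------------
# power / sample size
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerSpec:
    """Phenotype-difference power specification.

    ``diff`` is the detectable difference as a fraction of the mean and
    ``cv`` the coefficient of variation of the method, so the standardized
    effect size is ``d = diff / cv``.
    """

    cv: float
    diff: float
    alpha: float = 0.05
    power: float = 0.90
    design: str = "two_sample_t"

    def __post_init__(self) -> None:
        if not self.cv > 0:
            raise ValueError("cv must be > 0")
        if not self.diff > 0:
            raise ValueError("diff must be > 0 (d = 0 is unattainable)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.design not in ("two_sample_t", "one_sample_vs_reference"):
            raise ValueError(f"unknown design {self.design!r}")

    @property
    def effect_size(self) -> float:
        return self.diff / self.cv


def power_at_n(n: int, d: float, alpha: float, design: str) -> float:
    """Exact two-sided power of the t-test at group size n (noncentral t)."""
    if design == "two_sample_t":
        df = 2 * n - 2
        nc = d * np.sqrt(n / 2.0)
    elif design == "one_sample_vs_reference":
        df = n - 1
        nc = d * np.sqrt(n)
    else:
        raise ValueError(f"unknown design {design!r}")
    if df < 1:
        return 0.0
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def power_sample_size(spec: PowerSpec, n_max: int = 1_000_000) -> tuple[int, float]:
    """Minimal per-group n reaching the target power, plus achieved power.

    Searches upward from the normal-approximation guess (power is
    non-decreasing in n for these designs).
    """
    d = spec.effect_size
    z = sps.norm.ppf(1 - spec.alpha / 2) + sps.norm.ppf(spec.power)
    k = 2.0 if spec.design == "two_sample_t" else 1.0
    guess = int(np.floor(k * (z / d) ** 2)) - 2
    n = max(2, guess)
    while n > 2 and power_at_n(n - 1, d, spec.alpha, spec.design) >= spec.power:
        n -= 1
    while power_at_n(n, d, spec.alpha, spec.design) < spec.power:
        n += 1
        if n > n_max:
            raise ValueError(f"required n exceeds {n_max}; effect d={d:.3g} too small")
    return n, power_at_n(n, d, spec.alpha, spec.design)
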