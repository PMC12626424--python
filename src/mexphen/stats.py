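"""Shared resampling statistics.

Nonparametric machinery used by every stage of the pipeline: two-sided
Wilcoxon rank-sum tests, bootstrap-resampled Wilcoxon median p-values
(10,000 resamples of 50 points per group by default), Benjamini-Hochberg
adjustment, and a rank-based two-way ANOVA convenience for designs with
two founder lines.

The bootstrap median-p procedure summarises the p-value distribution of
many subsampled tests rather than a single test; it is robust to unequal
replicate structure across experiments, at the cost of not being a
calibrated single test.  Stars are reported on the bands
``*** p<1e-4``, ``** p<1e-3``, ``* p<1e-2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BootstrapSpec",
    "BootstrapResult",
    "wilcoxon_ranksum",
    "bootstrap_wilcoxon",
    "bh_adjust",
    "significance_band",
    "rank_anova_genotype",
]


@dataclass(frozen=True)
class BootstrapSpec:
    """Parameters of the bootstrap-Wilcoxon median-p procedure.

    ``subsample_per_group`` data points are drawn with replacement from
    each group at every iteration (per stratum when experiment strata
    are supplied), a two-sided rank-sum test is run, and the median of
    the resulting p-value distribution is reported.
    """

    n_boot: int = 10_000
    subsample_per_group: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.subsample_per_group < 2:
            raise ValueError("subsample_per_group must be >= 2")


@dataclass
class BootstrapResult:
    median_p: float
    p_quantiles: dict = field(default_factory=dict)  # 5%, 25%, 75%, 95%
    stars: str = "ns"


def wilcoxon_ranksum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when the pooled sample size is at most 20
    and there are no ties; otherwise the normal approximation with tie
    and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    exact = pooled.size <= 20 and np.unique(pooled).size == pooled.size
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=not exact)
    return float(res.pvalue)


def _draw(rng: np.random.Generator, values: np.ndarray, k: int,
          replace: bool) -> np.ndarray:
    return rng.choice(values, size=k, replace=replace)


def bootstrap_wilcoxon(a, b, spec: BootstrapSpec,
                       strata_a: Sequence | None = None,
                       strata_b: Sequence | None = None,
                       replace: bool = True) -> BootstrapResult:
    """Median p over ``spec.n_boot`` subsampled rank-sum tests.

    With ``strata_*`` given (e.g. experiment replicate labels), the
    subsample is drawn per stratum — ``subsample_per_group`` points from
    each stratum of each group — mirroring a per-experiment resampling
    design.  Draws are with replacement by default (``replace=False``
    requires every (stratum of a) group to hold at least the subsample).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(spec.seed)

    def groups_of(values: np.ndarray, strata) -> list[np.ndarray]:
        if strata is None:
            return [values]
        strata = np.asarray(strata)
        return [values[strata == s] for s in np.unique(strata)]

    ga = groups_of(a, strata_a)
    gb = groups_of(b, strata_b)
    k = spec.subsample_per_group
    ps = np.empty(spec.n_boot)
    for i in range(spec.n_boot):
        xa = np.concatenate([_draw(rng, g, k, replace or g.size < k) for g in ga])
        xb = np.concatenate([_draw(rng, g, k, replace or g.size < k) for g in gb])
        ps[i] = wilcoxon_ranksum(xa, xb)
    med = float(np.median(ps))
    q = {p: float(np.quantile(ps, p)) for p in (0.05, 0.25, 0.75, 0.95)}
    return BootstrapResult(median_p=med, p_quantiles=q, stars=significance_band(med))


def significance_band(p: float) -> str:
    """Star band for a p-value: *** <1e-4, ** <1e-3, * <1e-2, else ns."""
    if not np.isfinite(p):
        return "ns"
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 1e-2:
        return "*"
    return "ns"


def bh_adjust(p) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_anova_genotype(values, genotype, founder) -> float:
    """Genotype p-value from a two-way fixed-effects ANOVA on ranks.

    Convenience for designs where two founder lines of the same deletion
    are tested together: values are rank-transformed and modelled as
    ``rank ~ genotype + founder``; the genotype main-effect p is
    returned.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "r": sps.rankdata(np.asarray(values, dtype=float)),
        "genotype": pd.Categorical(genotype),
        "founder": pd.Categorical(founder),
    })
    fit = smf.ols("r ~ C(genotype) + C(founder)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    return float(table.loc["C(genotype)", "PR(>F)"])


def permutation_median_p(values_a, values_b, n_perm: int = 100,
                         subsample: int = 10, seed: int = 0) -> float:
    """Median p over ``n_perm`` rank-sum tests on subsampled groups.

    Each permutation selects ``subsample`` observations per group —
    without replacement when the group is at least that large, with
    replacement otherwise — and runs a two-sided rank-sum test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    ps = np.empty(n_perm)
    for i in range(n_perm):
        xa = rng.choice(a, size=subsample, replace=a.size < subsample)
        xb = rng.choice(b, size=subsample, replace=b.size < subsample)
        ps[i] = wilcoxon_ranksum(xa, xb)
    return float(np.median(ps))
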