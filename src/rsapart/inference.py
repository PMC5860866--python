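"""Model-data statistics: partial correlations, commonality-based variance
partitioning, nonparametric tests, FDR, noise ceilings, and the split-group
reproducibility permutation test.

Variance partitioning follows commonality analysis for three predictors:
the r-squared of all seven subset regressions (A, B, C, AB, AC, BC, ABC,
each with intercept) is decomposed into three unique components, three
pairwise-shared components and one triple-shared component,

    u_A   = r2_ABC - r2_BC                       (cyclic)
    s_AB  = r2_AC + r2_BC - r2_ABC - r2_C        (cyclic)
    s_ABC = r2_A + r2_B + r2_C - r2_AB - r2_AC - r2_BC + r2_ABC

which sum to r2_ABC exactly. Raw components can be negative (suppression);
the percentage view used for Euler-style reporting divides by r2_ABC and
clips at zero, recording that clipping occurred.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .behavior import average_rdms
from .rdm import RDM, correlate_rdms, vectorize_rdm

__all__ = [
    "TestResult",
    "VariancePartition",
    "NoiseCeiling",
    "ReproducibilityResult",
    "partial_correlation",
    "VariancePartitioner",
    "variance_partition",
    "signed_rank_test",
    "fdr_adjust",
    "noise_ceiling",
    "reproducibility_test",
]


# ---------------------------------------------------------------------------
# partial correlation


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of v after least squares on Z (with intercept)."""
    design = np.column_stack([np.ones(len(v)), Z]) if Z.size else np.ones((len(v), 1))
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_correlation(
    y: np.ndarray, x: np.ndarray, covariates: list[np.ndarray] | None = None
) -> float:
    """Pearson correlation of y and x after partialling out the covariates.

    Both y and x are regressed (with intercept) on the covariate set and
    the residuals correlated. With no covariates this reduces to the
    zero-order Pearson correlation.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    covariates = covariates or []
    Z = np.column_stack([np.asarray(c, dtype=float).ravel() for c in covariates]) if covariates else np.empty((len(y), 0))
    if x.shape != y.shape or (Z.size and Z.shape[0] != y.size):
        raise ValueError("all vectors must share one length")
    if Z.shape[1] and np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), Z])) < Z.shape[1] + 1:
        raise ValueError("collinear covariates")
    ry, rx = _residualize(y, Z), _residualize(x, Z)
    if np.std(ry) < 1e-14 or np.std(rx) < 1e-14:
        raise ValueError("zero residual variance after partialling out covariates")
    return float(stats.pearsonr(ry, rx).statistic)


# ---------------------------------------------------------------------------
# variance partitioning


@dataclass(frozen=True)
class VariancePartition:
    """Seven-way commonality decomposition of a 3-predictor regression.

    ``unique``/``shared`` hold the raw (possibly negative) components as
    fractions of total variance; ``percentages`` expresses each component
    as a percentage of ``r2_full`` with negatives clipped at zero
    (``clipped`` lists which were).
    """

    predictors: tuple[str, str, str]
    r2: dict[frozenset, float] = field(repr=False)
    r2_full: float = 0.0
    unique: dict[str, float] = field(default_factory=dict)
    shared: dict[frozenset, float] = field(default_factory=dict)
    percentages: dict[str, float] = field(default_factory=dict)
    clipped: tuple[str, ...] = ()

    def components_sum(self) -> float:
        return sum(self.unique.values()) + sum(self.shared.values())


class VariancePartitioner(BaseEstimator):
    """Commonality analysis over exactly three predictors.

    ``fit(X, y)`` takes an (n, 3) predictor matrix (RDM vectors as columns)
    and the dependent RDM vector; it fits the seven subset OLS regressions
    and applies the commonality identities.

    Attributes
    ----------
    partition_ : VariancePartition
    r2_full_ : float
    unique_ : dict of predictor name -> raw unique component
    shared_ : dict of predictor-name frozenset -> raw shared component
    """

    def __init__(self, predictor_names: tuple[str, str, str] = ("A", "B", "C")):
        self.predictor_names = predictor_names

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must have exactly 3 predictor columns")
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on length")
        names = tuple(self.predictor_names)
        if len(names) != 3:
            raise ValueError("need exactly 3 predictor names")
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < 4:
            raise ValueError("rank-deficient design: predictors are collinear")

        sst = np.sum((y - y.mean()) ** 2)
        if sst == 0:
            raise ValueError("dependent vector has zero variance")

        r2: dict[frozenset, float] = {}
        for k in (1, 2, 3):
            for combo in itertools.combinations(range(3), k):
                design = np.column_stack([np.ones(len(y)), X[:, combo]])
                coef, *_ = np.linalg.lstsq(design, y, rcond=None)
                sse = np.sum((y - design @ coef) ** 2)
                r2[frozenset(names[i] for i in combo)] = 1.0 - sse / sst

        A, B, C = names
        full = r2[frozenset(names)]
        unique = {
            A: full - r2[frozenset({B, C})],
            B: full - r2[frozenset({A, C})],
            C: full - r2[frozenset({A, B})],
        }
        shared = {
            frozenset({A, B}): r2[frozenset({A, C})] + r2[frozenset({B, C})] - full - r2[frozenset({C})],
            frozenset({A, C}): r2[frozenset({A, B})] + r2[frozenset({B, C})] - full - r2[frozenset({B})],
            frozenset({B, C}): r2[frozenset({A, B})] + r2[frozenset({A, C})] - full - r2[frozenset({A})],
            frozenset({A, B, C}): (
                r2[frozenset({A})] + r2[frozenset({B})] + r2[frozenset({C})]
                - r2[frozenset({A, B})] - r2[frozenset({A, C})] - r2[frozenset({B, C})]
                + full
            ),
        }

        def key(s: frozenset) -> str:
            return "&".join(sorted(s, key=names.index))

        raw = {**{n: unique[n] for n in names}, **{key(s): v for s, v in shared.items()}}
        clipped = tuple(k for k, v in raw.items() if v < 0)
        percentages = {
            k: (max(v, 0.0) / full * 100.0 if full > 0 else float("nan"))
            for k, v in raw.items()
        }

        self.partition_ = VariancePartition(
            predictors=names,
            r2=r2,
            r2_full=full,
            unique=unique,
            shared=shared,
            percentages=percentages,
            clipped=clipped,
        )
        self.r2_full_ = full
        self.unique_ = unique
        self.shared_ = shared
        return self


def variance_partition(
    y: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    names: tuple[str, str, str] = ("A", "B", "C"),
) -> VariancePartition:
    """Functional wrapper: 7-component commonality decomposition of y on A, B, C."""
    X = np.column_stack([np.ravel(A), np.ravel(B), np.ravel(C)])
    return VariancePartitioner(predictor_names=names).fit(X, np.ravel(y)).partition_


# ---------------------------------------------------------------------------
# signed-rank test


@dataclass(frozen=True)
class TestResult:
    """Wilcoxon signed-rank result: W is the sum of positive signed ranks."""

    W: float
    z: float
    p: float
    n: int
    sided: str

    def __post_init__(self):
        if not 0 <= self.W <= self.n * (self.n + 1) / 2:
            raise ValueError("W outside [0, n(n+1)/2]")
        if not 0 < self.p <= 1:
            raise ValueError("p outside (0, 1]")


def signed_rank_test(
    values: np.ndarray,
    null: float = 0.0,
    sided: str = "one",
    paired_with: np.ndarray | None = None,
) -> TestResult:
    """Wilcoxon signed-rank test of per-participant coefficients.

    One-sided tests the alternative that the (paired) differences exceed
    the null; two-sided is symmetric. Zero differences are dropped
    (Wilcoxon's original prescription). Exact p when n <= 25 with no tied
    absolute differences, otherwise the tie-corrected normal approximation.
    The z-ratio is always reported from the normal approximation.
    """
    values = np.asarray(values, dtype=float).ravel()
    if paired_with is not None:
        other = np.asarray(paired_with, dtype=float).ravel()
        if other.shape != values.shape:
            raise ValueError("paired samples must have equal length")
        d = values - other
    else:
        d = values - null
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")

    ranks = stats.rankdata(np.abs(d))
    W = float(np.sum(ranks[d > 0]))

    mu = n * (n + 1) / 4
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / 48
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24 - tie_term)
    z = (W - mu) / sigma

    alternative = "greater" if sided == "one" else "two-sided"
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    no_ties = np.unique(np.abs(d)).size == n
    if n <= 25 and no_ties:
        p = float(
            stats.wilcoxon(d, alternative=alternative, method="exact", zero_method="wilcox").pvalue
        )
    else:
        p = float(stats.norm.sf(z)) if sided == "one" else float(2 * stats.norm.sf(abs(z)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return TestResult(W=W, z=float(z), p=p, n=n, sided=sided)


def fdr_adjust(p_values, family_labels=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, within each family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if family_labels is None:
        family_labels = np.zeros(p.size)
    family_labels = np.asarray(family_labels)
    if family_labels.shape != p.shape:
        raise ValueError("family labels must align with p-values")
    adjusted = np.empty_like(p)
    for fam in np.unique(family_labels):
        mask = family_labels == fam
        adjusted[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return adjusted


# ---------------------------------------------------------------------------
# noise ceiling


@dataclass(frozen=True)
class NoiseCeiling:
    upper: float
    lower: float

    def __post_init__(self):
        if self.lower > self.upper + 1e-12:
            raise ValueError("noise-ceiling lower bound exceeds upper bound")


def noise_ceiling(rdms: list[RDM], method: str = "pearson") -> NoiseCeiling:
    """Upper/lower bounds on attainable model-RDM correlation.

    Upper bound: mean correlation between each participant's RDM and the
    group-average RDM (which includes that participant, so it overfits).
    Lower bound: leave-one-out version, correlating each participant with
    the average of the others.
    """
    if len(rdms) < 3:
        raise ValueError("need >= 3 participants")
    vectors = np.array([vectorize_rdm(r) for r in rdms])
    if np.any(vectors.std(axis=1) == 0):
        raise ValueError("constant RDM for at least one participant")
    grand = vectors.mean(axis=0)
    n = len(rdms)
    upper = np.mean([correlate_rdms(v, grand, method) for v in vectors])
    lower = np.mean(
        [
            correlate_rdms(vectors[i], np.delete(vectors, i, axis=0).mean(axis=0), method)
            for i in range(n)
        ]
    )
    return NoiseCeiling(upper=float(upper), lower=float(lower))


# ---------------------------------------------------------------------------
# split-group reproducibility


@dataclass(frozen=True)
class ReproducibilityResult:
    r: float
    ci: tuple[float, float] | None
    p: float
    n_permutations: int
    null_distribution: np.ndarray = field(repr=False, default=None)


def _permuted_correlations(
    rdm_fixed: RDM, rdm_permuted: RDM, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null correlations from joint row/column relabelings of one RDM.

    Enumerates all n! permutations when that is no more than n_perm,
    otherwise samples n_perm random permutations.
    """
    n = rdm_permuted.n_items
    fixed = vectorize_rdm(rdm_fixed)
    values = rdm_permuted.values
    total = math.factorial(n)
    if total <= n_perm:
        perms = [np.array(p) for p in itertools.permutations(range(n))]
    else:
        perms = [rng.permutation(n) for _ in range(n_perm)]
    idx = np.tril_indices(n, k=-1)
    permuted = np.stack([values[np.ix_(p, p)][idx] for p in perms])
    return _row_pearson(permuted, fixed)


def _row_pearson(rows: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``rows`` against ``fixed`` (vectorized)."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    fc = fixed - fixed.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (fc**2).sum())
    return rc @ fc / denom


def reproducibility_test(
    rdms_group1: list[RDM],
    rdms_group2: list[RDM],
    n_perm: int = 10_000,
    n_boot: int = 10_000,
    rng_seed: int | None = None,
    ci_level: float = 0.95,
) -> ReproducibilityResult:
    """Permutation test of RDM reproducibility across two participant groups.

    The observed statistic is the Pearson correlation between the two
    group-average RDM vectors. The null permutes the category labels of
    group 2's average RDM (rows and columns jointly) and recomputes the
    correlation; p uses the add-one convention (1 + k) / (1 + N). The CI
    is a percentile bootstrap over participants within each group.
    """
    import warnings

    if not rdms_group1 or not rdms_group2:
        raise ValueError("both groups must be nonempty")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value", stacklevel=2)
    rng = np.random.default_rng(rng_seed)
    avg1, avg2 = average_rdms(rdms_group1), average_rdms(rdms_group2)
    if avg1.labels != avg2.labels:
        raise ValueError("groups must share category labels")
    v1 = vectorize_rdm(avg1)
    r_obs = float(stats.pearsonr(v1, vectorize_rdm(avg2)).statistic)

    null = _permuted_correlations(avg1, avg2, n_perm, rng)
    p = (1 + int(np.sum(null >= r_obs))) / (1 + len(null))

    ci = None
    if n_boot > 0 and len(rdms_group1) > 1 and len(rdms_group2) > 1:
        V1 = np.array([vectorize_rdm(r) for r in rdms_group1])
        V2 = np.array([vectorize_rdm(r) for r in rdms_group2])
        boots = np.empty(n_boot)
        for b in range(n_boot):
            m1 = V1[rng.integers(0, len(V1), len(V1))].mean(axis=0)
            m2 = V2[rng.integers(0, len(V2), len(V2))].mean(axis=0)
            boots[b] = stats.pearsonr(m1, m2).statistic
        alpha = (1 - ci_level) / 2
        ci = (float(np.quantile(boots, alpha)), float(np.quantile(boots, 1 - alpha)))
    elif n_boot > 0:
        warnings.warn("a group has a single participant; CI omitted", stacklevel=2)

    return ReproducibilityResult(
        r=r_obs, ci=ci, p=float(p), n_permutations=len(null), null_distribution=null
    )
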