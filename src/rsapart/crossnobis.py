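"""Cross-validated Mahalanobis (crossnobis) RDMs from multi-run patterns.

The estimator whitens per-run GLM beta patterns by the shrinkage-regularized
voxel covariance of the residual time courses (multivariate noise
normalization), then computes leave-one-run-out cross-validated squared
Euclidean distances:

    d_m(i, j) = (u_bar_i - u_bar_j) . (u_i^(m) - u_j^(m)) / P

where u_bar is the mean whitened pattern over all runs except m, u^(m) the
left-out run's whitened pattern, and P the voxel count. The fold mean is
the reported distance. Because the two factors come from independent data
partitions, the estimate is unbiased: its expectation is zero when two
conditions evoke identical true patterns, and estimates live on a ratio
scale (they may be negative).

Division by P is a package convention that makes values comparable across
region and searchlight sizes; pass ``normalize_by_voxels=False`` for raw
sums over voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .rdm import RDM

__all__ = [
    "PatternDataset",
    "NoiseCovariance",
    "estimate_noise",
    "whiten",
    "crossnobis_rdm",
    "CrossnobisRDM",
    "read_pattern_dataset",
    "write_pattern_dataset",
]


@dataclass(frozen=True)
class PatternDataset:
    """Multi-run beta patterns plus residual time courses.

    Parameters
    ----------
    betas : ndarray, shape (n_runs, n_categories, n_voxels)
        Per-run GLM estimates (arbitrary BOLD units).
    residuals : ndarray, shape (n_runs, n_timepoints, n_voxels)
        Residual time courses of the same GLM, used for noise estimation.
    labels : tuple of str
        Category names, consistent across runs.
    runs : tuple
        Run identifiers.
    """

    betas: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    labels: tuple[str, ...] = ()
    runs: tuple = ()

    def __post_init__(self):
        betas = np.asarray(self.betas, dtype=float)
        residuals = np.asarray(self.residuals, dtype=float)
        if betas.ndim != 3:
            raise ValueError("betas must be (runs, categories, voxels)")
        if residuals.ndim != 3:
            raise ValueError("residuals must be (runs, timepoints, voxels)")
        if betas.shape[0] < 2:
            raise ValueError("need >= 2 runs for cross-validation")
        if residuals.shape[0] != betas.shape[0]:
            raise ValueError("betas and residuals disagree on run count")
        if residuals.shape[2] != betas.shape[2]:
            raise ValueError("betas and residuals disagree on voxel count")
        if not (np.all(np.isfinite(betas)) and np.all(np.isfinite(residuals))):
            raise ValueError("non-finite values in dataset")
        labels = tuple(str(l) for l in self.labels) or tuple(
            f"cond{i}" for i in range(betas.shape[1])
        )
        if len(labels) != betas.shape[1]:
            raise ValueError("label count must equal the category dimension")
        runs = tuple(self.runs) or tuple(range(betas.shape[0]))
        if len(runs) != betas.shape[0]:
            raise ValueError("run identifiers must match the run dimension")
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "residuals", residuals)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "runs", runs)

    @property
    def n_runs(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[2]


class NoiseCovariance(BaseEstimator):
    """Shrinkage-regularized voxel noise covariance and its whitener.

    Per-run sample covariances of the (run-demeaned) residuals are averaged
    into one pooled estimate S, then shrunk toward its diagonal:

        Sigma = (1 - lambda) * S + lambda * diag(S)

    With ``shrinkage="auto"`` the intensity is the analytic diagonal-target
    estimator of Schafer & Strimmer: the ratio of the summed sampling
    variances of the off-diagonal entries to their summed squares, clipped
    to [0, 1]. The whitening transform W = Sigma^(-1/2) is the symmetric
    (eigendecomposition) inverse square root, so W' Sigma W = I.

    Attributes
    ----------
    covariance_ : ndarray (voxels, voxels)
    shrinkage_ : float in [0, 1]
    whitener_ : ndarray (voxels, voxels)
    """

    def __init__(self, shrinkage: str | float = "auto"):
        self.shrinkage = shrinkage

    def fit(self, residuals: np.ndarray, y=None):
        R = np.asarray(residuals, dtype=float)
        if R.ndim == 2:
            R = R[None]
        if R.ndim != 3 or R.shape[0] < 1 or R.shape[1] < 2:
            raise ValueError("residuals must be (runs, timepoints>=2, voxels)")
        if not np.all(np.isfinite(R)):
            raise ValueError("non-finite residuals")
        var = R.var(axis=(0, 1))
        dead = np.flatnonzero(var == 0)
        if dead.size:
            raise ValueError(f"zero-variance voxel(s): {dead.tolist()}")

        covs = [np.cov(run, rowvar=False, ddof=1) for run in R]
        S = np.mean(covs, axis=0)

        if self.shrinkage == "auto":
            lam = _analytic_shrinkage(R)
        else:
            lam = float(self.shrinkage)
            if not 0.0 <= lam <= 1.0:
                raise ValueError("fixed shrinkage must lie in [0, 1]")
        sigma = (1.0 - lam) * S + lam * np.diag(np.diag(S))

        evals, evecs = np.linalg.eigh(sigma)
        if evals.min() <= 0:
            raise ValueError("shrunk covariance not positive definite")
        self.covariance_ = sigma
        self.shrinkage_ = lam
        self.whitener_ = (evecs / np.sqrt(evals)) @ evecs.T
        return self

    def transform(self, betas: np.ndarray) -> np.ndarray:
        """Whiten patterns: right-multiply the voxel axis by the whitener."""
        betas = np.asarray(betas, dtype=float)
        if betas.shape[-1] != self.whitener_.shape[0]:
            raise ValueError(
                f"voxel dimension {betas.shape[-1]} does not match noise model "
                f"({self.whitener_.shape[0]})"
            )
        return betas @ self.whitener_

    @classmethod
    def identity(cls, n_voxels: int) -> "NoiseCovariance":
        """A no-op noise model (identity covariance), e.g. for noiseless data."""
        model = cls(shrinkage=0.0)
        model.covariance_ = np.eye(n_voxels)
        model.shrinkage_ = 0.0
        model.whitener_ = np.eye(n_voxels)
        return model


def _analytic_shrinkage(R: np.ndarray) -> float:
    """Schafer-Strimmer optimal intensity for shrinkage toward diag(S)."""
    X = R - R.mean(axis=1, keepdims=True)  # demean per run
    X = X.reshape(-1, R.shape[2])
    n = X.shape[0]
    if n < 2:
        return 1.0
    S = X.T @ X / (n - 1)
    # var(s_ij) = n / (n-1)^3 * sum_k (w_kij - w_bar_ij)^2, w_kij = x_ki x_kj
    W_bar = S * (n - 1) / n
    sum_w_sq = (X**2).T @ (X**2)  # sum_k x_ki^2 x_kj^2
    var_s = n / (n - 1) ** 3 * (sum_w_sq - n * W_bar**2)
    off = ~np.eye(S.shape[0], dtype=bool)
    denom = np.sum(S[off] ** 2)
    if denom == 0:
        return 1.0
    return float(np.clip(np.sum(var_s[off]) / denom, 0.0, 1.0))


def estimate_noise(
    residuals: np.ndarray, shrinkage: str | float = "auto"
) -> NoiseCovariance:
    """Fit a :class:`NoiseCovariance` on (runs, timepoints, voxels) residuals."""
    return NoiseCovariance(shrinkage=shrinkage).fit(residuals)


def whiten(betas: np.ndarray, noise: NoiseCovariance) -> np.ndarray:
    return noise.transform(betas)


class CrossnobisRDM(BaseEstimator):
    """Leave-one-run-out cross-validated Mahalanobis RDM estimator.

    Parameters
    ----------
    shrinkage : "auto" or float
        Passed to :class:`NoiseCovariance` when no prefit noise model is
        supplied to :meth:`fit`.
    normalize_by_voxels : bool
        Divide distances by the voxel count (default), giving per-voxel
        distances comparable across region sizes.

    Attributes
    ----------
    rdm_ : RDM
        The fold-averaged cross-validated distance matrix.
    noise_ : NoiseCovariance
        The whitener used.
    """

    def __init__(self, shrinkage: str | float = "auto", normalize_by_voxels: bool = True):
        self.shrinkage = shrinkage
        self.normalize_by_voxels = normalize_by_voxels

    def fit(self, data: PatternDataset, noise: NoiseCovariance | None = None):
        if data.n_runs < 2:
            raise ValueError("crossnobis needs >= 2 runs")
        self.noise_ = noise if noise is not None else estimate_noise(
            data.residuals, self.shrinkage
        )
        U = self.noise_.transform(data.betas)  # (runs, cats, voxels)
        n_runs, n_cat, P = U.shape
        dist = np.zeros((n_cat, n_cat))
        for m in range(n_runs):
            mean_rest = (U.sum(axis=0) - U[m]) / (n_runs - 1)
            M = mean_rest @ U[m].T
            diag = np.diag(M)
            dist += diag[:, None] + diag[None, :] - M - M.T
        dist /= n_runs
        if self.normalize_by_voxels:
            dist /= P
        dist = 0.5 * (dist + dist.T)  # folds make it symmetric up to float noise
        np.fill_diagonal(dist, 0.0)
        self.rdm_ = RDM(data.labels, dist)
        return self


def crossnobis_rdm(
    data: PatternDataset,
    noise: NoiseCovariance | None = None,
    shrinkage: str | float = "auto",
    normalize_by_voxels: bool = True,
) -> RDM:
    """Functional wrapper: crossnobis RDM of a :class:`PatternDataset`."""
    est = CrossnobisRDM(shrinkage=shrinkage, normalize_by_voxels=normalize_by_voxels)
    return est.fit(data, noise=noise).rdm_


# ---------------------------------------------------------------------------
# HDF5 I/O: /betas (runs x categories x voxels), /residuals (runs x T x voxels),
# /labels, /runs


def read_pattern_dataset(path: str) -> PatternDataset:
    import h5py

    with h5py.File(path, "r") as f:
        labels = tuple(
            l.decode() if isinstance(l, bytes) else str(l) for l in f["labels"][()]
        )
        runs = tuple(
            r.decode() if isinstance(r, bytes) else r for r in f["runs"][()]
        )
        return PatternDataset(f["betas"][()], f["residuals"][()], labels, runs)


def write_pattern_dataset(data: PatternDataset, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("betas", data=data.betas)
        f.create_dataset("residuals", data=data.residuals)
        f.create_dataset("labels", data=np.array(data.labels, dtype="S"))
        f.create_dataset("runs", data=np.array([str(r) for r in data.runs], dtype="S"))
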