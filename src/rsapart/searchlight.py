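"""Volumetric searchlight mapping and TFCE sign-permutation group inference.

A spherical neighborhood sweeps over every in-mask voxel; within each
sphere a crossnobis RDM is computed from the local multi-voxel patterns and
the three model partial correlations are assigned to the center voxel,
yielding one whole-volume map per model and participant.

Group inference converts the participant maps to a one-sample t map
(t-to-z via the t CDF), applies threshold-free cluster enhancement (TFCE),
and corrects familywise error by sign-flip permutation: the null is the
distribution of the *maximum* TFCE statistic over the mask under random
sign assignments of whole participant maps.

The sphere convention resolves "3 voxel diameter ... 123 voxels" in favor
of the voxel count: all integer offsets with Euclidean norm <= 3.0
(boundary inclusive) number exactly 123, whereas a literal diameter-3 cube
cannot exceed 27.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator

from .crossnobis import NoiseCovariance, PatternDataset, crossnobis_rdm
from .inference import partial_correlation
from .rdm import vectorize_rdm

__all__ = [
    "SearchlightConfig",
    "TfceParams",
    "VolumePatternDataset",
    "GroupResult",
    "sphere_offsets",
    "run_searchlight",
    "SearchlightPartialCorrelation",
    "tfce_transform",
    "group_sign_permutation",
    "read_volume_nifti",
    "write_volume_nifti",
]


@dataclass(frozen=True)
class SearchlightConfig:
    """Spherical neighborhood geometry.

    radius : Euclidean radius in voxel units, boundary inclusive.
    min_voxels : smallest in-mask sphere still analyzed; smaller centers
        are skipped.
    """

    radius: float = 3.0
    min_voxels: int = 10

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be >= 0")


@dataclass(frozen=True)
class TfceParams:
    """TFCE integration parameters (CoSMoMVPA-style defaults E=0.5, H=2)."""

    E: float = 0.5
    H: float = 2.0
    dh: float = 0.1
    connectivity: int = 18
    z_threshold: float = 1.64  # one-sided p < .05 display threshold

    def __post_init__(self):
        if self.E <= 0 or self.H <= 0 or self.dh <= 0:
            raise ValueError("E, H and dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass(frozen=True)
class VolumePatternDataset:
    """Voxel-resolved beta patterns and residuals on a 3-D grid.

    betas : (runs, categories, nx, ny, nz)
    residuals : (runs, timepoints, nx, ny, nz)
    mask : (nx, ny, nz) boolean brain mask
    labels : category names
    """

    betas: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        betas = np.asarray(self.betas, dtype=float)
        residuals = np.asarray(self.residuals, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if betas.ndim != 5 or residuals.ndim != 5:
            raise ValueError("betas/residuals must be 5-D (runs, cond, x, y, z)")
        if betas.shape[2:] != mask.shape or residuals.shape[2:] != mask.shape:
            raise ValueError("volume dimensions must match the mask")
        if not mask.any():
            raise ValueError("empty mask")
        labels = tuple(str(l) for l in self.labels) or tuple(
            f"cond{i}" for i in range(betas.shape[1])
        )
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "residuals", residuals)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "labels", labels)


def sphere_offsets(cfg: SearchlightConfig) -> np.ndarray:
    """Integer offsets with Euclidean norm <= radius, lexicographic order."""
    r = int(np.floor(cfg.radius))
    grid = np.arange(-r, r + 1)
    pts = np.array(np.meshgrid(grid, grid, grid, indexing="ij")).reshape(3, -1).T
    keep = np.sum(pts**2, axis=1) <= cfg.radius**2 + 1e-12
    pts = pts[keep]
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    return pts[order]


class SearchlightPartialCorrelation(BaseEstimator):
    """Whole-volume maps of per-model partial correlations.

    For every in-mask center with at least ``config.min_voxels`` in-mask
    sphere voxels, a crossnobis RDM is estimated from the sphere's patterns
    (noise covariance re-estimated per sphere by default) and each model's
    partial correlation, controlling the other models, is written to the
    center voxel. Out-of-mask and skipped centers are NaN.

    Attributes
    ----------
    maps_ : dict of model name -> 3-D ndarray
    n_skipped_ : int
    """

    def __init__(
        self,
        config: SearchlightConfig = SearchlightConfig(),
        shrinkage: str | float = "auto",
        shared_noise: bool = False,
    ):
        self.config = config
        self.shrinkage = shrinkage
        self.shared_noise = shared_noise

    def fit(self, data: VolumePatternDataset, models: dict[str, np.ndarray]):
        n_pairs = len(data.labels) * (len(data.labels) - 1) // 2
        model_vecs = {}
        for name, v in models.items():
            v = np.asarray(v, dtype=float).ravel()
            if v.size != n_pairs:
                raise ValueError(
                    f"model {name!r} has length {v.size}, expected {n_pairs}"
                )
            model_vecs[name] = v
        names = list(model_vecs)

        offsets = sphere_offsets(self.config)
        mask = data.mask
        dims = mask.shape
        flat_betas = data.betas.reshape(*data.betas.shape[:2], -1)
        flat_resid = data.residuals.reshape(*data.residuals.shape[:2], -1)

        shared = None
        if self.shared_noise:
            in_mask = np.flatnonzero(mask.ravel())
            shared = NoiseCovariance(self.shrinkage).fit(flat_resid[:, :, in_mask])

        maps = {name: np.full(dims, np.nan) for name in names}
        self.n_skipped_ = 0
        centers = np.argwhere(mask)
        for cx, cy, cz in centers:
            coords = offsets + (cx, cy, cz)
            ok = np.all((coords >= 0) & (coords < dims), axis=1)
            coords = coords[ok]
            inside = mask[coords[:, 0], coords[:, 1], coords[:, 2]]
            coords = coords[inside]
            if len(coords) < self.config.min_voxels:
                self.n_skipped_ += 1
                continue
            flat_idx = np.ravel_multi_index(coords.T, dims)
            betas = flat_betas[:, :, flat_idx]
            resid = flat_resid[:, :, flat_idx]
            if self.shared_noise:
                # restrict the shared whitener to this sphere's voxels
                in_mask = np.flatnonzero(mask.ravel())
                sel = np.searchsorted(in_mask, flat_idx)
                noise = NoiseCovariance(0.0)
                noise.covariance_ = shared.covariance_[np.ix_(sel, sel)]
                ev, evec = np.linalg.eigh(noise.covariance_)
                noise.whitener_ = (evec / np.sqrt(ev)) @ evec.T
                noise.shrinkage_ = shared.shrinkage_
            else:
                noise = NoiseCovariance(self.shrinkage).fit(resid)
            ds = PatternDataset(betas, resid, data.labels, ())
            rdm_vec = vectorize_rdm(crossnobis_rdm(ds, noise=noise))
            for name in names:
                others = [model_vecs[m] for m in names if m != name]
                maps[name][cx, cy, cz] = partial_correlation(
                    rdm_vec, model_vecs[name], others
                )
        self.maps_ = maps
        return self


def run_searchlight(
    data: VolumePatternDataset,
    models: dict[str, np.ndarray],
    config: SearchlightConfig = SearchlightConfig(),
    shrinkage: str | float = "auto",
    shared_noise: bool = False,
) -> dict[str, np.ndarray]:
    """Functional wrapper around :class:`SearchlightPartialCorrelation`."""
    est = SearchlightPartialCorrelation(config, shrinkage, shared_noise)
    return est.fit(data, models).maps_


# ---------------------------------------------------------------------------
# TFCE


def _connectivity_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def tfce_transform(
    stat_volume: np.ndarray,
    params: TfceParams = TfceParams(),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a statistic volume.

    TFCE(v) = sum over heights h = dh, 2dh, ... of e_v(h)^E * h^H * dh,
    where e_v(h) is the extent of the supra-threshold connected cluster
    containing v at height h. Negative values are enhanced by transforming
    the negated map and negating the result.
    """
    stat = np.asarray(stat_volume, dtype=float)
    if stat.ndim != 3:
        raise ValueError("stat volume must be 3-D")
    if mask is not None:
        stat = np.where(np.asarray(mask, dtype=bool), stat, 0.0)
    if not np.all(np.isfinite(stat)):
        raise ValueError("non-finite in-mask statistic values")
    structure = _connectivity_structure(params.connectivity)

    def one_sided(pos: np.ndarray) -> np.ndarray:
        out = np.zeros_like(pos)
        top = pos.max()
        if top <= 0:
            return out
        heights = np.arange(params.dh, top + params.dh, params.dh)
        for h in heights:
            supra = pos >= h
            if not supra.any():
                break
            labels, n_clust = ndimage.label(supra, structure=structure)
            sizes = np.bincount(labels.ravel())
            extent = sizes[labels]
            out[supra] += extent[supra] ** params.E * h**params.H * params.dh
        return out

    return one_sided(stat) - one_sided(-stat)


# ---------------------------------------------------------------------------
# group-level sign-flip permutation


@dataclass(frozen=True)
class GroupResult:
    """Sign-permutation group inference output.

    t_map/z_map are voxelwise one-sample statistics; tfce_map is the TFCE
    of the z map; p_map holds familywise-corrected p-values from the
    max-TFCE null; z_thresholded masks the z map at the display threshold
    on the corrected p.
    """

    t_map: np.ndarray = field(repr=False)
    z_map: np.ndarray = field(repr=False)
    tfce_map: np.ndarray = field(repr=False)
    p_map: np.ndarray = field(repr=False)
    z_thresholded: np.ndarray = field(repr=False)
    null_max: np.ndarray = field(repr=False)
    n_permutations: int = 0


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    pos = t >= 0
    z = np.empty_like(t)
    z[pos] = stats.norm.isf(stats.t.sf(t[pos], df))
    z[~pos] = stats.norm.ppf(stats.t.cdf(t[~pos], df))
    return z


def _t_map(data: np.ndarray) -> np.ndarray:
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(data.shape[0]))
    return np.where(sd == 0, 0.0, t)


def group_sign_permutation(
    maps: list[np.ndarray],
    mask: np.ndarray | None = None,
    params: TfceParams = TfceParams(),
    n_perm: int = 10_000,
    rng_seed: int | None = None,
    alpha: float = 0.05,
) -> GroupResult:
    """One-sample group test with TFCE and max-statistic sign permutation.

    Each permutation flips the sign of whole participant maps at random,
    recomputes the t -> z -> TFCE pipeline and records the maximum TFCE
    over the mask. Corrected p per voxel = (1 + #{max_perm >= TFCE_obs}) /
    (1 + n_perm), one-sided for positive effects. Sign assignments are
    drawn antithetically (each random assignment is paired with its
    negation), which balances the null and makes it exactly invariant
    under global negation of the input maps.
    """
    import warnings

    data = np.array([np.asarray(m, dtype=float) for m in maps])
    if data.ndim != 4:
        raise ValueError("maps must be a list of aligned 3-D volumes")
    n_sub = data.shape[0]
    if n_sub < 5:
        raise ValueError("need >= 5 participants")
    if n_perm < 1 / alpha - 1:
        warnings.warn(
            f"n_perm = {n_perm} cannot resolve alpha = {alpha}", stacklevel=2
        )
    if mask is None:
        mask = np.all(np.isfinite(data), axis=0)
    mask = np.asarray(mask, dtype=bool)
    data = np.where(mask, data, 0.0)
    data = np.nan_to_num(data)
    rng = np.random.default_rng(rng_seed)
    df = n_sub - 1

    t_obs = _t_map(data)
    z_obs = np.where(mask, _t_to_z(t_obs, df), 0.0)
    tfce_obs = tfce_transform(z_obs, params, mask)

    null_max = np.empty(n_perm)
    signs = None
    for b in range(n_perm):
        if b % 2 == 0:
            signs = rng.choice([-1.0, 1.0], size=n_sub)[:, None, None, None]
        else:
            signs = -signs  # antithetic pair
        z_b = np.where(mask, _t_to_z(_t_map(data * signs), df), 0.0)
        null_max[b] = tfce_transform(z_b, params, mask).max()

    exceed = (null_max[None, None, None, :] >= tfce_obs[..., None]).sum(axis=-1)
    p_map = np.where(mask, (1.0 + exceed) / (1.0 + n_perm), 1.0)
    z_thr = np.where(
        mask & (p_map < alpha) & (z_obs >= params.z_threshold), z_obs, np.nan
    )
    return GroupResult(
        t_map=t_obs,
        z_map=z_obs,
        tfce_map=tfce_obs,
        p_map=p_map,
        z_thresholded=z_thr,
        null_max=null_max,
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# NIfTI I/O (volumes and masks)


def read_volume_nifti(path: str) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(path).get_fdata())


def write_volume_nifti(volume: np.ndarray, path: str, affine: np.ndarray | None = None) -> None:
    import nibabel as nib

    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), path)
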