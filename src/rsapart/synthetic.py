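"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its arguments (including the seed) and
returns the artifact together with a :class:`GroundTruth` record, so
recovery can be scored without any external data:

- model RDM triplets with controlled pairwise correlation (feature-level
  common-factor mixing);
- multi-run beta patterns whose true squared-distance structure realizes a
  target RDM, plus residual series sharing a known voxel covariance;
- circular-arena arrangements whose squared inter-thumbnail distances
  realize a target RDM plus jitter;
- labeled volumes with a planted region carrying representational
  structure, for searchlight recovery tests;
- composite "data" RDMs mixing model RDM vectors with known weights, for
  variance-partitioning recovery.

The generators emulate the *statistical* structure of arrangement and fMRI
measurements (second-moment geometry, run noise, voxel covariance), not
their physical realism: no hemodynamics, no image content, no spatial
autocorrelation beyond the supplied covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .behavior import Arrangement
from .crossnobis import PatternDataset
from .rdm import RDM, rdm_from_features, unvectorize_rdm, vectorize_rdm
from .searchlight import VolumePatternDataset

__all__ = [
    "GroundTruth",
    "gen_model_rdms",
    "gen_pattern_dataset",
    "gen_arrangement",
    "gen_searchlight_volume",
    "gen_composite_rdm",
    "gen_category_pool",
]


@dataclass(frozen=True)
class GroundTruth:
    """What a generator actually planted, for recovery scoring."""

    seed: int | None
    target_rdms: tuple[RDM, ...] = ()
    weights: tuple[float, ...] = ()
    noise_sd: float = 0.0
    noise_covariance: Any = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# model RDM triplets


def gen_model_rdms(
    n_items: int = 30,
    n_models: int = 3,
    target_pairwise_r: float = 0.25,
    n_features: int = 500,
    rng_seed: int | None = None,
) -> tuple[list[RDM], GroundTruth]:
    """Model RDMs whose vectors correlate pairwise near ``target_pairwise_r``.

    Each model's item x feature matrix is w * (shared latent) +
    sqrt(1 - w^2) * (independent part). Because the covariance between two
    models' dissimilarity entries is carried only by the shared factor, the
    expected RDM-vector correlation is w^4, so w = target^(1/4). Linear
    common-factor mixing cannot produce negative RDM correlations, so
    negative targets are rejected as infeasible. Achieved correlations
    fluctuate around the target with finite items; at n_items = 30 they are
    typically within +/- 0.08.
    """
    if not 0.0 <= target_pairwise_r < 1.0:
        raise ValueError(
            "target_pairwise_r must lie in [0, 1): common-factor mixing cannot "
            "realize negative or perfect RDM correlations"
        )
    if n_items < 4:
        raise ValueError("need n_items >= 4")
    rng = np.random.default_rng(rng_seed)
    w = target_pairwise_r**0.25
    shared = rng.standard_normal((n_items, n_features))
    labels = [f"item{i:02d}" for i in range(n_items)]
    rdms = []
    for _ in range(n_models):
        X = w * shared + np.sqrt(1 - w**2) * rng.standard_normal((n_items, n_features))
        rdms.append(rdm_from_features(pd.DataFrame(X, index=labels)))
    truth = GroundTruth(
        seed=rng_seed,
        target_rdms=tuple(rdms),
        extras={"target_pairwise_r": target_pairwise_r, "mixing_weight": w},
    )
    return rdms, truth


# ---------------------------------------------------------------------------
# beta patterns realizing a target RDM


def _embed_target(target: RDM, n_voxels: int, rng: np.random.Generator) -> np.ndarray:
    """Category base patterns whose squared distances / n_voxels equal the target.

    Classical distance-to-Gram construction: G = -1/2 C D C with C the
    centering matrix; eigenvalues clipped at zero (error if substantially
    negative, i.e. the target is not a Euclidean squared-distance matrix);
    coordinates spread over voxels through a random orthonormal mixing.
    """
    D = target.values
    n = target.n_items
    C = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * C @ D @ C
    evals, evecs = np.linalg.eigh(G)
    tol = 1e-8 * max(evals.max(), 1.0)
    if evals.min() < -max(tol, 1e-6 * abs(evals).max()):
        raise ValueError(
            "target RDM is not embeddable as squared Euclidean distances "
            f"(negative Gram eigenvalue {evals.min():.3g}); inflate the "
            "off-diagonal by a constant to restore embeddability"
        )
    evals = np.clip(evals, 0.0, None)
    k = min(n, n_voxels)
    order = np.argsort(evals)[::-1][:k]
    U = evecs[:, order] * np.sqrt(evals[order])  # (n, k), ||U_i - U_j||^2 = D_ij
    Q, _ = np.linalg.qr(rng.standard_normal((n_voxels, k)))
    return np.sqrt(n_voxels) * U @ Q.T  # (n, n_voxels)


def _make_noise_cov(spec, n_voxels: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec, np.ndarray):
        return spec
    if spec == "identity":
        return np.eye(n_voxels)
    if spec == "random_spd":
        A = rng.standard_normal((n_voxels, 2 * n_voxels))
        S = A @ A.T / (2 * n_voxels)
        S /= np.mean(np.diag(S))
        return S
    raise ValueError(f"unknown noise covariance spec: {spec!r}")


def gen_pattern_dataset(
    target: RDM,
    n_voxels: int = 60,
    n_runs: int = 4,
    signal_scale: float = 1.0,
    noise_sd: float = 1.0,
    noise_cov: str | np.ndarray = "identity",
    n_timepoints: int = 100,
    rng_seed: int | None = None,
) -> tuple[PatternDataset, GroundTruth]:
    """Multi-run beta patterns whose true distance structure is ``target``.

    Base patterns are an exact Euclidean embedding of the target scaled by
    ``signal_scale`` (distances scale by signal_scale^2); per-run betas add
    Gaussian noise with covariance noise_sd^2 * noise_cov, and residual
    time courses share that covariance so the noise model is recoverable.
    """
    if n_runs < 2:
        raise ValueError("need n_runs >= 2")
    rng = np.random.default_rng(rng_seed)
    base = signal_scale * _embed_target(target, n_voxels, rng)
    cov = _make_noise_cov(noise_cov, n_voxels, rng)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n_voxels))
    n_cat = target.n_items

    def noise(shape0):
        return noise_sd * rng.standard_normal((shape0, n_voxels)) @ L.T

    betas = np.stack([base + noise(n_cat) for _ in range(n_runs)])
    residuals = np.stack([noise(n_timepoints) for _ in range(n_runs)])
    data = PatternDataset(betas, residuals, target.labels, tuple(range(n_runs)))
    truth = GroundTruth(
        seed=rng_seed,
        target_rdms=(target,),
        noise_sd=noise_sd,
        noise_covariance=noise_sd**2 * cov,
        extras={"signal_scale": signal_scale, "base_patterns": base},
    )
    return data, truth


# ---------------------------------------------------------------------------
# circular-arena arrangements


def gen_arrangement(
    target: RDM,
    exemplars_per_category: int = 4,
    jitter_sd: float = 0.0,
    arena_radius: float = 800.0,
    rng_seed: int | None = None,
) -> tuple[Arrangement, GroundTruth]:
    """An arrangement whose category squared distances realize the target.

    Category anchors come from classical 2-D scaling of the target,
    rescaled to fit the arena (so the recovered RDM is *proportional* to
    the target when it is exactly 2-D embeddable and jitter is zero);
    exemplars scatter around their anchor with isotropic ``jitter_sd``.
    Points are radially clamped to the arena boundary.
    """
    if target.n_items < 2:
        raise ValueError("target must have at least 2 categories")
    if arena_radius <= 0:
        raise ValueError("arena_radius must be positive")
    rng = np.random.default_rng(rng_seed)
    D = target.values
    n = target.n_items
    C = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * C @ D @ C
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1][:2]
    anchors = evecs[:, order] * np.sqrt(np.clip(evals[order], 0.0, None))
    max_norm = np.max(np.linalg.norm(anchors, axis=1))
    scale = 0.8 * arena_radius / max_norm if max_norm > 0 else 1.0
    anchors = anchors * scale

    ids, cats, pts = [], [], []
    for i, cat in enumerate(target.labels):
        for e in range(exemplars_per_category):
            p = anchors[i] + jitter_sd * rng.standard_normal(2)
            r = np.linalg.norm(p)
            if r > arena_radius:
                p = p * (arena_radius / r)
            ids.append(f"{cat}_ex{e}")
            cats.append(cat)
            pts.append(p)
    arr = Arrangement(tuple(ids), tuple(cats), np.array(pts), arena_radius)
    truth = GroundTruth(
        seed=rng_seed,
        target_rdms=(target,),
        noise_sd=jitter_sd,
        extras={"scale": scale, "anchors": anchors},
    )
    return arr, truth


# ---------------------------------------------------------------------------
# searchlight volumes with a planted region


def gen_searchlight_volume(
    dims: tuple[int, int, int],
    planted_region: np.ndarray,
    region_target: RDM,
    noise_sd: float = 1.0,
    signal_scale: float = 1.0,
    n_runs: int = 4,
    n_timepoints: int = 60,
    rng_seed: int | None = None,
) -> tuple[VolumePatternDataset, np.ndarray, GroundTruth]:
    """A volume where only ``planted_region`` voxels carry the target structure.

    Region voxels receive base patterns embedding ``region_target`` (scaled
    by ``signal_scale``; zero scale plants nothing); every voxel receives
    i.i.d. run noise and residual series of standard deviation
    ``noise_sd``. Returns the dataset, the boolean truth mask, and the
    ground truth.
    """
    region = np.asarray(planted_region, dtype=bool)
    if region.shape != tuple(dims):
        raise ValueError("planted_region must match dims")
    if signal_scale > 0 and not region.any():
        raise ValueError("planted region is empty")
    rng = np.random.default_rng(rng_seed)
    n_cat = region_target.n_items
    n_region = int(region.sum())

    betas = noise_sd * rng.standard_normal((n_runs, n_cat, *dims))
    residuals = noise_sd * rng.standard_normal((n_runs, n_timepoints, *dims))
    if signal_scale > 0 and n_region > 0:
        base = signal_scale * _embed_target(region_target, n_region, rng)
        betas[:, :, region] += base[None]
    mask = np.ones(dims, dtype=bool)
    data = VolumePatternDataset(betas, residuals, mask, region_target.labels)
    truth = GroundTruth(
        seed=rng_seed,
        target_rdms=(region_target,),
        noise_sd=noise_sd,
        extras={"signal_scale": signal_scale, "truth_mask": region},
    )
    return data, region, truth


# ---------------------------------------------------------------------------
# composite data RDMs and category pools


def gen_composite_rdm(
    models: list[RDM],
    weights: tuple[float, ...],
    noise_sd: float = 0.0,
    rng_seed: int | None = None,
    orthonormalize: bool = False,
) -> tuple[RDM, GroundTruth]:
    """A "data" RDM whose vector is a weighted sum of model RDM vectors.

    With ``orthonormalize`` the model vectors are first centered and then
    replaced by their Gram-Schmidt orthonormal basis (rescaled to unit
    variance) before mixing, so squared weights map directly onto unique
    variance components. Centering matters: raw dissimilarities sit around
    a common positive mean, and orthonormalizing the uncentered vectors
    would waste the first basis direction on that constant.
    """
    if len(models) != len(weights):
        raise ValueError("one weight per model")
    V = np.array([vectorize_rdm(m) for m in models])
    if orthonormalize:
        centered = V - V.mean(axis=1, keepdims=True)
        basis, _ = np.linalg.qr(centered.T)
        V = basis.T * np.sqrt(V.shape[1])  # unit-variance components
    rng = np.random.default_rng(rng_seed)
    y = np.asarray(weights) @ V + noise_sd * rng.standard_normal(V.shape[1])
    y = y - y.min()  # dissimilarities shifted nonnegative; correlations unaffected
    rdm = unvectorize_rdm(y, models[0].labels)
    truth = GroundTruth(
        seed=rng_seed,
        target_rdms=tuple(models),
        weights=tuple(float(w) for w in weights),
        noise_sd=noise_sd,
    )
    return rdm, truth


def inflate_to_embeddable(rdm: RDM, margin: float = 1e-9) -> RDM:
    """Add the smallest constant to all off-diagonal entries that makes the
    RDM a valid squared-Euclidean distance matrix.

    Adding a constant a to every off-diagonal entry shifts all centered-Gram
    eigenvalues by a/2, so a = 2|min eigenvalue| restores positive
    semidefiniteness. Correlation-based analyses are unaffected by the
    shift.
    """
    D = rdm.values
    n = rdm.n_items
    C = np.eye(n) - np.ones((n, n)) / n
    evals = np.linalg.eigvalsh(-0.5 * C @ D @ C)
    if evals.min() >= 0:
        return rdm
    a = 2.0 * (-evals.min()) + margin
    return RDM(rdm.labels, D + a * (1.0 - np.eye(n)))


def gen_category_pool(
    n_per_class: int = 20,
    n_models: int = 3,
    target_pairwise_r: float = 0.4,
    n_features: int = 300,
    rng_seed: int | None = None,
):
    """A quota-structured category pool with correlated full-pool model RDMs.

    Convenience for exercising stimulus-set selection: three superordinate
    classes of ``n_per_class`` categories each, with model RDMs generated
    by :func:`gen_model_rdms` over the whole pool.
    """
    from .selection import CategoryPool

    classes = ("indoor", "outdoor man-made", "outdoor natural")
    n_items = n_per_class * len(classes)
    rdms, truth = gen_model_rdms(
        n_items=n_items,
        n_models=n_models,
        target_pairwise_r=target_pairwise_r,
        n_features=n_features,
        rng_seed=rng_seed,
    )
    labels = rdms[0].labels
    class_of = tuple(classes[i // n_per_class] for i in range(n_items))
    model_rdms = {f"model{k}": r for k, r in enumerate(rdms)}
    return CategoryPool(labels, class_of, model_rdms), truth
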