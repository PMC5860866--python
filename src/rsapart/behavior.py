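"""Behavioral RDMs from multi-arrangement data.

In the multi-arrangement task participants drag exemplar thumbnails inside
a circular arena so that on-screen proximity reflects perceived similarity.
The category-level dissimilarity between categories A and B is the mean of
the squared Euclidean screen distances over all exemplar pairs (a in A,
b in B); units are pixels squared. Within-category distances are discarded
(the diagonal is zero by construction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rdm import RDM

__all__ = ["Arrangement", "arrangement_to_rdm", "average_rdms", "read_arrangement"]


@dataclass(frozen=True)
class Arrangement:
    """One participant's thumbnail arrangement inside a circular arena.

    Parameters
    ----------
    exemplar_ids : tuple of str
        Unique thumbnail identifiers.
    categories : tuple of str
        Category of each exemplar, aligned with ``exemplar_ids``.
    xy : ndarray, shape (n_exemplars, 2)
        Screen coordinates in pixels, arena-centered.
    arena_radius : float
        Arena radius in pixels; all exemplars must lie inside.
    """

    exemplar_ids: tuple[str, ...]
    categories: tuple[str, ...]
    xy: np.ndarray = field(repr=False)
    arena_radius: float = np.inf

    def __post_init__(self):
        ids = tuple(str(e) for e in self.exemplar_ids)
        cats = tuple(str(c) for c in self.categories)
        xy = np.asarray(self.xy, dtype=float)
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate exemplar ids")
        if xy.shape != (len(ids), 2):
            raise ValueError(f"xy must be (n, 2), got {xy.shape}")
        if len(cats) != len(ids):
            raise ValueError("categories must align with exemplar_ids")
        if not np.all(np.isfinite(xy)):
            raise ValueError("non-finite coordinates")
        radii = np.linalg.norm(xy, axis=1)
        if np.any(radii > self.arena_radius + 1e-9):
            outside = [ids[i] for i in np.flatnonzero(radii > self.arena_radius + 1e-9)]
            raise ValueError(f"exemplars outside the arena: {outside}")
        xy = xy.copy()
        xy.flags.writeable = False
        object.__setattr__(self, "exemplar_ids", ids)
        object.__setattr__(self, "categories", cats)
        object.__setattr__(self, "xy", xy)

    @property
    def category_labels(self) -> list[str]:
        seen: list[str] = []
        for c in self.categories:
            if c not in seen:
                seen.append(c)
        return seen


def arrangement_to_rdm(arr: Arrangement) -> RDM:
    """Category-level RDM of mean pairwise squared on-screen distances (px^2)."""
    cats = arr.category_labels
    if len(cats) < 2:
        raise ValueError("need at least 2 categories")
    groups = {c: arr.xy[np.array(arr.categories) == c] for c in cats}
    n = len(cats)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            a, b = groups[cats[i]], groups[cats[j]]
            diff = a[:, None, :] - b[None, :, :]
            values[i, j] = values[j, i] = np.mean(np.sum(diff**2, axis=-1))
    return RDM(cats, values)


def average_rdms(rdms: list[RDM]) -> RDM:
    """Entrywise arithmetic mean of RDMs sharing one label set and order."""
    if not rdms:
        raise ValueError("need at least one RDM")
    ref = rdms[0]
    for k, rdm in enumerate(rdms[1:], start=1):
        if rdm.labels != ref.labels:
            raise ValueError(f"RDM {k} labels differ from RDM 0")
    return RDM(ref.labels, np.mean([r.values for r in rdms], axis=0))


def read_arrangement(csv_path: str, arena_radius: float | None = None) -> Arrangement:
    """Read an arrangement CSV (exemplar_id, category, x_px, y_px).

    The arena radius may come from a sidecar JSON (``<csv>.json`` with key
    ``arena_radius``) or the ``arena_radius`` argument; argument wins.
    """
    df = pd.read_csv(csv_path)
    required = {"exemplar_id", "category", "x_px", "y_px"}
    if not required.issubset(df.columns):
        raise ValueError(f"{csv_path}: missing columns {sorted(required - set(df.columns))}")
    if arena_radius is None:
        sidecar = str(csv_path) + ".json"
        try:
            with open(sidecar) as f:
                arena_radius = float(json.load(f)["arena_radius"])
        except FileNotFoundError:
            arena_radius = np.inf
    return Arrangement(
        tuple(df["exemplar_id"].astype(str)),
        tuple(df["category"].astype(str)),
        df[["x_px", "y_px"]].to_numpy(dtype=float),
        arena_radius,
    )
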