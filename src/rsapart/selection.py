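"""Decorrelated stimulus-set selection with a secretary-style stopping rule.

Three candidate feature models (e.g. scene functions, object labels,
network activations) are available as full-pool RDMs over a large pool of
scene categories. The goal is a fixed-size category set — with equal
quotas from the indoor / outdoor man-made / outdoor natural superordinate
classes — whose three model sub-RDMs are minimally inter-correlated, so
that downstream variance partitioning is well conditioned.

Because guaranteeing a global minimum over all quota-respecting subsets is
intractable, selection uses a stopping rule in the spirit of the odds
algorithm: sample a learning batch of candidates, record the best (lowest)
score seen, then keep sampling and accept the first candidate that beats
that record strictly. A candidate's score is the *maximum* of its three
pairwise inter-model Spearman correlations, so accepting a lower score
lowers the worst inter-model correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .rdm import RDM, correlate_rdms, rdm_subset, vectorize_rdm

__all__ = [
    "CategoryPool",
    "CandidateScore",
    "sample_candidate",
    "score_candidate",
    "select_set",
    "StimulusSetSelector",
]


@dataclass(frozen=True)
class CategoryPool:
    """A pool of candidate categories with class memberships and model RDMs.

    Parameters
    ----------
    labels : tuple of str
        Category identifiers.
    classes : tuple of str
        Superordinate class of each category, aligned with ``labels``.
    model_rdms : dict of str -> RDM
        The candidate feature models' full-pool RDMs; all must share the
        pool's label set and order.
    """

    labels: tuple[str, ...]
    classes: tuple[str, ...]
    model_rdms: dict[str, RDM] = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        object.__setattr__(self, "classes", tuple(str(c) for c in self.classes))
        if len(self.labels) != len(self.classes):
            raise ValueError("labels and classes must align")
        if len(self.model_rdms) < 2:
            raise ValueError("need at least two model RDMs to decorrelate")
        for name, rdm in self.model_rdms.items():
            if rdm.labels != self.labels:
                raise ValueError(f"model {name!r} labels differ from the pool's")

    def class_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for lab, cls in zip(self.labels, self.classes):
            out.setdefault(cls, []).append(lab)
        return out


@dataclass(frozen=True)
class CandidateScore:
    """Inter-model correlations of one candidate set; summary = max of them."""

    labels: tuple[str, ...]
    correlations: dict[tuple[str, str], float]
    summary: float

    def __post_init__(self):
        expected = max(self.correlations.values())
        if abs(self.summary - expected) > 1e-12:
            raise ValueError("summary must equal the maximum pairwise correlation")


def sample_candidate(
    pool: CategoryPool, set_size: int, rng: np.random.Generator | int
) -> list[str]:
    """Sample ``set_size`` categories uniformly with equal per-class quotas."""
    rng = np.random.default_rng(rng)
    members = pool.class_members()
    n_classes = len(members)
    if set_size % n_classes != 0:
        raise ValueError(f"set_size {set_size} not divisible by {n_classes} classes")
    quota = set_size // n_classes
    deficits = {c: quota - len(m) for c, m in members.items() if len(m) < quota}
    if deficits:
        raise ValueError(f"per-class deficit, cannot fill quota of {quota}: {deficits}")
    picked: list[str] = []
    for cls in sorted(members):
        picked.extend(rng.choice(members[cls], size=quota, replace=False))
    return picked


def score_candidate(pool: CategoryPool, labels: list[str]) -> CandidateScore:
    """Score a candidate: pairwise Spearman rho between its model sub-RDMs."""
    vectors = {
        name: vectorize_rdm(rdm_subset(rdm, labels))
        for name, rdm in pool.model_rdms.items()
    }
    names = sorted(vectors)
    corr: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            corr[(a, b)] = correlate_rdms(vectors[a], vectors[b], method="spearman")
    return CandidateScore(tuple(labels), corr, max(corr.values()))


class StimulusSetSelector(BaseEstimator):
    """Stopping-rule search for a minimally inter-correlated category set.

    Draws ``n_learning`` quota-respecting candidates, records the minimum
    of their summary scores (each summary being the candidate's maximum
    pairwise inter-model Spearman correlation), then accepts the first
    subsequent candidate scoring strictly below the record. If
    ``max_iterations`` total draws pass without acceptance, the best
    candidate seen anywhere is returned and ``exhausted_`` is set.

    Parameters
    ----------
    set_size : int
        Number of categories to select (divisible by the class count).
    n_learning : int
        Size of the rejected learning batch.
    max_iterations : int or None
        Total-draw guard; defaults to ``10 * n_learning``.
    random_state : int or None
        Seed; selection is reproducible from (pool, seed).

    Attributes
    ----------
    labels_ : tuple of str
        The selected category set.
    score_ : CandidateScore
        Its inter-model correlations and summary.
    learning_record_ : float
        Minimum summary observed during the learning phase.
    n_iterations_ : int
        Total candidates drawn.
    exhausted_ : bool
        True when the guard tripped and the best-seen candidate was
        returned instead of a record-beating one.
    """

    def __init__(
        self,
        set_size: int = 30,
        n_learning: int = 10_000,
        max_iterations: int | None = None,
        random_state: int | None = None,
    ):
        self.set_size = set_size
        self.n_learning = n_learning
        self.max_iterations = max_iterations
        self.random_state = random_state

    def fit(self, pool: CategoryPool):
        if self.n_learning < 1:
            raise ValueError("n_learning must be >= 1")
        max_iter = (
            10 * self.n_learning if self.max_iterations is None else self.max_iterations
        )
        if max_iter <= self.n_learning:
            raise ValueError("max_iterations must exceed n_learning")
        rng = np.random.default_rng(self.random_state)

        best: CandidateScore | None = None
        record = np.inf
        for i in range(max_iter):
            cand = score_candidate(pool, sample_candidate(pool, self.set_size, rng))
            if best is None or cand.summary < best.summary:
                best = cand
            if i < self.n_learning:
                record = min(record, cand.summary)
            elif cand.summary < record:
                self.labels_, self.score_ = cand.labels, cand
                self.learning_record_ = record
                self.n_iterations_ = i + 1
                self.exhausted_ = False
                return self
        assert best is not None
        self.labels_, self.score_ = best.labels, best
        self.learning_record_ = record
        self.n_iterations_ = max_iter
        self.exhausted_ = True
        return self


def select_set(
    pool: CategoryPool,
    set_size: int,
    n_learning: int,
    max_iterations: int | None = None,
    rng_seed: int | None = None,
) -> StimulusSetSelector:
    """Functional wrapper around :class:`StimulusSetSelector`."""
    return StimulusSetSelector(
        set_size=set_size,
        n_learning=n_learning,
        max_iterations=max_iterations,
        random_state=rng_seed,
    ).fit(pool)
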