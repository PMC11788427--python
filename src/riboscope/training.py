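"""Chromosome-fold allocation and the two-fold training / prediction protocol.

Two models are trained on non-overlapping chromosome folds so that every
transcript is scored by a model that never saw its chromosome during
training; the union of the two test folds covers the transcriptome. The
standard human-genome allocation (GRCh38-style chromosome names) is
exposed as ``scheme="paper"``; arbitrary allocations are available via
``scheme="custom"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .encoder import PositionScores
from .estimator import TISTransformer, make_pretrain_labels  # noqa: F401  (re-export)
from .ingest import ReadCountMatrix, SampleProfile
from .transcriptome import GenomeAnnotation

logger = logging.getLogger(__name__)

# Published two-fold allocation for human chromosome names.
_HUMAN_FOLDS = [
    {
        "train": ["3", "5", "7", "11", "13", "15", "19", "21", "X"],
        "val": ["1", "9", "17"],
        "test": ["2", "4", "6", "8", "10", "12", "14", "16", "18", "20", "22", "Y"],
    },
    {
        "train": ["2", "6", "8", "10", "14", "16", "18", "22", "Y"],
        "val": ["4", "12", "20"],
        "test": ["1", "3", "5", "7", "9", "11", "13", "15", "17", "19", "21", "X"],
    },
]


class FoldError(ValueError):
    pass


@dataclass
class Fold:
    train: frozenset[str]
    val: frozenset[str]
    test: frozenset[str]


@dataclass
class FoldAllocation:
    folds: list[Fold] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, f in enumerate(self.folds):
            overlap = (f.train & f.val) | (f.train & f.test) | (f.val & f.test)
            if overlap:
                raise FoldError(
                    f"fold {i}: chromosomes in multiple roles: {sorted(overlap)}"
                )
        tests = [f.test for f in self.folds]
        for i in range(len(tests)):
            for j in range(i + 1, len(tests)):
                both = tests[i] & tests[j]
                if both:
                    raise FoldError(
                        f"chromosome(s) {sorted(both)} in test sets of folds {i} and {j}"
                    )

    def model_for(self, chromosome: str) -> int:
        """Index of the model whose *test* fold holds this chromosome."""
        key = _norm(chromosome)
        for i, f in enumerate(self.folds):
            if key in f.test:
                return i
        raise FoldError(f"chromosome {chromosome!r} is in no test fold")

    def covers(self, chromosomes: Iterable[str]) -> bool:
        return all(any(_norm(c) in f.test for f in self.folds) for c in chromosomes)


def _norm(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def allocate_folds(
    chromosomes: Iterable[str],
    scheme: str = "paper",
    custom: Optional[Sequence[dict[str, Sequence[str]]]] = None,
) -> FoldAllocation:
    """Build a two-fold chromosome allocation.

    ``scheme="paper"`` applies the published human fold lists; chromosomes
    not named in them (unplaced scaffolds, alt contigs) are joined to model
    0's test set so they are still scored, by a model that never trained on
    them. ``scheme="custom"`` validates explicit train/val/test lists.
    """
    chroms = {_norm(c) for c in chromosomes}
    if scheme == "custom":
        if not custom:
            raise FoldError("scheme='custom' requires explicit fold lists")
        folds = [
            Fold(
                train=frozenset(_norm(c) for c in f.get("train", ())),
                val=frozenset(_norm(c) for c in f.get("val", ())),
                test=frozenset(_norm(c) for c in f.get("test", ())),
            )
            for f in custom
        ]
        alloc = FoldAllocation(folds)
        uncovered = {c for c in chroms if not any(c in f.test for f in folds)}
        if uncovered:
            raise FoldError(f"chromosomes in no test fold: {sorted(uncovered)}")
        return alloc
    if scheme != "paper":
        raise FoldError(f"unknown scheme {scheme!r}")
    named = {c for f in _HUMAN_FOLDS for role in f.values() for c in role}
    scaffolds = sorted(chroms - named)
    if scaffolds:
        logger.info("joining %d unlisted scaffolds to fold 0 test set", len(scaffolds))
    folds = [
        Fold(
            train=frozenset(_HUMAN_FOLDS[0]["train"]),
            val=frozenset(_HUMAN_FOLDS[0]["val"]),
            test=frozenset(_HUMAN_FOLDS[0]["test"]) | frozenset(scaffolds),
        ),
        Fold(
            train=frozenset(_HUMAN_FOLDS[1]["train"]),
            val=frozenset(_HUMAN_FOLDS[1]["val"]),
            test=frozenset(_HUMAN_FOLDS[1]["test"]),
        ),
    ]
    return FoldAllocation(folds)


def split_two_fold(chromosomes: Iterable[str]) -> FoldAllocation:
    """Even two-fold split for arbitrary (e.g. synthetic) chromosome names.

    Chromosomes are sorted and dealt alternately; within each model's share,
    roughly 2/3 train, 1/3 validate, and the *other* model's share is its
    test fold, so the two test folds partition the input.
    """
    chroms = sorted({_norm(c) for c in chromosomes})
    if len(chroms) < 4:
        raise FoldError("need at least 4 chromosomes for a two-fold split")
    half_a, half_b = chroms[0::2], chroms[1::2]

    def roles(own: list[str], other: list[str]) -> Fold:
        n_val = max(1, len(own) // 3)
        return Fold(
            train=frozenset(own[:-n_val]), val=frozenset(own[-n_val:]), test=frozenset(other)
        )

    return FoldAllocation([roles(half_a, half_b), roles(half_b, half_a)])


# ---------------------------------------------------------------------------
# Dataset assembly


def _fold_dataset(
    profiles: Sequence[SampleProfile],
    annotation: GenomeAnnotation,
    chromosomes: frozenset[str],
    supervised: bool,
) -> tuple[list[ReadCountMatrix], Optional[list[np.ndarray]], list[str]]:
    X: list[ReadCountMatrix] = []
    y: list[np.ndarray] = []
    ids: list[str] = []
    for prof in profiles:
        for t in annotation:
            if _norm(t.chromosome) not in chromosomes:
                continue
            m = prof.matrices.get(t.transcript_id)
            if m is None:
                continue
            X.append(m)
            ids.append(t.transcript_id)
            if supervised:
                labels = np.zeros(len(t))
                if t.cds is not None:
                    labels[t.cds.tis_index] = 1.0
                y.append(labels)
    return X, (y if supervised else None), ids


def train_supervised(
    profiles: Sequence[SampleProfile],
    annotation: GenomeAnnotation,
    allocation: FoldAllocation,
    init_states: Optional[Sequence[Optional[dict]]] = None,
    **estimator_params,
) -> list[TISTransformer]:
    """Fit one supervised TIS model per fold; returns the fitted estimators.

    ``init_states`` optionally warm-starts each fold model from a
    pretrained checkpoint's weights (fine-tuning); the pretraining head is
    dropped automatically because the supervised head has its own shape.
    """
    estimator_params.setdefault("objective", "supervised")
    models = []
    for i, fold in enumerate(allocation.folds):
        X, y, ids = _fold_dataset(profiles, annotation, fold.train, supervised=True)
        Xv, yv, _ = _fold_dataset(profiles, annotation, fold.val, supervised=True)
        if not X or sum(float(v.sum()) for v in y) == 0:
            raise FoldError(f"fold {i}: no positive TIS labels in training chromosomes")
        init = init_states[i] if init_states is not None else None
        est = TISTransformer(init_state=init, **estimator_params)
        est.fit(X, y, X_val=Xv or None, y_val=yv or None, ids=ids)
        models.append(est)
    return models


def pretrain(
    profiles: Sequence[SampleProfile],
    annotation: GenomeAnnotation,
    allocation: FoldAllocation,
    **estimator_params,
) -> list[TISTransformer]:
    """Masked self-supervised pretraining, one model per fold."""
    estimator_params.setdefault("objective", "masked_pretrain")
    models = []
    for fold in allocation.folds:
        X, _, ids = _fold_dataset(profiles, annotation, fold.train, supervised=False)
        Xv, _, _ = _fold_dataset(profiles, annotation, fold.val, supervised=False)
        est = TISTransformer(**estimator_params)
        est.fit(X, X_val=Xv or None, ids=ids)
        models.append(est)
    return models


def predict_sample(
    profile: SampleProfile,
    models: Sequence[TISTransformer],
    allocation: FoldAllocation,
    annotation: GenomeAnnotation,
) -> dict[str, PositionScores]:
    """Score every transcript with the model whose test fold owns its chromosome."""
    if len(models) != len(allocation.folds):
        raise FoldError("one fitted model per fold required")
    routed: dict[int, list[str]] = {}
    for t in annotation:
        if t.transcript_id in profile.matrices:
            routed.setdefault(allocation.model_for(t.chromosome), []).append(t.transcript_id)
    out: dict[str, PositionScores] = {}
    for idx, tids in routed.items():
        scored = models[idx].predict_proba([profile.matrices[tid] for tid in tids])
        for tid, s in zip(tids, scored):
            out[tid] = PositionScores(tid, s)
    return out
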