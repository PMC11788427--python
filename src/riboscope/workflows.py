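"""End-to-end convenience pipelines used by scripts and higher-level analyses.

These compose the library modules into the standard experiment shapes:
simulate a sample, train the two-fold TIS models, score the held-out
transcriptome, and summarize recovery. All randomness flows from explicit
seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .encoder import PositionScores
from .estimator import TISTransformer
from .evaluation import pr_auc, roc_auc
from .ingest import SampleProfile, ingest_alignments
from .simulate import SimulationConfig, SimulationTruth, simulate_reads, simulate_transcriptome
from .training import FoldAllocation, predict_sample, pretrain, split_two_fold, train_supervised
from .transcriptome import GenomeAnnotation

# Training settings for the desk-scale TIS-recovery experiment: a tiny
# encoder (h=32, 4 layers, 4 heads, exact attention) optimized with Adam.
DESK_SCALE_PARAMS: dict = dict(
    h=32,
    n_layers=4,
    n_heads=4,
    attention_kind="exact",
    dropout=0.0,
    learning_rate=2e-3,
    batch_size=16,
    weight_decay=1e-4,
    pos_weight=50.0,
    max_epochs=18,
    patience=5,
    monitor="pr_auc",
    max_transcript_length=512,
)


@dataclass
class TISExperiment:
    """Artifacts of one simulate-train-predict run."""

    annotation: GenomeAnnotation
    truth: SimulationTruth
    profile: SampleProfile
    allocation: FoldAllocation
    models: list[TISTransformer]
    scores: dict[str, PositionScores]
    heldout_pr_auc: float
    heldout_roc_auc: float
    epochs_to_best: list[int] = field(default_factory=list)


def simulated_sample(
    cfg: SimulationConfig, sam_path: Optional[Path] = None
) -> tuple[GenomeAnnotation, SimulationTruth, SampleProfile]:
    """Simulate annotation + reads; ingest through the SAM round trip when a
    path is given, else use the generator's matrices directly."""
    annotation, truth = simulate_transcriptome(cfg)
    if sam_path is not None:
        truth = simulate_reads(annotation, truth, cfg, sam_path)
        profile = ingest_alignments(sam_path, annotation, sample_id="simulated")
    else:
        import tempfile

        with tempfile.TemporaryDirectory() as d:
            truth = simulate_reads(annotation, truth, cfg, Path(d) / "reads.sam")
        profile = SampleProfile(
            "simulated",
            truth.matrices,
            mapped_reads=sum(m.total_reads for m in truth.matrices.values()),
            in_frame_occupancy=truth.realized_in_frame_occupancy,
        )
    return annotation, truth, profile


def tis_labels(annotation: GenomeAnnotation) -> dict[str, np.ndarray]:
    out = {}
    for t in annotation:
        y = np.zeros(len(t))
        if t.cds is not None:
            y[t.cds.tis_index] = 1.0
        out[t.transcript_id] = y
    return out


def heldout_auc(
    annotation: GenomeAnnotation, scores: dict[str, PositionScores]
) -> tuple[float, float]:
    """Pooled PR/ROC AUC of annotated-TIS detection over scored transcripts."""
    labels = tis_labels(annotation)
    y = np.concatenate([labels[tid] for tid in scores])
    s = np.concatenate([scores[tid].scores for tid in scores])
    return pr_auc(s, y), roc_auc(s, y)


def run_tis_experiment(
    annotation: GenomeAnnotation,
    truth: SimulationTruth,
    profile: SampleProfile,
    seed: int = 0,
    allocation: Optional[FoldAllocation] = None,
    init_states: Optional[Sequence[Optional[dict]]] = None,
    score: bool = True,
    **overrides,
) -> TISExperiment:
    """Two-fold training + held-out prediction of annotated TISs.

    ``score=False`` skips the transcriptome-wide prediction pass (useful
    when only the training trajectories are of interest).
    """
    params = dict(DESK_SCALE_PARAMS)
    params.update(overrides)
    params["seed"] = seed
    if allocation is None:
        allocation = split_two_fold(annotation.chromosomes)
    models = train_supervised(
        [profile], annotation, allocation, init_states=init_states, **params
    )
    if score:
        scores = predict_sample(profile, models, allocation, annotation)
        pr, roc = heldout_auc(annotation, scores)
    else:
        scores, pr, roc = {}, float("nan"), float("nan")
    return TISExperiment(
        annotation=annotation,
        truth=truth,
        profile=profile,
        allocation=allocation,
        models=models,
        scores=scores,
        heldout_pr_auc=pr,
        heldout_roc_auc=roc,
        epochs_to_best=[m.best_epoch_ for m in models],
    )


def run_single_fold(
    annotation: GenomeAnnotation,
    profile: SampleProfile,
    seed: int = 0,
    fold: int = 0,
    allocation: Optional[FoldAllocation] = None,
    **overrides,
) -> tuple[TISTransformer, float, float]:
    """Train one fold model and evaluate on its held-out test chromosomes.

    A cheaper variant of the two-fold experiment for parameter sweeps:
    the returned PR/ROC AUCs pool only the chosen fold's test transcripts.
    """
    from .training import _fold_dataset

    params = dict(DESK_SCALE_PARAMS)
    params.update(overrides)
    params["seed"] = seed
    if allocation is None:
        allocation = split_two_fold(annotation.chromosomes)
    f = allocation.folds[fold]
    X, y, ids = _fold_dataset([profile], annotation, f.train, supervised=True)
    Xv, yv, _ = _fold_dataset([profile], annotation, f.val, supervised=True)
    est = TISTransformer(**params)
    est.fit(X, y, X_val=Xv or None, y_val=yv or None, ids=ids)
    Xt, yt, _ = _fold_dataset([profile], annotation, f.test, supervised=True)
    scores = np.concatenate(est.predict_proba(Xt))
    labels = np.concatenate(yt)
    return est, pr_auc(scores, labels), roc_auc(scores, labels)


def run_pretraining(
    annotation: GenomeAnnotation,
    profile: SampleProfile,
    seed: int = 0,
    allocation: Optional[FoldAllocation] = None,
    **overrides,
) -> list[TISTransformer]:
    """Masked self-supervised pretraining of the two fold models."""
    params = dict(DESK_SCALE_PARAMS)
    params.update(overrides)
    params["seed"] = seed
    params["objective"] = "masked_pretrain"
    if allocation is None:
        allocation = split_two_fold(annotation.chromosomes)
    return pretrain([profile], annotation, allocation, **params)
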