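"""Scoring-quality metrics, ORF-library benchmarking and quantification.

ROC AUC is the Mann-Whitney probability P(score_pos > score_neg) + half
the tie probability; PR AUC is average precision (step-wise interpolation,
deliberately not trapezoidal, which is optimistic on sparse positives).
Benchmarking scores each entry of an externally defined ORF library by the
model probability at its TIS.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .ingest import SampleProfile
from .orf_calling import OrfCall, ScoresLike, _score_array


@dataclass
class LibraryEntry:
    transcript_id: str
    tis_index: int
    stop_index: int
    label: int  # 1 positive, 0 negative


@dataclass
class OrfLibrary:
    entries: list[LibraryEntry]
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [(e.transcript_id, e.tis_index, e.stop_index) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (transcript, tis, stop) entries in ORF library")

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "transcript_id": e.transcript_id,
                    "tis_index": e.tis_index,
                    "stop_index": e.stop_index,
                    "label": e.label,
                }
                for e in self.entries
            ]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "") -> "OrfLibrary":
        df = pd.read_csv(path, sep="\t")
        return cls(
            [
                LibraryEntry(
                    str(r.transcript_id), int(r.tis_index), int(r.stop_index), int(r.label)
                )
                for r in df.itertuples()
            ],
            provenance=provenance or str(path),
        )


def _check_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("AUC requires both a positive and a negative class")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_classes(labels)
    return float(roc_auc_score(labels, scores))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_classes(labels)
    return float(average_precision_score(labels, scores))


def benchmark_library(
    scores: ScoresLike, library: OrfLibrary
) -> tuple[float, float]:
    """(ROC AUC, PR AUC) of model scores at each library entry's TIS.

    Every library transcript must be scored; entries on unscored
    transcripts are an error, never silently dropped.
    """
    missing = sorted({e.transcript_id for e in library.entries} - set(scores.keys()))
    if missing:
        raise ValueError(f"library entries on unscored transcripts: {missing[:10]}")
    s = np.array([_score_array(scores, e.transcript_id)[e.tis_index] for e in library.entries])
    y = np.array([e.label for e in library.entries])
    return roc_auc(s, y), pr_auc(s, y)


# ---------------------------------------------------------------------------
# Quantification


def tpm_quantify(
    calls: Sequence[OrfCall],
    profiles: Sequence[SampleProfile] | Mapping[str, SampleProfile],
) -> pd.DataFrame:
    """ORF x sample TPM matrix from 5'-end counts within each ORF span.

    An ORF's rate is its in-span read count divided by its span length
    (reads per base); TPM scales rates to a million over all quantified
    ORFs per sample. A read belongs to an ORF when its 5'-end lies in
    ``[tis, stop + 3)``.
    """
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    orf_ids = [f"{c.transcript_id}:{c.tis_index}-{c.stop_index}" for c in calls]
    out = {}
    for prof in profiles:
        rates = np.zeros(len(calls))
        for i, c in enumerate(calls):
            m = prof.matrices.get(c.transcript_id)
            if m is None:
                continue
            lo, hi = c.span
            n = sum(v for (pos, _rl), v in m.counts.items() if lo <= pos < hi)
            rates[i] = n / (hi - lo)
        total = rates.sum()
        if total == 0:
            raise ValueError(f"sample {prof.sample_id}: zero total rate, cannot TPM-normalize")
        out[prof.sample_id] = rates / total * 1e6
    return pd.DataFrame(out, index=orf_ids)


def ncorf_cds_correlation(
    tpm: pd.DataFrame, pairs: Sequence[tuple[str, str]], min_samples: int = 4
) -> pd.DataFrame:
    """Two-sided Spearman correlation across samples for each (ncORF, CDS) pair.

    Ties are mid-ranked. Pairs with a constant TPM vector get ``rho = NaN``
    and ``defined = False`` (correlation undefined), not a silent zero.
    """
    if tpm.shape[1] < min_samples:
        raise ValueError(f"need >= {min_samples} samples, have {tpm.shape[1]}")
    rows = []
    for nc, cds in pairs:
        a = tpm.loc[nc].to_numpy(dtype=float)
        b = tpm.loc[cds].to_numpy(dtype=float)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            rows.append({"ncorf": nc, "cds": cds, "rho": np.nan, "p": np.nan, "defined": False})
            continue
        res = stats.spearmanr(a, b)
        rows.append(
            {"ncorf": nc, "cds": cds, "rho": float(res.statistic), "p": float(res.pvalue), "defined": True}
        )
    return pd.DataFrame(rows)
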