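"""From per-position TIS scores to called ORFs.

Candidate TISs are positions scoring above a threshold (default 0.15).
Each candidate is (1) moved to a nearby in-frame ATG when it is itself a
non-ATG codon and an ATG lies within nine codons, (2) extended to the first
in-frame stop codon (greedy scan), and (3) filtered: the start codon must
match N-T-G (ATG/CTG/GTG/TTG) and an in-frame stop must exist on the
transcript. Calls are deduplicated on (transcript, TIS, stop), keeping the
best score. A multi-sample consensus keeps ORFs called in at least
``min_samples`` samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .encoder import PositionScores
from .transcriptome import GenomeAnnotation, STOP_CODONS, TranscriptRecord

DEFAULT_SCORE_THRESHOLD = 0.15
NEIGHBORHOOD_CODONS = 9


@dataclass
class OrfCall:
    transcript_id: str
    tis_index: int
    stop_index: Optional[int]  # first base of the in-frame stop codon
    start_codon: str
    score: float = 0.0
    corrected_from: Optional[int] = None
    orf_type: Optional[str] = None
    evidence: Optional[str] = None
    support: int = 1
    gene_id: Optional[str] = None

    @property
    def key(self) -> tuple[str, int, Optional[int]]:
        return (self.transcript_id, self.tis_index, self.stop_index)

    @property
    def span(self) -> tuple[int, int]:
        """Half-open transcript span including the stop codon."""
        if self.stop_index is None:
            raise ValueError("ORF without stop codon has no span")
        return (self.tis_index, self.stop_index + 3)


ScoresLike = Union[Mapping[str, PositionScores], Mapping[str, np.ndarray]]


def _score_array(scores: ScoresLike, tid: str) -> np.ndarray:
    s = scores[tid]
    return s.scores if isinstance(s, PositionScores) else np.asarray(s)


def construct_orf(t: TranscriptRecord, tis: int) -> Optional[OrfCall]:
    """Greedy extension: scan codons from ``tis`` to the first in-frame stop.

    Returns ``None`` when no in-frame stop codon exists before the
    transcript end (absence is a value, filtered later).
    """
    if tis < 0 or tis + 3 > len(t):
        raise IndexError(f"TIS {tis} cannot host a codon on {t.transcript_id}")
    seq = t.sequence.upper().replace("U", "T")
    for pos in range(tis + 3, len(seq) - 2, 3):
        if seq[pos : pos + 3] in STOP_CODONS:
            return OrfCall(
                transcript_id=t.transcript_id,
                tis_index=tis,
                stop_index=pos,
                start_codon=seq[tis : tis + 3],
                gene_id=t.gene_id,
            )
    return None


def neighborhood_correct(
    t: TranscriptRecord, tis: int, scores: Optional[np.ndarray] = None
) -> int:
    """Move a non-ATG candidate to the nearest in-frame ATG within 9 codons.

    An ATG candidate is returned unchanged. Ties between an upstream and a
    downstream ATG at equal codon distance resolve upstream (the longer
    ORF). Idempotent: the result is always an ATG or the original position.
    """
    if t.codon_at(tis) == "ATG":
        return tis
    for k in range(1, NEIGHBORHOOD_CODONS + 1):
        up = tis - 3 * k
        if up >= 0 and up + 3 <= len(t) and t.codon_at(up) == "ATG":
            return up
        down = tis + 3 * k
        if down + 3 <= len(t) and t.codon_at(down) == "ATG":
            return down
    return tis


def apply_filters(call: OrfCall) -> tuple[bool, Optional[str]]:
    """Start-codon (N-T-G) and stop-presence filters; returns (keep, reason)."""
    if len(call.start_codon) != 3 or call.start_codon[1:] != "TG":
        return False, "invalid_start_codon"
    if call.stop_index is None:
        return False, "no_stop_on_transcript"
    return True, None


def call_orfs(
    scores: ScoresLike,
    annotation: GenomeAnnotation,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    correct_neighborhood: bool = True,
    audit: Optional[list] = None,
) -> list[OrfCall]:
    """Threshold, correct, construct and filter ORF calls for one sample.

    The threshold applies to the original predicted position; the score of
    a corrected call remains the score at the original position (the
    model's evidence), while the coordinate moves to the corrected ATG.
    """
    out: dict[tuple, OrfCall] = {}
    for tid in scores:
        if tid not in annotation:
            continue
        t = annotation[tid]
        arr = _score_array(scores, tid)
        if len(arr) != len(t):
            raise ValueError(f"{tid}: scores length {len(arr)} != transcript {len(t)}")
        for pos in np.nonzero(arr > threshold)[0]:
            pos = int(pos)
            if pos + 3 > len(t):
                continue
            tis = neighborhood_correct(t, pos) if correct_neighborhood else pos
            call = construct_orf(t, tis)
            if call is None:
                call = OrfCall(
                    transcript_id=tid,
                    tis_index=tis,
                    stop_index=None,
                    start_codon=t.codon_at(tis),
                    gene_id=t.gene_id,
                )
            call.score = float(arr[pos])
            if tis != pos:
                call.corrected_from = pos
            keep, reason = apply_filters(call)
            if not keep:
                if audit is not None:
                    audit.append((tid, pos, reason))
                continue
            prev = out.get(call.key)
            if prev is None or call.score > prev.score:
                out[call.key] = call
    return sorted(out.values(), key=lambda c: (c.transcript_id, c.tis_index))


def consensus_calls(
    call_sets: Sequence[Sequence[OrfCall]], min_samples: int = 2
) -> list[OrfCall]:
    """ORFs present in at least ``min_samples`` samples, with support counts."""
    if min_samples > len(call_sets):
        raise ValueError(
            f"min_samples={min_samples} exceeds number of samples {len(call_sets)}"
        )
    best: dict[tuple, OrfCall] = {}
    seen_in: dict[tuple, int] = {}
    for calls in call_sets:
        keys_this_sample = set()
        for c in calls:
            if c.key in keys_this_sample:
                continue
            keys_this_sample.add(c.key)
            seen_in[c.key] = seen_in.get(c.key, 0) + 1
            prev = best.get(c.key)
            if prev is None or c.score > prev.score:
                best[c.key] = c
    out = []
    for key, n in seen_in.items():
        if n >= min_samples:
            out.append(replace(best[key], support=n))
    return sorted(out, key=lambda c: (c.transcript_id, c.tis_index))


# ---------------------------------------------------------------------------
# Output


def calls_to_table(calls: Sequence[OrfCall], sample_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": sample_id,
                "transcript_id": c.transcript_id,
                "gene_id": c.gene_id,
                "tis_index": c.tis_index,
                "stop_index": c.stop_index,
                "start_codon": c.start_codon,
                "score": c.score,
                "support": c.support,
                "orf_type": c.orf_type,
                "corrected_from": c.corrected_from,
            }
            for c in calls
        ]
    )


def write_calls_tsv(calls: Sequence[OrfCall], path: str | Path, sample_id: str = "") -> None:
    calls_to_table(calls, sample_id).to_csv(path, sep="\t", index=False)


def write_calls_bed(
    calls: Sequence[OrfCall], annotation: GenomeAnnotation, path: str | Path
) -> None:
    """BED12 of ORF spans in genome coordinates (blocks follow exon structure)."""
    rows = []
    for c in calls:
        if c.stop_index is None:
            continue
        t = annotation[c.transcript_id]
        lo, hi = c.span
        gpos = sorted(t.to_genomic(p) for p in range(lo, hi))
        blocks: list[tuple[int, int]] = []
        for g in gpos:
            if blocks and g == blocks[-1][1]:
                blocks[-1] = (blocks[-1][0], g + 1)
            else:
                blocks.append((g, g + 1))
        chrom_start, chrom_end = blocks[0][0], blocks[-1][1]
        rows.append(
            "\t".join(
                str(v)
                for v in [
                    t.chromosome,
                    chrom_start,
                    chrom_end,
                    f"{c.transcript_id}:{c.tis_index}-{c.stop_index}",
                    int(round(1000 * c.score)),
                    t.strand,
                    chrom_start,
                    chrom_end,
                    "0,0,0",
                    len(blocks),
                    ",".join(str(e - s) for s, e in blocks) + ",",
                    ",".join(str(s - chrom_start) for s, _ in blocks) + ",",
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))
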