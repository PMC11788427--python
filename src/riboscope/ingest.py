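"""Ingestion of transcript-space RPF alignments into position x read-length counts.

Only each read's 5'-end position and aligned length are used. No P-site or
A-site offsetting is applied and no frame-based filtering happens here: the
count matrices are exactly what the model consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import h5py
import numpy as np
import pysam

from .transcriptome import GenomeAnnotation

logger = logging.getLogger(__name__)

MIN_READ_LENGTH = 20
MAX_READ_LENGTH = 40
N_READ_LENGTHS = MAX_READ_LENGTH - MIN_READ_LENGTH + 1  # 21


class IngestError(ValueError):
    pass


class NoCdsReadsError(ValueError):
    """In-frame occupancy is undefined: no reads fall inside annotated CDSs."""


@dataclass
class ReadCountMatrix:
    """Sparse per-transcript counts of RPF 5'-ends by position and read length."""

    transcript_id: str
    length: int  # transcript length in nt
    counts: dict[tuple[int, int], int] = field(default_factory=dict)

    def add(self, pos: int, read_length: int, n: int = 1) -> None:
        if not 0 <= pos < self.length:
            raise IngestError(
                f"{self.transcript_id}: position {pos} outside transcript of "
                f"length {self.length}"
            )
        if not MIN_READ_LENGTH <= read_length <= MAX_READ_LENGTH:
            raise IngestError(f"read length {read_length} outside [20, 40]")
        key = (pos, read_length)
        self.counts[key] = self.counts.get(key, 0) + n

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def to_dense(self) -> np.ndarray:
        """(length, 21) dense count array; column i is read length 20+i."""
        dense = np.zeros((self.length, N_READ_LENGTHS), dtype=np.int64)
        for (pos, rl), n in self.counts.items():
            dense[pos, rl - MIN_READ_LENGTH] = n
        return dense

    @classmethod
    def from_dense(cls, transcript_id: str, dense: np.ndarray) -> "ReadCountMatrix":
        if dense.ndim != 2 or dense.shape[1] != N_READ_LENGTHS:
            raise IngestError("dense matrix must have 21 read-length columns")
        m = cls(transcript_id=transcript_id, length=dense.shape[0])
        for pos, li in zip(*np.nonzero(dense)):
            m.counts[(int(pos), int(li) + MIN_READ_LENGTH)] = int(dense[pos, li])
        return m

    def position_totals(self) -> np.ndarray:
        tot = np.zeros(self.length, dtype=np.int64)
        for (pos, _rl), n in self.counts.items():
            tot[pos] += n
        return tot


@dataclass
class SampleProfile:
    sample_id: str
    matrices: dict[str, ReadCountMatrix]
    mapped_reads: int = 0
    in_frame_occupancy: Optional[float] = None

    def __getitem__(self, transcript_id: str) -> ReadCountMatrix:
        return self.matrices[transcript_id]


def ingest_alignments(
    bam_path: str | Path,
    annotation: GenomeAnnotation,
    length_min: int = MIN_READ_LENGTH,
    length_max: int = MAX_READ_LENGTH,
    sample_id: Optional[str] = None,
) -> SampleProfile:
    """Build per-transcript count matrices from a transcript-space SAM/BAM.

    Accepts primary, forward-strand alignments whose aligned reference span
    is within ``[length_min, length_max]``; increments the count at the
    read's 5'-end. Secondary/supplementary and reverse-strand alignments are
    skipped (RPFs are sense-strand by construction). Reads on transcripts
    absent from the annotation are counted and logged, not stored.

    Raises :class:`IngestError` when the file's reference names look like
    chromosomes rather than transcript ids (genome-space alignments).
    """
    bam_path = Path(bam_path)
    sample_id = sample_id or bam_path.stem
    mode = "rb" if bam_path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(bam_path), mode, check_sq=False) as fh:
        refs = list(fh.references)
        known = [r for r in refs if r in annotation]
        chrom_like = [r for r in refs if r in annotation.chromosomes]
        if not known and chrom_like:
            raise IngestError(
                "alignment reference names match chromosomes, not transcript ids: "
                "these look like genome-space alignments. Re-align to the "
                "transcriptome (e.g. STAR --quantMode TranscriptomeSAM) and retry."
            )
        matrices = {
            t.transcript_id: ReadCountMatrix(t.transcript_id, len(t))
            for t in annotation
        }
        accepted = 0
        unknown_ref = 0
        reverse = 0
        clipped = 0
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_reverse:
                reverse += 1
                continue
            if aln.cigartuples and any(op in (4, 5) for op, _ in aln.cigartuples):
                clipped += 1
            rl = aln.reference_length
            if rl is None or not length_min <= rl <= length_max:
                continue
            tid = aln.reference_name
            if tid not in matrices:
                unknown_ref += 1
                continue
            matrices[tid].add(aln.reference_start, rl)
            accepted += 1
    if unknown_ref:
        logger.warning("%s: %d reads on transcripts absent from annotation", sample_id, unknown_ref)
    if reverse:
        logger.info("%s: discarded %d reverse-strand alignments", sample_id, reverse)
    if clipped:
        logger.warning("%s: %d clipped alignments seen; 5'-ends taken as aligned start", sample_id, clipped)
    logger.info("%s: accepted %d alignments", sample_id, accepted)
    profile = SampleProfile(sample_id=sample_id, matrices=matrices, mapped_reads=accepted)
    try:
        profile.in_frame_occupancy = in_frame_occupancy(profile, annotation)
    except NoCdsReadsError:
        profile.in_frame_occupancy = None
    return profile


def in_frame_occupancy(profile: SampleProfile, annotation: GenomeAnnotation) -> float:
    """Fraction of CDS-internal reads whose 5'-end is in the CDS reading frame.

    Reads are pooled over all transcripts with an annotated CDS
    (micro-average); a read is CDS-internal when its 5'-end lies within
    ``[tis, stop + 3)``. Raises :class:`NoCdsReadsError` when no read falls
    inside any CDS, which is distinct from an occupancy of 0.0.
    """
    in_frame = 0
    total = 0
    for t in annotation:
        if t.cds is None:
            continue
        m = profile.matrices.get(t.transcript_id)
        if m is None:
            continue
        lo, hi = t.cds.span
        for (pos, _rl), n in m.counts.items():
            if lo <= pos < hi:
                total += n
                if (pos - t.cds.tis_index) % 3 == 0:
                    in_frame += n
    if total == 0:
        raise NoCdsReadsError("no reads within annotated CDS regions")
    return in_frame / total


def reads_per_base(matrix: ReadCountMatrix, start: int, stop: int) -> float:
    """Mean 5'-end count per nucleotide over ``[start, stop)``."""
    if not 0 <= start < stop <= matrix.length:
        raise IngestError(
            f"bad interval [{start}, {stop}) on {matrix.transcript_id} "
            f"(length {matrix.length})"
        )
    n = sum(c for (pos, _rl), c in matrix.counts.items() if start <= pos < stop)
    return n / (stop - start)


# ---------------------------------------------------------------------------
# Persistence


def save_profile(profile: SampleProfile, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["sample_id"] = profile.sample_id
        fh.attrs["mapped_reads"] = profile.mapped_reads
        if profile.in_frame_occupancy is not None:
            fh.attrs["in_frame_occupancy"] = profile.in_frame_occupancy
        grp = fh.create_group("transcripts")
        for tid, m in profile.matrices.items():
            g = grp.create_group(tid)
            g.attrs["length"] = m.length
            if m.counts:
                items = sorted(m.counts.items())
                arr = np.array(
                    [(p, rl, n) for (p, rl), n in items], dtype=np.int64
                )
            else:
                arr = np.zeros((0, 3), dtype=np.int64)
            g.create_dataset("counts", data=arr)


def load_profile(path: str | Path) -> SampleProfile:
    with h5py.File(path, "r") as fh:
        matrices = {}
        for tid, g in fh["transcripts"].items():
            m = ReadCountMatrix(tid, int(g.attrs["length"]))
            for p, rl, n in g["counts"][()]:
                m.counts[(int(p), int(rl))] = int(n)
            matrices[tid] = m
        return SampleProfile(
            sample_id=str(fh.attrs["sample_id"]),
            matrices=matrices,
            mapped_reads=int(fh.attrs["mapped_reads"]),
            in_frame_occupancy=float(fh.attrs["in_frame_occupancy"])
            if "in_frame_occupancy" in fh.attrs
            else None,
        )


def qc_table(profiles: Iterable[SampleProfile]):
    """QC summary rows (sample, mapped reads, in-frame occupancy) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "mapped_reads": p.mapped_reads,
                "in_frame_occupancy": p.in_frame_occupancy,
            }
            for p in profiles
        ]
    )
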