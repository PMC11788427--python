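"""Transcript annotation model: records, coordinate maps and codon access.

All coordinates are 0-based, half-open. Transcript coordinates are
strand-resolved: position 0 is the 5' end of the mature transcript
regardless of genomic strand. The GTF/GFF3 1-based closed convention is
converted once, at the parser boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"(\w+)=([^;]+)")


class AnnotationError(ValueError):
    """Raised for unusable annotation inputs."""


@dataclass
class CdsSpan:
    """Annotated coding region in transcript coordinates.

    ``tis_index`` is the first base of the start codon, ``stop_index`` the
    first base of the stop codon, so the translated span is
    ``[tis_index, stop_index)`` and the full CDS footprint including the
    stop codon is ``[tis_index, stop_index + 3)``.
    """

    tis_index: int
    stop_index: int

    @property
    def span(self) -> tuple[int, int]:
        return self.tis_index, self.stop_index + 3


@dataclass
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, 0-based half-open, sorted ascending
    sequence: str  # 5'->3' transcript orientation, DNA alphabet
    biotype_tags: frozenset[str] = field(default_factory=frozenset)
    cds: Optional[CdsSpan] = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if sum(e - s for s, e in self.exons) != len(self.sequence):
            raise AnnotationError(
                f"{self.transcript_id}: exon span sum != sequence length"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_coding(self) -> bool:
        return self.cds is not None

    def to_genomic(self, pos: int) -> int:
        """Map a transcript coordinate to its genomic coordinate."""
        if not 0 <= pos < len(self.sequence):
            raise IndexError(
                f"position {pos} out of range for transcript "
                f"{self.transcript_id} (length {len(self.sequence)})"
            )
        if self.strand == "+":
            off = pos
            for start, end in self.exons:
                if off < end - start:
                    return start + off
                off -= end - start
        else:
            off = pos
            for start, end in reversed(self.exons):
                if off < end - start:
                    return end - 1 - off
                off -= end - start
        raise AssertionError("unreachable: exon map exhausted")

    def to_transcript(self, gpos: int) -> int:
        """Map a genomic coordinate on an exon to its transcript coordinate."""
        if self.strand == "+":
            off = 0
            for start, end in self.exons:
                if start <= gpos < end:
                    return off + (gpos - start)
                off += end - start
        else:
            off = 0
            for start, end in reversed(self.exons):
                if start <= gpos < end:
                    return off + (end - 1 - gpos)
                off += end - start
        raise IndexError(
            f"genomic position {gpos} not exonic on transcript {self.transcript_id}"
        )

    def codon_at(self, pos: int) -> str:
        """Return the uppercase DNA codon starting at transcript position ``pos``."""
        if pos < 0 or pos + 3 > len(self.sequence):
            raise IndexError(
                f"codon at {pos} out of range on {self.transcript_id} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[pos : pos + 3].upper().replace("U", "T")


def codon_at(t: TranscriptRecord, pos: int) -> str:
    return t.codon_at(pos)


def transcript_to_genomic(t: TranscriptRecord, pos: int) -> int:
    return t.to_genomic(pos)


def genomic_to_transcript(t: TranscriptRecord, gpos: int) -> int:
    return t.to_transcript(gpos)


class GenomeAnnotation:
    """Keyed collection of transcripts plus a genomic CDS interval index.

    The interval index stores, per chromosome, every annotated CDS footprint
    (start codon through stop codon, genomic coordinates) and the genomic
    start/stop codon sites themselves, supporting the overlap and
    shared-site queries used by ORF taxonomy assignment.
    """

    def __init__(self, transcripts: Iterable[TranscriptRecord]):
        self.transcripts: dict[str, TranscriptRecord] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise AnnotationError(f"duplicate transcript id {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
        self._cds_tree: dict[str, IntervalTree] = {}
        self._exon_tree: dict[str, IntervalTree] = {}
        # genomic first-base of annotated start / stop codons, per chromosome+strand
        self._cds_start_sites: set[tuple[str, str, int]] = set()
        self._cds_stop_sites: set[tuple[str, str, int]] = set()
        for t in self.transcripts.values():
            if t.cds is not None:
                lo, hi = t.cds.span
                g = sorted(
                    (t.to_genomic(lo), t.to_genomic(hi - 1))
                )
                self._cds_tree.setdefault(t.chromosome, IntervalTree()).addi(
                    g[0], g[1] + 1, t.transcript_id
                )
                self._cds_start_sites.add(
                    (t.chromosome, t.strand, t.to_genomic(t.cds.tis_index))
                )
                self._cds_stop_sites.add(
                    (t.chromosome, t.strand, t.to_genomic(t.cds.stop_index))
                )
            if "protein_coding" in t.biotype_tags or t.cds is not None:
                tree = self._exon_tree.setdefault(t.chromosome, IntervalTree())
                for s, e in t.exons:
                    tree.addi(s, e, t.transcript_id)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptRecord]:
        return iter(self.transcripts.values())

    def __getitem__(self, transcript_id: str) -> TranscriptRecord:
        return self.transcripts[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    @property
    def chromosomes(self) -> set[str]:
        return {t.chromosome for t in self.transcripts.values()}

    def cds_overlapping(self, chromosome: str, gpos: int) -> set[str]:
        """Transcript ids whose annotated CDS footprint covers ``gpos``."""
        tree = self._cds_tree.get(chromosome)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(gpos)}

    def coding_exon_overlapping(self, chromosome: str, gpos: int) -> set[str]:
        tree = self._exon_tree.get(chromosome)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(gpos)}

    def is_cds_start_site(self, chromosome: str, strand: str, gpos: int) -> bool:
        return (chromosome, strand, gpos) in self._cds_start_sites

    def is_cds_stop_site(self, chromosome: str, strand: str, gpos: int) -> bool:
        return (chromosome, strand, gpos) in self._cds_stop_sites


# ---------------------------------------------------------------------------
# GTF / GFF3 parsing


def _parse_attributes(attr_field: str) -> dict[str, str]:
    # GTF: key "value"; pairs. GFF3: key=value; pairs. Auto-detect per line.
    if "=" in attr_field and '"' not in attr_field:
        return {k: v.strip() for k, v in _GFF3_ATTR.findall(attr_field)}
    return dict(_GTF_ATTR.findall(attr_field))


_BIOTYPE_KEYS = ("transcript_biotype", "transcript_type", "gene_biotype", "gene_type", "biotype")
_TAG_KEYS = ("tag",)


def load_annotation(
    gtf_path: str | Path,
    fasta_path: str | Path,
    strict_cds: bool = False,
) -> GenomeAnnotation:
    """Load a GTF/GFF3 annotation plus genome or transcript FASTA.

    Spliced transcript sequences are extracted from a genome FASTA (and
    reverse-complemented for minus-strand transcripts); when the FASTA
    records are keyed by transcript id instead, sequences are taken verbatim.
    CDS positions come from ``start_codon``/``stop_codon`` features when
    present, otherwise from the 5'-most / 3'-most CDS feature codons.

    With ``strict_cds=False`` (default) a CDS whose stop codon is not
    TAA/TAG/TGA or whose length is not a codon multiple is kept but the
    record is tagged ``nonstandard_cds``; with ``strict_cds=True`` such
    transcripts are rejected.
    """
    gtf_path, fasta_path = Path(gtf_path), Path(fasta_path)
    seqs = {rec.id: str(rec.seq).upper().replace("U", "T") for rec in SeqIO.parse(str(fasta_path), "fasta")}

    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    cds_feats: dict[str, list[tuple[int, int]]] = {}
    start_feats: dict[str, list[tuple[int, int]]] = {}
    stop_feats: dict[str, list[tuple[int, int]]] = {}
    skipped = 0

    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                skipped += 1
                continue
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts
            try:
                iv = (int(start) - 1, int(end))  # 1-based closed -> 0-based half-open
            except ValueError:
                skipped += 1
                continue
            a = _parse_attributes(attrs)
            tid = a.get("transcript_id") or a.get("Parent") or a.get("ID")
            if tid is None:
                continue
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
                m = meta.setdefault(tid, {"chrom": chrom, "strand": strand, "tags": set()})
                m["gene_id"] = a.get("gene_id", m.get("gene_id", tid))
                for key in _BIOTYPE_KEYS:
                    if key in a:
                        m["tags"].add(a[key])
                for key in _TAG_KEYS:
                    if key in a:
                        m["tags"].add(a[key])
            elif feature == "CDS":
                cds_feats.setdefault(tid, []).append(iv)
            elif feature == "start_codon":
                start_feats.setdefault(tid, []).append(iv)
            elif feature == "stop_codon":
                stop_feats.setdefault(tid, []).append(iv)
    if skipped:
        logger.warning("skipped %d malformed feature lines in %s", skipped, gtf_path)

    records: list[TranscriptRecord] = []
    missing_chrom: list[str] = []
    rejected = 0
    for tid, ex in exons.items():
        m = meta[tid]
        ex = sorted(ex)
        if not ex or sum(e - s for s, e in ex) < 3:
            rejected += 1
            continue
        if tid in seqs:
            seq = seqs[tid]
        elif m["chrom"] in seqs:
            chrom_seq = seqs[m["chrom"]]
            seq = "".join(chrom_seq[s:e] for s, e in ex)
            if m["strand"] == "-":
                seq = str(Seq(seq).reverse_complement())
        else:
            missing_chrom.append(tid)
            continue
        rec = TranscriptRecord(
            transcript_id=tid,
            gene_id=m.get("gene_id", tid),
            chromosome=m["chrom"],
            strand=m["strand"],
            exons=ex,
            sequence=seq,
            biotype_tags=frozenset(m["tags"]),
        )
        cds = _resolve_cds(rec, start_feats.get(tid), stop_feats.get(tid), cds_feats.get(tid))
        if cds is not None:
            flags = set()
            length = cds.stop_index - cds.tis_index
            ok = length > 0 and length % 3 == 0
            if ok and cds.stop_index + 3 <= len(seq):
                ok = rec.codon_at(cds.stop_index) in STOP_CODONS
            else:
                ok = False
            if not ok:
                if strict_cds:
                    rejected += 1
                    continue
                flags.add("nonstandard_cds")
            rec.cds = cds
            rec.flags = frozenset(flags)
        records.append(rec)

    if missing_chrom:
        raise AnnotationError(
            "FASTA lacks sequence for transcripts: " + ", ".join(sorted(missing_chrom)[:10])
        )
    if rejected:
        logger.warning("rejected %d transcripts (too short / non-standard CDS)", rejected)
    return GenomeAnnotation(records)


def _resolve_cds(
    rec: TranscriptRecord,
    starts: Optional[list[tuple[int, int]]],
    stops: Optional[list[tuple[int, int]]],
    cds: Optional[list[tuple[int, int]]],
) -> Optional[CdsSpan]:
    """Derive (tis_index, stop_index) in transcript coordinates."""

    def five_prime_base(ivs: list[tuple[int, int]]) -> int:
        gs = [g for s, e in ivs for g in (s, e - 1)]
        g = min(gs) if rec.strand == "+" else max(gs)
        return rec.to_transcript(g)

    tis: Optional[int] = None
    stop: Optional[int] = None
    if starts:
        tis = five_prime_base(starts)
    if stops:
        stop = five_prime_base(stops)
    if cds:
        first = five_prime_base(cds)
        gs = [g for s, e in cds for g in (s, e - 1)]
        g_last = max(gs) if rec.strand == "+" else min(gs)
        last = rec.to_transcript(g_last)
        if tis is None:
            tis = first
        if stop is None:
            # CDS features may or may not include the stop codon; if the codon
            # right after the CDS footprint is a stop, use it, else assume the
            # footprint's final codon is the stop.
            after = last + 1
            if after + 3 <= len(rec.sequence) and rec.codon_at(after) in STOP_CODONS:
                stop = after
            else:
                stop = last - 2
    if tis is not None and stop is None:
        # start_codon-only dialect: greedy scan to the first in-frame stop
        for pos in range(tis + 3, len(rec.sequence) - 2, 3):
            if rec.codon_at(pos) in STOP_CODONS:
                stop = pos
                break
    if tis is None or stop is None:
        return None
    return CdsSpan(tis_index=tis, stop_index=stop)
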