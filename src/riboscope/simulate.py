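"""Synthetic Ribo-Seq generator with known ground truth.

Emulates the structures the TIS classifier must distinguish: random
transcriptomes with planted canonical CDSs and non-canonical ORFs of every
taxonomy class, and ribosome footprints whose 5'-ends have configurable
in-frame fidelity, a unimodal 20-40 nt length distribution peaked at 28,
optional footprint enrichment around TISs (the homoharringtonine-like
regime), and uniform background noise on untranslated positions.

Footprints attach to the codons of *translated* ORFs — planted
non-canonical ORFs are translated at a reduced coverage multiplier — so
both in-frame structure and TIS-proximal density carry learnable signal.
What the generator does not emulate: sequencing errors, rRNA
contamination, UMI structure, or isoform-sharing read ambiguity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .ingest import ReadCountMatrix
from .transcriptome import (
    CdsSpan,
    GenomeAnnotation,
    STOP_CODONS,
    TranscriptRecord,
)

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
]
_STOPS = sorted(STOP_CODONS)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Generator settings; the defaults are the study conditions.

    ``mean_coverage`` is footprints per CDS nucleotide; ``in_frame_prob``
    is the probability that a footprint's 5'-end falls on its codon's
    frame-0 position (the remainder split evenly over frames 1/2), matching
    the 36-75% in-frame occupancy range seen in real samples at its
    default. ``tis_enrichment`` multiplies footprint density for codons
    within ``tis_window`` nt of a TIS (1 = untreated-like; large values
    emulate initiation-blocking treatment). ``background_rate`` is
    spurious reads per nucleotide across the whole transcript.
    """

    seed: int = 0
    n_chromosomes: int = 6
    n_transcripts: int = 300
    utr5_range: tuple[int, int] = (24, 60)
    cds_range: tuple[int, int] = (90, 180)
    utr3_range: tuple[int, int] = (24, 60)
    two_exon_fraction: float = 0.25
    minus_fraction: float = 0.5
    lncrna_fraction: float = 0.15
    uorf_rate: float = 0.2
    uoorf_rate: float = 0.1
    intorf_rate: float = 0.1
    dorf_rate: float = 0.15
    doorf_rate: float = 0.05
    cds_variant_fraction: float = 0.3  # of lncRNA transcripts
    lncrna_tis_in_cds_fraction: float = 0.25  # of remaining lncRNA transcripts
    lncrna_translated_fraction: float = 0.35  # lncRNA ORFs with ribosome occupancy
    mean_coverage: float = 2.0
    ncorf_coverage_multiplier: float = 0.3
    in_frame_prob: float = 0.6
    read_length_probs: dict[int, float] = field(
        default_factory=lambda: {
            26: 0.05, 27: 0.15, 28: 0.35, 29: 0.20, 30: 0.12, 31: 0.08, 32: 0.05
        }
    )
    tis_enrichment: float = 1.0
    tis_window: int = 30
    background_rate: float = 0.02

    def __post_init__(self) -> None:
        for p in (
            self.in_frame_prob, self.two_exon_fraction, self.minus_fraction,
            self.lncrna_fraction, self.uorf_rate, self.uoorf_rate, self.intorf_rate,
            self.dorf_rate, self.doorf_rate, self.cds_variant_fraction,
            self.lncrna_tis_in_cds_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"probability {p} outside [0,1]")
        if min(self.mean_coverage, self.background_rate, self.tis_enrichment) < 0:
            raise SimulationError("rates must be non-negative")
        if self.cds_range[0] < 9:
            raise SimulationError("CDS must be at least 9 nt (start, one codon, stop)")
        if self.n_chromosomes < 1 or self.n_transcripts < 1:
            raise SimulationError("need at least one chromosome and transcript")
        lens = np.array(list(self.read_length_probs))
        if lens.min() < 20 or lens.max() > 40:
            raise SimulationError("read lengths must be within [20, 40]")
        if abs(sum(self.read_length_probs.values()) - 1.0) > 1e-9:
            raise SimulationError("read_length_probs must sum to 1")


@dataclass
class PlantedOrf:
    transcript_id: str
    tis_index: int
    stop_index: int
    orf_class: str  # CDS / uORF / uoORF / intORF / dORF / doORF / lncRNA_ORF / CDS_variant
    coverage_multiplier: float = 1.0


@dataclass
class SimulationTruth:
    orfs: list[PlantedOrf]
    config: SimulationConfig
    matrices: Optional[dict[str, ReadCountMatrix]] = None
    realized_in_frame_occupancy: Optional[float] = None

    def by_transcript(self) -> dict[str, list[PlantedOrf]]:
        out: dict[str, list[PlantedOrf]] = {}
        for o in self.orfs:
            out.setdefault(o.transcript_id, []).append(o)
        return out


# ---------------------------------------------------------------------------
# Sequence construction helpers


def _rand_bases(rng: np.random.Generator, n: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=n)])


def _rand_nonstop_codons(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n)
    return [_NONSTOP_CODONS[i] for i in idx]


def _first_inframe_stop(seq: str, tis: int) -> Optional[int]:
    for pos in range(tis + 3, len(seq) - 2, 3):
        if seq[pos : pos + 3] in STOP_CODONS:
            return pos
    return None


def _scrub_frame_stops(bases: list[str], start: int, end: int, frame_anchor: int,
                       rng: np.random.Generator) -> None:
    """Mutate bases so no stop codon starts at frame positions of ``frame_anchor``
    within [start, end)."""
    pos = frame_anchor
    while pos < start:
        pos += 3
    while pos + 3 <= end:
        codon = "".join(bases[pos : pos + 3])
        while codon in STOP_CODONS:
            bases[pos + 2] = str(rng.choice(["C", "G"]))
            codon = "".join(bases[pos : pos + 3])
        pos += 3


def _plant_orf_in_utr(bases: list[str], offset: int, n_codons: int,
                      rng: np.random.Generator) -> tuple[int, int]:
    """Write ATG + n_codons non-stop codons + stop into ``bases`` at ``offset``."""
    orf = "ATG" + "".join(_rand_nonstop_codons(rng, n_codons)) + _STOPS[rng.integers(0, 3)]
    bases[offset : offset + len(orf)] = list(orf)
    return offset, offset + len(orf) - 3  # (tis, stop_index)


# ---------------------------------------------------------------------------
# Transcript builders


@dataclass
class _Built:
    sequence: str
    biotype: str
    cds: Optional[CdsSpan]
    planted: list[tuple[int, int, str]]  # (tis, stop_index, class)
    inframe_atg: Optional[int] = None  # internal in-frame ATG (transcript coord)


def _build_coding(cfg: SimulationConfig, rng: np.random.Generator) -> _Built:
    u5 = int(rng.integers(cfg.utr5_range[0], cfg.utr5_range[1] + 1))
    u3 = int(rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1))
    n_codons = int(rng.integers(cfg.cds_range[0] // 3, cfg.cds_range[1] // 3 + 1)) - 2
    n_codons = max(1, n_codons)

    codons = ["ATG"] + _rand_nonstop_codons(rng, n_codons) + [_STOPS[rng.integers(0, 3)]]
    # guarantee an internal in-frame ATG (host site for CDS-variant construction)
    internal_idx = int(rng.integers(1 + n_codons // 3, 1 + 2 * n_codons // 3 + 1))
    internal_idx = min(internal_idx, n_codons)
    codons[internal_idx] = "ATG"

    planted: list[tuple[int, int, str]] = []
    oof_plants: list[tuple[int, str]] = []  # (tis within CDS, intended class)

    if rng.random() < cfg.intorf_rate and n_codons >= 14:
        j = int(rng.integers(2, n_codons // 2))
        if abs(j - internal_idx) > 1:
            if rng.random() < 0.5:
                codons[j], codons[j + 1] = "CAT", "GGC"  # ATG at frame +1
                oof_plants.append((3 * j + 1, "intORF"))
            else:
                codons[j], codons[j + 1] = "GCA", "TGG"  # ATG at frame +2
                oof_plants.append((3 * j + 2, "intORF"))
    if rng.random() < cfg.doorf_rate and n_codons >= 8:
        j = n_codons - 2  # near the 3' end of the CDS
        if abs(j - internal_idx) > 1 and not any(abs(3 * j - p) < 9 for p, _ in oof_plants):
            codons[j], codons[j + 1] = "CAT", "GGC"
            oof_plants.append((3 * j + 1, "doORF"))

    cds_seq = "".join(codons)
    utr5 = _rand_bases(rng, u5)
    utr3 = _rand_bases(rng, u3)

    if rng.random() < cfg.uorf_rate and u5 >= 18:
        n_body = int(rng.integers(1, max(2, (u5 - 12) // 3)))
        n_body = min(n_body, (u5 - 9) // 3)
        _, stop = _plant_orf_in_utr(utr5, 1, n_body, rng)
        planted.append((1, stop, "uORF"))
    if rng.random() < cfg.uoorf_rate and u5 >= 30:
        # ATG in the 5'UTR, out of frame with the CDS (CDS starts at u5)
        p = u5 - 3 - int(rng.integers(1, 3))  # u5-4 or u5-5 -> (u5 - p) % 3 != 0
        used = planted and planted[-1][1] + 3 > p
        if not used:
            utr5[p : p + 3] = list("ATG")
            _scrub_frame_stops(utr5, p + 3, u5, p, rng)
            planted.append((p, -1, "uoORF"))  # stop resolved after assembly

    if rng.random() < cfg.dorf_rate and u3 >= 18:
        n_body = min(int(rng.integers(1, max(2, (u3 - 12) // 3))), (u3 - 9) // 3)
        tis_rel, stop_rel = _plant_orf_in_utr(utr3, 2, n_body, rng)
        planted.append((u5 + len(cds_seq) + tis_rel, u5 + len(cds_seq) + stop_rel, "dORF"))

    seq = "".join(utr5) + cds_seq + "".join(utr3)
    cds = CdsSpan(tis_index=u5, stop_index=u5 + len(cds_seq) - 3)
    out = _Built(seq, "protein_coding", cds, [], inframe_atg=u5 + 3 * internal_idx)
    out.planted.append((cds.tis_index, cds.stop_index, "CDS"))

    cds_lo, cds_hi = cds.tis_index, cds.stop_index + 3
    for tis, stop, klass in planted:
        if klass == "uoORF":
            s = _first_inframe_stop(seq, tis)
            # realized uoORF requires overlap of the CDS start and a stop on transcript
            if s is not None and s + 3 > cds_lo:
                out.planted.append((tis, s, "uoORF"))
            elif s is not None:
                out.planted.append((tis, s, "uORF"))
        else:
            out.planted.append((tis, stop, klass))
    for tis_rel, klass in oof_plants:
        tis = u5 + tis_rel
        s = _first_inframe_stop(seq, tis)
        if s is None:
            continue
        if s + 3 <= cds_hi:
            out.planted.append((tis, s, "intORF"))
        elif tis < cds_hi:
            out.planted.append((tis, s, "doORF"))
    return out


def _build_standalone_lncrna(cfg: SimulationConfig, rng: np.random.Generator) -> _Built:
    f5 = int(rng.integers(10, 40))
    f3 = int(rng.integers(10, 40))
    n_body = int(rng.integers(8, 30))
    bases = _rand_bases(rng, f5 + 3 * n_body + 6 + f3)
    tis, stop = _plant_orf_in_utr(bases, f5, n_body, rng)
    return _Built("".join(bases), "lncRNA", None, [(tis, stop, "lncRNA_ORF")])


# ---------------------------------------------------------------------------
# Genome assembly


class _ChromosomeBuilder:
    def __init__(self, name: str, rng: np.random.Generator):
        self.name = name
        self.rng = rng
        self.bases: list[str] = []

    def place(self, transcript_seq: str, two_exon: bool, minus: bool) -> list[tuple[int, int]]:
        """Append a locus for ``transcript_seq``; returns genomic exon intervals."""
        from Bio.Seq import Seq

        gap = int(self.rng.integers(20, 51))
        self.bases.extend(_rand_bases(self.rng, gap))
        genome_seq = str(Seq(transcript_seq).reverse_complement()) if minus else transcript_seq
        start = len(self.bases)
        if two_exon and len(transcript_seq) >= 40:
            cut = int(self.rng.integers(10, len(genome_seq) - 10))
            intron = _rand_bases(self.rng, int(self.rng.integers(30, 61)))
            self.bases.extend(genome_seq[:cut])
            e1 = (start, start + cut)
            self.bases.extend(intron)
            e2 = (len(self.bases), len(self.bases) + len(genome_seq) - cut)
            self.bases.extend(genome_seq[cut:])
            return [e1, e2]
        self.bases.extend(genome_seq)
        return [(start, start + len(genome_seq))]

    @property
    def sequence(self) -> str:
        return "".join(self.bases)


def simulate_transcriptome(cfg: SimulationConfig) -> tuple[GenomeAnnotation, SimulationTruth]:
    rng = np.random.default_rng(cfg.seed)
    chrom_rngs = [np.random.default_rng([cfg.seed, 11, i]) for i in range(cfg.n_chromosomes)]
    chroms = [_ChromosomeBuilder(f"chr{i + 1}", chrom_rngs[i]) for i in range(cfg.n_chromosomes)]

    records: list[TranscriptRecord] = []
    planted: list[PlantedOrf] = []
    hosts: list[tuple[TranscriptRecord, _Built]] = []  # plus-strand single-exon coding

    n_lnc = int(round(cfg.lncrna_fraction * cfg.n_transcripts))
    n_coding = cfg.n_transcripts - n_lnc
    n_variant = int(round(cfg.cds_variant_fraction * n_lnc))
    n_overlap = int(round(cfg.lncrna_tis_in_cds_fraction * (n_lnc - n_variant)))
    n_standalone = n_lnc - n_variant - n_overlap

    def register(built: _Built, chrom: _ChromosomeBuilder, tid: str,
                 two_exon: bool, minus: bool) -> TranscriptRecord:
        exons = chrom.place(built.sequence, two_exon, minus)
        rec = TranscriptRecord(
            transcript_id=tid,
            gene_id=f"gene_{tid}",
            chromosome=chrom.name,
            strand="-" if minus else "+",
            exons=exons,
            sequence=built.sequence,
            biotype_tags=frozenset({built.biotype}),
            cds=built.cds,
        )
        records.append(rec)
        for tis, stop, klass in built.planted:
            if klass == "CDS":
                mult = 1.0
            elif klass == "lncRNA_ORF" and rng.random() >= cfg.lncrna_translated_fraction:
                mult = 0.0  # lncRNA without ribosome occupancy: background only
            else:
                mult = cfg.ncorf_coverage_multiplier
            planted.append(PlantedOrf(tid, tis, stop, klass, mult))
        return rec

    for i in range(n_coding):
        built = _build_coding(cfg, rng)
        chrom = chroms[i % cfg.n_chromosomes]
        two_exon = rng.random() < cfg.two_exon_fraction
        minus = rng.random() < cfg.minus_fraction
        rec = register(built, chrom, f"tx{i:05d}", two_exon, minus)
        if not two_exon and not minus:
            hosts.append((rec, built))

    for i in range(n_standalone):
        built = _build_standalone_lncrna(cfg, rng)
        chrom = chroms[(n_coding + i) % cfg.n_chromosomes]
        register(built, chrom, f"lnc{i:05d}", rng.random() < cfg.two_exon_fraction,
                 rng.random() < cfg.minus_fraction)

    if (n_variant or n_overlap) and not hosts:
        raise SimulationError(
            "no plus-strand single-exon coding transcripts available to host "
            "overlapping lncRNAs; increase n_transcripts or lower minus/two-exon fractions"
        )

    def host_pick() -> tuple[TranscriptRecord, _Built]:
        return hosts[int(rng.integers(0, len(hosts)))]

    made_variant = 0
    attempts = 0
    while made_variant < n_variant and attempts < 50 * max(1, n_variant):
        attempts += 1
        rec, built = host_pick()
        gs = rec.exons[0][0]
        a = built.inframe_atg
        cds = rec.cds
        assert cds is not None and a is not None
        f5 = int(rng.integers(0, 7))
        if a - f5 < 0:
            continue
        f3 = int(rng.integers(3, 16))
        g_lo = gs + a - f5
        g_hi = gs + cds.stop_index + 3 + f3
        if g_hi > rec.exons[0][1]:
            continue
        seq = rec.sequence[a - f5 : cds.stop_index + 3 + f3]
        tid = f"lncv{made_variant:05d}"
        lnc = TranscriptRecord(
            transcript_id=tid, gene_id=f"gene_{tid}", chromosome=rec.chromosome,
            strand="+", exons=[(g_lo, g_hi)], sequence=seq,
            biotype_tags=frozenset({"lncRNA"}),
        )
        records.append(lnc)
        mult = (cfg.ncorf_coverage_multiplier
                if rng.random() < cfg.lncrna_translated_fraction else 0.0)
        planted.append(PlantedOrf(tid, f5, f5 + (cds.stop_index - a), "CDS_variant", mult))
        made_variant += 1

    made_overlap = 0
    attempts = 0
    while made_overlap < n_overlap and attempts < 50 * max(1, n_overlap):
        attempts += 1
        rec, built = host_pick()
        cds = rec.cds
        assert cds is not None
        seq = rec.sequence
        # existing out-of-frame ATG strictly inside the CDS footprint
        candidates = [
            q
            for q in range(cds.tis_index + 1, cds.stop_index - 3)
            if seq[q : q + 3] == "ATG" and (q - cds.tis_index) % 3 != 0
        ]
        if not candidates:
            continue
        q = int(candidates[rng.integers(0, len(candidates))])
        f5 = int(rng.integers(0, 7))
        if q - f5 < 0:
            continue
        sub = seq[q - f5 :]
        s = _first_inframe_stop(sub, f5)
        if s is None:
            continue
        gs = rec.exons[0][0]
        g_stop = gs + (q - f5) + s
        g_tis = gs + q
        if (g_tis == gs + cds.tis_index) or (g_stop == gs + cds.stop_index):
            continue
        tid = f"lnco{made_overlap:05d}"
        lnc = TranscriptRecord(
            transcript_id=tid, gene_id=f"gene_{tid}", chromosome=rec.chromosome,
            strand="+", exons=[(gs + q - f5, gs + q - f5 + len(sub))], sequence=sub,
            biotype_tags=frozenset({"lncRNA"}),
        )
        records.append(lnc)
        mult = (cfg.ncorf_coverage_multiplier
                if rng.random() < cfg.lncrna_translated_fraction else 0.0)
        planted.append(PlantedOrf(tid, f5, s, "lncRNA_ORF", mult))
        made_overlap += 1

    annotation = GenomeAnnotation(records)
    annotation.chromosome_sequences = {c.name: c.sequence for c in chroms}  # type: ignore[attr-defined]
    return annotation, SimulationTruth(orfs=planted, config=cfg)


# ---------------------------------------------------------------------------
# File emission


def write_annotation(annotation: GenomeAnnotation, gtf_path: str | Path,
                     fasta_path: str | Path) -> None:
    """Emit the synthetic annotation as GTF + genome FASTA."""
    chrom_seqs = getattr(annotation, "chromosome_sequences", None)
    if chrom_seqs is None:
        raise SimulationError("annotation lacks attached chromosome sequences")
    with open(fasta_path, "w") as fh:
        for name, seq in chrom_seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    def blocks(t: TranscriptRecord, lo: int, hi: int) -> list[tuple[int, int]]:
        gpos = sorted(t.to_genomic(p) for p in range(lo, hi))
        out: list[tuple[int, int]] = []
        for g in gpos:
            if out and g == out[-1][1]:
                out[-1] = (out[-1][0], g + 1)
            else:
                out.append((g, g + 1))
        return out

    with open(gtf_path, "w") as fh:
        for t in annotation:
            biotype = sorted(t.biotype_tags)[0] if t.biotype_tags else "misc_RNA"
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_biotype "{biotype}";'
            )

            def row(feature: str, lo: int, hi: int) -> str:
                return (
                    f"{t.chromosome}\triboscope_sim\t{feature}\t{lo + 1}\t{hi}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )

            for s, e in t.exons:
                fh.write(row("exon", s, e))
            if t.cds is not None:
                for lo, hi in blocks(t, t.cds.tis_index, t.cds.stop_index):
                    fh.write(row("CDS", lo, hi))
                for lo, hi in blocks(t, t.cds.tis_index, t.cds.tis_index + 3):
                    fh.write(row("start_codon", lo, hi))
                for lo, hi in blocks(t, t.cds.stop_index, t.cds.stop_index + 3):
                    fh.write(row("stop_codon", lo, hi))


def write_truth(truth: SimulationTruth, tsv_path: str | Path, json_path: str | Path) -> None:
    pd.DataFrame([asdict(o) for o in truth.orfs]).to_csv(tsv_path, sep="\t", index=False)
    payload = {
        "config": asdict(truth.config),
        "n_planted_orfs": len(truth.orfs),
        "realized_in_frame_occupancy": truth.realized_in_frame_occupancy,
    }
    Path(json_path).write_text(json.dumps(payload, indent=2, default=list))


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(
    annotation: GenomeAnnotation,
    truth: SimulationTruth,
    cfg: SimulationConfig,
    sam_path: str | Path,
) -> SimulationTruth:
    """Draw footprints, write a sorted transcript-space SAM, record truth counts.

    Per translated ORF and codon, the footprint count is Poisson with mean
    ``3 * mean_coverage * multiplier``, boosted by ``tis_enrichment`` for
    codons within ``tis_window`` nt of the ORF's TIS. Each footprint's
    5'-end lands on the codon's frame-0 position with probability
    ``in_frame_prob``, else uniformly on frame 1/2; its length is drawn
    from the configured distribution. Background reads are Poisson per
    position at ``background_rate``. Reads that would run past the
    transcript end are not emitted (end-to-end alignment).
    """
    if cfg.mean_coverage == 0 and cfg.background_rate == 0:
        raise SimulationError("zero coverage and zero background: empty sample")
    rng = np.random.default_rng([cfg.seed, 7])
    lengths = np.array(sorted(cfg.read_length_probs))
    probs = np.array([cfg.read_length_probs[x] for x in lengths], dtype=float)
    probs = probs / probs.sum()

    matrices: dict[str, ReadCountMatrix] = {
        t.transcript_id: ReadCountMatrix(t.transcript_id, len(t)) for t in annotation
    }
    by_tx = truth.by_transcript()

    for t in annotation:
        L = len(t)
        m = matrices[t.transcript_id]
        for orf in by_tx.get(t.transcript_id, []):
            starts = np.arange(orf.tis_index, orf.stop_index + 3, 3)
            lam = 3.0 * cfg.mean_coverage * orf.coverage_multiplier * np.where(
                np.abs(starts - orf.tis_index) <= cfg.tis_window, cfg.tis_enrichment, 1.0
            )
            counts = rng.poisson(lam)
            for codon_start, n in zip(starts, counts):
                if n == 0:
                    continue
                frames = np.where(
                    rng.random(n) < cfg.in_frame_prob, 0, rng.integers(1, 3, size=n)
                )
                rls = lengths[rng.choice(len(lengths), size=n, p=probs)]
                for fr, rl in zip(frames, rls):
                    pos = int(codon_start + fr)
                    if pos + int(rl) <= L:
                        m.add(pos, int(rl))
        if cfg.background_rate > 0:
            n_bg = rng.poisson(cfg.background_rate * L)
            if n_bg:
                poss = rng.integers(0, L, size=n_bg)
                rls = lengths[rng.choice(len(lengths), size=n_bg, p=probs)]
                for pos, rl in zip(poss, rls):
                    if int(pos) + int(rl) <= L:
                        m.add(int(pos), int(rl))

    _write_sam(annotation, matrices, sam_path)
    truth.matrices = matrices
    truth.realized_in_frame_occupancy = _realized_occupancy(annotation, matrices)
    return truth


def _realized_occupancy(annotation: GenomeAnnotation,
                        matrices: dict[str, ReadCountMatrix]) -> Optional[float]:
    in_frame = total = 0
    for t in annotation:
        if t.cds is None:
            continue
        lo, hi = t.cds.span
        for (pos, _rl), n in matrices[t.transcript_id].counts.items():
            if lo <= pos < hi:
                total += n
                in_frame += n if (pos - t.cds.tis_index) % 3 == 0 else 0
    return in_frame / total if total else None


def _write_sam(annotation: GenomeAnnotation, matrices: dict[str, ReadCountMatrix],
               sam_path: str | Path) -> None:
    tids = [t.transcript_id for t in annotation]
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": tid, "LN": len(annotation[tid])} for tid in tids],
    }
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        serial = 0
        for ref_id, tid in enumerate(tids):
            for (pos, rl), n in sorted(matrices[tid].counts.items()):
                for _ in range(n):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = f"sim{serial:09d}"
                    a.reference_id = ref_id
                    a.reference_start = pos
                    a.mapping_quality = 255
                    a.cigarstring = f"{rl}M"
                    a.flag = 0
                    out.write(a)
                    serial += 1
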