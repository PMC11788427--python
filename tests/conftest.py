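import numpy as np
import pytest

from riboscope.ingest import SampleProfile
from riboscope.simulate import SimulationConfig, simulate_reads, simulate_transcriptome
from riboscope.transcriptome import CdsSpan, GenomeAnnotation, TranscriptRecord


def make_transcript(
    seq: str,
    transcript_id: str = "t1",
    chromosome: str = "c1",
    strand: str = "+",
    offset: int = 100,
    cds: tuple[int, int] | None = None,
    biotype: str = "protein_coding",
) -> TranscriptRecord:
    """Single-exon transcript over ``seq`` placed at ``offset`` on the genome."""
    return TranscriptRecord(
        transcript_id=transcript_id,
        gene_id=f"g_{transcript_id}",
        chromosome=chromosome,
        strand=strand,
        exons=[(offset, offset + len(seq))],
        sequence=seq,
        biotype_tags=frozenset({biotype}),
        cds=CdsSpan(*cds) if cds else None,
    )


@pytest.fixture
def toy_gtf_fasta(tmp_path):
    """Two-exon toy annotation on a 50-nt chromosome, one per strand.

    Chromosome layout: exon1 = [10, 20), exon2 = [30, 40). The plus
    transcript carries a start codon at genomic [30, 33) ("ATG"), with an
    in-frame stop two codons later, so its CDS starts at transcript
    position 10.
    """
    chrom = list("A" * 50)
    chrom[10:20] = list("CCGGTTAACC")
    chrom[30:40] = list("ATGAAATAAC")
    fasta = tmp_path / "toy.fa"
    fasta.write_text(">c1\n" + "".join(chrom) + "\n")
    rows = []
    for tid, strand in (("tplus", "+"), ("tminus", "-")):
        attrs = f'gene_id "g1"; transcript_id "{tid}"; transcript_biotype "protein_coding";'
        rows.append(f"c1\ttest\texon\t11\t20\t.\t{strand}\t.\t{attrs}")
        rows.append(f"c1\ttest\texon\t31\t40\t.\t{strand}\t.\t{attrs}")
        if strand == "+":
            rows.append(f"c1\ttest\tstart_codon\t31\t33\t.\t{strand}\t.\t{attrs}")
    gtf = tmp_path / "toy.gtf"
    gtf.write_text("\n".join(rows) + "\n")
    return gtf, fasta


@pytest.fixture(scope="session")
def small_simulation():
    """Modest simulated dataset shared by read-level tests (fast, seeded)."""
    cfg = SimulationConfig(seed=11, n_transcripts=80)
    annotation, truth = simulate_transcriptome(cfg)
    return cfg, annotation, truth


@pytest.fixture(scope="session")
def small_reads(small_simulation, tmp_path_factory):
    cfg, annotation, truth = small_simulation
    sam = tmp_path_factory.mktemp("sim") / "reads.sam"
    truth = simulate_reads(annotation, truth, cfg, sam)
    profile = SampleProfile("sim", truth.matrices)
    return cfg, annotation, truth, profile, sam
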