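"""Taxonomy assignment on a hand-written fixture of edge cases.

The coding transcript has its CDS at transcript [30, 60): TIS = 30,
stop codon = [57, 60). It lives at genomic offset 1000 on the plus strand,
so the genomic CDS start site is 1030 and the stop site 1057. Non-coding
transcripts overlap it (or not) to exercise the CDS-variant and
lncRNA-ORF precedence rules.
"""

import pytest

from riboscope.orf_annotation import (
    annotate_calls,
    classify_orf,
    lncRNA_overlap_profile,
    taxonomy_counts,
)
from riboscope.orf_calling import OrfCall
from riboscope.transcriptome import GenomeAnnotation

from conftest import make_transcript


def build_fixture_annotation():
    cod = make_transcript("A" * 90, transcript_id="cod", offset=1000, cds=(30, 57))
    lnc = make_transcript("A" * 100, transcript_id="lnc", offset=1000,
                          biotype="lncRNA")
    lnc_far = make_transcript("A" * 60, transcript_id="lnc_far", offset=5000,
                              biotype="lncRNA")
    lnc_minus = make_transcript("A" * 100, transcript_id="lnc_minus", offset=1000,
                                strand="-", biotype="lncRNA")
    proc = make_transcript("A" * 100, transcript_id="proc", offset=1000,
                           biotype="processed_transcript")
    return GenomeAnnotation([cod, lnc, lnc_far, lnc_minus, proc])


@pytest.fixture(scope="module")
def fixture_annotation():
    return build_fixture_annotation()


CASES = [
    # --- coding transcript, CDS tis=30 stop=57 ---
    ("cod", 30, 57, "annotated_CDS"),          # exact CDS
    ("cod", 24, 57, "N_terminal_extension"),   # shared stop, upstream in-frame
    ("cod", 0, 57, "N_terminal_extension"),    # extension from transcript start
    ("cod", 36, 57, "N_terminal_truncation"),  # shared stop, downstream in-frame
    ("cod", 6, 18, "uORF"),                    # entirely 5' of CDS
    ("cod", 3, 24, "uORF"),                    # 5' of CDS, in CDS frame: still uORF
    ("cod", 15, 27, "uORF"),                   # stop codon ends at cds_start - 1
    ("cod", 16, 28, "uoORF"),                  # overlaps CDS start by one base, out of frame
    ("cod", 13, 43, "uoORF"),                  # classic out-of-frame overlap of CDS start
    ("cod", 10, 61, "uoORF"),                  # out-of-frame ORF spanning the whole CDS
    ("cod", 34, 46, "intORF"),                 # nested, out of frame
    ("cod", 52, 64, "doORF"),                  # TIS in CDS, stop 3' of CDS
    ("cod", 59, 65, "doORF"),                  # TIS on last CDS-footprint base
    ("cod", 63, 75, "dORF"),                   # entirely 3'
    ("cod", 60, 69, "dORF"),                   # starts on first base after CDS footprint
    ("cod", 36, 51, "other"),                  # in-frame nested, stop not shared
    ("cod", 30, 45, "other"),                  # shares TIS only, in-frame
    ("cod", 57, 69, "other"),                  # in-frame from stop-codon position
    # --- non-coding transcripts ---
    ("lnc", 30, 57, "CDS_variant"),            # shares both genomic sites
    ("lnc", 30, 48, "CDS_variant"),            # shares genomic start site only
    ("lnc", 12, 57, "CDS_variant"),            # shares genomic stop site only
    ("lnc", 10, 40, "lncRNA_ORF"),             # overlaps CDS but no shared site
    ("lnc", 35, 53, "lncRNA_ORF"),             # TIS inside CDS, no shared site
    ("lnc_far", 10, 31, "lncRNA_ORF"),         # intergenic lncRNA ORF
    ("lnc_minus", 69, 81, "lncRNA_ORF"),       # opposite strand: site NOT shared
    ("proc", 12, 57, "CDS_variant"),           # non-lncRNA biotype still CDS variant
    ("proc", 10, 40, "other"),                 # non-coding, no lncRNA tag, no shared site
]


class TestClassifyOrf:
    @pytest.mark.parametrize("tid,tis,stop,expected", CASES)
    def test_fixture_table(self, fixture_annotation, tid, tis, stop, expected):
        call = OrfCall(tid, tis, stop, "ATG")
        tax = classify_orf(call, fixture_annotation[tid], fixture_annotation)
        assert tax.label == expected, tax.evidence

    def test_exactly_one_label_per_call(self, fixture_annotation):
        for tid, tis, stop, _ in CASES:
            tax = classify_orf(OrfCall(tid, tis, stop, "ATG"),
                               fixture_annotation[tid], fixture_annotation)
            assert isinstance(tax.label, str) and tax.evidence

    def test_missing_stop_is_other(self, fixture_annotation):
        tax = classify_orf(OrfCall("cod", 10, None, "ATG"),
                           fixture_annotation["cod"], fixture_annotation)
        assert tax.label == "other"

    def test_planted_classes_recovered_on_simulation(self, small_simulation):
        """The generator's planted taxonomy agrees with the classifier for
        at least 99% of plants."""
        _, annotation, truth = small_simulation
        label_map = {"CDS": "annotated_CDS"}
        n = ok = 0
        for o in truth.orfs:
            expected = label_map.get(o.orf_class, o.orf_class)
            tax = classify_orf(OrfCall(o.transcript_id, o.tis_index, o.stop_index, "ATG"),
                               annotation[o.transcript_id], annotation)
            n += 1
            ok += tax.label == expected
        assert n > 50
        assert ok / n >= 0.99


class TestOverlapProfile:
    def _annotated(self, fixture_annotation, specs):
        calls = [OrfCall(tid, tis, stop, "ATG") for tid, tis, stop in specs]
        return annotate_calls(calls, fixture_annotation)

    def test_single_tis_inside_cds(self, fixture_annotation):
        calls = self._annotated(fixture_annotation, [("lnc", 35, 53)])
        prof = lncRNA_overlap_profile(calls, fixture_annotation)
        assert prof["tis_in_cds"] == 1.0
        assert prof["tis_in_coding_exon"] == 1.0

    def test_intergenic_lncrna(self, fixture_annotation):
        calls = self._annotated(fixture_annotation, [("lnc_far", 10, 31)])
        prof = lncRNA_overlap_profile(calls, fixture_annotation)
        assert prof == {"tis_in_cds": 0.0, "tis_in_coding_exon": 0.0, "intergenic": 1.0}

    def test_mixed_fractions(self, fixture_annotation):
        calls = self._annotated(
            fixture_annotation,
            [("lnc", 35, 53), ("lnc", 10, 40), ("lnc_far", 10, 31)],
        )
        prof = lncRNA_overlap_profile(calls, fixture_annotation)
        assert prof["tis_in_cds"] == pytest.approx(1 / 3)
        assert prof["tis_in_coding_exon"] == pytest.approx(2 / 3)
        assert prof["intergenic"] == pytest.approx(1 / 3)

    def test_planted_overlap_fraction_recovered(self):
        """Generator round-trip: the configured fraction of lncRNA ORFs with
        TIS inside a CDS is recovered from classification."""
        from riboscope.simulate import SimulationConfig, simulate_transcriptome

        cfg = SimulationConfig(seed=23, n_transcripts=600, lncrna_fraction=0.5,
                               cds_variant_fraction=0.0,
                               lncrna_tis_in_cds_fraction=0.4)
        annotation, truth = simulate_transcriptome(cfg)
        calls = [OrfCall(o.transcript_id, o.tis_index, o.stop_index, "ATG")
                 for o in truth.orfs if o.orf_class == "lncRNA_ORF"]
        annotate_calls(calls, annotation)
        lnc_calls = [c for c in calls if c.orf_type == "lncRNA_ORF"]
        assert len(lnc_calls) >= 250
        prof = lncRNA_overlap_profile(lnc_calls, annotation)
        assert prof["tis_in_cds"] == pytest.approx(0.4, abs=0.05)

    def test_empty_input_errors(self, fixture_annotation):
        with pytest.raises(ValueError):
            lncRNA_overlap_profile([], fixture_annotation)


def test_taxonomy_counts_table(fixture_annotation):
    calls = [OrfCall("cod", 30, 57, "ATG"), OrfCall("cod", 6, 18, "ATG"),
             OrfCall("cod", 63, 75, "ATG")]
    annotate_calls(calls, fixture_annotation)
    df = taxonomy_counts(calls, "s1")
    assert set(df.orf_type) == {"annotated_CDS", "uORF", "dORF"}
    assert df.n.sum() == 3
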