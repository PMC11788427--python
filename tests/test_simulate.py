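import numpy as np
import pytest

from riboscope.ingest import SampleProfile, in_frame_occupancy, ingest_alignments
from riboscope.simulate import (
    SimulationConfig,
    SimulationError,
    simulate_reads,
    simulate_transcriptome,
    write_annotation,
    write_truth,
)


class TestSimulationConfig:
    def test_infeasible_cds_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(cds_range=(3, 6))

    def test_bad_probability_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(in_frame_prob=1.5)

    def test_read_lengths_outside_window_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(read_length_probs={19: 1.0})

    def test_empty_sample_rejected(self, tmp_path):
        cfg = SimulationConfig(seed=0, n_transcripts=5, mean_coverage=0.0,
                               background_rate=0.0)
        ann, truth = simulate_transcriptome(cfg)
        with pytest.raises(SimulationError, match="empty"):
            simulate_reads(ann, truth, cfg, tmp_path / "r.sam")


class TestSimulateTranscriptome:
    def test_fixed_seed_bitwise_identical_outputs(self, tmp_path):
        for run in ("a", "b"):
            cfg = SimulationConfig(seed=42, n_transcripts=40)
            ann, truth = simulate_transcriptome(cfg)
            write_annotation(ann, tmp_path / f"{run}.gtf", tmp_path / f"{run}.fa")
            simulate_reads(ann, truth, cfg, tmp_path / f"{run}.sam")
            write_truth(truth, tmp_path / f"{run}.tsv", tmp_path / f"{run}.json")
        for ext in ("gtf", "fa", "sam", "tsv", "json"):
            assert (tmp_path / f"a.{ext}").read_bytes() == (tmp_path / f"b.{ext}").read_bytes()

    def test_zero_ncorf_rates_leave_only_cds_and_lncrna(self):
        cfg = SimulationConfig(seed=1, n_transcripts=60, uorf_rate=0, uoorf_rate=0,
                               intorf_rate=0, dorf_rate=0, doorf_rate=0,
                               lncrna_fraction=0.0)
        _, truth = simulate_transcriptome(cfg)
        assert {o.orf_class for o in truth.orfs} == {"CDS"}

    def test_uorf_rate_recovered_binomially(self):
        cfg = SimulationConfig(seed=2, n_transcripts=1000, lncrna_fraction=0.0,
                               uorf_rate=0.3, uoorf_rate=0, intorf_rate=0,
                               dorf_rate=0, doorf_rate=0, utr5_range=(30, 60))
        _, truth = simulate_transcriptome(cfg)
        n_uorf = sum(1 for o in truth.orfs if o.orf_class == "uORF")
        # binomial(1000, 0.3): 3 sigma ~ 43; some plants skipped on short UTRs
        assert 230 <= n_uorf <= 345

    def test_planted_orf_coordinates_are_codon_consistent(self, small_simulation):
        _, annotation, truth = small_simulation
        for o in truth.orfs:
            t = annotation[o.transcript_id]
            assert (o.stop_index - o.tis_index) % 3 == 0
            assert t.codon_at(o.tis_index) == "ATG"
            assert t.codon_at(o.stop_index) in {"TAA", "TAG", "TGA"}
            # no internal stop in the planted frame
            for pos in range(o.tis_index + 3, o.stop_index, 3):
                assert t.codon_at(pos) not in {"TAA", "TAG", "TGA"}


class TestSimulateReads:
    def test_pure_in_frame_reads_give_occupancy_one(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_transcripts=30, in_frame_prob=1.0,
                               background_rate=0.0, lncrna_fraction=0.0,
                               uorf_rate=0, uoorf_rate=0, intorf_rate=0,
                               dorf_rate=0, doorf_rate=0)
        ann, truth = simulate_transcriptome(cfg)
        truth = simulate_reads(ann, truth, cfg, tmp_path / "r.sam")
        assert truth.realized_in_frame_occupancy == 1.0

    def test_read_totals_near_expectation(self, tmp_path):
        cfg = SimulationConfig(seed=4, n_transcripts=50, mean_coverage=1.0,
                               background_rate=0.0, lncrna_fraction=0.0,
                               uorf_rate=0, uoorf_rate=0, intorf_rate=0,
                               dorf_rate=0, doorf_rate=0, tis_enrichment=1.0)
        ann, truth = simulate_transcriptome(cfg)
        truth = simulate_reads(ann, truth, cfg, tmp_path / "r.sam")
        # expectation ~= coverage * total CDS nt (minus 3'-edge truncation)
        expected = sum(o.stop_index + 3 - o.tis_index for o in truth.orfs)
        total = sum(m.total_reads for m in truth.matrices.values())
        assert abs(total - expected) < 4 * np.sqrt(expected) + 0.02 * expected

    def test_tis_enrichment_concentrates_footprints(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_transcripts=60, mean_coverage=2.0,
                               tis_enrichment=10.0, background_rate=0.0,
                               lncrna_fraction=0.0, uorf_rate=0, uoorf_rate=0,
                               intorf_rate=0, dorf_rate=0, doorf_rate=0)
        ann, truth = simulate_transcriptome(cfg)
        truth = simulate_reads(ann, truth, cfg, tmp_path / "r.sam")
        near = far = near_nt = far_nt = 0
        for o in truth.orfs:
            m = truth.matrices[o.transcript_id]
            for (pos, _rl), n in m.counts.items():
                if o.tis_index <= pos < o.stop_index + 3:
                    if pos - o.tis_index <= cfg.tis_window:
                        near += n
                    else:
                        far += n
            near_nt += min(cfg.tis_window + 3, o.stop_index + 3 - o.tis_index)
            far_nt += max(0, o.stop_index + 3 - o.tis_index - cfg.tis_window - 3)
        ratio = (near / near_nt) / (far / far_nt)
        assert ratio == pytest.approx(10.0, rel=0.2)

    def test_read_lengths_within_configured_support(self, small_reads):
        _, _, truth, _, _ = small_reads
        lengths = {rl for m in truth.matrices.values() for (_p, rl) in m.counts}
        assert lengths <= set(range(26, 33))


class TestOccupancyRecovery:
    @pytest.mark.parametrize("ifp", [0.4, 0.75])
    def test_in_frame_prob_recovered(self, tmp_path, ifp):
        """Monte-Carlo: realized occupancy matches the generator parameter."""
        cfg = SimulationConfig(seed=6, n_transcripts=150, mean_coverage=3.0,
                               in_frame_prob=ifp, background_rate=0.0,
                               lncrna_fraction=0.0, uorf_rate=0, uoorf_rate=0,
                               intorf_rate=0, dorf_rate=0, doorf_rate=0)
        ann, truth = simulate_transcriptome(cfg)
        truth = simulate_reads(ann, truth, cfg, tmp_path / "r.sam")
        total = sum(m.total_reads for m in truth.matrices.values())
        assert total >= 50_000
        assert truth.realized_in_frame_occupancy == pytest.approx(ifp, abs=0.01)
        # and the ingest-side computation agrees on the emitted file
        prof = ingest_alignments(tmp_path / "r.sam", ann)
        assert in_frame_occupancy(prof, ann) == pytest.approx(
            truth.realized_in_frame_occupancy, abs=1e-12
        )
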