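import numpy as np
import pytest

from riboscope.encoder import ModelConfig, TISNet
from riboscope.estimator import TISTransformer, make_pretrain_labels
from riboscope.ingest import ReadCountMatrix, SampleProfile
from riboscope.training import (
    FoldError,
    allocate_folds,
    predict_sample,
    split_two_fold,
    train_supervised,
)
from riboscope.transcriptome import GenomeAnnotation

from conftest import make_transcript


class TestAllocateFolds:
    def test_published_human_scheme(self):
        chroms = [str(i) for i in range(1, 23)] + ["X", "Y"]
        alloc = allocate_folds(chroms, scheme="paper")
        # chromosome 3 trains the first model and is tested by the second
        assert "3" in alloc.folds[0].train
        assert "3" in alloc.folds[1].test
        assert alloc.model_for("3") == 1
        # chromosome 1 validates model 0 and is scored by model 1
        assert "1" in alloc.folds[0].val
        assert alloc.model_for("1") == 1
        assert alloc.model_for("chr1") == 1  # chr-prefixed names normalized

    def test_test_folds_partition_all_chromosomes(self):
        chroms = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
        alloc = allocate_folds(chroms, scheme="paper")
        assert alloc.covers(chroms)
        assert not (alloc.folds[0].test & alloc.folds[1].test)

    def test_scaffold_joined_to_exactly_one_test_set(self):
        alloc = allocate_folds(["1", "2", "KI270728.1"], scheme="paper")
        hits = [i for i, f in enumerate(alloc.folds) if "KI270728.1" in f.test]
        assert hits == [0]

    def test_custom_two_chromosome_split(self):
        alloc = allocate_folds(
            ["A", "B"],
            scheme="custom",
            custom=[{"train": ["A"], "test": ["B"]}, {"train": ["B"], "test": ["A"]}],
        )
        assert alloc.model_for("B") == 0

    def test_custom_overlapping_test_sets_rejected(self):
        with pytest.raises(FoldError, match="A"):
            allocate_folds(
                ["A", "B"],
                scheme="custom",
                custom=[{"train": ["B"], "test": ["A"]}, {"test": ["A", "B"]}],
            )

    def test_custom_role_overlap_within_model_rejected(self):
        with pytest.raises(FoldError):
            allocate_folds(
                ["A", "B"],
                scheme="custom",
                custom=[{"train": ["A"], "val": ["A"], "test": ["B"]},
                        {"train": ["B"], "test": ["A"]}],
            )

    def test_chromosome_in_no_test_fold_errors(self):
        alloc = split_two_fold(["c1", "c2", "c3", "c4"])
        with pytest.raises(FoldError, match="c9"):
            alloc.model_for("c9")


class TestPretrainLabels:
    def test_positive_where_read_present(self):
        m = ReadCountMatrix("t", 20)
        m.add(10, 28, 3)
        labels = make_pretrain_labels(m)
        assert labels[10, 28 - 20] == 1
        assert labels.sum() == 1

    def test_empty_position_all_zero(self):
        labels = make_pretrain_labels(ReadCountMatrix("t", 5))
        assert labels.shape == (5, 21) and labels.sum() == 0

    def test_threshold_semantics(self):
        m = ReadCountMatrix("t", 20)
        m.add(10, 28, 1)
        assert make_pretrain_labels(m, read_presence_threshold=2)[10, 8] == 0
        m.add(10, 28, 1)
        assert make_pretrain_labels(m, read_presence_threshold=2)[10, 8] == 1


class TestMasking:
    def _estimator(self, **kw):
        defaults = dict(h=8, n_layers=1, n_heads=2, objective="masked_pretrain",
                        max_epochs=1, dropout=0.0, max_transcript_length=1024)
        defaults.update(kw)
        return TISTransformer(**defaults)

    def test_mask_fraction_of_positions(self):
        est = self._estimator()
        masked = est._masked_positions(1000, epoch=1, item=0)
        assert abs(masked.sum() - 150) <= 1

    def test_masking_deterministic_for_seed(self):
        a = self._estimator(seed=5)._masked_positions(500, 2, 3)
        b = self._estimator(seed=5)._masked_positions(500, 2, 3)
        c = self._estimator(seed=6)._masked_positions(500, 2, 3)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_masked_inputs_carry_no_information(self):
        """Substituting arbitrary values at masked positions leaves the
        forward pass bitwise unchanged: masking cannot leak."""
        net = TISNet(ModelConfig(h=8, n_layers=1, n_heads=2, dropout=0.0,
                                 max_transcript_length=64, seed=0))
        rng = np.random.default_rng(0)
        L = 30
        c = rng.random((1, L))
        l = rng.dirichlet(np.ones(21), size=(1, L))
        masked = rng.random((1, L)) < 0.3
        out1 = net.forward(c, l, head="pretrain", masked=masked).data
        c2, l2 = c.copy(), l.copy()
        c2[masked] = rng.random(masked.sum())
        l2[masked] = rng.dirichlet(np.ones(21), size=int(masked.sum()))
        out2 = net.forward(c2, l2, head="pretrain", masked=masked).data
        assert np.array_equal(out1, out2)

    def test_pretrain_beats_base_rate_on_structured_counts(self):
        """After a few epochs of masked pretraining on strongly structured
        counts, masked-position loss is below the best constant predictor."""
        rng = np.random.default_rng(1)
        X = []
        for _ in range(24):
            dense = np.zeros((120, 21), dtype=np.int64)
            dense[::3, 8] = 4  # every third position, one read length
            X.append(dense)
        est = self._estimator(h=16, n_layers=2, max_epochs=70, patience=70,
                              learning_rate=5e-3, seed=0, batch_size=8)
        est.fit(X)
        # per-length empirical base-rate predictor: the strongest constant model
        labels = np.concatenate([make_pretrain_labels(x) for x in X])
        p_len = np.clip(labels.mean(axis=0), 1e-9, 1 - 1e-9)
        base_rate_loss = float(np.mean(
            -(p_len * np.log(p_len) + (1 - p_len) * np.log(1 - p_len))
        ))
        assert est.history_[-1]["train_loss"] < base_rate_loss


def _toy_world(n_per_chrom=3, chroms=("c1", "c2", "c3", "c4")):
    """Tiny annotation+profile where the TIS is trivially identifiable."""
    rng = np.random.default_rng(0)
    records, matrices = [], {}
    i = 0
    for chrom in chroms:
        for _ in range(n_per_chrom):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            seq = seq[:20] + "ATG" + "GCT" * 3 + "TAA" + seq[35:]
            t = make_transcript(seq[:60], transcript_id=f"t{i}", chromosome=chrom,
                                cds=(20, 32))
            records.append(t)
            m = ReadCountMatrix(t.transcript_id, len(t))
            m.add(20, 28, 20)
            matrices[t.transcript_id] = m
            i += 1
    return GenomeAnnotation(records), SampleProfile("s", matrices)


class TestTwoFoldProtocol:
    def test_fold_hygiene_and_routing(self):
        annotation, profile = _toy_world()
        alloc = split_two_fold(annotation.chromosomes)
        models = train_supervised(
            [profile], annotation, alloc,
            h=8, n_layers=1, n_heads=2, max_epochs=2, patience=2,
            dropout=0.0, max_transcript_length=128, seed=0,
        )
        scores = predict_sample(profile, models, alloc, annotation)
        assert set(scores) == set(profile.matrices)
        for i, est in enumerate(models):
            test_ids = {
                t.transcript_id for t in annotation
                if alloc.model_for(t.chromosome) == i
            }
            assert set(est.train_ids_).isdisjoint(test_ids)

    def test_no_positive_labels_errors(self):
        annotation, profile = _toy_world()
        for t in annotation:
            t.cds = None
        alloc = split_two_fold(annotation.chromosomes)
        with pytest.raises(FoldError, match="positive"):
            train_supervised([profile], annotation, alloc, h=8, n_layers=1,
                             n_heads=2, max_epochs=1, max_transcript_length=128)

    def test_seeded_runs_reproduce_history(self):
        annotation, profile = _toy_world()
        alloc = split_two_fold(annotation.chromosomes)
        kw = dict(h=8, n_layers=1, n_heads=2, max_epochs=2, patience=2,
                  dropout=0.1, max_transcript_length=128, seed=3)
        m1 = train_supervised([profile], annotation, alloc, **kw)
        m2 = train_supervised([profile], annotation, alloc, **kw)
        assert m1[0].history_ == m2[0].history_
        for k, v in m1[0].state_.items():
            assert np.array_equal(v, m2[0].state_[k])

    def test_finetune_from_pretrained_trunk(self):
        annotation, profile = _toy_world()
        alloc = split_two_fold(annotation.chromosomes)
        from riboscope.training import pretrain

        kw = dict(h=8, n_layers=1, n_heads=2, max_epochs=2, patience=2,
                  dropout=0.0, max_transcript_length=128, seed=0)
        pre = pretrain([profile], annotation, alloc, **kw)
        init_states = [m.state_ for m in pre]
        fine = train_supervised([profile], annotation, alloc,
                                init_states=init_states, **kw)
        # trunk initialized from pretraining; the 21-wide head is swapped out
        assert "head_tis.W" in fine[0].state_
        assert fine[0].history_  # trained without error
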