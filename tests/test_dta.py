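"""Affinity units, label encoding, CNN regression and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from denovotki import (
    AffinityRecord,
    DTAModelConfig,
    kd_from_pkd,
    label_encode,
    pkd_from_kd,
    predict_affinity,
    rank_and_screen,
    train_dta,
)
from denovotki.dta import build_vocab, protein_vocab


class TestPkd:
    @pytest.mark.parametrize("kd,expected", [(1.0, 9.0), (1e9, 0.0), (100.0, 7.0)])
    def test_reference_points(self, kd, expected):
        assert pkd_from_kd(kd) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pkd_from_kd(0.0)

    @given(st.floats(min_value=1e-3, max_value=1e9))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, kd):
        assert kd_from_pkd(pkd_from_kd(kd)) == pytest.approx(kd, rel=1e-12)

    def test_strictly_decreasing(self):
        assert pkd_from_kd(1.0) > pkd_from_kd(10.0) > pkd_from_kd(100.0)

    def test_record_derives_pkd_from_kd(self):
        rec = AffinityRecord("CCO", "MKV", kd=100.0)
        assert rec.pkd == pytest.approx(7.0)


class TestLabelEncode:
    def test_padding_pattern(self):
        vocab = build_vocab(["CCO"])
        enc = label_encode("CCO", vocab, 5)
        assert enc.tolist() == [vocab["C"], vocab["C"], vocab["O"], 0, 0]

    def test_truncation(self):
        vocab = protein_vocab()
        assert label_encode("MKVLAA", vocab, 3).shape == (3,)

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            label_encode("CXZ?", build_vocab(["CCO"]), 10)


class TestTraining:
    def test_heldout_correlation_with_ground_truth(self, dta_study):
        from scipy.stats import pearsonr

        r = pearsonr(dta_study["pred_test"], dta_study["truth_test"])[0]
        assert r >= 0.7

    def test_training_loss_decreases(self, dta_study):
        log = dta_study["model"].training_log
        assert log[-1] < log[0]

    def test_constant_target_collapses_predictions(self):
        rng = np.random.default_rng(0)
        smiles = ["CCO", "CCN", "c1ccccc1", "CC(=O)O", "CCCl"]
        records = [
            AffinityRecord("".join(rng.choice(list("CNO"))) + s, "MKVHKWWHAC" * 5,
                           pkd=6.0)
            for s in smiles for _ in range(8)
        ]
        config = DTAModelConfig(protein_max_len=60, smiles_max_len=20, epochs=30,
                                conv_filters=(8, 8, 8), dense_widths=(32, 16), seed=1)
        model = train_dta(records, config)
        preds = predict_affinity(model, [r.ligand_smiles for r in records[:10]],
                                 records[0].protein_sequence)
        assert float(np.mean((np.asarray(preds) - 6.0) ** 2)) < 1.0

    def test_deterministic_under_seed(self):
        records = [AffinityRecord("CCO", "MKVA" * 10, pkd=5.0),
                   AffinityRecord("CCN", "MKCA" * 10, pkd=7.0)] * 10
        config = DTAModelConfig(protein_max_len=40, smiles_max_len=10, epochs=3,
                                conv_filters=(4, 4, 4), dense_widths=(8, 8), seed=7)
        a = train_dta(records, config)
        b = train_dta(records, DTAModelConfig(**{**config.__dict__, "smiles_vocab": {}}))
        pa = predict_affinity(a, ["CCO", "CCN"], records[0].protein_sequence)
        pb = predict_affinity(b, ["CCO", "CCN"], records[0].protein_sequence)
        assert pa == pb

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_dta([])


class TestPredict:
    def test_repeated_ligand_same_score(self, dta_study):
        model = dta_study["model"]
        prot = dta_study["test"][0].protein_sequence
        scores = predict_affinity(model, ["CCO", "CCO", "CCO"], prot)
        assert scores[0] == scores[1] == scores[2]

    def test_empty_ligand_list(self, dta_study):
        assert predict_affinity(dta_study["model"], [], "MKV") == []

    def test_separates_high_from_low_affinity_groups(self, dta_study):
        """Ligand groups defined by the synthetic ground-truth function are
        ranked correctly on average."""
        from denovotki.synthetic_data import ground_truth_score

        model = dta_study["model"]
        prot = dta_study["test"][0].protein_sequence
        ligands = sorted({r.ligand_smiles for r in dta_study["test"]})
        truth = np.array([ground_truth_score(l, prot) for l in ligands])
        lo, hi = np.percentile(truth, [25, 75])
        high = [l for l, t in zip(ligands, truth) if t >= hi]
        low = [l for l, t in zip(ligands, truth) if t <= lo]
        mean_high = np.mean(predict_affinity(model, high, prot))
        mean_low = np.mean(predict_affinity(model, low, prot))
        assert mean_high > mean_low


class TestRankAndScreen:
    SCORED = [("CCO", 7.0), ("CCN", 9.0), ("CCC", 8.0), ("CCS", 6.5)]

    def test_top_k_order(self):
        out = rank_and_screen(self.SCORED, top_k=3)
        assert [s for s, _ in out] == ["CCN", "CCC", "CCO"]

    def test_threshold_above_max_is_empty(self):
        assert rank_and_screen(self.SCORED, pkd_threshold=10.0) == []

    def test_deterministic_tie_break(self):
        out = rank_and_screen([("CCN", 7.0), ("CCA", 7.0)], top_k=2)
        assert [s for s, _ in out] == ["CCA", "CCN"]

    def test_permutation_preserved(self):
        out = rank_and_screen(self.SCORED)
        assert sorted(out) == sorted(self.SCORED)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_and_screen([])
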