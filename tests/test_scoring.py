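"""ADS desirability, QED, synthetic accessibility and the parameter filter.

The QED and SA implementations are validated against the independent
reference implementations distributed with the chemistry toolkit.
"""

import math
import os
import sys

import numpy as np
import pytest

from denovotki import (
    ADSParams,
    FilterCriteria,
    QEDParameterTable,
    SyntheticSpec,
    ads_desirability,
    compute_descriptors,
    filter_generated,
    gen_base_corpus,
    parameter_filter,
    parse_and_canonicalize,
    qed,
    sa_score,
)
from denovotki.chemio import DESCRIPTOR_NAMES, DescriptorVector
from denovotki.scoring import load_fragment_contributions


def mid_range_descriptors(**overrides):
    """A descriptor vector comfortably inside every filter bound."""
    values = dict(MW=450.0, ALOGP=4.0, HBA=6, HBD=3, PSA=100.0, ROTB=6,
                  AROM=3, ALERTS=0)
    values.update(overrides)
    return DescriptorVector(**values)


class TestADS:
    def test_symmetric_zero_case(self):
        p = ADSParams(a=0, b=1, c=0, d=0, e=1, f=1)
        assert ads_desirability(0.0, p) == pytest.approx(0.25)  # 0.5 * 0.5

    def test_tail_limits_equal_a(self):
        p = ADSParams(a=0.3, b=2.0, c=1.0, d=4.0, e=0.8, f=1.2)
        assert ads_desirability(-1e4, p) == pytest.approx(p.a, abs=1e-9)
        assert ads_desirability(+1e4, p) == pytest.approx(p.a, abs=1e-9)

    def test_symmetry_about_c_when_slopes_equal(self):
        p = ADSParams(a=0.1, b=1.5, c=2.0, d=3.0, e=0.7, f=0.7)
        for t in np.linspace(0.1, 5, 23):
            assert ads_desirability(p.c + t, p) == pytest.approx(
                ads_desirability(p.c - t, p), rel=1e-10)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            ADSParams(a=0, b=1, c=0, d=0, e=0, f=1)


class TestQED:
    def test_unity_when_all_desirabilities_one(self):
        table = QEDParameterTable(
            params={k: ADSParams(a=0, b=1, c=0, d=0, e=1, f=1, dmax=0.25)
                    for k in DESCRIPTOR_NAMES},
            weights={k: float(i + 1) for i, k in enumerate(DESCRIPTOR_NAMES)},
        )
        # at x = 0 every raw desirability is 0.25, normalized to 1.0
        desc = mid_range_descriptors(**{k: 0 for k in DESCRIPTOR_NAMES})
        assert qed(desc, table) == pytest.approx(1.0)

    def test_constant_desirability_geometric_mean(self):
        table = QEDParameterTable(
            params={k: ADSParams(a=0, b=1, c=0, d=0, e=1, f=1) for k in DESCRIPTOR_NAMES},
            weights={k: 1.0 for k in DESCRIPTOR_NAMES},
        )
        desc = mid_range_descriptors(**{k: 0 for k in DESCRIPTOR_NAMES})
        assert qed(desc, table) == pytest.approx(0.25)

    def test_weight_scale_invariance(self):
        desc = compute_descriptors(parse_and_canonicalize("CC(=O)Oc1ccccc1C(=O)O"))
        base = QEDParameterTable.published()
        scaled = QEDParameterTable(params=base.params,
                                   weights={k: 7.0 * w for k, w in base.weights.items()})
        assert qed(desc, base) == pytest.approx(qed(desc, scaled), rel=1e-12)

    def test_matches_reference_implementation_on_aspirin(self):
        from rdkit import Chem
        from rdkit.Chem import QED as RefQED

        smi = "CC(=O)Oc1ccccc1C(=O)O"
        ours = qed(compute_descriptors(parse_and_canonicalize(smi)))
        ref = RefQED.qed(Chem.MolFromSmiles(smi))
        assert ours == pytest.approx(ref, abs=1e-3)

    def test_matches_reference_on_synthetic_corpus(self, base_corpus_small):
        from rdkit import Chem
        from rdkit.Chem import QED as RefQED

        for rec in base_corpus_small:
            ours = qed(compute_descriptors(rec))
            ref = RefQED.qed(Chem.MolFromSmiles(rec.canonical_smiles))
            assert ours == pytest.approx(ref, abs=1e-3), rec.canonical_smiles


class TestSAScore:
    def test_simple_molecule_easier_than_complex_polycycle(self):
        easy = sa_score(parse_and_canonicalize("CCO"))
        hard = sa_score(parse_and_canonicalize(
            "C[C@H]1CC[C@@H]2[C@@H](C1)C1(CC1)C[C@@]21CCC1(C)C"))
        assert easy.sa_score < hard.sa_score

    def test_range_clamp(self, base_corpus_small):
        for rec in base_corpus_small:
            assert 1.0 <= sa_score(rec).sa_score <= 10.0

    def test_matches_reference_scorer(self, base_corpus_small):
        from rdkit import RDPaths

        sys.path.append(os.path.join(RDPaths.RDContribDir, "SA_Score"))
        import sascorer
        from rdkit import Chem

        for rec in base_corpus_small[:20]:
            ours = sa_score(rec).sa_score
            ref = sascorer.calculateScore(Chem.MolFromSmiles(rec.canonical_smiles))
            assert ours == pytest.approx(ref, abs=0.05), rec.canonical_smiles

    def test_components_recombine(self):
        comp = sa_score(parse_and_canonicalize("c1ccc2ncncc2c1"))
        raw = comp.fragment_score - comp.complexity_penalty
        # the scaled score is a monotone decreasing map of the raw score
        assert comp.sa_score == pytest.approx(
            min(max(11.0 - (raw + 5.0) / 6.5 * 9.0, 1.0), 10.0), abs=0.5)

    def test_missing_table_errors(self):
        with pytest.raises(FileNotFoundError):
            load_fragment_contributions("/nonexistent/table.pkl.gz")


class TestParameterFilter:
    def test_low_mw_fails_only_mw(self):
        ok, failed = parameter_filter(mid_range_descriptors(MW=250.0))
        assert not ok and failed == ["MW"]

    def test_inclusive_boundaries_pass(self):
        for overrides in (dict(MW=300.0), dict(MW=700.0), dict(PSA=140.0),
                          dict(ROTB=12), dict(HBA=8, HBD=6)):
            ok, failed = parameter_filter(mid_range_descriptors(**overrides))
            assert ok, failed

    def test_sum_rule(self):
        ok, _ = parameter_filter(mid_range_descriptors(HBA=8, HBD=6))
        assert ok  # 14 exactly
        ok, failed = parameter_filter(mid_range_descriptors(HBA=9, HBD=6))
        assert not ok and failed == ["HBA_HBD"]

    def test_monotone_in_bounds(self):
        desc = mid_range_descriptors(MW=250.0)
        relaxed = FilterCriteria(mw_range=(200.0, 700.0))
        assert parameter_filter(desc, relaxed)[0]

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            FilterCriteria(mw_range=(700.0, 300.0))

    def test_criteria_json_round_trip(self):
        c = FilterCriteria(rotb_max=10.0)
        assert FilterCriteria.from_json(c.to_json()) == c


class TestFilterGenerated:
    def test_validity_stage(self):
        report = filter_generated(["CCO", "C1CC", "c1ccccc1"])
        assert report.valid_count == 2

    def test_duplicates_counted_once(self):
        report = filter_generated(["CCO", "OCC", "C(C)O"])
        assert report.valid_count == 3 and report.unique_count == 1

    def test_passed_counts_match_brute_force(self):
        corpus = gen_base_corpus(SyntheticSpec(n=100, seed=21))
        smiles = [r.canonical_smiles for r in corpus]
        report = filter_generated(smiles)
        brute = sum(
            parameter_filter(compute_descriptors(parse_and_canonicalize(s)))[0]
            for s in set(smiles))
        assert report.passed_count == brute

    def test_empty_strings_treated_as_invalid(self):
        report = filter_generated(["", "CCO"])
        assert report.input_count == 2 and report.valid_count == 1
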