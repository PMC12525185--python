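"""Statistical defects, the applicability domain and outlier search."""

import itertools

import numpy as np
import pytest

import smilescw as s
from smilescw.errors import UnknownAttributeError


class TestAttributeDefect:
    def test_equal_probabilities_give_zero(self):
        assert s.attribute_defect(10, 10, 10, 20, 20, 20) == 0.0
        assert s.attribute_defect(5, 10, 15, 10, 20, 30) == 0.0

    def test_absent_from_one_set_is_maximal(self):
        # attributes invisible to the calibration set carry defect 1.0
        assert s.attribute_defect(2, 1, 0, 63, 63, 65) == 1.0
        assert s.attribute_defect(0, 3, 3, 63, 63, 65) == 1.0

    def test_hand_arithmetic_oracle(self):
        nA, nP, nC = 41, 43, 39
        sA, sP, sC = 63, 63, 65
        pA, pP, pC = nA / sA, nP / sP, nC / sC
        expected = (
            abs(pA - pP) / (nA + nP)
            + abs(pA - pC) / (nA + nC)
            + abs(pP - pC) / (nP + nC)
        )
        assert s.attribute_defect(nA, nP, nC, sA, sP, sC) == pytest.approx(
            expected, rel=1e-12
        )

    def test_symmetric_under_set_permutation(self):
        triple = [(12, 63), (8, 59), (20, 65)]
        base = s.attribute_defect(*(n for n, _ in triple), *(m for _, m in triple))
        for perm in itertools.permutations(triple):
            val = s.attribute_defect(*(n for n, _ in perm), *(m for _, m in perm))
            assert val == pytest.approx(base, rel=1e-12)

    def test_unknown_attribute(self):
        with pytest.raises(UnknownAttributeError):
            s.attribute_defect(0, 0, 0, 10, 10, 10)


class TestInDomain:
    def test_boundary_is_strict(self):
        assert s.in_domain(0.0, 1.0)
        assert s.in_domain(1.9, 1.0)
        assert not s.in_domain(2.0, 1.0)
        assert not s.in_domain(2.5, 1.0)

    def test_requires_positive_dbar(self):
        with pytest.raises(ValueError):
            s.in_domain(0.5, 0.0)


def _profiles(smiles_list):
    return [s.profile_from_smiles(sm) for sm in smiles_list]


class TestCompoundDefect:
    def test_zero_defect_attributes(self):
        # identical attribute distribution in all three sets -> all dk = 0
        profiles = _profiles(["CC", "CO"])
        domain = s.build_domain(profiles, profiles, profiles, {"C", "O", "CC", "OC"})
        assert all(rec.dk == 0.0 for rec in domain.defects.values())
        assert s.compound_defect(profiles[0], domain) == 0.0

    def test_additive_over_concatenation(self, small_model):
        model, _, records, _ = small_model
        domain = model.domain
        a, b = records[0].smiles, records[1].smiles
        combined = s.profile_from_smiles(a + b)
        pa = s.profile_from_smiles(a)
        pb = s.profile_from_smiles(b)
        # Dj is a sum over the attribute multiset, so it deviates from
        # additivity only by the single junction pair created at the seam
        joined = s.compound_defect(combined, domain)
        parts = s.compound_defect(pa, domain) + s.compound_defect(pb, domain)
        toks_a = s.tokenize(s.normalize_smiles(a))
        toks_b = s.tokenize(s.normalize_smiles(b))
        seam = s.pair_attribute(toks_a[-1], toks_b[0])
        seam_dk = (
            domain.defects[seam].dk
            if seam in domain.defects
            else (0.0 if seam in domain.known else 1.0)
        )
        assert joined == pytest.approx(parts + seam_dk, rel=1e-10)

    def test_brute_force_summation_oracle(self, small_model):
        model, _, records, _ = small_model
        domain = model.domain
        for record in records[:10]:
            profile = s.profile_from_smiles(record.smiles)
            expected = 0.0
            for attr, cnt in profile.merged().items():
                if attr in domain.defects:
                    expected += cnt * domain.defects[attr].dk
                elif attr not in domain.known:
                    expected += cnt * 1.0
            assert s.compound_defect(profile, domain) == pytest.approx(
                expected, rel=1e-12
            )


class TestFindOutliers:
    def test_identical_compounds_have_no_outliers(self):
        records = [s.SmilesRecord(f"i{k}", "CCOC", 1.0) for k in range(12)]
        labels = ["A", "P", "C", "V"] * 3
        split = s.FourWaySplit(
            split_id=1, assignment={r.id: lab for r, lab in zip(records, labels)}
        )
        profiles = _profiles([r.smiles for r in records[:3]])
        domain = s.build_domain(profiles, profiles, profiles, set(profiles[0].merged()))
        model = s.FittedModel(
            table=s.CorrelationWeightTable({}, frozenset(), 1),
            c0=0.0, c1=1.0, config=s.TF1_PRESET, domain=domain,
        )
        outliers = s.find_outliers(model, records, split)
        assert outliers["total"] == 0

    def test_planted_foreign_compounds_are_flagged(self, small_model):
        model, _, records, split = small_model
        # five compounds built from bracket-atom attributes that occur only
        # in the validation portion, never in the modeling sets
        planted = [
            s.SmilesRecord(f"planted{k}", "[Xe][Kr][Xe][Kr]", 0.0) for k in range(5)
        ]
        assignment = dict(split.assignment)
        for record in planted:
            assignment[record.id] = "V"
        extended = s.FourWaySplit(split_id=split.split_id, assignment=assignment)
        outliers = s.find_outliers(model, records + planted, extended)
        for record in planted:
            assert record.id in outliers["V"]

    def test_empty_validation_set(self, small_model):
        model, _, records, split = small_model
        no_v = s.FourWaySplit(
            split_id=1,
            assignment={
                cid: (lab if lab != "V" else "C")
                for cid, lab in split.assignment.items()
            },
        )
        outliers = s.find_outliers(model, records, no_v)
        assert outliers["V"] == []


def test_domain_outlier_rate_shrinks_with_identical_distributions():
    """When A/P/C are drawn from one distribution, most compounds lie inside."""
    spec = s.SyntheticSpec(n_compounds=240, seed=31, noise_fraction=0.1)
    records, _ = s.generate_dataset(spec)
    split = s.make_split([r.id for r in records], seed=8)
    by = lambda lab: [
        s.profile_from_smiles(r.smiles)
        for r in records
        if split.assignment[r.id] == lab
    ]
    profiles_a = by("A")
    active = s.active_attributes(profiles_a, 1)
    domain = s.build_domain(profiles_a, by("P"), by("C"), active)
    djs = [s.compound_defect(p, domain) for p in profiles_a]
    inside = [s.in_domain(dj, domain.dbar) for dj in djs]
    assert np.mean(inside) > 0.8
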