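"""Two-domain generator: determinism, class balance, hazards, screening sets."""

import numpy as np
import pytest
from rdkit import Chem

from offtarget_bias.curation import Removed, build_labeled_dataset, standardize, standardize_all
from offtarget_bias.synthetic_data import (
    DomainSpec,
    GenerationError,
    LatentActivityRule,
    default_library,
    generate_domain,
    generate_screening_set,
    proprietary_domain_spec,
    public_domain_spec,
)


def _spec(**kw):
    base = dict(name="t", n_compounds=200, active_fraction=0.5, seed=7)
    base.update(kw)
    return DomainSpec(**base)


class TestSpecValidation:
    def test_active_fraction_bounds(self):
        with pytest.raises(ValueError):
            _spec(active_fraction=0.0)
        with pytest.raises(ValueError):
            _spec(active_fraction=1.0)

    def test_hazard_rate_bounds(self):
        with pytest.raises(ValueError):
            _spec(hazard_rates={"duplicate": 0.6})
        with pytest.raises(ValueError):
            _spec(hazard_rates={"not_a_hazard": 0.1})

    def test_label_noise_bounds(self):
        with pytest.raises(ValueError):
            _spec(label_noise=0.5)


def test_rule_potency_deterministic_and_pchembl_scaled(rule):
    lib = default_library()
    smiles = [lib.smiles(i) for i in range(0, 5000, 731)]
    pots = [rule.potency(s) for s in smiles]
    assert pots == [rule.potency(s) for s in smiles]
    assert all(2.0 < p < 11.0 for p in pots)
    # input-form invariance: potency is a function of the molecule
    canon = Chem.CanonSmiles(smiles[0])
    assert rule.potency(canon) == pytest.approx(rule.potency(smiles[0]))


def test_domain_active_quota_and_determinism(rule):
    spec = DomainSpec(name="pub", n_compounds=500, active_fraction=0.8, seed=1)
    domain = generate_domain(spec, rule)
    assert len(domain.records) == 500
    n_active = sum(r.potency_values[0] >= 5.0 for r in domain.records)
    assert abs(n_active - 400) <= 15
    again = generate_domain(spec, rule)
    assert [(r.raw_structure, r.potency_values, r.release_tag) for r in domain.records] == [
        (r.raw_structure, r.potency_values, r.release_tag) for r in again.records
    ]


def test_all_emitted_structures_are_valid_smiles(rule):
    domain = generate_domain(
        _spec(hazard_rates={k: 0.05 for k in ("salt_adduct", "stereo_pair_conflict", "inorganic", "mw_outlier")}),
        rule,
    )
    for rec in domain.records:
        assert Chem.MolFromSmiles(rec.raw_structure) is not None, rec.raw_structure


def test_every_record_carries_release_tag(rule):
    domain = generate_domain(_spec(), rule)
    tags = {r.release_tag for r in domain.records}
    assert tags <= {28, 30, 31} and len(tags) > 1


def test_class_balance_concentrates_at_large_n(rule):
    spec = DomainSpec(name="big", n_compounds=5000, active_fraction=0.8, label_noise=0.02, seed=3)
    domain = generate_domain(spec, rule)
    realized = domain.truth["realized_active_fraction"]
    assert abs(realized - 0.8) <= 0.02


def test_stereo_conflict_pairs_injected_at_requested_rate(rule):
    spec = _spec(n_compounds=100, hazard_rates={"stereo_pair_conflict": 0.1})
    domain = generate_domain(spec, rule)
    conflicts = [h for h in domain.truth["hazards"] if h["type"] == "stereo_pair_conflict"]
    assert len(conflicts) == 10
    for entry in conflicts:
        i, j = entry["record_indices"]
        pi, pj = domain.records[i].potency_values[0], domain.records[j].potency_values[0]
        assert (pi >= 5.0) != (pj >= 5.0), "pair members must straddle the threshold"
        # stereoisomers: identical once stereochemistry is stripped
        a = standardize(domain.records[i])
        b = standardize(domain.records[j])
        assert a.inchi_nostereo == b.inchi_nostereo and a.inchi != b.inchi


def test_same_rule_gives_same_potency_across_domains(rule):
    pub = generate_domain(DomainSpec(name="a", n_compounds=400, active_fraction=0.7, seed=5), rule)
    priv = generate_domain(DomainSpec(name="b", n_compounds=400, active_fraction=0.3, seed=6), rule)
    pub_pot = {r.raw_structure: r.potency_values[0] for r in pub.records}
    priv_pot = {r.raw_structure: r.potency_values[0] for r in priv.records}
    shared = set(pub_pot) & set(priv_pot)
    assert shared, "domains of 400 from the same library should overlap"
    for smi in shared:
        assert pub_pot[smi] == pytest.approx(priv_pot[smi])


def test_unsatisfiable_spec_fails_with_named_gap():
    all_active_rule = LatentActivityRule(anchor_contributions={}, baseline_potency=9.0, noise_sd=0.1)
    with pytest.raises(GenerationError, match="inactives"):
        generate_domain(_spec(active_fraction=0.5, n_compounds=200), all_active_rule)


def test_curation_removes_injected_hazards_and_keeps_clean_records(rule):
    """Clean records all survive curation; injected conflicts and inorganics never do."""
    spec = DomainSpec(
        name="hz",
        n_compounds=150,
        active_fraction=0.5,
        label_noise=0.0,
        seed=11,
        hazard_rates={
            "salt_adduct": 0.04,
            "duplicate": 0.04,
            "stereo_pair_conflict": 0.06,
            "inorganic": 0.04,
            "mw_outlier": 0.03,
        },
    )
    domain = generate_domain(spec, rule)
    kept, removed = standardize_all(domain.records)
    dataset, _ = build_labeled_dataset(kept, 5.0, "hz")
    curated_keys = set(dataset.keys)

    clean_keys = set()
    for i in domain.truth["clean_indices"]:
        clean_keys.add(standardize(domain.records[i]).key)
    assert clean_keys <= curated_keys, "no clean compound may be lost to curation"

    for entry in domain.truth["hazards"]:
        if entry["type"] == "stereo_pair_conflict":
            key = standardize(domain.records[entry["record_indices"][0]]).key
            assert key not in curated_keys, "conflicting stereo pair must be dropped"
        if entry["type"] == "inorganic":
            assert all(
                isinstance(standardize(domain.records[i]), Removed)
                for i in entry["record_indices"]
            )

    # salt adducts standardize to their parent -> collapsed by dedup, not duplicated
    n_keys = len(dataset.keys)
    assert n_keys == len(set(dataset.keys))


class TestScreeningSet:
    def test_cardinality_and_determinism(self, rule):
        out = generate_screening_set(50, rule, seed=7)
        assert len(out) == 50
        assert out == generate_screening_set(50, rule, seed=7)

    def test_single_structure(self, rule):
        assert len(generate_screening_set(1, rule, seed=0)) == 1

    def test_invalid_n(self, rule):
        with pytest.raises(ValueError):
            generate_screening_set(0, rule, seed=0)

    def test_two_seeds_mostly_disjoint(self, rule):
        a = generate_screening_set(300, rule, seed=1)
        b = generate_screening_set(300, rule, seed=2)

        def flat_inchi(smi):
            mol = Chem.MolFromSmiles(smi)
            Chem.RemoveStereochemistry(mol)
            return Chem.MolToInchi(mol)

        keys_a = {flat_inchi(s) for s in a}
        keys_b = {flat_inchi(s) for s in b}
        overlap = len(keys_a & keys_b) / 300
        assert overlap < 0.05
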