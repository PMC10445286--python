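"""Standardization, labeling, deduplication, selection and splitting."""

import warnings

import pandas as pd
import pytest
from rdkit import Chem
from rdkit.Chem import Descriptors

from offtarget_bias.curation import (
    CompoundRecord,
    Removed,
    assign_label,
    build_labeled_dataset,
    deduplicate,
    exclude_seen,
    filter_assay_metadata,
    filter_mw_window,
    merge_assay_values,
    select_targets,
    standardize,
    standardize_all,
    time_series_split,
)
from offtarget_bias.reference_tables import SELECTED_TARGETS, TARGET_PANEL_COUNTS


def _rec(smiles, potency=6.0, tag=30, target="t"):
    return CompoundRecord(raw_structure=smiles, potency_values=[potency], release_tag=tag, target_id=target)


class TestStandardize:
    def test_salt_stripped_and_neutralized(self):
        out = standardize(_rec("CC(=O)[O-].[Na+]"))
        assert isinstance(out, CompoundRecord)
        assert out.standardized_structure == Chem.CanonSmiles("CC(=O)O")

    def test_water_removed_as_nonorganic(self):
        out = standardize(_rec("O"))
        assert isinstance(out, Removed) and out.reason == "nonorganic"

    def test_salt_pair_without_carbon_removed(self):
        out = standardize(_rec("[Na+].[Cl-]"))
        assert isinstance(out, Removed) and out.reason == "nonorganic"

    def test_unparseable_returns_removed_not_exception(self):
        out = standardize(_rec("not_a_smiles(("))
        assert isinstance(out, Removed) and out.reason == "parse_failure"

    def test_idempotent_on_clean_structure(self):
        once = standardize(_rec("c1ccccc1"))
        twice = standardize(once)
        assert twice.standardized_structure == once.standardized_structure
        assert twice.inchi == once.inchi

    def test_stereo_stripped_inchi_merges_stereoisomers(self):
        a = standardize(_rec("C[C@H](O)c1ccccc1"))
        b = standardize(_rec("C[C@@H](O)c1ccccc1"))
        assert a.inchi != b.inchi
        assert a.inchi_nostereo == b.inchi_nostereo

    def test_batch_continues_past_bad_rows(self):
        kept, removed = standardize_all([_rec("CCO"), _rec("zzz"), _rec("O")])
        assert len(kept) == 1 and len(removed) == 2


@pytest.mark.parametrize(
    "values, expected",
    [([6.0], 6.0), ([5.0, 6.0, 7.0], 6.0), ([4.0, 8.0], 6.0), ([5.0, 5.0, 9.9], 5.0)],
)
def test_merge_assay_values_is_median(values, expected):
    assert merge_assay_values(values) == expected


def test_merge_empty_rejected():
    with pytest.raises(ValueError):
        merge_assay_values([])


@pytest.mark.parametrize(
    "potency, threshold, label",
    [(5.0, 5, 1), (4.99, 5, 0), (5.5, 6, 0), (6.0, 6, 1), (9.3, 5, 1)],
)
def test_assign_label_boundary_is_active(potency, threshold, label):
    assert assign_label(potency, threshold) == label


def test_assign_label_nonfinite_rejected():
    with pytest.raises(ValueError):
        assign_label(float("nan"), 5)


class TestDeduplicate:
    def _pair(self):
        a = standardize(_rec("C[C@H](O)c1ccccc1"))
        b = standardize(_rec("C[C@@H](O)c1ccccc1"))
        return a, b

    def test_agreeing_stereoisomers_keep_one(self):
        a, b = self._pair()
        kept, labels, log = deduplicate([a, b], [1, 1])
        assert len(kept) == 1 and labels == [1]
        # deterministic representative: smallest full InChI
        assert kept[0].inchi == min(a.inchi, b.inchi)

    def test_conflicting_stereoisomers_drop_both(self):
        a, b = self._pair()
        kept, labels, log = deduplicate([a, b], [1, 0])
        assert kept == [] and labels == []
        assert log[0]["reason"] == "label_conflict" and log[0]["n_dropped"] == 2

    def test_distinct_molecules_untouched(self):
        recs = [standardize(_rec(s)) for s in ("CCO", "CCC", "c1ccccc1")]
        kept, labels, _ = deduplicate(recs, [1, 0, 1])
        assert len(kept) == 3 and labels == [1, 0, 1]

    def test_output_keys_unique(self):
        recs = [standardize(_rec(s)) for s in ("CCO", "CCO", "CCC")]
        kept, _, _ = deduplicate(recs, [1, 1, 0])
        keys = [r.key for r in kept]
        assert len(keys) == len(set(keys))


def test_build_labeled_dataset_merges_assays_before_thresholding():
    rec = standardize(_rec("CCO"))
    rec.potency_values = [4.0, 8.0, 4.5]  # median 4.5 -> inactive at 5
    ds, _ = build_labeled_dataset([rec], threshold=5.0)
    assert ds.labels == [0]


class TestSelectTargets:
    def test_panel_selects_exactly_four(self):
        counts = [(name, i or 0, a) for name, i, a, *_ in TARGET_PANEL_COUNTS]
        report = select_targets(counts)
        assert set(report.selected) == SELECTED_TARGETS

    def test_panel_pct_inactive_matches_printed_values(self):
        counts = [(name, i, a, pct) for name, i, a, pct, *_ in TARGET_PANEL_COUNTS if pct is not None]
        report = select_targets([(n, i, a) for n, i, a, _ in counts])
        got = dict(zip(report.rows["target_id"], report.rows["pct_inactive"]))
        for name, _, _, printed in counts:
            assert got[name] == pytest.approx(printed, abs=0.005)

    def test_sorted_by_pct_descending(self):
        report = select_targets([("a", 10, 90), ("b", 50, 50), ("c", 30, 70)])
        assert list(report.rows["target_id"]) == ["b", "c", "a"]

    def test_boundary_total_not_strictly_greater(self):
        report = select_targets([("edge", 500, 499)])  # total 999, 50% inactive
        assert report.selected == []
        report = select_targets([("edge", 500, 501)])  # total 1001
        assert report.selected == ["edge"]

    def test_empty_input(self):
        assert len(select_targets([]).rows) == 0


class TestTimeSeriesSplit:
    def _records(self):
        smiles = ["CCO", "CCC", "CCN", "CCCl", "c1ccccc1"]
        tags = [28, 30, 31, 31, 28]
        return [standardize(_rec(s, tag=t)) for s, t in zip(smiles, tags)]

    def test_cut_at_30_puts_31_in_test(self):
        train, test, _ = time_series_split(self._records(), 30)
        assert {r.release_tag for r in train} == {28, 30}
        assert {r.release_tag for r in test} == {31}

    def test_cut_at_28_moves_30_and_31_to_test(self):
        train, test, _ = time_series_split(self._records(), 28)
        assert all(r.release_tag == 28 for r in train)
        assert {r.release_tag for r in test} == {30, 31}

    def test_test_duplicates_of_train_dropped(self):
        recs = [standardize(_rec("CCO", tag=28)), standardize(_rec("CCO", tag=31))]
        train, test, log = time_series_split(recs, 30)
        assert len(train) == 1 and test == []
        assert log[0]["reason"] == "test_duplicate_of_train"

    def test_empty_test_warns(self):
        recs = [standardize(_rec("CCO", tag=28))]
        with pytest.warns(UserWarning):
            time_series_split(recs, 30)


def test_mw_window_boundaries_inclusive():
    ethanol = standardize(_rec("CCO"))
    mw = Descriptors.MolWt(Chem.MolFromSmiles(ethanol.standardized_structure))
    kept, _ = filter_mw_window([ethanol], min_da=mw, max_da=mw + 1)
    assert kept, "record exactly at the lower bound must be retained"
    kept, removed = filter_mw_window([ethanol], min_da=mw + 0.01, max_da=mw + 1)
    assert not kept and "mw_out_of_range" in removed[0].reason
    kept, _ = filter_mw_window([ethanol], min_da=mw - 1, max_da=mw)
    assert kept, "record exactly at the upper bound must be retained"


def test_mw_default_window_excludes_extremes():
    tiny = standardize(_rec("C=O"))  # ~30 Da
    huge = standardize(_rec("C" * 200))  # ~2800 Da
    normal = standardize(_rec("c1ccccc1CCN"))
    kept, removed = filter_mw_window([tiny, huge, normal])
    assert [r.raw_structure for r in kept] == [normal.raw_structure]
    assert len(removed) == 2


class TestExcludeSeen:
    def test_exact_duplicate_dropped(self):
        train = [standardize(_rec("CCO"))]
        probe = [standardize(_rec("CCO")), standardize(_rec("CCC"))]
        kept, n = exclude_seen(probe, [train])
        assert n == 1 and kept[0].standardized_structure == Chem.CanonSmiles("CCC")

    def test_stereoisomer_of_train_compound_dropped(self):
        train = [standardize(_rec("C[C@H](O)c1ccccc1"))]
        probe = [standardize(_rec("C[C@@H](O)c1ccccc1"))]
        kept, n = exclude_seen(probe, [train])
        assert kept == [] and n == 1

    def test_empty_reference_is_noop(self):
        probe = [standardize(_rec("CCO"))]
        kept, n = exclude_seen(probe, [])
        assert kept == probe and n == 0


def test_assay_metadata_filter():
    rows = pd.DataFrame(
        {
            "organism": ["Homo sapiens", "Rattus norvegicus", "Homo sapiens", "Homo sapiens"],
            "target_type": ["SINGLE PROTEIN", "SINGLE PROTEIN", "PROTEIN COMPLEX", "SINGLE PROTEIN"],
            "standard_type": ["IC50", "IC50", "Ki", "Percent inhibition"],
        }
    )
    kept, dropped = filter_assay_metadata(rows)
    assert len(kept) == 1 and kept.index[0] == 0
    assert list(dropped["drop_reason"]) == ["organism", "target_type", "standard_type"]
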