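"""Compound standardization, deduplication, labeling, and splitting.

The curation contract mirrors standard ChEMBL-extract practice for QSAR
dataset assembly:

* structures are cleaned to a single neutral organic parent (salts,
  solvents and counterions stripped, charges neutralized); nonorganic or
  unparseable entries are removed with a reason, never by raising mid-batch;
* multiple assay potencies for the same compound-target pair are merged by
  the median on the pChEMBL scale;
* activity labels come from a pChEMBL threshold (5 by default, i.e. 10 μM;
  a potency exactly at the threshold counts as active);
* because the downstream fingerprints ignore stereochemistry, duplicates
  are detected on stereo-stripped InChIs — stereoisomer groups with one
  consistent label keep a single representative, groups with conflicting
  labels are dropped entirely;
* modeling targets are those with more than 1000 compounds and at least
  15% inactives;
* validation uses a release-tag time-series split (train on earlier
  database releases, test on compounds that appeared later).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from statistics import median
from typing import Iterable, Sequence

import math

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit import RDLogger

from offtarget_bias.metrics import pct_inactive

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CompoundRecord",
    "Removed",
    "LabeledDataset",
    "TargetSelectionReport",
    "standardize",
    "standardize_all",
    "merge_assay_values",
    "assign_label",
    "deduplicate",
    "build_labeled_dataset",
    "select_targets",
    "time_series_split",
    "filter_mw_window",
    "exclude_seen",
    "filter_assay_metadata",
]

#: Elements allowed in an "organic" parent structure.
_ORGANIC_ELEMENTS = frozenset("H B C N O F Si P S Cl Se Br I".split())


@dataclass
class CompoundRecord:
    """One structure with its potency observations and provenance tag."""

    raw_structure: str
    potency_values: list[float] = field(default_factory=list)
    assay_kind: str = "IC50"
    release_tag: int | str | None = None
    target_id: str | None = None
    standardized_structure: str | None = None
    inchi: str | None = None
    inchi_nostereo: str | None = None

    @property
    def potency(self) -> float:
        """Merged (median) pChEMBL potency across assays."""
        return merge_assay_values(self.potency_values)

    @property
    def key(self) -> str:
        """Stereo-agnostic dedup key (requires standardization)."""
        if self.inchi_nostereo is None:
            raise ValueError("record not standardized: inchi_nostereo missing")
        return self.inchi_nostereo


@dataclass(frozen=True)
class Removed:
    """Marker returned when curation drops a record, with the reason."""

    raw_structure: str
    reason: str


@dataclass
class LabeledDataset:
    """Curated per-target set of (structure, 0/1 label) pairs."""

    target_id: str
    threshold: float
    structures: list[str]
    labels: list[int]
    keys: list[str] = field(default_factory=list)
    split_assignment: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.structures) != len(self.labels):
            raise ValueError("structures and labels must be parallel")
        if any(l not in (0, 1) for l in self.labels):
            raise ValueError("labels must be 0/1")
        if self.keys and len(set(self.keys)) != len(self.keys):
            raise ValueError("duplicate dedup keys in labeled dataset")

    @property
    def n_active(self) -> int:
        return sum(self.labels)

    @property
    def n_inactive(self) -> int:
        return len(self.labels) - self.n_active

    def __len__(self) -> int:
        return len(self.structures)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"smiles": self.structures, "label": self.labels, "target_id": self.target_id}
        )


@dataclass
class TargetSelectionReport:
    """Per-target counts with the modeling-selection verdict.

    ``selected`` is true iff total > 1000 and the (unrounded) inactive
    percentage is at least 15; the reported percentage is rounded to two
    decimals.  Rows are sorted by percentage of inactives, descending.
    """

    rows: pd.DataFrame

    @property
    def selected(self) -> list[str]:
        return list(self.rows.loc[self.rows["selected"], "target_id"])


def _neutralized(mol: Chem.Mol) -> Chem.Mol:
    return rdMolStandardize.Uncharger().uncharge(mol)


def standardize(record: CompoundRecord) -> CompoundRecord | Removed:
    """Clean one structure to its neutral organic parent.

    Keeps the largest organic fragment (dropping salts, solvents and
    counterions), neutralizes charges where chemically valid, and computes
    canonical SMILES, InChI and stereo-stripped InChI.  Returns a
    :class:`Removed` marker (never raises) for unparseable or nonorganic
    input, so a batch is never halted by a single bad row.
    Idempotent: standardizing an already-clean record returns the same
    structure.
    """
    mol = Chem.MolFromSmiles(record.raw_structure)
    if mol is None:
        return Removed(record.raw_structure, "parse_failure")
    try:
        mol = rdMolStandardize.Cleanup(mol)
        mol = rdMolStandardize.LargestFragmentChooser(preferOrganic=True).choose(mol)
        mol = _neutralized(mol)
    except Exception:
        return Removed(record.raw_structure, "standardization_failure")
    if mol is None or mol.GetNumAtoms() == 0:
        return Removed(record.raw_structure, "empty_after_cleanup")
    symbols = {a.GetSymbol() for a in mol.GetAtoms()}
    if "C" not in symbols or not symbols <= _ORGANIC_ELEMENTS:
        return Removed(record.raw_structure, "nonorganic")
    smiles = Chem.MolToSmiles(mol)
    inchi = Chem.MolToInchi(mol)
    flat = Chem.Mol(mol)
    Chem.RemoveStereochemistry(flat)
    inchi_nostereo = Chem.MolToInchi(flat)
    if not inchi or not inchi_nostereo:
        return Removed(record.raw_structure, "inchi_failure")
    return replace(
        record,
        standardized_structure=smiles,
        inchi=inchi,
        inchi_nostereo=inchi_nostereo,
    )


def standardize_all(
    records: Iterable[CompoundRecord],
) -> tuple[list[CompoundRecord], list[Removed]]:
    """Standardize a batch; returns (kept, removed-with-reasons)."""
    kept: list[CompoundRecord] = []
    removed: list[Removed] = []
    for rec in records:
        out = standardize(rec)
        (removed if isinstance(out, Removed) else kept).append(out)
    return kept, removed


def merge_assay_values(values: Sequence[float]) -> float:
    """Merge several pChEMBL observations of one compound into one value.

    Median across assays: robust to a single outlying assay, and for an
    even number of observations the mean of the middle pair.
    """
    if not values:
        raise ValueError("cannot merge an empty list of potencies")
    return float(median(values))


def assign_label(potency: float, threshold: float = 5.0) -> int:
    """Binary activity at a pChEMBL threshold; the boundary is active.

    Returns 1 if ``potency >= threshold`` else 0 (only potencies strictly
    below the threshold are inactive).
    """
    if not math.isfinite(potency):
        raise ValueError(f"potency must be finite, got {potency}")
    return 1 if potency >= threshold else 0


def deduplicate(
    records: Sequence[CompoundRecord], labels: Sequence[int]
) -> tuple[list[CompoundRecord], list[int], list[dict]]:
    """Collapse stereoisomer/duplicate groups on stereo-stripped InChI.

    A group whose members all share one label keeps exactly one
    representative (the lexicographically smallest full InChI — a
    deterministic, seed-free choice); a group with conflicting labels is
    dropped entirely.  Returns (kept records, kept labels, drop log).
    """
    if len(records) != len(labels):
        raise ValueError("records and labels must be parallel")
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(rec.key, []).append(i)
    kept_r: list[CompoundRecord] = []
    kept_l: list[int] = []
    log: list[dict] = []
    for key, idxs in groups.items():
        group_labels = {labels[i] for i in idxs}
        if len(group_labels) > 1:
            log.append({"key": key, "reason": "label_conflict", "n_dropped": len(idxs)})
            continue
        rep = min(idxs, key=lambda i: (records[i].inchi or "", i))
        if len(idxs) > 1:
            log.append({"key": key, "reason": "duplicate_group", "n_dropped": len(idxs) - 1})
        kept_r.append(records[rep])
        kept_l.append(labels[rep])
    return kept_r, kept_l, log


def build_labeled_dataset(
    records: Sequence[CompoundRecord],
    threshold: float = 5.0,
    target_id: str = "synthetic",
) -> tuple[LabeledDataset, list[dict]]:
    """Label standardized records at a threshold and deduplicate.

    Each record's assay values are merged by the median before thresholding.
    Returns the dataset plus the dedup drop log.
    """
    labels = [assign_label(rec.potency, threshold) for rec in records]
    kept, kept_labels, log = deduplicate(records, labels)
    return (
        LabeledDataset(
            target_id=target_id,
            threshold=threshold,
            structures=[r.standardized_structure or r.raw_structure for r in kept],
            labels=kept_labels,
            keys=[r.key for r in kept],
        ),
        log,
    )


def select_targets(
    counts: Iterable[tuple[str, int, int]],
    min_total: int = 1000,
    min_pct_inactive: float = 15.0,
) -> TargetSelectionReport:
    """Apply the modeling-target filter: total > 1000 and >= 15% inactives.

    The percentage test uses the unrounded value (rounding happens only in
    the report view), avoiding artifacts for targets sitting exactly at the
    boundary.
    """
    rows = []
    for target_id, n_inactive, n_active in counts:
        if n_inactive < 0 or n_active < 0:
            raise ValueError(f"negative counts for {target_id}")
        total = n_inactive + n_active
        pct_raw = pct_inactive(n_inactive, n_active, ndigits=None) if total else 0.0
        rows.append(
            {
                "target_id": target_id,
                "n_inactive": n_inactive,
                "n_active": n_active,
                "total": total,
                "pct_inactive": round(pct_raw, 2),
                "selected": total > min_total and pct_raw >= min_pct_inactive,
                "_pct_raw": pct_raw,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["target_id", "n_inactive", "n_active", "total", "pct_inactive", "selected", "_pct_raw"],
    )
    if len(frame):
        frame = frame.sort_values("_pct_raw", ascending=False, kind="stable").reset_index(drop=True)
    frame = frame.drop(columns="_pct_raw")
    return TargetSelectionReport(rows=frame)


def time_series_split(
    records: Sequence[CompoundRecord], train_max_release: int | str
) -> tuple[list[CompoundRecord], list[CompoundRecord], list[dict]]:
    """Split by release tag: train ≤ cut, test > cut; test is leak-free.

    Emulates prospective validation on database releases: compounds first
    seen after ``train_max_release`` form the test set.  Test records whose
    stereo-stripped InChI already occurs in the training set are dropped
    and logged.  An empty test set triggers a warning, not an error.
    """
    train: list[CompoundRecord] = []
    test: list[CompoundRecord] = []
    for rec in records:
        if rec.release_tag is None:
            raise ValueError("record without release tag")
        (train if rec.release_tag <= train_max_release else test).append(rec)
    train_keys = {r.key for r in train}
    log: list[dict] = []
    clean_test = []
    for rec in test:
        if rec.key in train_keys:
            log.append({"key": rec.key, "reason": "test_duplicate_of_train"})
        else:
            clean_test.append(rec)
    if not clean_test:
        warnings.warn("time-series split produced an empty test set", stacklevel=2)
    return train, clean_test, log


def filter_mw_window(
    records: Sequence[CompoundRecord], min_da: float = 61.0, max_da: float = 2323.0
) -> tuple[list[CompoundRecord], list[Removed]]:
    """Keep records with molecular weight in [min_da, max_da] (inclusive).

    The default window matches the weight range of the training corpora;
    screening compounds outside it are outside the models' applicability.
    """
    kept: list[CompoundRecord] = []
    removed: list[Removed] = []
    for rec in records:
        smi = rec.standardized_structure or rec.raw_structure
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            removed.append(Removed(rec.raw_structure, "parse_failure"))
            continue
        mw = Descriptors.MolWt(mol)
        if min_da <= mw <= max_da:
            kept.append(rec)
        else:
            removed.append(Removed(rec.raw_structure, f"mw_out_of_range({mw:.1f})"))
    return kept, removed


def exclude_seen(
    records: Sequence[CompoundRecord],
    reference_sets: Sequence[Iterable[CompoundRecord] | LabeledDataset],
) -> tuple[list[CompoundRecord], int]:
    """Drop records whose stereo-stripped InChI occurs in any reference set.

    Used to purge external validation sets of compounds already present in
    training or test data; matching is stereochemistry-agnostic, so a
    stereoisomer of a training compound is also excluded.  Returns
    (kept, n_dropped).
    """
    seen: set[str] = set()
    for ref in reference_sets:
        if isinstance(ref, LabeledDataset):
            seen.update(ref.keys)
        else:
            seen.update(r.key for r in ref)
    kept = [r for r in records if r.key not in seen]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.info("exclude_seen dropped %d records", n_dropped)
    return kept, n_dropped


def filter_assay_metadata(
    rows: pd.DataFrame,
    organism: str = "Homo sapiens",
    target_type: str = "SINGLE PROTEIN",
    standard_types: Sequence[str] = ("IC50", "Ki"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep only human single-protein IC50/Ki rows of an activity export.

    Works on the metadata columns (``organism``, ``target_type``,
    ``standard_type``) of a ChEMBL-style activity table.  Returns
    (kept rows, dropped rows with a ``drop_reason`` column).
    """
    required = {"organism", "target_type", "standard_type"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"missing metadata columns: {sorted(missing)}")
    reasons = pd.Series("", index=rows.index, dtype=object)
    reasons[rows["organism"] != organism] = "organism"
    ok_tt = rows["target_type"] == target_type
    reasons[~ok_tt & (reasons == "")] = "target_type"
    ok_st = rows["standard_type"].isin(standard_types)
    reasons[~ok_st & (reasons == "")] = "standard_type"
    keep = reasons == ""
    dropped = rows.loc[~keep].copy()
    dropped["drop_reason"] = reasons[~keep]
    return rows.loc[keep].copy(), dropped
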