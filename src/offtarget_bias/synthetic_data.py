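"""Two-domain synthetic compound generator with a shared latent activity rule.

Real off-target corpora differ sharply by provenance: public databases are
dominated by actives (on-target-optimized chemistry plus publication bias),
while pharmaceutical screening collections are dominated by inactives.  To
study that bias without any database access, this module generates valid
drug-like SMILES from a small fragment grammar (scaffold × two decorations)
and assigns each structure a latent pChEMBL potency from substructure
"anchor" contributions plus Gaussian assay noise.  Because the potency rule
is substructure-based, the signal is learnable by ECFP models — which is
the property the downstream bias analysis depends on.

Both domains draw from the *same* rule; they differ only in how they sample
the active/inactive pools, so a compound present in both domains carries
the same potency.  Curation hazards (salt adducts, duplicates, stereoisomer
pairs with agreeing or conflicting labels, inorganics, molecular-weight
outliers) are injected as extra records with a machine-readable "truth"
sidecar, giving curation tests exact ground truth of what must be removed.

The generator makes no attempt at synthesizability or at matching real
property distributions; it reproduces the *statistical* structure of the
two domains, not their chemistry.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from offtarget_bias.curation import CompoundRecord

__all__ = [
    "FragmentLibrary",
    "LatentActivityRule",
    "DomainSpec",
    "GeneratedDomain",
    "GenerationError",
    "generate_domain",
    "generate_screening_set",
    "public_domain_spec",
    "proprietary_domain_spec",
    "default_rule",
    "default_library",
    "write_domain_csv",
]

HAZARD_KINDS = ("salt_adduct", "duplicate", "stereo_pair_agree", "stereo_pair_conflict", "inorganic", "mw_outlier")

# Scaffold templates; ring-closure digits 1-2 are reserved for scaffolds,
# 8-9 for substituents, so any (scaffold, substituent) combination parses.
_SCAFFOLDS: tuple[str, ...] = (
    "c1ccc({0})cc1{1}",                      # para-disubstituted benzene
    "c1cc({0})cc({1})c1",                    # meta-disubstituted benzene
    "c1ccc({0})nc1{1}",                      # pyridine
    "c1cc({0})oc1{1}",                       # furan
    "c1cc({0})sc1{1}",                       # thiophene
    "C1CCC({0})CC1{1}",                      # cyclohexane
    "O=C(N{0})c1ccc({1})cc1",                # benzamide
    "O=S(=O)(N{0})c1ccc({1})cc1",            # benzenesulfonamide
    "N({0})CCN({1})C",                       # ethylenediamine (polyamine)
    "c1ccc2c(c1)nc({0})n2{1}",               # benzimidazole
    "c1ccc2c(c1)cc({0})cc2{1}",              # naphthalene
    "O=C1N({0})C(=O)c2cc({1})ccc21",         # phthalimide
)

_SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "CCCC", "C(C)C", "C(C)(C)C",
    "CCO", "CCN", "CO", "CN", "O", "OC", "OCC",
    "N", "N(C)C", "NC(C)=O",
    "C(=O)O", "C(=O)OC", "C(=O)N", "C(=O)NC", "C(=O)C",
    "C#N", "[N+](=O)[O-]", "F", "Cl", "Br", "C(F)(F)F",
    "S(=O)(=O)C", "SC", "CSC",
    "c8ccccc8", "c8ccncc8", "c8ccc(Cl)cc8", "c8ccc(O)cc8", "c8ccc(N)cc8",
    "Cc8ccccc8", "CCc8ccco8", "C8CC8", "C8CCCCC8", "C8CCNCC8",
)

# Signed potency contributions of substructure anchors (pChEMBL units,
# applied once per match).  Basic nitrogens and lipophilic halogens push
# potency up; acids, nitro groups, nitriles and esters push it down.
DEFAULT_ANCHORS: dict[str, float] = {
    "[NX3;H2]": 1.0,
    "c1ccncc1": 0.8,
    "[OX2H]": 0.4,
    "C(=O)[OX2H1]": -1.2,
    "[N+](=O)[O-]": -1.3,
    "S(=O)(=O)N": 0.9,
    "C#N": -0.8,
    "[Cl]": 0.3,
    "C(F)(F)F": 0.5,
    "C(=O)O[CX4]": -0.6,
}


class GenerationError(RuntimeError):
    """A domain spec that the latent rule cannot satisfy."""


class FragmentLibrary:
    """Enumerable scaffold × decoration × decoration SMILES space."""

    def __init__(
        self,
        scaffolds: Sequence[str] = _SCAFFOLDS,
        substituents: Sequence[str] = _SUBSTITUENTS,
    ) -> None:
        self.scaffolds = tuple(scaffolds)
        self.substituents = tuple(substituents)

    def __len__(self) -> int:
        return len(self.scaffolds) * len(self.substituents) ** 2

    def smiles(self, idx: int) -> str:
        k = len(self.substituents)
        scaffold_i, rest = divmod(idx, k * k)
        i, j = divmod(rest, k)
        return self.scaffolds[scaffold_i].format(self.substituents[i], self.substituents[j])


_DEFAULT_LIBRARY: FragmentLibrary | None = None


def default_library() -> FragmentLibrary:
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        _DEFAULT_LIBRARY = FragmentLibrary()
    return _DEFAULT_LIBRARY


def _stable_seed(*parts: object) -> int:
    digest = hashlib.blake2b("|".join(map(str, parts)).encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big")


@dataclass
class LatentActivityRule:
    """Substructure-additive latent potency on the pChEMBL scale.

    ``potency = baseline + sum(matches(anchor) * contribution) + noise``,
    with zero-mean Gaussian noise whose seed is a stable hash of the
    canonical SMILES and ``noise_seed`` — so a structure's potency is a
    deterministic function of (rule, structure), identical across domains
    built from the same rule.  Typical outputs fall in pChEMBL 3-10.
    """

    anchor_contributions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ANCHORS))
    baseline_potency: float = 4.7
    noise_sd: float = 0.4
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self._patterns = [
            (Chem.MolFromSmarts(s), c) for s, c in self.anchor_contributions.items()
        ]
        if any(p is None for p, _ in self._patterns):
            raise ValueError("invalid anchor SMARTS pattern")
        self._cache: dict[str, float] = {}

    def potency(self, smiles: str) -> float:
        """Deterministic latent pChEMBL potency of one structure."""
        cached = self._cache.get(smiles)
        if cached is not None:
            return cached
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable structure: {smiles!r}")
        canonical = Chem.MolToSmiles(mol)
        value = self.baseline_potency
        for pattern, contribution in self._patterns:
            value += len(mol.GetSubstructMatches(pattern)) * contribution
        rng = np.random.default_rng(_stable_seed("latent-noise", self.noise_seed, canonical))
        value += float(rng.normal(0.0, self.noise_sd))
        self._cache[smiles] = value
        return value


def default_rule(noise_seed: int = 0) -> LatentActivityRule:
    return LatentActivityRule(noise_seed=noise_seed)


@dataclass
class DomainSpec:
    """Sampling recipe for one data domain.

    ``active_fraction`` is the target share of compounds at pChEMBL >= 5;
    ``label_noise`` reflects that fraction of potencies across the
    threshold (assay-error surrogate); ``release_tags`` are (tag, weight)
    pairs defining the release distribution for time-series splits;
    ``hazard_rates`` inject curation hazards as extra records at
    ``round(rate * n_compounds)`` each.
    """

    name: str
    n_compounds: int
    active_fraction: float
    seed: int
    label_noise: float = 0.0
    release_tags: tuple[tuple[int | str, float], ...] = ((28, 0.4), (30, 0.35), (31, 0.25))
    hazard_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be positive")
        if not 0.0 < self.active_fraction < 1.0:
            raise ValueError("active_fraction must be strictly between 0 and 1")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if not self.release_tags:
            raise ValueError("at least one release tag required")
        unknown = set(self.hazard_rates) - set(HAZARD_KINDS)
        if unknown:
            raise ValueError(f"unknown hazard kinds: {sorted(unknown)}")
        if any(not 0.0 <= r < 0.5 for r in self.hazard_rates.values()):
            raise ValueError("hazard rates must be in [0, 0.5)")


def public_domain_spec(n: int = 2000, seed: int = 0, **hazards: float) -> DomainSpec:
    """Canonical active-majority domain (80% actives, light label noise)."""
    return DomainSpec(
        name="public",
        n_compounds=n,
        active_fraction=0.8,
        label_noise=0.02,
        seed=seed,
        hazard_rates=dict(hazards),
    )


def proprietary_domain_spec(n: int = 2000, seed: int = 1, **hazards: float) -> DomainSpec:
    """Canonical inactive-majority domain (20% actives, light label noise)."""
    return DomainSpec(
        name="proprietary",
        n_compounds=n,
        active_fraction=0.2,
        label_noise=0.02,
        seed=seed,
        hazard_rates=dict(hazards),
    )


@dataclass
class GeneratedDomain:
    """Generator output: records plus a ground-truth sidecar for tests.

    ``truth`` holds the indices of clean records, every injected hazard
    with its type and record indices, the indices whose potency was
    noise-reflected, and the realized active fraction at threshold 5.
    """

    spec: DomainSpec
    records: list[CompoundRecord]
    truth: dict

    def __len__(self) -> int:
        return len(self.records)


_SALT_FRAGMENTS = (".Cl", ".[Na+].[Cl-]", ".O", ".[K+].[Br-]")
_INORGANICS = ("O", "[Na+].[Cl-]", "[K+].[I-]", "N", "[Ca+2].[Cl-].[Cl-]", "O=S(=O)([O-])[O-].[Na+].[Na+]")
_MW_OUTLIERS = ("C=O", "O=C=O", "CO", "C" * 180, "C" * 200)
_ACTIVITY_THRESHOLD = 5.0


def _sample_release(rng: np.random.Generator, tags: tuple[tuple[int | str, float], ...]):
    weights = np.array([w for _, w in tags], dtype=float)
    weights /= weights.sum()
    return tags[int(rng.choice(len(tags), p=weights))][0]


def generate_domain(
    spec: DomainSpec,
    rule: LatentActivityRule,
    library: FragmentLibrary | None = None,
) -> GeneratedDomain:
    """Sample one domain from the shared latent rule.

    Walks a seed-shuffled enumeration of the fragment library, computing
    each candidate's latent potency, until the active/inactive quotas
    implied by ``active_fraction`` (at pChEMBL threshold 5) are filled;
    label noise then reflects a fixed fraction of potencies across the
    threshold.  Hazard records are appended after the ``n_compounds`` clean
    records and logged in the truth sidecar.  Deterministic: the same spec
    and rule give byte-identical output.

    Raises :class:`GenerationError` if the quotas cannot be filled after
    examining ``10 * n_compounds`` candidates (the rule cannot achieve the
    requested class balance).
    """
    library = library or default_library()
    rng = np.random.default_rng(_stable_seed("domain", spec.seed, spec.name))
    n = spec.n_compounds
    n_active = int(round(n * spec.active_fraction))
    n_inactive = n - n_active

    order = rng.permutation(len(library))
    actives: list[tuple[str, float]] = []
    inactives: list[tuple[str, float]] = []
    examined = 0
    for idx in order:
        if len(actives) >= n_active and len(inactives) >= n_inactive:
            break
        if examined >= 10 * n:
            gap_a = n_active - len(actives)
            gap_i = n_inactive - len(inactives)
            raise GenerationError(
                f"rule cannot achieve active_fraction={spec.active_fraction} for "
                f"n={n}: short {max(gap_a, 0)} actives / {max(gap_i, 0)} inactives "
                f"after examining {examined} candidates"
            )
        examined += 1
        smi = library.smiles(int(idx))
        p = rule.potency(smi)
        bucket = actives if p >= _ACTIVITY_THRESHOLD else inactives
        if (bucket is actives and len(actives) < n_active) or (
            bucket is inactives and len(inactives) < n_inactive
        ):
            bucket.append((smi, p))
    if len(actives) < n_active or len(inactives) < n_inactive:
        raise GenerationError(
            f"library exhausted: short {n_active - len(actives)} actives / "
            f"{n_inactive - len(inactives)} inactives for active_fraction="
            f"{spec.active_fraction}"
        )

    sampled = actives + inactives
    perm = rng.permutation(len(sampled))
    sampled = [sampled[i] for i in perm]

    n_flip = int(round(spec.label_noise * n))
    flip_idx = set(map(int, rng.choice(n, size=n_flip, replace=False))) if n_flip else set()

    records: list[CompoundRecord] = []
    for i, (smi, p) in enumerate(sampled):
        if i in flip_idx:
            p = 2 * _ACTIVITY_THRESHOLD - p
        records.append(
            CompoundRecord(
                raw_structure=smi,
                potency_values=[p],
                release_tag=_sample_release(rng, spec.release_tags),
                target_id=spec.name,
            )
        )

    truth: dict = {
        "clean_indices": list(range(n)),
        "potency_flipped_indices": sorted(flip_idx),
        "hazards": [],
        "realized_active_fraction": sum(
            r.potency_values[0] >= _ACTIVITY_THRESHOLD for r in records
        )
        / n,
    }

    def _clean_pick() -> CompoundRecord:
        return records[int(rng.integers(0, n))]

    for kind in HAZARD_KINDS:
        count = int(round(spec.hazard_rates.get(kind, 0.0) * n))
        for _ in range(count):
            entry: dict = {"type": kind}
            if kind == "salt_adduct":
                parent = _clean_pick()
                salt = _SALT_FRAGMENTS[int(rng.integers(len(_SALT_FRAGMENTS)))]
                rec = CompoundRecord(
                    raw_structure=parent.raw_structure + salt,
                    potency_values=list(parent.potency_values),
                    release_tag=parent.release_tag,
                    target_id=spec.name,
                )
                entry["parent"] = parent.raw_structure
                new = [rec]
            elif kind == "duplicate":
                parent = _clean_pick()
                rec = CompoundRecord(
                    raw_structure=parent.raw_structure,
                    potency_values=list(parent.potency_values),
                    release_tag=parent.release_tag,
                    target_id=spec.name,
                )
                entry["parent"] = parent.raw_structure
                new = [rec]
            elif kind in ("stereo_pair_agree", "stereo_pair_conflict"):
                sub = library.substituents[int(rng.integers(len(library.substituents)))]
                pair_smiles = (
                    f"C[C@H](O)c1ccc({sub})cc1",
                    f"C[C@@H](O)c1ccc({sub})cc1",
                )
                if kind == "stereo_pair_agree":
                    side_active = bool(rng.integers(2))
                    lo, hi = (5.3, 7.0) if side_active else (3.0, 4.7)
                    potencies = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
                else:
                    potencies = (float(rng.uniform(5.3, 7.0)), float(rng.uniform(3.0, 4.7)))
                tag = _sample_release(rng, spec.release_tags)
                new = [
                    CompoundRecord(
                        raw_structure=s, potency_values=[p], release_tag=tag, target_id=spec.name
                    )
                    for s, p in zip(pair_smiles, potencies)
                ]
            elif kind == "inorganic":
                smi = _INORGANICS[int(rng.integers(len(_INORGANICS)))]
                new = [
                    CompoundRecord(
                        raw_structure=smi,
                        potency_values=[float(rng.uniform(3.0, 7.0))],
                        release_tag=_sample_release(rng, spec.release_tags),
                        target_id=spec.name,
                    )
                ]
            else:  # mw_outlier
                smi = _MW_OUTLIERS[int(rng.integers(len(_MW_OUTLIERS)))]
                new = [
                    CompoundRecord(
                        raw_structure=smi,
                        potency_values=[float(rng.uniform(3.0, 7.0))],
                        release_tag=_sample_release(rng, spec.release_tags),
                        target_id=spec.name,
                    )
                ]
            entry["record_indices"] = list(range(len(records), len(records) + len(new)))
            entry["structures"] = [r.raw_structure for r in new]
            records.extend(new)
            truth["hazards"].append(entry)

    return GeneratedDomain(spec=spec, records=records, truth=truth)


def generate_screening_set(
    n: int,
    rule: LatentActivityRule,
    seed: int,
    library: FragmentLibrary | None = None,
) -> list[str]:
    """Sample ``n`` unlabeled screening structures (deterministic per seed).

    Drawn without replacement from the fragment library, so two different
    seeds give mostly disjoint sets when ``n`` is small relative to the
    library.  The rule is accepted so callers can recover latent ground
    truth via :meth:`LatentActivityRule.potency` when scoring experiments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    library = library or default_library()
    if n > len(library):
        raise ValueError(f"n={n} exceeds library size {len(library)}")
    rng = np.random.default_rng(_stable_seed("screening", seed))
    idx = rng.choice(len(library), size=n, replace=False)
    return [library.smiles(int(i)) for i in idx]


def write_domain_csv(domain: GeneratedDomain, path: str | Path, truth_sidecar: bool = True) -> None:
    """Write a generated domain as CSV plus an optional JSON truth sidecar."""
    path = Path(path)
    pd.DataFrame(
        {
            "smiles": [r.raw_structure for r in domain.records],
            "potency_pchembl": [r.potency_values[0] for r in domain.records],
            "release_tag": [r.release_tag for r in domain.records],
            "target_id": [r.target_id for r in domain.records],
        }
    ).to_csv(path, index=False)
    if truth_sidecar:
        path.with_suffix(".truth.json").write_text(json.dumps(domain.truth, indent=1))
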