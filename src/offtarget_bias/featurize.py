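"""Circular fingerprints and Tanimoto similarity.

Two fingerprint configurations are used in this package: ECFP4 folded to
1024 bits (radius 2) as the classifier input representation, and ECFP6
folded to 4096 bits (radius 3) for nearest-neighbor similarity analysis,
where the longer, less collision-prone vectors give a sharper similarity
scale.  Stereochemistry is not encoded by these fingerprints, which is why
deduplication upstream works on stereo-stripped InChIs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "FingerprintConfig",
    "FingerprintMatrix",
    "MODELING_FP",
    "SIMILARITY_FP",
    "fingerprint",
    "tanimoto",
    "tanimoto_matrix",
]


@dataclass(frozen=True)
class FingerprintConfig:
    """Morgan/ECFP configuration: ``radius`` and folded length ``n_bits``."""

    radius: int = 2
    n_bits: int = 1024

    def __post_init__(self) -> None:
        if self.radius not in (2, 3):
            raise ValueError(f"radius must be 2 or 3, got {self.radius}")
        if self.n_bits < 1 or (self.n_bits & (self.n_bits - 1)) != 0:
            raise ValueError(f"n_bits must be a power of two, got {self.n_bits}")


#: ECFP4/1024 — classifier input representation.
MODELING_FP = FingerprintConfig(radius=2, n_bits=1024)
#: ECFP6/4096 — applicability-domain similarity analysis.
SIMILARITY_FP = FingerprintConfig(radius=3, n_bits=4096)


@dataclass
class FingerprintMatrix:
    """Binary fingerprint matrix with row-aligned compound keys.

    ``errors`` maps key -> reason for structures that could not be
    fingerprinted; their rows are all-zero placeholders so downstream
    alignment is preserved.
    """

    keys: list[str]
    bits: np.ndarray
    config: FingerprintConfig
    errors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.keys):
            raise ValueError("bits must be (len(keys), n_bits)")
        if self.bits.size and self.bits.shape[1] != self.config.n_bits:
            raise ValueError("bit length does not match config.n_bits")

    def __len__(self) -> int:
        return len(self.keys)

    def row(self, key: str) -> np.ndarray:
        return self.bits[self.keys.index(key)]

    def save(self, path: str | Path) -> None:
        """Persist as compressed sparse columns + JSON header naming the config."""
        from scipy import sparse

        path = Path(path)
        sparse.save_npz(path.with_suffix(".npz"), sparse.csc_matrix(self.bits))
        header = {
            "keys": self.keys,
            "config": {"radius": self.config.radius, "n_bits": self.config.n_bits},
            "errors": self.errors,
        }
        path.with_suffix(".json").write_text(json.dumps(header))

    @classmethod
    def load(cls, path: str | Path) -> "FingerprintMatrix":
        from scipy import sparse

        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        bits = sparse.load_npz(path.with_suffix(".npz")).toarray().astype(np.uint8)
        return cls(
            keys=header["keys"],
            bits=bits,
            config=FingerprintConfig(**header["config"]),
            errors=header.get("errors", {}),
        )


def fingerprint(
    structures: list[str],
    config: FingerprintConfig = MODELING_FP,
    keys: list[str] | None = None,
) -> FingerprintMatrix:
    """Compute folded Morgan fingerprints for a list of SMILES.

    Bit vectors are canonicalization-invariant: any SMILES of the same
    molecule yields the same row.  Unparseable entries are recorded in
    ``errors`` (all-zero row) and do not abort the batch.
    """
    if keys is None:
        keys = list(structures)
    if len(keys) != len(structures):
        raise ValueError("keys and structures must be parallel")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=config.radius, fpSize=config.n_bits)
    bits = np.zeros((len(structures), config.n_bits), dtype=np.uint8)
    errors: dict[str, str] = {}
    for i, smi in enumerate(structures):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            errors[keys[i]] = "parse_failure"
            continue
        fp = gen.GetFingerprint(mol)
        bits[i, list(fp.GetOnBits())] = 1
    return FingerprintMatrix(keys=keys, bits=bits, config=config, errors=errors)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two binary vectors.

    ``|a AND b| / |a OR b|``.  The degenerate all-zero/all-zero pair is
    defined as 1.0 (identical objects); all-zero versus non-zero is 0.0,
    keeping the function total.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def tanimoto_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarities between the rows of two bit matrices.

    Exact (no approximation): similarities are computed from integer
    intersection and union counts via one matrix product.  Degenerate
    all-zero rows follow the same convention as :func:`tanimoto`.
    """
    a = np.asarray(a, dtype=np.float32)
    b = np.asarray(b, dtype=np.float32)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("inputs must be 2D with equal bit length")
    # float32 matmul is exact here (integer counts well below 2**24);
    # the division is done in float64 so results match the scalar path bitwise
    inter = (a @ b.T).astype(np.float64)
    counts_a = a.sum(axis=1, keepdims=True).astype(np.float64)
    counts_b = b.sum(axis=1, keepdims=True).astype(np.float64)
    union = counts_a + counts_b.T - inter
    sim = np.divide(inter, union, out=np.zeros_like(inter), where=union > 0)
    # all-zero vs all-zero -> identical by convention
    both_empty = (counts_a == 0) & (counts_b.T == 0)
    sim[both_empty] = 1.0
    return sim
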