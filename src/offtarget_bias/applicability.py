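"""Applicability-domain analysis via nearest-training-neighbor similarity.

For every test or screening compound, the maximum Tanimoto similarity to
any training compound (ECFP radius 3, 4096 bits by convention) is a proxy
for how far the compound sits from the model's applicability domain.  Two
uses: (i) leakage detection — similarities at or near 1.0 mean a test
compound is effectively present in the training set (stereoisomers
included, since the fingerprints ignore stereochemistry); (ii) relating
prediction correctness to distance from the training data, which for these
models shows only a weak tendency and is therefore reported, not asserted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from offtarget_bias.featurize import tanimoto_matrix

__all__ = ["SimilarityProfile", "LeakageReport", "nearest_train_similarity", "leakage_check", "plot_similarity_histogram"]


@dataclass
class SimilarityProfile:
    """Per-compound nearest-training similarities, with correctness if known."""

    rows: pd.DataFrame  # id, nearest_train_similarity, prediction_correct (bool or NA)

    def histogram(self, bin_width: float = 0.05) -> pd.DataFrame:
        """Binned counts split by correctness (NA rows counted separately)."""
        edges = np.arange(0.0, 1.0 + bin_width, bin_width)
        sims = self.rows["nearest_train_similarity"].to_numpy()
        correct = self.rows["prediction_correct"]
        out = {"bin_left": edges[:-1], "bin_right": edges[1:]}
        for name, mask in (
            ("correct", correct == True),  # noqa: E712 — pandas NA-safe comparison
            ("incorrect", correct == False),  # noqa: E712
            ("unlabeled", correct.isna()),
        ):
            counts, _ = np.histogram(sims[mask.to_numpy()], bins=edges)
            out[name] = counts
        return pd.DataFrame(out)


@dataclass
class LeakageReport:
    """Compounds whose nearest-training similarity reaches the threshold."""

    threshold: float
    flagged: pd.DataFrame

    @property
    def passed(self) -> bool:
        return len(self.flagged) == 0


def nearest_train_similarity(
    test_fps: np.ndarray,
    train_fps: np.ndarray,
    keys: Sequence[str] | None = None,
    prediction_correct: Sequence[bool] | None = None,
) -> SimilarityProfile:
    """Maximum Tanimoto similarity of each test compound over the train set.

    Brute-force exact over all train compounds (no approximate nearest
    neighbors) — monotone in the training set: adding a training compound
    can only increase a test compound's nearest similarity.
    """
    test_fps = np.asarray(test_fps)
    train_fps = np.asarray(train_fps)
    if train_fps.size == 0 or train_fps.shape[0] == 0:
        raise ValueError("training set must be non-empty")
    sims = tanimoto_matrix(test_fps, train_fps).max(axis=1)
    n = len(sims)
    rows = pd.DataFrame(
        {
            "id": list(keys) if keys is not None else [f"cmpd_{i}" for i in range(n)],
            "nearest_train_similarity": sims,
            "prediction_correct": pd.array(
                prediction_correct if prediction_correct is not None else [pd.NA] * n,
                dtype="boolean",
            ),
        }
    )
    return SimilarityProfile(rows=rows)


def leakage_check(profile: SimilarityProfile, threshold: float = 0.99) -> LeakageReport:
    """Flag compounds at or above the similarity threshold (default 0.99).

    An empty flag list is a pass: no test compound is (nearly) identical
    to a training compound.
    """
    flagged = profile.rows[profile.rows["nearest_train_similarity"] >= threshold]
    return LeakageReport(threshold=threshold, flagged=flagged.reset_index(drop=True))


def plot_similarity_histogram(
    profile: SimilarityProfile, path: str | Path, bin_width: float = 0.05
) -> Path:
    """Histogram of nearest-train similarities, red correct / blue incorrect."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = profile.histogram(bin_width)
    centers = (hist["bin_left"] + hist["bin_right"]) / 2
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(centers, hist["incorrect"], width=bin_width * 0.9, color="tab:blue", label="incorrect", alpha=0.7)
    ax.bar(
        centers,
        hist["correct"],
        width=bin_width * 0.9,
        bottom=hist["incorrect"],
        color="tab:red",
        label="correct",
        alpha=0.7,
    )
    if hist["unlabeled"].sum():
        ax.bar(
            centers,
            hist["unlabeled"],
            width=bin_width * 0.9,
            bottom=hist["incorrect"] + hist["correct"],
            color="0.6",
            label="unlabeled",
            alpha=0.7,
        )
    ax.set_xlabel("nearest-training-compound Tanimoto similarity")
    ax.set_ylabel("compounds")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
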