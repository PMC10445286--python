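"""Two-model consensus scoring for off-target risk flagging.

Models trained on active-rich public data and inactive-rich proprietary
data carry opposite prediction biases; requiring *both* to call a
screening compound active cancels much of either bias, so a consensus
active is treated as a warning flag for potential off-target risk.  The
report keeps all three outcomes explicit — consensus active (both call 1),
consensus inactive (both call 0), and discordant — rather than folding
disagreements into the inactive bucket.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ConsensusReport", "consensus_score"]


@dataclass
class ConsensusReport:
    """Per-compound consensus calls with the marginal and joint counts."""

    per_compound: pd.DataFrame  # id, p_public, p_private, call_public, call_private, consensus_flag
    n_active_public: int
    n_active_private: int
    consensus_active_count: int
    consensus_inactive_count: int
    discordant_count: int

    @property
    def n_compounds(self) -> int:
        return len(self.per_compound)

    def summary(self) -> dict:
        """Counts table shaped like a screening-prediction summary."""
        return {
            "public": {
                "actives": self.n_active_public,
                "inactives": self.n_compounds - self.n_active_public,
            },
            "private": {
                "actives": self.n_active_private,
                "inactives": self.n_compounds - self.n_active_private,
            },
            "consensus": {
                "actives": self.consensus_active_count,
                "inactives": self.consensus_inactive_count,
                "discordant": self.discordant_count,
            },
        }


def consensus_score(
    calls_public: Sequence[int],
    calls_private: Sequence[int],
    keys: Sequence[str] | None = None,
    proba_public: Sequence[float] | None = None,
    proba_private: Sequence[float] | None = None,
    keys_private: Sequence[str] | None = None,
) -> ConsensusReport:
    """Combine two models' binary calls into per-compound consensus flags.

    A compound is consensus *active* iff both calls are 1, consensus
    *inactive* iff both are 0, and *discordant* otherwise; consequently the
    consensus active count can never exceed either model's active count,
    and the three counts partition the compound set.  If ``keys_private``
    is given it must equal ``keys``; a mismatch raises with the offending
    keys listed (predictions from differently ordered runs must be aligned
    by the caller).
    """
    a = np.asarray(calls_public, dtype=int)
    b = np.asarray(calls_private, dtype=int)
    if a.shape != b.shape:
        raise ValueError(f"prediction lengths differ: {a.shape} vs {b.shape}")
    if keys is None:
        keys = [f"cmpd_{i}" for i in range(len(a))]
    keys = list(keys)
    if len(keys) != len(a):
        raise ValueError("keys must be parallel to the calls")
    if keys_private is not None and list(keys_private) != keys:
        missing = sorted(set(keys) ^ set(keys_private))
        raise ValueError(f"compound keys do not align; mismatched keys: {missing[:10]}")
    if not set(np.unique(a)) <= {0, 1} or not set(np.unique(b)) <= {0, 1}:
        raise ValueError("calls must be binary 0/1")
    flag = np.where(a & b, "active", np.where((a | b) == 0, "inactive", "discordant"))
    frame = pd.DataFrame(
        {
            "id": keys,
            "p_public": np.nan if proba_public is None else np.asarray(proba_public, dtype=float),
            "p_private": np.nan if proba_private is None else np.asarray(proba_private, dtype=float),
            "call_public": a,
            "call_private": b,
            "consensus_flag": flag,
        }
    )
    return ConsensusReport(
        per_compound=frame,
        n_active_public=int(a.sum()),
        n_active_private=int(b.sum()),
        consensus_active_count=int((a & b).sum()),
        consensus_inactive_count=int(((a | b) == 0).sum()),
        discordant_count=int((a ^ b).sum()),
    )
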