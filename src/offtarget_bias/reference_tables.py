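"""Published benchmark tables for a 41-target ChEMBL off-target panel.

These constants are the reference inputs of the analysis: per-target
active/inactive counts for a panel of safety-pharmacology off-targets at
pChEMBL activity thresholds 5 and 6, the published confusion matrices of a
public-data model and an industry-data model evaluated on the same
prospective test sets, the statistics tables derived from them, and the
screening-set consensus counts.  Counts are data, not code; they let the
target-selection filter, the metric formulas, and the consensus accounting
be exercised against their published values without any database access.

``None`` marks cells the source leaves blank (one target has no inactive
count at either threshold).
"""

from __future__ import annotations

from offtarget_bias.metrics import ConfusionMatrix

__all__ = [
    "TARGET_PANEL_COUNTS",
    "TOP_TARGETS_BY_PCT_INACTIVE",
    "SELECTED_TARGETS",
    "PUBLIC_MODEL_TEST_CONFUSIONS",
    "INDUSTRY_MODEL_TEST_CONFUSIONS",
    "PUBLIC_MODEL_TEST_METRICS",
    "INDUSTRY_MODEL_TEST_METRICS",
    "SCREENING_CONSENSUS_COUNTS",
]

# (target name, TH5 inactive, TH5 active, TH5 % inactive as printed,
#  TH6 inactive, TH6 active, TH6 % inactive as printed)
TARGET_PANEL_COUNTS: list[tuple[str, int | None, int, float | None, int | None, int, float | None]] = [
    ("Dopamine D2 receptor", 205, 6636, 3.00, 1505, 5336, 22.00),
    ("Acetylcholinesterase", 951, 3797, 20.03, 2356, 2392, 49.62),
    ("Serotonin 1a (5-HT1a) receptor", 82, 4267, 1.89, 553, 3796, 12.72),
    ("Serotonin 2a (5-HT2a) receptor", 47, 4273, 1.09, 707, 3613, 16.37),
    ("Mu opioid receptor", 125, 4157, 2.92, 945, 3337, 22.07),
    ("Adenosine A1 receptor", 145, 4025, 3.48, 1178, 2992, 28.25),
    ("Serotonin transporter", 86, 3949, 2.13, 783, 3252, 19.41),
    ("Adenosine A3 receptor", 178, 3805, 4.47, 925, 3058, 23.22),
    ("Histamine H3 receptor", 84, 3803, 2.16, 361, 3526, 9.29),
    ("Cannabinoid CB1 receptor", 91, 3776, 2.35, 958, 2909, 24.77),
    ("Kappa opioid receptor", 133, 3727, 3.45, 942, 2918, 24.40),
    ("Cyclooxygenase-2", 573, 2946, 16.28, 1646, 1873, 46.77),
    ("Glycogen synthase kinase-3 beta", 292, 3028, 8.80, 1146, 2174, 34.52),
    ("Estrogen receptor alpha", 326, 2246, 12.67, 826, 1746, 32.12),
    ("Matrix metalloproteinase 9", 302, 2169, 12.22, 679, 1792, 27.48),
    ("Monoamine oxidase A", 987, 1384, 41.63, 1800, 571, 75.92),
    # % printed at three decimals in the source for this row
    ("Tyrosine-protein kinase ABL", 159, 2094, 7.057, 475, 1778, 21.08),
    ("Glucocorticoid receptor", 28, 2211, 1.25, 244, 1995, 10.90),
    ("Androgen Receptor", 83, 1969, 4.04, 580, 1472, 28.27),
    ("Cyclin-dependent kinase 2", 180, 1818, 9.01, 696, 1302, 34.83),
    ("Peroxisome proliferator-activated receptor gamma", 96, 1600, 5.66, 562, 1134, 33.14),
    ("Muscarinic acetylcholine receptor M1", 129, 1528, 7.79, 579, 1078, 34.94),
    ("Muscarinic acetylcholine receptor M2", 120, 1489, 7.46, 478, 1131, 29.71),
    ("Serotonin 2b (5-HT2b) receptor", 13, 1391, 0.93, 307, 1097, 21.87),
    ("Histamine H1 receptor", 83, 1299, 6.01, 389, 993, 28.15),
    ("Alpha-1a adrenergic receptor", 8, 1354, 0.59, 141, 1221, 10.35),
    ("Sodium/glucose cotransporter 2", 40, 1162, 3.33, 129, 1073, 10.73),
    ("Phosphodiesterase 4D", 189, 891, 17.50, 470, 610, 43.52),
    ("Dopamine D1 receptor", 31, 1041, 2.89, 294, 778, 27.43),
    ("Beta-2 adrenergic receptor", 87, 844, 9.34, 323, 608, 34.69),
    ("Alpha-2a adrenergic receptor", 41, 799, 4.88, 264, 576, 31.43),
    ("Beta-1 adrenergic receptor", 96, 711, 11.90, 385, 422, 47.71),
    ("Glycogen synthase kinase-3 alpha", 55, 742, 6.90, 304, 493, 38.14),
    ("Histamine H2 receptor", 118, 322, 26.82, 314, 126, 71.36),
    ("Cholecystokinin A receptor", 10, 389, 2.51, 86, 313, 21.55),
    ("Tyrosine-protein kinase ZAP-70", 48, 202, 19.20, 130, 120, 52.00),
    ("Voltage-gated L-type calcium channel alpha-1C subunit", 48, 112, 30.00, 111, 49, 69.38),
    ("Phosphodiesterase 3B", 24, 132, 15.38, 73, 83, 46.79),
    ("Neuronal acetylcholine receptor protein alpha-4 subunit", None, 81, None, None, 81, None),
    ("Angiotensin-converting enzyme 2", 2, 56, 3.45, 6, 52, 10.34),
    ("GABA receptor alpha-1 subunit", 1, 45, 2.17, 2, 44, 4.35),
]

# (target, inactive, active, sum, % inactive) — the seven panel targets with
# >15% inactives at threshold 5, sorted as published.
TOP_TARGETS_BY_PCT_INACTIVE: list[tuple[str, int, int, int, float]] = [
    ("Acetylcholinesterase", 951, 3797, 4748, 20.03),
    ("Cyclooxygenase-2", 573, 2946, 3519, 16.28),
    ("Monoamine oxidase A", 987, 1384, 2371, 41.63),
    ("Phosphodiesterase 4D", 189, 891, 1080, 17.50),
    ("Histamine H2 receptor", 118, 322, 440, 26.82),
    ("Tyrosine-protein kinase ZAP-70", 48, 202, 250, 19.20),
    ("Phosphodiesterase 3B", 24, 132, 156, 15.38),
]

# Targets passing "total > 1000 and >= 15% inactive" at threshold 5.
SELECTED_TARGETS = frozenset(
    {"Acetylcholinesterase", "Cyclooxygenase-2", "Monoamine oxidase A", "Phosphodiesterase 4D"}
)

# Confusion matrices on the prospective (time-series) test sets.
PUBLIC_MODEL_TEST_CONFUSIONS: dict[str, ConfusionMatrix] = {
    "AChE": ConfusionMatrix(tp=81, fp=30, tn=15, fn=22),
    "MAO-A": ConfusionMatrix(tp=11, fp=3, tn=29, fn=24),
    "COX-2": ConfusionMatrix(tp=47, fp=1, tn=5, fn=12),
    "PDE4D": ConfusionMatrix(tp=114, fp=16, tn=6, fn=1),
}

INDUSTRY_MODEL_TEST_CONFUSIONS: dict[str, ConfusionMatrix] = {
    "AChE": ConfusionMatrix(tp=0, fp=0, tn=45, fn=103),
    "MAO-A": ConfusionMatrix(tp=0, fp=0, tn=32, fn=35),
    "COX-2": ConfusionMatrix(tp=1, fp=0, tn=6, fn=58),
    "PDE4D": ConfusionMatrix(tp=0, fp=0, tn=22, fn=115),
}

# Published statistics on the same test sets (2-decimal; None marks the
# dash used for zero-denominator cells).  Column order: BA, ACC, Recall,
# PRC, Sen, Spe, F-score, MCC.  (The published AUC column is omitted: it
# is not derivable from a confusion matrix.)
_COLS = ("balanced_accuracy", "accuracy", "recall", "precision", "sensitivity", "specificity", "f_measure", "mcc")

PUBLIC_MODEL_TEST_METRICS: dict[str, dict[str, float | None]] = {
    "AChE": dict(zip(_COLS, (0.56, 0.65, 0.79, 0.73, 0.79, 0.33, 0.76, 0.13))),
    "MAO-A": dict(zip(_COLS, (0.61, 0.60, 0.31, 0.79, 0.31, 0.91, 0.45, 0.27))),
    "COX-2": dict(zip(_COLS, (0.82, 0.80, 0.80, 0.98, 0.80, 0.83, 0.88, 0.41))),
    "PDE4D": dict(zip(_COLS, (0.63, 0.88, 0.99, 0.88, 0.99, 0.27, 0.93, 0.44))),
}

INDUSTRY_MODEL_TEST_METRICS: dict[str, dict[str, float | None]] = {
    "AChE": dict(zip(_COLS, (0.50, 0.30, 0.0, None, 0.0, 1.0, None, None))),
    "MAO-A": dict(zip(_COLS, (0.50, 0.48, 0.0, None, 0.0, 1.0, None, None))),
    "COX-2": dict(zip(_COLS, (0.51, 0.11, 0.02, 1.0, 0.02, 1.0, 0.03, 0.04))),
    "PDE4D": dict(zip(_COLS, (0.50, 0.16, 0.0, None, 0.0, 1.0, None, None))),
}

# Screening-set predictions of the threshold-6 public models and the
# industry models on ~10k drug-like compounds, with the both-models-agree
# consensus counts: {target: (pub_act, pub_inact, ind_act, ind_inact,
# consensus_act, consensus_inact)}.
SCREENING_CONSENSUS_COUNTS: dict[str, tuple[int, int, int, int, int, int]] = {
    "AChE": (1855, 8251, 82, 10024, 29, 8198),
    "MAO-A": (416, 9690, 13, 10093, 0, 9677),
    "COX-2": (2790, 7316, 603, 9503, 143, 6856),
    "PDE4D": (3020, 7086, 0, 10106, 0, 7089),
}
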