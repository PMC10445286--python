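"""End-to-end study orchestration on synthetic two-domain data.

The study design: generate a public-style domain (active-majority) and a
proprietary-style domain (inactive-majority) from one shared latent
activity rule, curate both, train one imbalance-weighted classifier per
domain, and then

* evaluate both models on a common balanced, train-disjoint test set —
  the public-domain model should show the higher false-positive rate and
  the proprietary-domain model the higher false-negative rate (the
  opposing-bias pattern);
* apply both models to an unlabeled screening set and flag consensus
  actives;
* embed the screening set with the hybrid structure/coherence distance
  and score the embedding against a shuffled-coordinate null;
* profile nearest-training-neighbor similarities for leakage and
  applicability-domain context.

:func:`run_study` executes all stages into a run directory with a manifest
(config, seeds, per-file checksums); the ``run_*_experiment`` functions are
the reusable building blocks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from offtarget_bias import synthetic_data as synth
from offtarget_bias.applicability import leakage_check, nearest_train_similarity, plot_similarity_histogram
from offtarget_bias.consensus import ConsensusReport, consensus_score
from offtarget_bias.curation import LabeledDataset, build_labeled_dataset, exclude_seen, standardize_all
from offtarget_bias.featurize import MODELING_FP, SIMILARITY_FP, fingerprint
from offtarget_bias.metrics import MetricReport, UNDEFINED, compute_metrics, confusion_from_calls
from offtarget_bias.model import ClassifierArtifact, TrainConfig, predict, train_classifier
from offtarget_bias.prediction_space import (
    EmbeddingQuality,
    EmbeddingResult,
    HybridDistanceConfig,
    embed,
    evaluate_embedding,
    plot_embedding,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ConfigError",
    "StageError",
    "BiasExperimentResult",
    "run_bias_experiment",
    "run_prediction_space_experiment",
    "run_study",
]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause!r}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Serializable study configuration; every stage seed derives from ``seed``."""

    seed: int
    n_per_domain: int = 2000
    n_test: int = 600
    n_screening: int = 600
    threshold: float = 5.0
    w: float = 0.05
    hidden_units: int = 256
    batch_size: int = 128
    max_epochs: int = 150
    label_noise: float = 0.02

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is required")
        if self.n_per_domain < 50 or self.n_test < 50 or self.n_screening < 50:
            raise ConfigError("dataset sizes must be at least 50")
        if not 0.0 <= self.w <= 1.0:
            raise ConfigError("w must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if "seed" not in data:
            raise ConfigError("config missing required field 'seed'")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def _sub_seed(seed: int, label: str) -> int:
    digest = hashlib.blake2b(f"{seed}|{label}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _curate(domain: synth.GeneratedDomain, threshold: float) -> LabeledDataset:
    kept, _removed = standardize_all(domain.records)
    dataset, _log = build_labeled_dataset(kept, threshold, domain.spec.name)
    return dataset


@dataclass
class BiasExperimentResult:
    """Two trained domain models with their common-test-set error profile."""

    public_dataset: LabeledDataset
    private_dataset: LabeledDataset
    public_artifact: ClassifierArtifact
    private_artifact: ClassifierArtifact
    test_structures: list[str]
    test_labels: np.ndarray
    public_report: MetricReport
    private_report: MetricReport
    public_fpr: float
    public_fnr: float
    private_fpr: float
    private_fnr: float
    rule: synth.LatentActivityRule


def _error_rates(y_true: np.ndarray, calls: np.ndarray) -> tuple[float, float]:
    cm = confusion_from_calls(y_true, calls)
    fpr = cm.fp / (cm.fp + cm.tn) if (cm.fp + cm.tn) else float("nan")
    fnr = cm.fn / (cm.fn + cm.tp) if (cm.fn + cm.tp) else float("nan")
    return fpr, fnr


def run_bias_experiment(
    seed: int,
    n_per_domain: int = 2000,
    n_test: int = 600,
    threshold: float = 5.0,
    train_config: TrainConfig | None = None,
    label_noise: float = 0.02,
) -> BiasExperimentResult:
    """Train one model per domain and compare error rates on a balanced test.

    Both domains and the balanced (50/50) test domain are drawn from the
    same latent rule; test compounds already present in either training
    set are excluded (stereo-agnostic match), so the comparison is
    prospective.  Returns per-model metric reports and false-positive /
    false-negative rates.
    """
    rule = synth.default_rule(noise_seed=_sub_seed(seed, "rule"))
    pub_spec = dataclasses.replace(
        synth.public_domain_spec(n_per_domain, seed=_sub_seed(seed, "public")),
        label_noise=label_noise,
    )
    priv_spec = dataclasses.replace(
        synth.proprietary_domain_spec(n_per_domain, seed=_sub_seed(seed, "private")),
        label_noise=label_noise,
    )
    test_spec = synth.DomainSpec(
        name="balanced_test",
        n_compounds=n_test,
        active_fraction=0.5,
        label_noise=label_noise,
        seed=_sub_seed(seed, "test"),
    )
    pub_ds = _curate(synth.generate_domain(pub_spec, rule), threshold)
    priv_ds = _curate(synth.generate_domain(priv_spec, rule), threshold)

    test_domain = synth.generate_domain(test_spec, rule)
    test_kept, _ = standardize_all(test_domain.records)
    test_kept, _n = exclude_seen(test_kept, [pub_ds, priv_ds])
    test_ds, _ = build_labeled_dataset(test_kept, threshold, "balanced_test")

    base = train_config or TrainConfig(max_epochs=150)
    fp_pub = fingerprint(pub_ds.structures, MODELING_FP).bits
    fp_priv = fingerprint(priv_ds.structures, MODELING_FP).bits
    fp_test = fingerprint(test_ds.structures, MODELING_FP).bits
    y_test = np.asarray(test_ds.labels)

    pub_art = train_classifier(
        fp_pub, np.asarray(pub_ds.labels), dataclasses.replace(base, seed=_sub_seed(seed, "fit_pub"))
    )
    priv_art = train_classifier(
        fp_priv, np.asarray(priv_ds.labels), dataclasses.replace(base, seed=_sub_seed(seed, "fit_priv"))
    )

    _, pub_calls = predict(pub_art, fp_test)
    _, priv_calls = predict(priv_art, fp_test)
    pub_fpr, pub_fnr = _error_rates(y_test, pub_calls)
    priv_fpr, priv_fnr = _error_rates(y_test, priv_calls)
    return BiasExperimentResult(
        public_dataset=pub_ds,
        private_dataset=priv_ds,
        public_artifact=pub_art,
        private_artifact=priv_art,
        test_structures=test_ds.structures,
        test_labels=y_test,
        public_report=compute_metrics(confusion_from_calls(y_test, pub_calls)),
        private_report=compute_metrics(confusion_from_calls(y_test, priv_calls)),
        public_fpr=pub_fpr,
        public_fnr=pub_fnr,
        private_fpr=priv_fpr,
        private_fnr=priv_fnr,
        rule=rule,
    )


def run_prediction_space_experiment(
    bias: BiasExperimentResult,
    seed: int,
    n_screening: int = 600,
    w: float = 0.05,
) -> tuple[ConsensusReport, EmbeddingResult, EmbeddingQuality]:
    """Score a screening set with both models, flag consensus, embed, grade.

    The screening set is unlabeled; both models' probabilities feed the
    consensus flags and (through the hybrid metric, weight ``w``) the UMAP
    embedding, whose quality is the coordinates→class AUC versus its
    shuffled-coordinate null.
    """
    structures = synth.generate_screening_set(n_screening, bias.rule, seed=_sub_seed(seed, "screen"))
    fps = fingerprint(structures, MODELING_FP).bits
    p_pub, calls_pub = predict(bias.public_artifact, fps)
    p_priv, calls_priv = predict(bias.private_artifact, fps)
    report = consensus_score(calls_pub, calls_priv, keys=structures, proba_public=p_pub, proba_private=p_priv)
    result = embed(
        fps,
        p_pub,
        p_priv,
        HybridDistanceConfig(w=w),
        seed=_sub_seed(seed, "umap"),
        keys=structures,
    )
    quality = evaluate_embedding(result, p_pub, seed=_sub_seed(seed, "xgb"))
    return report, result, quality


def _report_to_jsonable(report: MetricReport) -> dict:
    return {k: (None if v is UNDEFINED else v) for k, v in report.as_dict().items()}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full study into ``out_dir``; returns the run directory.

    Stages: generate → curate → train → evaluate → consensus → embed →
    applicability.  Any stage failure raises :class:`StageError` naming the
    stage.  The manifest links every written file to the config and seeds
    via SHA-256 checksums, so a rerun with the same config is verifiable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_json(name: str, payload: Any) -> None:
        path = out / name
        path.write_text(json.dumps(payload, indent=1, default=float))
        written.append(path)

    def _write_csv(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)

    stage = "generate+curate+train+evaluate"
    try:
        bias = run_bias_experiment(
            seed=config.seed,
            n_per_domain=config.n_per_domain,
            n_test=config.n_test,
            threshold=config.threshold,
            train_config=TrainConfig(
                hidden_units=config.hidden_units,
                batch_size=config.batch_size,
                max_epochs=config.max_epochs,
            ),
            label_noise=config.label_noise,
        )
        _write_json(
            "bias_evaluation.json",
            {
                "public_model": _report_to_jsonable(bias.public_report),
                "private_model": _report_to_jsonable(bias.private_report),
                "public_fpr": bias.public_fpr,
                "public_fnr": bias.public_fnr,
                "private_fpr": bias.private_fpr,
                "private_fnr": bias.private_fnr,
                "n_train_public": len(bias.public_dataset),
                "n_train_private": len(bias.private_dataset),
                "n_test": int(len(bias.test_labels)),
            },
        )
        _write_csv("train_public.csv", bias.public_dataset.to_frame())
        _write_csv("train_private.csv", bias.private_dataset.to_frame())
    except Exception as exc:  # noqa: BLE001 — abort with the stage name
        raise StageError(stage, exc) from exc

    stage = "consensus+embed"
    try:
        consensus, embedding, quality = run_prediction_space_experiment(
            bias, seed=config.seed, n_screening=config.n_screening, w=config.w
        )
        _write_json("consensus_summary.json", consensus.summary())
        _write_csv("consensus_per_compound.csv", consensus.per_compound)
        _write_csv("embedding_coordinates.csv", embedding.to_frame())
        _write_json(
            "embedding_quality.json",
            {
                "auc_real": quality.auc_real,
                "auc_null": quality.auc_null,
                "class_threshold": quality.class_threshold,
            },
        )
        written.append(plot_embedding(embedding, out / "embedding_public.png", "p_public"))
        written.append(plot_embedding(embedding, out / "embedding_private.png", "p_private"))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "applicability"
    try:
        train_fp = fingerprint(bias.public_dataset.structures, SIMILARITY_FP).bits
        test_fp = fingerprint(bias.test_structures, SIMILARITY_FP).bits
        _, pub_calls = predict(
            bias.public_artifact, fingerprint(bias.test_structures, MODELING_FP).bits
        )
        profile = nearest_train_similarity(
            test_fp,
            train_fp,
            keys=bias.test_structures,
            prediction_correct=list(pub_calls == bias.test_labels),
        )
        leak = leakage_check(profile)
        _write_csv("applicability_profile.csv", profile.rows)
        _write_json(
            "leakage_report.json",
            {"threshold": leak.threshold, "passed": leak.passed, "n_flagged": len(leak.flagged)},
        )
        written.append(plot_similarity_histogram(profile, out / "applicability_hist.png"))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    manifest = {
        "config": config.to_dict(),
        "files": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
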