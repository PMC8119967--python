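"""Orchestration of the three analysis arms and the final stacking ensemble.

The pipeline turns a stacked subject-day mobility table plus binary group
labels into one out-of-fold Group-1 probability per subject:

* **Arm 1** — nested LOSO day-level DART models on the raw (DMA, MDR) rows
  give 3–7 out-of-fold probabilities per subject; their 15 distributional
  statistics feed the five classifier families under repeated k-fold CV.
* **Arm 2** — the 14-column wide day matrix feeds the same five families.
* **Arm 3** — the 39 engineered features of the stacked series feed them.
* **Ensemble** — the 15 resulting probability columns (3 arms x 5 learners)
  are stacked by a DART gradient-boosting meta-model under repeated k-fold
  CV; its out-of-fold probabilities are the evaluation surface.

Every stage is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import features as fe
from .evaluation import PerformanceReport, evaluate
from .learners import (
    LEARNER_KINDS,
    LearnerSpec,
    ResamplingPlan,
    cross_validated_probabilities,
    default_grid,
    derive_seed,
    fast_grid,
    nested_loso_probabilities,
)

ARM_IDS = (1, 2, 3)


@dataclass
class PipelineConfig:
    """Seeds, grids, and resampling settings for a full run."""

    seed: int = 0
    k: int = 10
    repeats: int = 5
    inner_k: int = 3
    loso_inner_k: int = 5
    smote_k: int = 5
    smote_ratio: float = 1.0
    grids: dict = field(default_factory=dict)  # kind -> grid; empty = default_grid
    fast: bool = False

    @classmethod
    def fast_config(cls, seed: int = 0, **kwargs) -> "PipelineConfig":
        """Minimal grids for full-pipeline runs at desk scale."""
        return cls(seed=seed, grids={k: fast_grid(k) for k in LEARNER_KINDS}, fast=True, **kwargs)

    def spec(self, kind: str, *seed_parts) -> LearnerSpec:
        grid = self.grids.get(kind) or default_grid(kind)
        return LearnerSpec(kind=kind, grid=grid, seed=derive_seed(self.seed, kind, *seed_parts))

    def plan(self, *seed_parts) -> ResamplingPlan:
        return ResamplingPlan(
            scheme="repeated_kfold", k=self.k, repeats=self.repeats,
            seed=derive_seed(self.seed, "plan", *seed_parts),
        )


@dataclass
class ArmOutput:
    """Five out-of-fold probability tables (one per learner family) for one arm."""

    arm_id: int
    probabilities: dict  # learner kind -> DataFrame(subject_id, prob_group1, arm, learner)
    features: pd.DataFrame  # the feature matrix the learners consumed
    day_probabilities: pd.DataFrame | None = None  # Arm 1 only

    def matrix(self) -> pd.DataFrame:
        cols = {}
        for kind in LEARNER_KINDS:
            df = self.probabilities[kind]
            cols[f"arm{self.arm_id}_{kind}"] = df.set_index("subject_id")["prob_group1"]
        return pd.DataFrame(cols)


def _run_five_learners(
    X: pd.DataFrame, labels: pd.DataFrame, config: PipelineConfig, arm_id: int
) -> dict:
    label_series = labels.set_index("subject_id")["group"]
    out = {}
    for kind in LEARNER_KINDS:
        out[kind] = cross_validated_probabilities(
            config.spec(kind, f"arm{arm_id}"),
            X,
            label_series,
            config.plan(f"arm{arm_id}"),
            smote_k=config.smote_k,
            smote_ratio=config.smote_ratio,
            inner_k=config.inner_k,
            arm=f"arm{arm_id}",
        )
    return out


def run_arm1(stacked: pd.DataFrame, labels: pd.DataFrame, config: PipelineConfig) -> ArmOutput:
    """Nested LOSO day-level DART probabilities -> 15 distributional features -> five learners."""
    day_probs = nested_loso_probabilities(
        stacked,
        labels,
        config.spec("dart_gradient_boosting", "loso"),
        inner_k=config.loso_inner_k,
        smote_k=config.smote_k,
        smote_ratio=config.smote_ratio,
    )
    X = fe.engineer_prediction_features(day_probs)
    X = X.loc[labels["subject_id"]]
    return ArmOutput(1, _run_five_learners(X, labels, config, 1), X, day_probabilities=day_probs)


def run_arm2(stacked: pd.DataFrame, labels: pd.DataFrame, config: PipelineConfig) -> ArmOutput:
    """Wide-format 14 day-based variables -> five learners."""
    X = fe.to_wide(stacked).loc[labels["subject_id"]]
    return ArmOutput(2, _run_five_learners(X, labels, config, 2), X)


def run_arm3(stacked: pd.DataFrame, labels: pd.DataFrame, config: PipelineConfig) -> ArmOutput:
    """39 engineered features of the stacked series -> five learners."""
    missing = set(stacked["subject_id"]) - set(labels["subject_id"])
    if missing:
        raise ValueError(f"subjects absent from label table: {sorted(missing)[:5]}")
    X = fe.engineer_arm3(stacked).loc[labels["subject_id"]]
    return ArmOutput(3, _run_five_learners(X, labels, config, 3), X)


def build_ensemble_matrix(arm_outputs: list[ArmOutput]) -> pd.DataFrame:
    """Assemble the 15-column meta-feature matrix from three complete arms."""
    mats = [a.matrix() for a in sorted(arm_outputs, key=lambda a: a.arm_id)]
    subjects = mats[0].index
    for m in mats[1:]:
        if not m.index.equals(subjects):
            raise ValueError("arm outputs cover different subject sets")
    matrix = pd.concat(mats, axis=1)
    if matrix.shape[1] != 15:
        raise ValueError(f"ensemble expects 15 predictor columns, got {matrix.shape[1]}")
    return matrix


def run_ensemble(
    arm_outputs: list[ArmOutput], labels: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """DART-boosted stacker over the 15 lower-level probability columns.

    Returns final out-of-fold Group-1 probabilities, one row per subject.
    """
    matrix = build_ensemble_matrix(arm_outputs)
    label_series = labels.set_index("subject_id")["group"]
    return cross_validated_probabilities(
        config.spec("dart_gradient_boosting", "ensemble"),
        matrix,
        label_series,
        config.plan("ensemble"),
        smote_k=config.smote_k,
        smote_ratio=config.smote_ratio,
        inner_k=config.inner_k,
        arm="ensemble",
    )


@dataclass
class PipelineResult:
    report: PerformanceReport
    final_probabilities: pd.DataFrame
    arm_outputs: list[ArmOutput]
    ensemble_matrix: pd.DataFrame


def run_full_pipeline(
    stacked: pd.DataFrame,
    labels: pd.DataFrame,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute Arms 1-3, the stacking ensemble, and the evaluation.

    When ``out_dir`` is given every intermediate table, the seeds in effect,
    and the performance report are persisted there as CSV/JSON.
    """
    arms = [
        run_arm1(stacked, labels, config),
        run_arm2(stacked, labels, config),
        run_arm3(stacked, labels, config),
    ]
    final = run_ensemble(arms, labels, config)
    merged = final.merge(labels, on="subject_id")
    report = evaluate(merged["prob_group1"], merged["group"])
    result = PipelineResult(
        report=report,
        final_probabilities=final,
        arm_outputs=arms,
        ensemble_matrix=build_ensemble_matrix(arms),
    )
    if out_dir is not None:
        _persist(result, stacked, labels, config, Path(out_dir))
    return result


def _persist(result, stacked, labels, config, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stacked.to_csv(out_dir / "stacked_gps.csv", index=False)
    labels.to_csv(out_dir / "labels.csv", index=False)
    for arm in result.arm_outputs:
        arm.features.rename_axis("subject_id").to_csv(out_dir / f"arm{arm.arm_id}_features.csv")
        pd.concat(arm.probabilities.values()).to_csv(
            out_dir / f"arm{arm.arm_id}_oof_probabilities.csv", index=False
        )
        if arm.day_probabilities is not None:
            arm.day_probabilities.to_csv(out_dir / "arm1_loso_day_probabilities.csv", index=False)
    result.ensemble_matrix.rename_axis("subject_id").to_csv(out_dir / "ensemble_matrix.csv")
    result.final_probabilities.to_csv(out_dir / "final_oof_probabilities.csv", index=False)
    result.report.to_json(out_dir / "performance_report.json")
    provenance = {
        "seed": config.seed,
        "k": config.k,
        "repeats": config.repeats,
        "inner_k": config.inner_k,
        "loso_inner_k": config.loso_inner_k,
        "smote_k": config.smote_k,
        "smote_ratio": config.smote_ratio,
        "grids": {k: (config.grids.get(k) or default_grid(k)) for k in LEARNER_KINDS},
        "conditional_forest_implementation": "rf_fallback",
    }
    import yaml

    with open(out_dir / "provenance.yaml", "w") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=True)
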