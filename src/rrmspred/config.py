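"""Pipeline configuration: every declared analysis decision is a toggle here."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict

from .features import DEFAULT_INTERACTIONS, DEFAULT_REFERENCES, InteractionSpec
from .vocab import CONTINUOUS_PREDICTORS


class SimulateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_patients: int = 2000
    n_centres: int = 20
    sigma_centre: float = 0.3
    cdp_plant_rate: float = 0.0
    gap_rate: float = 0.4
    overlap_rate: float = 0.1
    study_window: tuple[str, str] = ("2011-01-01", "2021-12-15")
    visit_interval_days: tuple[float, float] = (90.0, 30.0)


class ModelBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    prior_scale: float = 1.0
    intercept_prior_sd: float = 10.0
    sigma_prior_scale: float = 1.0
    n_chains: int = 4
    n_draws: int = 1000
    rhat_max: float = 1.01
    ess_min: float = 400.0
    max_divergences: int = 0


class PipelineConfig(BaseModel):
    """Full analysis configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    indir: Optional[str] = None
    split_date: str = "2017-01-01"
    registry_start: str = "2011-01-01"
    extraction_date: str = "2021-12-15"
    train_includes_boundary: bool = False

    bayes: bool = False
    cv_folds: int = 10
    n_boot: int = 500

    # declared analysis decisions, all flippable
    sustain_mode: str = "threshold"
    never_relapsed_distance_cat: str = "3 or more"
    cdp_log_duration: bool = True
    count_calibration_method: str = "bins"
    mad_scaled: bool = True
    standardize_prev_year_count: bool = True

    interactions: list[list[str]] = [list(p) for p in DEFAULT_INTERACTIONS]
    references: dict[str, str] = dict(DEFAULT_REFERENCES)

    model: ModelBlock = ModelBlock()
    simulate: Optional[SimulateBlock] = None

    def interaction_spec(self) -> InteractionSpec:
        return InteractionSpec(
            interactions=tuple(tuple(p) for p in self.interactions),
            references=dict(self.references),
        )

    def continuous_predictors(self) -> tuple:
        if self.standardize_prev_year_count:
            return CONTINUOUS_PREDICTORS
        return tuple(p for p in CONTINUOUS_PREDICTORS if p != "relapse_count_prev_year")


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)
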