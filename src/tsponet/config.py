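"""Run configuration: YAML-backed, schema-validated settings for the CLI.

Every constant the analysis depends on (feature times, K1 fit window,
confound terms, classifier grids, simulator conditions, seeds) lives here
rather than being hard-coded; unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .classify import ClassifierConfig

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FeatureSettings(_Strict):
    suv_times: tuple[float, float, float] = (1.25, 13.5, 50.0)
    k1_window: float = Field(3.0, gt=0)


class ClassifierSettings(_Strict):
    test_size: float = Field(0.3, gt=0, lt=1)
    n_folds: int = Field(10, ge=2)
    n_repeats: int = Field(10, ge=1)
    c_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)
    n_boot: int = Field(1000, ge=1)
    max_iter: int = Field(5000, ge=1)
    knn_grid: tuple[int, ...] = (3, 5, 7, 9)
    l1_ratio_grid: tuple[float, ...] = (0.1, 0.5, 0.9)
    svm_kernels: tuple[str, ...] = ("linear", "poly", "rbf")

    def to_classifier_config(self, seed: int) -> ClassifierConfig:
        return ClassifierConfig(test_size=self.test_size, n_folds=self.n_folds,
                                n_repeats=self.n_repeats, c_grid=self.c_grid,
                                n_boot=self.n_boot, seed=seed,
                                max_iter=self.max_iter, knn_grid=self.knn_grid,
                                l1_ratio_grid=self.l1_ratio_grid,
                                svm_kernels=self.svm_kernels)


class BatchSettings(_Strict):
    name: str
    tracer: str = "PBR28"
    scale: float = Field(1.0, gt=0)
    noise_level: float = Field(0.1, ge=0)
    genotyped: bool = True


class CohortBlockSettings(_Strict):
    batch: str
    group: str
    n: int = Field(..., ge=1)
    sessions: str = "single"


class DiseaseSettings(_Strict):
    group: str
    target_rois: tuple[str, ...]
    expression_multiplier: float = Field(1.5, gt=0)


class SimulateSettings(_Strict):
    atlas_name: str = "reduced"
    batches: tuple[BatchSettings, ...] = (BatchSettings(name="SITE1"),)
    cohort: tuple[CohortBlockSettings, ...] = (
        CohortBlockSettings(batch="SITE1", group="HC", n=10),)
    diseases: tuple[DiseaseSettings, ...] = ()
    occupancy: float = Field(0.9, ge=0, le=1)
    subject_sd: float = Field(0.10, ge=0)
    session_sd: float = Field(0.02, ge=0)


class RunConfig(_Strict):
    """Top-level configuration for ``tsponet`` subcommands."""

    atlas: str = "default"
    seed: int = 0
    features: FeatureSettings = FeatureSettings()
    confound_terms: tuple[str, ...] = ("batch", "sex", "genotype", "age",
                                       "dose_over_weight")
    classifier: ClassifierSettings = ClassifierSettings()
    simulate: SimulateSettings = SimulateSettings()


def load_config(path: Optional[str]) -> RunConfig:
    """Load and validate a YAML run configuration (defaults when ``path``
    is None)."""
    if path is None:
        return RunConfig()
    with open(Path(path)) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(payload)
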