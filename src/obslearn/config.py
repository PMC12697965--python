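"""Run configuration: one YAML file with a section per pipeline stage.

The master ``seed`` fully determines every stage's randomness (stage seeds
are derived from it with fixed offsets).  Two bundled configurations are
provided: ``paper.yaml`` (the full-scale settings: 74 participants, 4
blocks, 4 chains x 1000/1000, 40 recovery replicates, 500 PPC replicates)
and ``reduced.yaml`` (a desk-scale configuration that runs the whole
pipeline in minutes).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .synthetic_data import StudyDesign


class DesignSection(BaseModel):
    n_participants: int = 74
    n_blocks: int = 4
    passive_trials: int = 30
    observational_trials: int = 60
    practice_trials: int = 60
    p_low_noise: float = 0.7
    reward_probs: tuple[float, float, float] = (0.25, 0.50, 0.75)

    def to_design(self, seed: int) -> StudyDesign:
        return StudyDesign(seed=seed, **self.model_dump())


class FitSection(BaseModel):
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000


class RecoverySection(BaseModel):
    n_reps: int = 40
    reduced_scale: bool = False  # use the desk-scale design for recovery loops


class RegressSection(BaseModel):
    engine: str = "auto"  # 'auto' | 'vb' | 'glm'


class PPCSection(BaseModel):
    n_reps: int = 500
    refit_glmm: bool = True
    glmm_engine: str = "glm"


class RunConfig(BaseModel):
    seed: int = Field(..., description="master seed; required")
    outdir: Path = Path("obslearn_out")
    model: str = "full"
    design: DesignSection = DesignSection()
    fit: FitSection = FitSection()
    recovery: RecoverySection = RecoverySection()
    regress: RegressSection = RegressSection()
    ppc: PPCSection = PPCSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


def bundled_config(name: str) -> RunConfig:
    """Load a packaged configuration ('paper' or 'reduced')."""
    text = resources.files("obslearn").joinpath(f"configs/{name}.yaml").read_text()
    return RunConfig.model_validate(yaml.safe_load(text))
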