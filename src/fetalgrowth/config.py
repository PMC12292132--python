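"""Run configuration: a validated JSON document driving the pipeline.

Unknown keys are rejected so a typo in a config file fails loudly rather
than silently falling back to a default. The JSON schema is exportable
for external validation tooling.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import InvalidParameterError
from .records import Parameter


class RunConfig(BaseModel):
    """Configuration of an end-to-end pipeline run."""

    model_config = ConfigDict(extra="forbid")

    input_path: Optional[str] = None  # records CSV; None → simulate a cohort
    out_dir: str = "fetalgrowth_out"
    parameters: Optional[list[Parameter]] = None  # None → all six
    degree_policy: Literal["fixed", "auto"] = "fixed"
    degree: int = Field(default=2, ge=0, le=6)
    epsilon: float = Field(default=0.005, ge=0)  # degree-selection tolerance
    lambda_policy: Literal["fixed", "grid"] = "fixed"
    lam: float = Field(default=0.1, ge=0)
    lambda_grid: list[float] = Field(default=[0.01, 0.1, 1.0, 10.0])
    penalize_intercept: bool = True
    ratio: float = Field(default=0.7, gt=0, lt=1)
    k: int = Field(default=10, ge=2)
    band_mode: Literal["coefficient", "rmse"] = "coefficient"
    skew_threshold: float = Field(default=0.5, gt=0)
    kurtosis_threshold: float = Field(default=1.0, gt=0)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    adjustment: Literal["holm", "bonferroni", "none"] = "holm"
    seed: int = 0

    @model_validator(mode="after")
    def _check_grid(self) -> "RunConfig":
        if self.lambda_policy == "grid" and not self.lambda_grid:
            raise ValueError("lambda_policy='grid' requires a nonempty lambda_grid")
        if any(l < 0 for l in self.lambda_grid):
            raise ValueError("lambda_grid values must be >= 0")
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            data = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise InvalidParameterError(f"{path}: invalid JSON: {exc}") from exc
        try:
            return cls.model_validate(data)
        except Exception as exc:
            raise InvalidParameterError(f"{path}: invalid config: {exc}") from exc

    def to_json(self, path: str | Path | None = None) -> str:
        payload = self.model_dump_json(indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def config_schema() -> dict:
    """The published JSON schema of :class:`RunConfig`."""
    return RunConfig.model_json_schema()
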