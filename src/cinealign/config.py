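"""Run configuration: one object bundling every stage's parameters.

Round-trips losslessly through JSON or YAML (chosen by file extension).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .phantom import PerturbationSpec, PhantomSpec
from .reconstruction import ReconstructionParams
from .registration import GicpParams, RealignParams

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class ValidationOptions:
    sample_step: float = 0.1  # mm, curve resampling for the Hausdorff distance


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    realign: RealignParams = field(default_factory=RealignParams)
    reconstruction: ReconstructionParams = field(default_factory=ReconstructionParams)
    validation: ValidationOptions = field(default_factory=ValidationOptions)
    seed: int = 0
    output_dir: str = "cinealign_out"

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"]["lv_semi_axes"] = list(d["phantom"]["lv_semi_axes"])
        d["reconstruction"]["labels"] = list(d["reconstruction"]["labels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(tp, sub):
            kwargs = dict(sub or {})
            return tp(**kwargs)

        ph = dict(d.get("phantom", {}))
        if "lv_semi_axes" in ph:
            ph["lv_semi_axes"] = tuple(ph["lv_semi_axes"])
        rc = dict(d.get("reconstruction", {}))
        if "labels" in rc:
            rc["labels"] = tuple(rc["labels"])
        ra = dict(d.get("realign", {}))
        if "gicp" in ra:
            ra["gicp"] = GicpParams(**ra["gicp"])
        return cls(
            phantom=PhantomSpec(**ph),
            perturbation=build(PerturbationSpec, d.get("perturbation")),
            realign=RealignParams(**ra),
            reconstruction=ReconstructionParams(**rc),
            validation=build(ValidationOptions, d.get("validation")),
            seed=int(d.get("seed", 0)),
            output_dir=str(d.get("output_dir", "cinealign_out")),
        )

    def write(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def read(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(path.read_text()))
        return cls.from_dict(json.loads(path.read_text()))

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, seed=seed,
            phantom=dataclasses.replace(self.phantom, seed=seed),
            perturbation=dataclasses.replace(self.perturbation, seed=seed))
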