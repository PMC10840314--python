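"""Run configuration: every tunable constant in one serializable record."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .exceptions import ValidationError
from .guinier import AutoGuinierConfig, _Stage
from .ift import BiftConfig
from .series_lc import SeriesConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Aggregated configuration for a full processing run.

    Defaults reproduce all documented behaviour; unknown keys in a config
    file are rejected rather than silently ignored.
    """

    seed: int = 0
    mc_replicates: int = 0          # Monte Carlo P(r) error replicates (0 = off)
    refine_dmax: bool = True
    mw_molecule: str = "protein"
    guinier: AutoGuinierConfig = field(default_factory=AutoGuinierConfig)
    bift: BiftConfig = field(default_factory=BiftConfig)
    series: SeriesConfig = field(default_factory=SeriesConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["guinier"]["stages"] = [dataclasses.asdict(s) if dataclasses.is_dataclass(s)
                                  else dict(s) for s in self.guinier.stages]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(dc_type, sub: dict):
            names = {f.name for f in dataclasses.fields(dc_type)}
            unknown = set(sub) - names
            if unknown:
                raise ValidationError(
                    f"unknown config keys for {dc_type.__name__}: {sorted(unknown)}")
            return sub

        data = dict(data)
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "guinier" in data:
            sub = dict(build(AutoGuinierConfig, data["guinier"]))
            if "stages" in sub:
                sub["stages"] = tuple(_Stage(**build(_Stage, dict(s)))
                                      for s in sub["stages"])
            for key in ("score_weights",):
                if key in sub:
                    sub[key] = tuple(sub[key])
            data["guinier"] = AutoGuinierConfig(**sub)
        if "bift" in data:
            sub = dict(build(BiftConfig, data["bift"]))
            if "dmax_bracket" in sub:
                sub["dmax_bracket"] = tuple(sub["dmax_bracket"])
            data["bift"] = BiftConfig(**sub)
        if "series" in data:
            data["series"] = SeriesConfig(**build(SeriesConfig, data["series"]))
        return cls(**data)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
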