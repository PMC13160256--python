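"""Serializable fit artifacts shared by all model families."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dynopt.ann import ANNSpec


@dataclass
class FitResult:
    """A fitted model: time-invariant parameters, optional network, optional
    time-variant parameter trajectories, objective and solver diagnostics."""

    model: str
    tiv: dict
    objective: float
    ann: ANNSpec | None = None
    tvp: np.ndarray | None = None
    tvp_times: np.ndarray | None = None
    cv_record: list = field(default_factory=list)
    start_log: list = field(default_factory=list)
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "tiv": {k: float(v) for k, v in self.tiv.items()},
            "objective": float(self.objective),
            "ann": self.ann.to_dict() if self.ann is not None else None,
            "tvp": self.tvp.tolist() if self.tvp is not None else None,
            "tvp_times": self.tvp_times.tolist() if self.tvp_times is not None else None,
            "cv_record": self.cv_record,
            "start_log": self.start_log,
            "seed": self.seed,
            "extra": self.extra,
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            model=d["model"],
            tiv=d["tiv"],
            objective=d["objective"],
            ann=ANNSpec.from_dict(d["ann"]) if d.get("ann") else None,
            tvp=np.asarray(d["tvp"]) if d.get("tvp") is not None else None,
            tvp_times=np.asarray(d["tvp_times"]) if d.get("tvp_times") is not None else None,
            cv_record=d.get("cv_record", []),
            start_log=d.get("start_log", []),
            seed=d.get("seed"),
            extra=d.get("extra", {}),
        )

    @classmethod
    def from_json(cls, path) -> "FitResult":
        return cls.from_dict(json.loads(Path(path).read_text()))
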