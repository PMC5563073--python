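"""Generator bookkeeping: the ground truth behind a synthetic dataset."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

__all__ = ["TrueDock", "TrueProtrusion", "GroundTruth"]


@dataclass
class TrueDock:
    granule_id: int
    position_um: float
    start_s: float
    end_s: float
    coupled_protrusion_id: Optional[int] = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class TrueProtrusion:
    protrusion_id: int
    birth_s: float
    death_s: Optional[float]  # None when censored by the observation window
    origin_s_um: float
    max_length_um: float
    kind: str  # "filopodium" | "branch"


@dataclass
class GroundTruth:
    """True events and rates behind one generated dataset.

    Used by parameter-recovery tests to compare estimator output against the
    generating process; carries no information an estimator is allowed to see.
    """

    rng_seed: int
    true_rates: dict = field(default_factory=dict)
    true_docks: list = field(default_factory=list)
    true_protrusions: list = field(default_factory=list)
    granule_classes: dict = field(default_factory=dict)  # granule_id -> class

    def __post_init__(self) -> None:
        ids = {p.protrusion_id for p in self.true_protrusions}
        for d in self.true_docks:
            if d.coupled_protrusion_id is not None and d.coupled_protrusion_id not in ids:
                raise ValueError(
                    f"dock of granule {d.granule_id} couples to unknown "
                    f"protrusion {d.coupled_protrusion_id}"
                )

    def to_json(self, path=None) -> str:
        payload = {
            "rng_seed": self.rng_seed,
            "true_rates": self.true_rates,
            "true_docks": [dataclasses.asdict(d) for d in self.true_docks],
            "true_protrusions": [dataclasses.asdict(p) for p in self.true_protrusions],
            "granule_classes": {str(k): v for k, v in self.granule_classes.items()},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GroundTruth":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            rng_seed=payload["rng_seed"],
            true_rates=payload.get("true_rates", {}),
            true_docks=[TrueDock(**d) for d in payload.get("true_docks", [])],
            true_protrusions=[
                TrueProtrusion(**p) for p in payload.get("true_protrusions", [])
            ],
            granule_classes={
                int(k): v for k, v in payload.get("granule_classes", {}).items()
            },
        )
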