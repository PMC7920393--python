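"""Model constants shared across the pipeline.

All times are in seconds and all rates in 1/s. The defaults are the values
used throughout the method: the artificial seizure limit ``t_lim`` (regions
whose onset falls beyond it are treated as non-seizing), the onset-time
observation noise ``sigma_t``, the hyperparameter prior scale ``sigma_q``,
the alignment time ``t1`` of the earliest observed onset, the temporal
resolution ``T`` of the onset-prediction accuracy, the high-excitability
threshold ``c_h``, and the band-power detection threshold ``delta``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path


@dataclass(frozen=True)
class ModelConstants:
    t_lim: float = 90.0   # s, seizure time limit
    sigma_t: float = 5.0  # s, onset observation noise SD
    sigma_q: float = 30.0  # prior SD of the excitation hyperparameters
    t1: float = 30.0      # s, alignment time of the first observed onset
    T: float = 5.0        # s, tolerance of the onset prediction accuracy
    c_h: float = 2.0      # high-excitability threshold on c
    delta: float = 5.0    # power-increase factor for SEEG onset detection

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"constant {name} must be positive, got {value}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelConstants":
        return cls(**json.loads(Path(path).read_text()))


DEFAULT_CONSTANTS = ModelConstants()
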