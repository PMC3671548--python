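"""Run configuration: the analysis parameter set with reference defaults.

The defaults are the values used for the reference coarse-grained system:
midline spacing s = 1 nm, leaflet graph cutoff r_p = 2.0 nm, low-pass
cutoff λ_c = 15 nm, temperature T = 320 K and trajectory frame spacing
4.0 ns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .errors import MemcurvError


@dataclass
class RunConfig:
    marker_name: str = "PO4"
    chol_name: str = "ROH"
    s: float = 1.0                 # midline spacing, nm
    r_p: float = 2.0               # leaflet graph cutoff, nm
    r_loc: float = 3.0             # local-frame lateral radius, nm
    lambda_c: float = 15.0         # spectral cutoff wavelength, nm
    kappa_bin_width: float = 0.0085  # |κ| histogram bin, nm⁻¹
    interval_bin_width: float = 2.0  # flip-flop interval bin, ns
    temperature: float = 320.0     # K
    frame_dt: float = 4.0          # ns
    debounce: float = 0.0          # ns; 0 disables
    seed: int = 0
    structure: str | None = None
    trajectory: str | None = None
    out: str | None = None
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("s", "r_p", "r_loc", "kappa_bin_width",
                     "interval_bin_width", "frame_dt"):
            if getattr(self, name) <= 0:
                raise MemcurvError(f"{name} must be positive")
        if self.temperature <= 0:
            raise MemcurvError("temperature must be positive")
        if self.lambda_c < 0 or self.debounce < 0:
            raise MemcurvError("lambda_c and debounce must be non-negative")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)
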