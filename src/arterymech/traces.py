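"""Instrument-trace containers shared by the simulator and the analysis.

A biaxial myograph protocol produces two trace types per sample:

* force-length test — equilibrium axial force versus axial stretch at one
  constant pressure (repeated at several pressures);
* pressure sweep — outer diameter (and recorded axial force) versus
  pressure at fixed axial stretch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ForceLengthCurve:
    """Equilibrium axial force vs axial stretch at one constant pressure."""

    pressure_mmhg: float
    lambda_z: np.ndarray
    force_mn: np.ndarray
    outer_diameter_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        lz = np.asarray(self.lambda_z, dtype=float)
        f = np.asarray(self.force_mn, dtype=float)
        if lz.ndim != 1 or lz.size < 2:
            raise ValueError("force-length curve needs >= 2 points")
        if np.any(np.diff(lz) <= 0.0):
            raise ValueError("lambda_z must be strictly increasing")
        if f.shape != lz.shape:
            raise ValueError("force and stretch arrays must align")
        object.__setattr__(self, "lambda_z", lz)
        object.__setattr__(self, "force_mn", f)
        if self.outer_diameter_um is not None:
            od = np.asarray(self.outer_diameter_um, dtype=float)
            if od.shape != lz.shape:
                raise ValueError("outer diameter array must align with stretch grid")
            object.__setattr__(self, "outer_diameter_um", od)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.lambda_z[0]), float(self.lambda_z[-1])


@dataclass(frozen=True)
class PressureSweep:
    """Outer diameter and axial force vs pressure at fixed axial stretch."""

    axial_stretch: float
    pressure_mmhg: np.ndarray
    outer_diameter_um: np.ndarray
    force_mn: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pressure_mmhg, dtype=float)
        od = np.asarray(self.outer_diameter_um, dtype=float)
        f = np.asarray(self.force_mn, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("pressure sweep needs >= 1 point")
        if od.shape != p.shape or f.shape != p.shape:
            raise ValueError("sweep columns must align with the pressure grid")
        if self.axial_stretch <= 0.0:
            raise ValueError("axial stretch must be > 0")
        object.__setattr__(self, "pressure_mmhg", p)
        object.__setattr__(self, "outer_diameter_um", od)
        object.__setattr__(self, "force_mn", f)
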