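"""Vessel wall kinematics under incompressibility.

A cannulated artery segment is modelled as an incompressible cylindrical
membrane.  The myograph measures loaded outer diameter; the unloaded
(unstretched, unpressurized) outer radius ``R_o`` and wall thickness ``H``
are measured once per sample.  Conservation of wall volume,

    pi * (r_o^2 - r_i^2) * lambda_z = pi * (R_o^2 - R_i^2),

then determines the loaded inner radius and wall thickness from each
measured outer diameter at known axial stretch ``lambda_z``.  The
circumferential stretch is the mid-wall radius ratio by default (the
inner-wall ratio is available as an alternative convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateGeometryError(ValueError):
    """Measured diameter is inconsistent with the unloaded wall volume."""


@dataclass(frozen=True)
class UnloadedGeometry:
    """Reference (unpressurized, unstretched) dimensions of one sample.

    Parameters
    ----------
    R_o : float
        Unloaded outer radius, um.
    H : float
        Unloaded wall thickness, um.
    """

    R_o: float
    H: float

    def __post_init__(self) -> None:
        if not (0.0 < self.H < self.R_o):
            raise ValueError(
                f"require 0 < H < R_o, got H={self.H}, R_o={self.R_o}"
            )

    @property
    def R_i(self) -> float:
        """Unloaded inner radius, um."""
        return self.R_o - self.H

    @property
    def annulus(self) -> float:
        """R_o^2 - R_i^2, the wall cross-section divided by pi (um^2)."""
        return self.R_o**2 - self.R_i**2

    @property
    def midwall_radius(self) -> float:
        """Unloaded mid-wall radius (R_i + H/2), um."""
        return self.R_i + 0.5 * self.H

    @classmethod
    def from_measurements(cls, unloaded_od_um: float, unloaded_h_um: float) -> "UnloadedGeometry":
        return cls(R_o=0.5 * unloaded_od_um, H=unloaded_h_um)


@dataclass(frozen=True)
class DeformedGeometry:
    """Loaded geometry and biaxial stretches at one (pressure, stretch) point."""

    r_o: float
    r_i: float
    h: float
    lambda_z: float
    lambda_theta: float

    def __post_init__(self) -> None:
        if self.r_i <= 0.0 or self.h <= 0.0:
            raise DegenerateGeometryError(
                f"non-positive loaded geometry: r_i={self.r_i}, h={self.h}"
            )


def loaded_geometry(
    unloaded: UnloadedGeometry,
    od_measured: float,
    lambda_z: float,
    convention: str = "midwall",
) -> DeformedGeometry:
    """Loaded inner radius, thickness, and stretches from measured OD.

    Parameters
    ----------
    unloaded : UnloadedGeometry
    od_measured : float
        Loaded outer diameter, um.
    lambda_z : float
        Axial stretch (> 0) at which the diameter was recorded.
    convention : {"midwall", "inner"}
        Radius ratio used for the circumferential stretch.

    Raises
    ------
    DegenerateGeometryError
        If the measured OD is too small for the wall volume at this
        ``lambda_z`` (negative discriminant).
    """
    if lambda_z <= 0.0:
        raise ValueError(f"lambda_z must be > 0, got {lambda_z}")
    if convention not in ("midwall", "inner"):
        raise ValueError(f"unknown circumferential-stretch convention {convention!r}")
    r_o = 0.5 * float(od_measured)
    disc = r_o**2 - unloaded.annulus / lambda_z
    if disc <= 0.0:
        raise DegenerateGeometryError(
            f"od_measured={od_measured} um is below the incompressibility bound "
            f"{2.0 * np.sqrt(unloaded.annulus / lambda_z):.3f} um at lambda_z={lambda_z}"
        )
    r_i = float(np.sqrt(disc))
    h = r_o - r_i
    if convention == "midwall":
        lambda_theta = (r_i + 0.5 * h) / unloaded.midwall_radius
    else:
        lambda_theta = r_i / unloaded.R_i
    return DeformedGeometry(
        r_o=r_o, r_i=r_i, h=h, lambda_z=float(lambda_z), lambda_theta=lambda_theta
    )
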