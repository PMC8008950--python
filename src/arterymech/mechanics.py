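"""Biaxial mean Cauchy wall stresses and tangent moduli.

Mean-wall (Laplace) stress forms for a pressurized, axially loaded
cylinder:

    sigma_theta = P r_i / h
    sigma_z     = (f + P pi r_i^2) / (pi h (2 r_i + h))

with pressure converted at 1 mmHg = 0.133322 kPa, transducer force ``f``
in mN, geometry in um, stresses in kPa.  The circumferential form is the
exact through-thickness mean of the hoop stress (radial equilibrium
integrates to P r_i); the axial form balances the capped-tube free body on
the deformed wall annulus.

Tangent moduli d(sigma)/d(lambda) are estimated from discrete
stress-stretch curves by a sliding-window local linear fit (default) or
central differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import DegenerateGeometryError, DeformedGeometry, loaded_geometry
from .units import MMHG_TO_KPA


def circumferential_stress(pressure_mmhg: float, geometry: DeformedGeometry) -> float:
    """Mean circumferential (hoop) Cauchy stress, kPa."""
    if geometry.h <= 0.0:
        raise DegenerateGeometryError("wall thickness must be positive")
    return pressure_mmhg * MMHG_TO_KPA * geometry.r_i / geometry.h


_FORCE_FACTOR = {"um": 1e6, "mm": 1.0}  # 1 mN = 1e6 kPa*um^2 = 1 kPa*mm^2


def axial_stress(
    force_mn: float,
    pressure_mmhg: float,
    geometry: DeformedGeometry,
    geometry_unit: str = "um",
) -> float:
    """Mean axial Cauchy stress, kPa, from transducer force and pressure.

    The transducer reads the wall load minus the pressure-on-cap term, so
    the total axial force on the wall annulus is f + P pi r_i^2.
    ``geometry_unit`` normalizes the mN force to the unit the geometry is
    expressed in, so the stress is independent of that choice.
    """
    if geometry.h <= 0.0:
        raise DegenerateGeometryError("wall thickness must be positive")
    try:
        factor = _FORCE_FACTOR[geometry_unit]
    except KeyError:
        raise ValueError(f"unknown geometry unit {geometry_unit!r}") from None
    p_kpa = pressure_mmhg * MMHG_TO_KPA
    total = force_mn * factor + p_kpa * np.pi * geometry.r_i**2
    return total / (np.pi * geometry.h * (2.0 * geometry.r_i + geometry.h))


@dataclass(frozen=True)
class StressStretchCurve:
    """Ordered (stretch, stress) points for one axis, with provenance."""

    axis: str  # "circumferential" | "axial"
    stretch: np.ndarray
    stress_kpa: np.ndarray
    sample_id: str = ""
    context_pressure_mmhg: float | None = None  # axial curves: constant test pressure
    pressure_mmhg: np.ndarray | None = None     # circumferential curves: sweep steps

    def __post_init__(self) -> None:
        if self.axis not in ("circumferential", "axial"):
            raise ValueError(f"unknown axis {self.axis!r}")
        x = np.asarray(self.stretch, dtype=float)
        y = np.asarray(self.stress_kpa, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("stretch and stress must be aligned 1-D arrays")
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        if np.any(np.diff(x) <= 0.0):
            raise ValueError("stretch values must be distinct")
        object.__setattr__(self, "stretch", x)
        object.__setattr__(self, "stress_kpa", y)
        if self.pressure_mmhg is not None:
            p = np.asarray(self.pressure_mmhg, dtype=float)[order]
            object.__setattr__(self, "pressure_mmhg", p)

    def __len__(self) -> int:
        return int(self.stretch.size)


def build_stress_stretch(
    recording,
    unloaded,
    axis: str,
    context_pressure_mmhg: float = 90.0,
    sample_id: str = "",
    convention: str = "midwall",
) -> StressStretchCurve:
    """Assemble one sample's stress-stretch curve from its tidy recording.

    Parameters
    ----------
    recording : pandas.DataFrame
        Rows for one sample with columns test_type, pressure_mmHg,
        axial_stretch, outer_diameter_um, force_mN.
    unloaded : UnloadedGeometry
    axis : {"circumferential", "axial"}
        Circumferential: (lambda_theta, sigma_theta) per pressure step of
        the pressure sweep recorded at the sample's IVS.  Axial:
        (lambda_z, sigma_z) per stretch step of the force-length test at
        ``context_pressure_mmhg`` (90 mmHg by default; 80 supported for
        the younger-mice protocol).
    """
    if axis == "circumferential":
        rows = recording[recording["test_type"] == "pressure_sweep"]
        if rows.empty:
            raise ValueError(f"sample {sample_id!r}: no pressure_sweep recording")
        rows = rows.sort_values("pressure_mmHg")
        stretches, stresses = [], []
        for _, r in rows.iterrows():
            geom = loaded_geometry(
                unloaded, r["outer_diameter_um"], r["axial_stretch"], convention
            )
            stretches.append(geom.lambda_theta)
            stresses.append(circumferential_stress(r["pressure_mmHg"], geom))
        return StressStretchCurve(
            axis=axis,
            stretch=np.array(stretches),
            stress_kpa=np.array(stresses),
            sample_id=sample_id,
            pressure_mmhg=rows["pressure_mmHg"].to_numpy(float),
        )
    if axis == "axial":
        rows = recording[
            (recording["test_type"] == "force_length")
            & (np.isclose(recording["pressure_mmHg"], context_pressure_mmhg))
        ]
        if rows.empty:
            raise ValueError(
                f"sample {sample_id!r}: no force_length recording at "
                f"{context_pressure_mmhg} mmHg"
            )
        rows = rows.sort_values("axial_stretch")
        stretches, stresses = [], []
        for _, r in rows.iterrows():
            geom = loaded_geometry(
                unloaded, r["outer_diameter_um"], r["axial_stretch"], convention
            )
            stresses.append(axial_stress(r["force_mN"], r["pressure_mmHg"], geom))
            stretches.append(r["axial_stretch"])
        return StressStretchCurve(
            axis=axis,
            stretch=np.array(stretches),
            stress_kpa=np.array(stresses),
            sample_id=sample_id,
            context_pressure_mmhg=float(context_pressure_mmhg),
        )
    raise ValueError(f"unknown axis {axis!r}")


@dataclass(frozen=True)
class TangentModulusCurve:
    """Pointwise stiffness dsigma/dlambda (kPa) along a stress-stretch curve."""

    axis: str
    stretch: np.ndarray
    e_tan_kpa: np.ndarray
    sample_id: str = ""
    method: str = "window"


def tangent_modulus(
    curve: StressStretchCurve,
    method: str = "window",
    window: int = 5,
) -> TangentModulusCurve:
    """Tangent modulus of a discrete stress-stretch curve.

    method="window" (default): slope of a local least-squares line over a
    sliding window of ``window`` points (odd, >= 3) centred on each
    interior point, with one-sided windows at the endpoints.
    method="central": three-point central differences on the non-uniform
    grid, one-sided at the endpoints.

    A window larger than the curve is shrunk to the largest odd size that
    fits, with a warning.
    """
    x = curve.stretch
    y = curve.stress_kpa
    n = x.size
    if n < 3:
        raise ValueError("tangent modulus needs >= 3 points")
    if method == "central":
        d = np.gradient(y, x)
        return TangentModulusCurve(
            axis=curve.axis, stretch=x.copy(), e_tan_kpa=d,
            sample_id=curve.sample_id, method=method,
        )
    if method != "window":
        raise ValueError(f"unknown tangent-modulus method {method!r}")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > n:
        shrunk = n if n % 2 == 1 else n - 1
        warnings.warn(
            f"tangent-modulus window {window} exceeds curve length {n}; using {shrunk}",
            stacklevel=2,
        )
        window = shrunk
    half = window // 2
    d = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        # one-sided at the ends, keeping the window size
        if hi - lo < window:
            if lo == 0:
                hi = min(n, window)
            else:
                lo = max(0, n - window)
        xi, yi = x[lo:hi], y[lo:hi]
        xm = xi - xi.mean()
        d[i] = float(xm @ (yi - yi.mean()) / (xm @ xm))
    return TangentModulusCurve(
        axis=curve.axis, stretch=x.copy(), e_tan_kpa=d,
        sample_id=curve.sample_id, method="window",
    )
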