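"""Forward simulation of biaxial inflation-extension experiments.

Given ground-truth constitutive parameters and unloaded geometry, every
simulated point solves the thin-wall (membrane) equilibrium

    P = sigma_theta(lambda_theta, lambda_z) * h / r_i

for the circumferential stretch, with the loaded geometry (r_i, h) tied to
the stretches by incompressibility, and reports what the instrument
records: outer diameter and transducer axial force

    f = sigma_z * pi h (2 r_i + h) - P * pi r_i^2

(total axial wall load minus the pressure-on-cap term).  Additive Gaussian
noise on OD and force emulates instrument error; pressure and axial
stretch are treated as exactly controlled.

The module also provides the ground-truth definition of the in-vivo axial
stretch (IVS): the axial stretch minimizing the across-pressure spread of
noiseless transducer force — the operational quantity the force-length
crossover protocol estimates — plus a curve-level generator of exactly
intersecting linear force curves, and a calibration routine that rotates
the diagonal fiber pair so the ground-truth IVS hits a prescribed setpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .constitutive import (
    ConstitutiveParams,
    cauchy_stresses,
    default_params,
    set_diagonal_angle,
)
from .geometry import UnloadedGeometry
from .traces import ForceLengthCurve, PressureSweep
from .units import KPA_UM2_TO_MN, MMHG_TO_KPA


class EquilibriumError(RuntimeError):
    """No membrane-equilibrium solution at a requested (pressure, stretch)."""

    def __init__(self, pressure_mmhg: float, lambda_z: float):
        self.pressure_mmhg = pressure_mmhg
        self.lambda_z = lambda_z
        super().__init__(
            f"membrane equilibrium not bracketed at P={pressure_mmhg} mmHg, "
            f"lambda_z={lambda_z}"
        )


def _deformed_radii(unloaded: UnloadedGeometry, lambda_theta, lambda_z):
    """Closed-form loaded (r_i, r_o) from mid-wall stretch and incompressibility.

    Mid-wall convention: lambda_theta = (r_i + r_o) / (R_i + R_o); combined
    with (r_o^2 - r_i^2) lambda_z = R_o^2 - R_i^2 this gives
    r_i = (S^2 - A/lambda_z) / (2 S) with S = lambda_theta (R_i + R_o).
    """
    a = unloaded.annulus
    s = np.asarray(lambda_theta, dtype=float) * (unloaded.R_i + unloaded.R_o)
    r_i = (s * s - a / np.asarray(lambda_z, dtype=float)) / (2.0 * s)
    r_o = s - r_i
    return r_i, r_o


def luminal_pressure_mmhg(
    params: ConstitutiveParams,
    unloaded: UnloadedGeometry,
    lambda_theta,
    lambda_z,
):
    """Equilibrium luminal pressure (mmHg) at given stretches; NaN if r_i <= 0."""
    r_i, r_o = _deformed_radii(unloaded, lambda_theta, lambda_z)
    sig_t, _ = cauchy_stresses(params, lambda_theta, lambda_z)
    h = r_o - r_i
    with np.errstate(invalid="ignore", divide="ignore"):
        p_kpa = np.where(r_i > 0.0, sig_t * h / r_i, np.nan)
    return p_kpa / MMHG_TO_KPA


def transducer_force_mn(
    params: ConstitutiveParams,
    unloaded: UnloadedGeometry,
    lambda_theta,
    lambda_z,
    pressure_mmhg,
):
    """Axial force the transducer records (mN) at given stretches and pressure."""
    r_i, r_o = _deformed_radii(unloaded, lambda_theta, lambda_z)
    h = r_o - r_i
    _, sig_z = cauchy_stresses(params, lambda_theta, lambda_z)
    p_kpa = np.asarray(pressure_mmhg, dtype=float) * MMHG_TO_KPA
    return (sig_z * np.pi * h * (2.0 * r_i + h) - p_kpa * np.pi * r_i**2) * KPA_UM2_TO_MN


_SCAN_LO, _SCAN_HI, _SCAN_N = 0.3, 4.0, 160
_BISECT_ITERS = 70


def equilibrium_circ_stretch(
    params: ConstitutiveParams,
    unloaded: UnloadedGeometry,
    pressure_mmhg,
    lambda_z,
):
    """Solve the membrane equilibrium for lambda_theta, vectorized.

    ``pressure_mmhg`` and ``lambda_z`` broadcast to any shape.  The solver
    scans a fixed lambda_theta grid, picks the outermost sign change of
    P_model - P (the stable, strain-stiffening branch), and bisects it to
    machine precision.

    Raises
    ------
    EquilibriumError
        If no sign change exists for some point (naming it).
    """
    p, lz = np.broadcast_arrays(
        np.asarray(pressure_mmhg, dtype=float), np.asarray(lambda_z, dtype=float)
    )
    shape = p.shape
    p_f = p.ravel()
    lz_f = lz.ravel()
    # per-point lower bound: lambda_theta at which r_i -> 0 under incompressibility
    lt_floor = np.sqrt(unloaded.annulus / lz_f) / (unloaded.R_i + unloaded.R_o)
    lo_grid = np.maximum(_SCAN_LO, lt_floor * (1.0 + 1e-9))
    frac = np.linspace(0.0, 1.0, _SCAN_N)[:, np.newaxis]
    grid = lo_grid + frac * (_SCAN_HI - lo_grid)  # (scan, n)

    def residual(lt):
        pm = luminal_pressure_mmhg(params, unloaded, lt, lz_f)
        return np.where(np.isfinite(pm), pm, -np.inf) - p_f

    g = residual(grid)  # (scan, n)
    pos = g > 0.0
    change = pos[1:, :] != pos[:-1, :]  # sign change between grid[i], grid[i+1]
    any_change = change.any(axis=0)
    if not bool(np.all(any_change)):
        bad = int(np.flatnonzero(~any_change)[0])
        raise EquilibriumError(float(p_f[bad]), float(lz_f[bad]))
    # outermost (largest-lambda_theta) sign change = stable inflation branch
    idx = change.shape[0] - 1 - np.argmax(change[::-1, :], axis=0)
    cols = np.arange(grid.shape[1])
    lo = grid[idx, cols]
    hi = grid[idx + 1, cols]
    g_lo = np.take_along_axis(g, idx[np.newaxis, :], axis=0).ravel()
    lo_pos = g_lo > 0.0
    for _ in range(_BISECT_ITERS):
        mid = 0.5 * (lo + hi)
        g_mid = residual(mid)
        mid_pos = g_mid > 0.0
        same = mid_pos == lo_pos
        lo = np.where(same, mid, lo)
        hi = np.where(same, hi, mid)
    lt = 0.5 * (lo + hi)
    return lt.reshape(shape) if shape else float(lt[0])


@dataclass(frozen=True)
class ArteryGroundTruth:
    """A simulated artery: parameters, geometry, and its operational IVS."""

    params: ConstitutiveParams
    unloaded: UnloadedGeometry
    ivs_true: float

    def __post_init__(self) -> None:
        if self.ivs_true <= 1.0:
            raise ValueError("ivs_true must exceed 1")

    @property
    def stress_fn(self) -> Callable:
        """Analytic map (lambda_theta, lambda_z) -> (sigma_theta, sigma_z) in kPa."""
        return lambda lt, lz: cauchy_stresses(self.params, lt, lz)


def _rng_for(params: ConstitutiveParams, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(params.seed)


def protocol_stretch_grid(lo: float = 1.3, hi: float = 2.1, increment: float = 0.1) -> np.ndarray:
    """Axial stretch grid in fixed increments of the unloaded length (default 10%)."""
    n = int(round((hi - lo) / increment))
    return lo + increment * np.arange(n + 1)


def simulate_force_length_test(
    truth: ArteryGroundTruth,
    pressures: Sequence[float],
    stretch_grid: Sequence[float] | None = None,
    noisy: bool = False,
    rng: np.random.Generator | None = None,
) -> list[ForceLengthCurve]:
    """Force-length tests: one equilibrium force curve per constant pressure.

    Default grid follows the protocol of 10% axial-stretch increments.
    Outer diameter is recorded alongside force, as the instrument does.
    """
    pressures = np.asarray(list(pressures), dtype=float)
    if pressures.size == 0:
        raise ValueError("pressures must be non-empty")
    if np.any(pressures < 0.0):
        raise ValueError("pressures must be non-negative")
    if stretch_grid is None:
        stretch_grid = protocol_stretch_grid()
    lz = np.asarray(stretch_grid, dtype=float)
    if np.any(np.diff(lz) <= 0.0) or np.any(lz <= 1.0):
        raise ValueError("stretch grid must be strictly increasing and > 1")
    gen = _rng_for(truth.params, rng)
    pp, zz = np.meshgrid(pressures, lz, indexing="ij")
    lt = equilibrium_circ_stretch(truth.params, truth.unloaded, pp, zz)
    f = transducer_force_mn(truth.params, truth.unloaded, lt, zz, pp)
    _, r_o = _deformed_radii(truth.unloaded, lt, zz)
    od = 2.0 * r_o
    if noisy:
        f = f + gen.normal(0.0, truth.params.noise_f_sd, size=f.shape)
        od = od + gen.normal(0.0, truth.params.noise_od_sd, size=od.shape)
    return [
        ForceLengthCurve(
            pressure_mmhg=float(pressures[i]),
            lambda_z=lz.copy(),
            force_mn=f[i],
            outer_diameter_um=od[i],
        )
        for i in range(pressures.size)
    ]


def pressure_grid(p_min: float = 0.0, p_max: float = 140.0, step: float = 10.0) -> np.ndarray:
    if step <= 0.0:
        raise ValueError("step must be > 0")
    n = int(np.floor((p_max - p_min) / step + 1e-9))
    return float(p_min) + float(step) * np.arange(n + 1, dtype=float)


def simulate_pressure_sweep(
    truth: ArteryGroundTruth,
    axial_stretch: float,
    p_min: float = 0.0,
    p_max: float = 140.0,
    step: float = 10.0,
    noisy: bool = False,
    rng: np.random.Generator | None = None,
) -> PressureSweep:
    """Pressure-diameter sweep at fixed axial stretch (default 0-140 by 10 mmHg)."""
    if axial_stretch < 1.0:
        raise ValueError("axial_stretch must be >= 1")
    p = pressure_grid(p_min, p_max, step)
    gen = _rng_for(truth.params, rng)
    lt = equilibrium_circ_stretch(
        truth.params, truth.unloaded, p, np.full(p.shape, float(axial_stretch))
    )
    _, r_o = _deformed_radii(truth.unloaded, lt, axial_stretch)
    od = 2.0 * r_o
    f = transducer_force_mn(truth.params, truth.unloaded, lt, axial_stretch, p)
    if noisy:
        od = od + gen.normal(0.0, truth.params.noise_od_sd, size=od.shape)
        f = f + gen.normal(0.0, truth.params.noise_f_sd, size=f.shape)
    return PressureSweep(
        axial_stretch=float(axial_stretch), pressure_mmhg=p, outer_diameter_um=od, force_mn=f
    )


def force_spread_oracle(
    params: ConstitutiveParams,
    unloaded: UnloadedGeometry,
    pressures: Sequence[float],
    grid_step: float = 1e-4,
    span: tuple[float, float] = (1.25, 2.30),
) -> float:
    """Brute-force IVS: argmin over a fine lambda_z grid of the relative
    across-pressure spread (max-min)/mean of noiseless transducer forces.

    Grid points where the mean force is not positive are excluded (the
    spread statistic is undefined there).
    """
    pressures = np.asarray(list(pressures), dtype=float)
    if pressures.size < 2:
        raise ValueError("need >= 2 pressures for the force-spread oracle")
    if grid_step > 1e-3:
        raise ValueError("grid_step must be <= 1e-3")

    def argmin_spread(lz: np.ndarray) -> float:
        pp, zz = np.meshgrid(pressures, lz, indexing="ij")
        lt = equilibrium_circ_stretch(params, unloaded, pp, zz)
        f = transducer_force_mn(params, unloaded, lt, zz, pp)
        mean = f.mean(axis=0)
        spread = np.where(mean > 0.0, (f.max(axis=0) - f.min(axis=0)) / mean, np.inf)
        if not np.any(np.isfinite(spread)):
            raise EquilibriumError(float(pressures[0]), float(lz[0]))
        return float(lz[int(np.argmin(spread))])

    # coarse pass locates the dip basin, fine pass resolves it at grid_step
    coarse = 1e-3
    best = argmin_spread(np.arange(span[0], span[1] + 0.5 * coarse, coarse))
    if grid_step >= coarse:
        return best
    lo = max(span[0], best - 3.0 * coarse)
    hi = min(span[1], best + 3.0 * coarse)
    return argmin_spread(np.arange(lo, hi + 0.5 * grid_step, grid_step))


def simulator_oracle_ivs(
    truth: ArteryGroundTruth,
    pressures: Sequence[float] = (90.0, 120.0, 140.0),
    grid_step: float = 1e-4,
    span: tuple[float, float] = (1.25, 2.30),
) -> float:
    """Ground-truth IVS of a simulated artery (see :func:`force_spread_oracle`)."""
    return force_spread_oracle(truth.params, truth.unloaded, pressures, grid_step, span)


def linear_force_curves(
    pressures: Sequence[float],
    crossing_stretch: float,
    crossing_force_mn: float,
    stretch_grid: Sequence[float],
    slope_per_mmhg: float = 0.05,
    base_slope: float = 10.0,
    noise_f_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[ForceLengthCurve]:
    """Curve-level generator: straight force-stretch lines through one
    designated common point, with pressure-dependent slope.

    Provides the exact-intersection case that real (and simulated) arteries
    only approximate: every pair of curves crosses exactly at
    ``crossing_stretch``.
    """
    lz = np.asarray(stretch_grid, dtype=float)
    gen = rng if rng is not None else np.random.default_rng(0)
    curves = []
    for p in pressures:
        slope = base_slope + slope_per_mmhg * float(p)
        f = crossing_force_mn + slope * (lz - crossing_stretch)
        if noise_f_sd > 0.0:
            f = f + gen.normal(0.0, noise_f_sd, size=f.shape)
        curves.append(ForceLengthCurve(pressure_mmhg=float(p), lambda_z=lz.copy(), force_mn=f))
    return curves


DEFAULT_UNLOADED = UnloadedGeometry(R_o=200.0, H=40.0)


def calibrate_to_ivs(
    params: ConstitutiveParams,
    unloaded: UnloadedGeometry,
    target_ivs: float,
    pressures: Sequence[float] = (90.0, 120.0, 140.0),
    grid_step: float = 2e-4,
    bracket_deg: tuple[float, float] = (27.0, 42.0),
    tol: float = 5e-4,
) -> tuple[ConstitutiveParams, float, float]:
    """Rotate the diagonal fiber pair so the ground-truth IVS hits a setpoint.

    The across-pressure force crossover moves to smaller stretch as the
    diagonal fibers rotate toward the axis (larger angle from the
    circumferential direction); purely axial stiffness cannot move it,
    because an axial-fiber force contribution is pressure-independent and
    cancels between force-length curves.  The angle is bisected until the
    force-spread oracle matches ``target_ivs``.

    Returns
    -------
    (calibrated params, achieved ivs, d(ivs)/d(alpha) sensitivity per rad)
    """
    def ivs_at(alpha: float) -> float:
        return force_spread_oracle(
            set_diagonal_angle(params, alpha), unloaded, pressures, grid_step
        )

    lo, hi = np.deg2rad(bracket_deg[0]), np.deg2rad(bracket_deg[1])
    f_lo, f_hi = ivs_at(lo), ivs_at(hi)
    # ivs decreases with diagonal angle: f_lo > f_hi expected
    if not (min(f_lo, f_hi) - 1e-9 <= target_ivs <= max(f_lo, f_hi) + 1e-9):
        raise ValueError(
            f"target IVS {target_ivs} outside calibration range "
            f"[{min(f_lo, f_hi):.3f}, {max(f_lo, f_hi):.3f}]"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f_mid = ivs_at(mid)
        if abs(f_mid - target_ivs) <= tol or hi - lo < 1e-5:
            lo = hi = mid
            break
        if (f_mid > target_ivs) == (f_lo > target_ivs):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    calibrated = set_diagonal_angle(params, alpha)
    achieved = force_spread_oracle(calibrated, unloaded, pressures, grid_step)
    d = np.deg2rad(0.5)
    sens = (ivs_at(alpha + d) - ivs_at(alpha - d)) / (2.0 * d)
    return calibrated, achieved, sens


def default_artery(
    ivs_target: float = 1.85,
    fiber_multiplier: float = 1.0,
    unloaded: UnloadedGeometry = DEFAULT_UNLOADED,
    seed: int = 0,
    noise_od_sd: float = 2.0,
    noise_f_sd: float = 0.05,
) -> ArteryGroundTruth:
    """Calibrated default artery (wild-type-like at multiplier 1)."""
    base = default_params(
        fiber_multiplier=fiber_multiplier,
        noise_od_sd=noise_od_sd,
        noise_f_sd=noise_f_sd,
        seed=seed,
    )
    params, achieved, _ = calibrate_to_ivs(base, unloaded, ivs_target)
    return ArteryGroundTruth(params=params, unloaded=unloaded, ivs_true=achieved)
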