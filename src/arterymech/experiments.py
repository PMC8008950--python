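"""Canned simulation experiments used by the analysis scripts and the
acceptance checks: IVS recovery, closed-form agreement, ANOVA calibration
and power, and the QC partition.

These experiments deliberately switch biological jitter off (measurement
noise only) wherever a test statistic's null calibration matters: the
curve-wise two-way ANOVA treats pressure-matched points within an artery
as independent observations, so between-artery biological variance
inflates its type-I error (see the methods note).  Under measurement
noise alone the test is correctly calibrated, which is the regime in
which power and type-I properties are interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constitutive import default_params, stress_derivatives
from .geometry import DegenerateGeometryError, loaded_geometry
from .ivs import estimate_ivs, qc_axial_force_spread
from .mechanics import (
    StressStretchCurve,
    axial_stress,
    circumferential_stress,
    tangent_modulus,
)
from .simulate import (
    DEFAULT_UNLOADED,
    ArteryGroundTruth,
    calibrate_to_ivs,
    equilibrium_circ_stretch,
    simulate_force_length_test,
    simulate_pressure_sweep,
)
from .stats import two_way_anova_curves
from .traces import PressureSweep

_CALIBRATION_CACHE: dict[tuple[float, float], ArteryGroundTruth] = {}


def calibrated_artery(
    ivs_target: float = 1.85, fiber_multiplier: float = 1.0
) -> ArteryGroundTruth:
    """Cached calibrated ground truth on the default geometry."""
    key = (ivs_target, fiber_multiplier)
    if key not in _CALIBRATION_CACHE:
        params, achieved, _ = calibrate_to_ivs(
            default_params(fiber_multiplier=fiber_multiplier),
            DEFAULT_UNLOADED,
            ivs_target,
        )
        _CALIBRATION_CACHE[key] = ArteryGroundTruth(
            params=params, unloaded=DEFAULT_UNLOADED, ivs_true=achieved
        )
    return _CALIBRATION_CACHE[key]


@dataclass(frozen=True)
class RecoveryResult:
    ivs_true: float
    mean_recovered: float
    sd: float
    se: float
    n: int

    @property
    def bias(self) -> float:
        return self.mean_recovered - self.ivs_true

    @property
    def within_2se(self) -> bool:
        return bool(abs(self.bias) <= 2.0 * self.se)


def ivs_recovery_experiment(
    ivs_target: float,
    fiber_multiplier: float,
    n_per_group: int,
    n_replicates: int,
    rng: np.random.Generator,
) -> RecoveryResult:
    """Repeatedly simulate noisy force-length protocols on one calibrated
    artery and estimate the IVS; reports the recovery bias against the
    ground-truth (force-spread oracle) value."""
    truth = calibrated_artery(ivs_target, fiber_multiplier)
    estimates = []
    for _ in range(n_replicates):
        for _ in range(n_per_group):
            curves = simulate_force_length_test(
                truth, [90.0, 120.0, 140.0], noisy=True, rng=rng
            )
            estimates.append(estimate_ivs(curves).ivs)
    est = np.asarray(estimates)
    sd = float(est.std(ddof=1))
    return RecoveryResult(
        ivs_true=truth.ivs_true,
        mean_recovered=float(est.mean()),
        sd=sd,
        se=sd / np.sqrt(est.size),
        n=est.size,
    )


def closed_form_agreement(truth: ArteryGroundTruth) -> dict[str, float]:
    """Pipeline stresses and tangent moduli vs the simulator's analytic
    stress function on densely sampled noiseless data.

    Returns maximum relative errors: stresses over the 10-mmHg protocol
    sweep (pressures > 0), windowed tangent moduli over interior points of
    densely sampled curves (0.5-mmHg sweep; 0.01 axial-stretch grid).
    """
    unl = truth.unloaded
    lz = truth.ivs_true

    sweep = simulate_pressure_sweep(truth, lz)
    lt = equilibrium_circ_stretch(
        truth.params, unl, sweep.pressure_mmhg, np.full(sweep.pressure_mmhg.shape, lz)
    )
    st_true, sz_true = truth.stress_fn(lt, lz)
    st_err = sz_err = 0.0
    for k in range(sweep.pressure_mmhg.size):
        geom = loaded_geometry(unl, sweep.outer_diameter_um[k], lz)
        sz = axial_stress(sweep.force_mn[k], sweep.pressure_mmhg[k], geom)
        sz_err = max(sz_err, abs(sz - sz_true[k]) / abs(sz_true[k]))
        if sweep.pressure_mmhg[k] > 0:
            st = circumferential_stress(sweep.pressure_mmhg[k], geom)
            st_err = max(st_err, abs(st - st_true[k]) / abs(st_true[k]))

    dense = simulate_pressure_sweep(truth, lz, 0.0, 140.0, 0.5)
    lts, sts = [], []
    for p, od in zip(dense.pressure_mmhg, dense.outer_diameter_um):
        geom = loaded_geometry(unl, od, lz)
        lts.append(geom.lambda_theta)
        sts.append(circumferential_stress(p, geom))
    circ = StressStretchCurve("circumferential", np.array(lts), np.array(sts))
    tan_c = tangent_modulus(circ)
    d_t, _ = stress_derivatives(truth.params, tan_c.stretch, lz)
    tan_c_err = float(
        (np.abs(tan_c.e_tan_kpa - d_t) / np.abs(d_t))[2:-2].max()
    )

    grid = np.arange(1.35, 2.05001, 0.01)
    (fl,) = simulate_force_length_test(truth, [90.0], grid)
    szs = [
        axial_stress(f, 90.0, loaded_geometry(unl, od, z))
        for z, od, f in zip(fl.lambda_z, fl.outer_diameter_um, fl.force_mn)
    ]
    axial = StressStretchCurve("axial", fl.lambda_z, np.array(szs))
    tan_z = tangent_modulus(axial)
    # oracle: total derivative of the analytic sigma_z along the solved
    # constant-pressure path, by symmetric fine differences
    eps = 1e-5
    lz_hi, lz_lo = tan_z.stretch + eps, tan_z.stretch - eps
    lt_hi = equilibrium_circ_stretch(truth.params, unl, np.full(lz_hi.shape, 90.0), lz_hi)
    lt_lo = equilibrium_circ_stretch(truth.params, unl, np.full(lz_lo.shape, 90.0), lz_lo)
    _, sz_hi = truth.stress_fn(lt_hi, lz_hi)
    _, sz_lo = truth.stress_fn(lt_lo, lz_lo)
    d_z = (sz_hi - sz_lo) / (2.0 * eps)
    tan_z_err = float((np.abs(tan_z.e_tan_kpa - d_z) / np.abs(d_z))[2:-2].max())

    return {
        "sigma_theta_max_rel_err": float(st_err),
        "sigma_z_max_rel_err": float(sz_err),
        "tangent_circ_max_rel_err": tan_c_err,
        "tangent_axial_max_rel_err": tan_z_err,
    }


def _sample_curve_rows(
    truth: ArteryGroundTruth, group: str, sid: str, rng: np.random.Generator
) -> list[dict]:
    sweep = simulate_pressure_sweep(truth, truth.ivs_true, noisy=True, rng=rng)
    rows = []
    for p, od in zip(sweep.pressure_mmhg, sweep.outer_diameter_um):
        try:
            geom = loaded_geometry(truth.unloaded, od, truth.ivs_true)
        except DegenerateGeometryError:
            continue
        rows.append(
            dict(group=group, sample=sid, x=p, y=circumferential_stress(p, geom))
        )
    return rows


def anova_power_experiment(
    multipliers: list[float],
    n_replicates: int,
    rng: np.random.Generator,
    n_control: int = 7,
    n_stiff: int = 6,
    alpha: float = 0.05,
) -> dict[float, float]:
    """Group-effect rejection rate of the curve-wise two-way ANOVA as a
    function of the stiff group's fiber multiplier (measurement noise
    only; both groups share the IVS setpoint so the multiplier is the only
    systematic difference)."""
    rates = {}
    for mult in multipliers:
        rejections = 0
        for _ in range(n_replicates):
            rows: list[dict] = []
            for i in range(n_control):
                rows += _sample_curve_rows(
                    calibrated_artery(1.85, 1.0), "control", f"c{i}", rng
                )
            for i in range(n_stiff):
                rows += _sample_curve_rows(
                    calibrated_artery(1.85, mult), "stiff", f"s{i}", rng
                )
            res = two_way_anova_curves(pd.DataFrame(rows))
            rejections += res.effects["group"].p < alpha
        rates[mult] = rejections / n_replicates
    return rates


def anova_null_calibration(
    n_replicates: int,
    rng: np.random.Generator,
    n_groups: int = 2,
    n_points: int = 8,
    n_per_cell: int = 4,
    alpha: float = 0.05,
) -> tuple[float, np.ndarray]:
    """Type-I error of the two-way ANOVA group effect under an iid
    Gaussian null; returns (rejection rate, the p-values)."""
    ps = np.empty(n_replicates)
    for r in range(n_replicates):
        rows = [
            dict(group=f"g{g}", x=x, y=rng.normal())
            for g in range(n_groups)
            for x in range(n_points)
            for _ in range(n_per_cell)
        ]
        ps[r] = two_way_anova_curves(pd.DataFrame(rows)).effects["group"].p
    return float((ps < alpha).mean()), ps


def qc_partition_experiment(
    spreads: list[float], threshold: float = 0.25
) -> dict[float, bool]:
    """Construct pressure sweeps whose axial-force spread is exactly the
    requested fraction and report the QC verdicts (True = retained)."""
    pressures = np.arange(0.0, 150.0, 10.0)
    verdicts = {}
    for target in spreads:
        f = np.full(pressures.size, 2.0)
        kept = pressures >= 20.0
        k = int(np.flatnonzero(kept)[-1])
        # one deviant point: max |f - mean| / mean == target  =>  solve for d
        n_kept = int(kept.sum())
        d = target * 2.0 * n_kept / (n_kept - 1 - target)
        f[k] = 2.0 + d
        sweep = PressureSweep(
            axial_stretch=1.85,
            pressure_mmhg=pressures,
            outer_diameter_um=np.full(pressures.size, 500.0),
            force_mn=f,
        )
        spread, ok = qc_axial_force_spread(sweep, threshold=threshold)
        if abs(spread - target) > 1e-9:
            raise AssertionError(f"constructed spread {spread} != target {target}")
        verdicts[target] = ok
    return verdicts
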