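"""Synthetic cohorts: groups of simulated arteries written in the package's
CSV interchange format, with a ground-truth sidecar.

Each group is defined by a fiber-stiffness multiplier (collagen-like
families; > 1 emulates a stiffened phenotype whose circumferential
stress-stretch curve is left-shifted relative to control) and a
ground-truth IVS setpoint reached by calibrating the diagonal fiber
angle.  Per-sample biological variability enters as Gaussian jitter of
the IVS setpoint (each sample's angle is re-calibrated to its own drawn
setpoint) and lognormal jitter of the unloaded geometry; measurement
noise is additive Gaussian on outer diameter and force.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .constitutive import default_params
from .geometry import UnloadedGeometry
from .simulate import (
    ArteryGroundTruth,
    calibrate_to_ivs,
    simulate_force_length_test,
    simulate_pressure_sweep,
)

# jittered per-sample IVS setpoints are clipped to the calibratable band
_IVS_JITTER_RANGE = (1.67, 2.05)


class GroupSpec(BaseModel):
    """One cohort group."""

    name: str
    n: int = Field(ge=2, description="samples per group")
    fiber_multiplier: float = Field(default=1.0, gt=0.0)
    ivs_target: float = Field(default=1.85, gt=1.0)
    ivs_jitter_sd: float = Field(default=0.05, ge=0.0)
    sex: str = "M"
    age_label: str = "2mo"


class CohortConfig(BaseModel):
    """Schema-validated cohort specification (protocol defaults)."""

    groups: list[GroupSpec] = Field(min_length=1)
    seed: int = 0
    fl_pressures: list[float] = Field(default=[90.0, 120.0, 140.0])
    fl_stretch_min: float = 1.3
    fl_stretch_max: float = 2.1
    fl_stretch_increment: float = Field(default=0.1, gt=0.0)
    sweep_min: float = 0.0
    sweep_max: float = 140.0
    sweep_step: float = Field(default=10.0, gt=0.0)
    unloaded_od_um: float = Field(default=400.0, gt=0.0)
    unloaded_h_um: float = Field(default=40.0, gt=0.0)
    geometry_jitter_frac: float = Field(default=0.0, ge=0.0)
    noise_od_sd: float = Field(default=2.0, ge=0.0)
    noise_f_sd: float = Field(default=0.05, ge=0.0)

    @field_validator("fl_pressures")
    @classmethod
    def _pressures_ok(cls, v: list[float]) -> list[float]:
        if len(v) < 2 or any(p < 0 for p in v):
            raise ValueError("fl_pressures must be >= 2 non-negative values")
        return v

    @field_validator("groups")
    @classmethod
    def _unique_names(cls, v: list[GroupSpec]) -> list[GroupSpec]:
        names = [g.name for g in v]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate group names: {names}")
        return v


@dataclass
class CohortData:
    """In-memory cohort bundle mirroring the on-disk CSV layout."""

    recordings: pd.DataFrame
    geometry: pd.DataFrame
    metadata: pd.DataFrame
    ground_truth: dict[str, dict]
    config: CohortConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "recordings": outdir / "recordings.csv",
            "geometry": outdir / "geometry.csv",
            "metadata": outdir / "metadata.csv",
            "ground_truth": outdir / "ground_truth.json",
        }
        self.recordings.to_csv(paths["recordings"], index=False)
        self.geometry.to_csv(paths["geometry"], index=False)
        self.metadata.to_csv(paths["metadata"], index=False)
        paths["ground_truth"].write_text(
            json.dumps(self.ground_truth, indent=2, sort_keys=True)
        )
        return paths


def _fl_grid(config: CohortConfig) -> np.ndarray:
    n = int(round((config.fl_stretch_max - config.fl_stretch_min) / config.fl_stretch_increment))
    return config.fl_stretch_min + config.fl_stretch_increment * np.arange(n + 1)


def generate_cohort(config: CohortConfig) -> CohortData:
    """Simulate every sample of every group and assemble the cohort tables.

    Deterministic in ``config.seed``: identical configs reproduce
    byte-identical CSV files.
    """
    rng = np.random.default_rng(config.seed)
    rec_rows: list[dict] = []
    geo_rows: list[dict] = []
    meta_rows: list[dict] = []
    truth_out: dict[str, dict] = {}
    fl_grid = _fl_grid(config)

    for group in config.groups:
        base = default_params(
            fiber_multiplier=group.fiber_multiplier,
            noise_od_sd=config.noise_od_sd,
            noise_f_sd=config.noise_f_sd,
            seed=config.seed,
        )
        nominal_unloaded = UnloadedGeometry.from_measurements(
            config.unloaded_od_um, config.unloaded_h_um
        )
        params0, ivs0, _ = calibrate_to_ivs(
            base, nominal_unloaded, group.ivs_target, config.fl_pressures
        )
        for i in range(group.n):
            sample_id = f"{group.name}_{i + 1:02d}"
            # biological variability: Gaussian IVS jitter realized by
            # re-calibrating the fiber angle per sample (a linearized angle
            # jitter would skew the IVS distribution, since IVS is a convex
            # function of the angle), plus lognormal geometry jitter
            if group.ivs_jitter_sd > 0.0:
                target_i = float(
                    np.clip(
                        rng.normal(group.ivs_target, group.ivs_jitter_sd),
                        _IVS_JITTER_RANGE[0],
                        _IVS_JITTER_RANGE[1],
                    )
                )
            else:
                target_i = group.ivs_target
            if config.geometry_jitter_frac > 0.0:
                g_od = float(np.exp(rng.normal(0.0, config.geometry_jitter_frac)))
                g_h = float(np.exp(rng.normal(0.0, config.geometry_jitter_frac)))
            else:
                g_od = g_h = 1.0
            unloaded_i = UnloadedGeometry.from_measurements(
                config.unloaded_od_um * g_od, config.unloaded_h_um * g_h
            )
            if target_i == group.ivs_target and g_od == 1.0 and g_h == 1.0:
                params_i, ivs_i = params0, ivs0
            else:
                params_i, ivs_i, _ = calibrate_to_ivs(
                    base, unloaded_i, target_i, config.fl_pressures,
                    grid_step=1e-3, tol=1e-3,
                )
            truth = ArteryGroundTruth(params=params_i, unloaded=unloaded_i, ivs_true=ivs_i)

            curves = simulate_force_length_test(
                truth, config.fl_pressures, fl_grid, noisy=True, rng=rng
            )
            for c in curves:
                for k in range(c.lambda_z.size):
                    rec_rows.append(
                        dict(
                            sample_id=sample_id,
                            test_type="force_length",
                            pressure_mmHg=c.pressure_mmhg,
                            axial_stretch=c.lambda_z[k],
                            outer_diameter_um=c.outer_diameter_um[k],
                            force_mN=c.force_mn[k],
                        )
                    )
            sweep = simulate_pressure_sweep(
                truth, ivs_i, config.sweep_min, config.sweep_max, config.sweep_step,
                noisy=True, rng=rng,
            )
            for k in range(sweep.pressure_mmhg.size):
                rec_rows.append(
                    dict(
                        sample_id=sample_id,
                        test_type="pressure_sweep",
                        pressure_mmHg=sweep.pressure_mmhg[k],
                        axial_stretch=sweep.axial_stretch,
                        outer_diameter_um=sweep.outer_diameter_um[k],
                        force_mN=sweep.force_mn[k],
                    )
                )
            geo_rows.append(
                dict(
                    sample_id=sample_id,
                    unloaded_od_um=unloaded_i.R_o * 2.0,
                    unloaded_h_um=unloaded_i.H,
                    n_sections_averaged=3,
                )
            )
            meta_rows.append(
                dict(
                    sample_id=sample_id,
                    group=group.name,
                    sex=group.sex,
                    age_label=group.age_label,
                )
            )
            truth_out[sample_id] = dict(
                ivs_true=ivs_i,
                c_iso=params_i.c_iso,
                fibers=[asdict(f) for f in params_i.fibers],
                unloaded_od_um=unloaded_i.R_o * 2.0,
                unloaded_h_um=unloaded_i.H,
                fiber_multiplier=group.fiber_multiplier,
            )

    return CohortData(
        recordings=pd.DataFrame(rec_rows),
        geometry=pd.DataFrame(geo_rows),
        metadata=pd.DataFrame(meta_rows),
        ground_truth=truth_out,
        config=config,
    )
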