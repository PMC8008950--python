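"""End-to-end analysis pipeline: recordings -> IVS + QC -> stress-stretch
and tangent-modulus curves -> group summaries -> statistics -> report.

Per-sample failures (degenerate geometry, missing tests, failed QC)
quarantine the sample and are listed in the exclusion log; the pipeline
fails only if an entire group becomes empty.  All outputs are written with
a manifest (content hashes, configuration, versions) for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import UnloadedGeometry
from .io import RecordingBundle, RunConfig
from .ivs import (
    IntersectionError,
    IVSResult,
    QCUndefinedError,
    estimate_ivs,
    qc_axial_force_spread,
)
from .mechanics import build_stress_stretch, tangent_modulus
from .stats import (
    holm_sidak,
    mann_whitney,
    significance_stars,
    summarize_group_curves,
    two_way_anova_curves,
)
from .traces import ForceLengthCurve, PressureSweep

log = logging.getLogger(__name__)


@dataclass
class SampleResult:
    sample_id: str
    group: str
    ivs: IVSResult
    circ_curve: object
    axial_curve: object
    circ_tangent: object
    axial_tangent: object


@dataclass
class PipelineResult:
    samples: list[SampleResult]
    exclusions: list[dict]
    ivs_table: pd.DataFrame
    curve_table: pd.DataFrame
    tangent_table: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    stats: dict
    config: RunConfig


def _force_length_curves(rec: pd.DataFrame, pressures: list[float]) -> list[ForceLengthCurve]:
    fl = rec[rec["test_type"] == "force_length"]
    curves = []
    for p in pressures:
        rows = fl[np.isclose(fl["pressure_mmHg"], p)].sort_values("axial_stretch")
        if len(rows) >= 2:
            curves.append(
                ForceLengthCurve(
                    pressure_mmhg=float(p),
                    lambda_z=rows["axial_stretch"].to_numpy(float),
                    force_mn=rows["force_mN"].to_numpy(float),
                )
            )
    return curves


def _pressure_sweep(rec: pd.DataFrame) -> PressureSweep:
    sw = rec[rec["test_type"] == "pressure_sweep"].sort_values("pressure_mmHg")
    if sw.empty:
        raise ValueError("no pressure_sweep recording")
    return PressureSweep(
        axial_stretch=float(sw["axial_stretch"].iloc[0]),
        pressure_mmhg=sw["pressure_mmHg"].to_numpy(float),
        outer_diameter_um=sw["outer_diameter_um"].to_numpy(float),
        force_mn=sw["force_mN"].to_numpy(float),
    )


def analyze_sample(
    sample_id: str,
    rec: pd.DataFrame,
    unloaded: UnloadedGeometry,
    config: RunConfig,
    group: str = "",
) -> SampleResult:
    """Full single-sample analysis: IVS + QC, both curves, both tangent moduli."""
    curves = _force_length_curves(rec, config.fl_pressures)
    if len(curves) < 2:
        raise ValueError(
            f"sample {sample_id}: force-length tests at >= 2 of the configured "
            f"pressures {config.fl_pressures} are required"
        )
    ivs = estimate_ivs(curves)
    sweep = _pressure_sweep(rec)
    spread, passed = qc_axial_force_spread(
        sweep, config.qc_threshold, config.qc_pressure_floor
    )
    ivs = ivs.with_qc(spread, passed)
    circ = build_stress_stretch(
        rec, unloaded, "circumferential",
        sample_id=sample_id, convention=config.stretch_convention,
    )
    axial = build_stress_stretch(
        rec, unloaded, "axial",
        context_pressure_mmhg=config.axial_context_pressure,
        sample_id=sample_id, convention=config.stretch_convention,
    )
    return SampleResult(
        sample_id=sample_id,
        group=group,
        ivs=ivs,
        circ_curve=circ,
        axial_curve=axial,
        circ_tangent=tangent_modulus(circ, config.tangent_method, config.tangent_window),
        axial_tangent=tangent_modulus(axial, config.tangent_method, config.tangent_window),
    )


def run_pipeline(
    config: RunConfig,
    bundle: RecordingBundle,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Analyze every sample, aggregate by group, and run the comparisons."""
    groups = dict(zip(bundle.metadata["sample_id"], bundle.metadata["group"]))
    geo = bundle.geometry.set_index("sample_id")
    samples: list[SampleResult] = []
    exclusions: list[dict] = []

    for sid in bundle.sample_ids():
        rec = bundle.recordings[bundle.recordings["sample_id"] == sid]
        try:
            unloaded = UnloadedGeometry.from_measurements(
                float(geo.loc[sid, "unloaded_od_um"]), float(geo.loc[sid, "unloaded_h_um"])
            )
            result = analyze_sample(sid, rec, unloaded, config, groups.get(sid, "all"))
        except (ValueError, IntersectionError, QCUndefinedError) as exc:
            exclusions.append({"sample_id": sid, "reason": str(exc)})
            log.warning("sample %s quarantined: %s", sid, exc)
            continue
        if not result.ivs.qc_pass:
            exclusions.append(
                {
                    "sample_id": sid,
                    "reason": (
                        f"axial force varied from the mean by "
                        f"{100 * result.ivs.qc_force_spread:.1f}% (> "
                        f"{100 * config.qc_threshold:.0f}%) with pressure"
                    ),
                }
            )
            log.info("sample %s excluded by axial-force QC", sid)
            continue
        samples.append(result)

    group_counts = pd.Series([s.group for s in samples]).value_counts()
    for g in set(groups.values()):
        if g not in group_counts.index:
            raise RuntimeError(f"group {g!r} has no samples surviving QC")

    ivs_table = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "ivs": s.ivs.ivs,
                "spread": s.ivs.spread,
                "qc_force_spread": s.ivs.qc_force_spread,
                "qc_pass": s.ivs.qc_pass,
                "low_confidence": s.ivs.low_confidence,
            }
            for s in samples
        ]
    )

    curve_rows, tangent_rows = [], []
    for s in samples:
        for curve, tang in ((s.circ_curve, s.circ_tangent), (s.axial_curve, s.axial_tangent)):
            ctx = curve.context_pressure_mmhg
            for k in range(len(curve)):
                curve_rows.append(
                    {
                        "sample_id": s.sample_id,
                        "group": s.group,
                        "axis": curve.axis,
                        "x": curve.stretch[k],
                        "y": curve.stress_kpa[k],
                        "pressure_mmHg": (
                            curve.pressure_mmhg[k] if curve.pressure_mmhg is not None else np.nan
                        ),
                        "context_pressure_mmHg": ctx if ctx is not None else np.nan,
                    }
                )
                tangent_rows.append(
                    {
                        "sample_id": s.sample_id,
                        "group": s.group,
                        "axis": curve.axis,
                        "x": tang.stretch[k],
                        "e_tan_kpa": tang.e_tan_kpa[k],
                    }
                )
    curve_table = pd.DataFrame(curve_rows)
    tangent_table = pd.DataFrame(tangent_rows)

    # group summaries: circumferential curves matched on the pressure step,
    # axial curves matched on the protocol stretch grid
    circ = curve_table[curve_table["axis"] == "circumferential"].copy()
    circ["stress"] = circ["y"]
    circ_summary = summarize_group_curves(
        circ, dispersion=config.dispersion_circumferential,
        x_col="pressure_mmHg", y_col="stress",
    )
    circ_stretch_summary = summarize_group_curves(
        circ, dispersion=config.dispersion_circumferential,
        x_col="pressure_mmHg", y_col="x",
    ).rename(columns={"mean": "mean_stretch"})[["group", "pressure_mmHg", "mean_stretch"]]
    axial = curve_table[curve_table["axis"] == "axial"].copy()
    axial_summary = summarize_group_curves(
        axial, dispersion=config.dispersion_axial, x_col="x", y_col="y"
    )

    # statistics vs the reference group
    ref = config.reference_group or (
        sorted(set(groups.values()))[0] if groups else "all"
    )
    stats: dict = {"reference_group": ref, "mann_whitney_ivs": {}, "anova": {}}
    others = [g for g in sorted(set(s.group for s in samples)) if g != ref]
    mw_ps = []
    for g in others:
        x = ivs_table.loc[ivs_table["group"] == ref, "ivs"].to_numpy()
        y = ivs_table.loc[ivs_table["group"] == g, "ivs"].to_numpy()
        res = mann_whitney(x, y)
        mw_ps.append(res.p)
        stats["mann_whitney_ivs"][g] = {
            "U": res.statistic, "p": res.p, "stars": res.stars, "note": res.note,
        }
    if mw_ps:
        adj = holm_sidak(mw_ps)
        for g, a in zip(others, adj):
            stats["mann_whitney_ivs"][g]["p_adjusted"] = float(a)
            stats["mann_whitney_ivs"][g]["stars_adjusted"] = significance_stars(float(a))
    for g in others:
        for axis, df_ax, xc in (
            ("circumferential", circ, "pressure_mmHg"),
            ("axial", axial, "x"),
        ):
            sub = df_ax[df_ax["group"].isin([ref, g])]
            if sub["group"].nunique() < 2:
                continue
            res = two_way_anova_curves(sub, x_col=xc, y_col="y")
            stats["anova"][f"{g}_vs_{ref}_{axis}"] = {
                name: {
                    "F": e.f_stat, "df_num": e.df_num, "df_den": e.df_den,
                    "p": e.p, "stars": e.stars,
                }
                for name, e in res.effects.items()
            }

    result = PipelineResult(
        samples=samples,
        exclusions=exclusions,
        ivs_table=ivs_table,
        curve_table=curve_table,
        tangent_table=tangent_table,
        summaries={
            "circumferential": circ_summary,
            "circumferential_stretch": circ_stretch_summary,
            "axial": axial_summary,
        },
        stats=stats,
        config=config,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(result: PipelineResult, outdir: str | Path) -> Path:
    """Write all result tables, the run report, and the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def save_csv(name: str, df: pd.DataFrame) -> None:
        p = outdir / name
        df.to_csv(p, index=False)
        files[name] = p

    save_csv("ivs_results.csv", result.ivs_table)
    save_csv("stress_stretch_curves.csv", result.curve_table)
    save_csv("tangent_modulus_curves.csv", result.tangent_table)
    for key, df in result.summaries.items():
        save_csv(f"group_summary_{key}.csv", df)
    save_csv("exclusions.csv", pd.DataFrame(result.exclusions, columns=["sample_id", "reason"]))
    (outdir / "stats.json").write_text(json.dumps(result.stats, indent=2, sort_keys=True))
    files["stats.json"] = outdir / "stats.json"
    (outdir / "report.md").write_text(render_report(result))
    files["report.md"] = outdir / "report.md"

    config_json = result.config.model_dump_json(indent=2)
    manifest = {
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": result.config.seed,
        "versions": {
            "arterymech": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "files": {name: _sha256(p) for name, p in sorted(files.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def render_report(result: PipelineResult) -> str:
    """Markdown run report: group IVS summaries, tests, exclusions."""
    lines = ["# Biaxial myography analysis report", ""]
    lines.append("## In-vivo stretch (IVS) by group")
    lines.append("")
    lines.append("| group | n | IVS (mean) | IVS (SD) |")
    lines.append("|---|---|---|---|")
    for g, sub in result.ivs_table.groupby("group"):
        lines.append(
            f"| {g} | {len(sub)} | {sub['ivs'].mean():.3f} | {sub['ivs'].std():.3f} |"
        )
    lines.append("")
    mw = result.stats.get("mann_whitney_ivs", {})
    if mw:
        ref = result.stats["reference_group"]
        lines.append(f"## Mann-Whitney tests on IVS (vs {ref})")
        lines.append("")
        lines.append("| group | U | p | stars | p (Holm-Sidak) |")
        lines.append("|---|---|---|---|---|")
        for g, r in mw.items():
            lines.append(
                f"| {g} | {r['U']:.1f} | {r['p']:.4g} | {r['stars'] or 'NS'} "
                f"| {r.get('p_adjusted', float('nan')):.4g} |"
            )
        lines.append("")
    if result.stats.get("anova"):
        lines.append("## Two-way ANOVA across pressure/stretch-matched curves")
        lines.append("")
        lines.append("| comparison | effect | F | df | p | stars |")
        lines.append("|---|---|---|---|---|---|")
        for cmp_name, effects in result.stats["anova"].items():
            for eff, r in effects.items():
                lines.append(
                    f"| {cmp_name} | {eff} | {r['F']:.3f} | "
                    f"{r['df_num']:.0f}, {r['df_den']:.0f} | {r['p']:.4g} "
                    f"| {r['stars'] or 'NS'} |"
                )
        lines.append("")
    lines.append("## Exclusions")
    lines.append("")
    if result.exclusions:
        for e in result.exclusions:
            lines.append(f"- {e['sample_id']}: {e['reason']}")
    else:
        lines.append("- none")
    lines.append("")
    return "\n".join(lines)
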