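"""CSV interchange formats and run configuration.

All tables are RFC-4180 CSV, UTF-8, '.' decimal, with units embedded in
the column names so um/mm and mN/N mistakes fail loudly:

* recordings.csv — sample_id, test_type (force_length | pressure_sweep),
  pressure_mmHg, axial_stretch, outer_diameter_um, force_mN
* geometry.csv — sample_id, unloaded_od_um, unloaded_h_um,
  n_sections_averaged
* metadata.csv — sample_id, group, sex, age_label
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

log = logging.getLogger(__name__)

RECORDING_COLUMNS = [
    "sample_id",
    "test_type",
    "pressure_mmHg",
    "axial_stretch",
    "outer_diameter_um",
    "force_mN",
]
GEOMETRY_COLUMNS = ["sample_id", "unloaded_od_um", "unloaded_h_um", "n_sections_averaged"]
METADATA_COLUMNS = ["sample_id", "group", "sex", "age_label"]
TEST_TYPES = ("force_length", "pressure_sweep")


class RecordingValidationError(ValueError):
    """Schema or unit violation in an input table, with row numbers."""


@dataclass
class RecordingBundle:
    """Validated recordings + per-sample geometry + group metadata."""

    recordings: pd.DataFrame
    geometry: pd.DataFrame
    metadata: pd.DataFrame

    def sample_ids(self) -> list[str]:
        return sorted(self.recordings["sample_id"].unique())


class RunConfig(BaseModel):
    """Analysis configuration; defaults are the myograph protocol values."""

    fl_pressures: list[float] = Field(
        default=[90.0, 120.0, 140.0],
        description="constant pressures (mmHg) of the force-length tests",
    )
    sweep_min: float = 0.0
    sweep_max: float = 140.0
    sweep_step: float = Field(default=10.0, gt=0.0)
    axial_context_pressure: float = Field(
        default=90.0, description="pressure (mmHg) at which axial curves are built"
    )
    qc_threshold: float = Field(default=0.25, gt=0.0)
    qc_pressure_floor: float = Field(default=20.0, ge=0.0)
    dispersion_circumferential: str = "se"
    dispersion_axial: str = "sd"
    stretch_convention: str = "midwall"
    tangent_method: str = "window"
    tangent_window: int = 5
    reference_group: str | None = None
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())


def _require_columns(
    df: pd.DataFrame, required: list[str], name: str, optional: tuple[str, ...] = ()
) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordingValidationError(f"{name}: missing columns {missing}")
    extra = [c for c in df.columns if c not in required and c not in optional]
    if extra:
        log.warning("%s: unrecognized columns %s preserved", name, extra)


def read_recordings(
    path: str | Path,
    geometry_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
) -> RecordingBundle:
    """Read and validate the recording tables.

    ``path`` may be the recordings CSV (with geometry/metadata CSVs given
    explicitly or found alongside it) or a directory holding
    recordings.csv, geometry.csv, metadata.csv.

    Raises
    ------
    RecordingValidationError
        Missing columns, unknown test types, negative pressures,
        non-positive stretches, duplicate (sample, test, x) keys, or
        samples with recordings but no geometry — each citing row numbers.
    """
    path = Path(path)
    if path.is_dir():
        rec_path = path / "recordings.csv"
        geometry_path = geometry_path or path / "geometry.csv"
        metadata_path = metadata_path or path / "metadata.csv"
    else:
        rec_path = path
        geometry_path = geometry_path or path.parent / "geometry.csv"
        metadata_path = metadata_path or path.parent / "metadata.csv"

    rec = pd.read_csv(rec_path)
    _require_columns(rec, RECORDING_COLUMNS, rec_path.name)

    def rows(mask) -> list[int]:
        # +2: 1-based with the header line
        return [int(i) + 2 for i in rec.index[mask][:10]]

    bad = ~rec["test_type"].isin(TEST_TYPES)
    if bad.any():
        raise RecordingValidationError(
            f"{rec_path.name}: unknown test_type at rows {rows(bad)}"
        )
    bad = rec["pressure_mmHg"] < 0
    if bad.any():
        raise RecordingValidationError(
            f"{rec_path.name}: negative pressure_mmHg at rows {rows(bad)}"
        )
    bad = rec["axial_stretch"] <= 0
    if bad.any():
        raise RecordingValidationError(
            f"{rec_path.name}: non-positive axial_stretch at rows {rows(bad)}"
        )
    key = ["sample_id", "test_type", "pressure_mmHg", "axial_stretch"]
    dup = rec.duplicated(subset=key, keep=False) & rec.duplicated(subset=key, keep="first")
    if dup.any():
        raise RecordingValidationError(
            f"{rec_path.name}: duplicate (sample, test, pressure, stretch) keys "
            f"at rows {rows(dup)}"
        )

    geo = pd.read_csv(geometry_path)
    _require_columns(geo, GEOMETRY_COLUMNS[:3], Path(geometry_path).name, optional=("n_sections_averaged",))
    orphans = sorted(set(rec["sample_id"]) - set(geo["sample_id"]))
    if orphans:
        raise RecordingValidationError(
            f"samples with recordings but no geometry: {orphans}"
        )
    bad_geo = (geo["unloaded_h_um"] <= 0) | (geo["unloaded_h_um"] * 2 >= geo["unloaded_od_um"])
    if bad_geo.any():
        bad_ids = geo.loc[bad_geo, "sample_id"].tolist()
        raise RecordingValidationError(f"invalid unloaded geometry for samples {bad_ids}")

    if metadata_path and Path(metadata_path).exists():
        meta = pd.read_csv(metadata_path)
        _require_columns(meta, METADATA_COLUMNS[:2], Path(metadata_path).name, optional=("sex", "age_label"))
    else:
        meta = pd.DataFrame(
            {"sample_id": sorted(rec["sample_id"].unique()), "group": "all"}
        )
    return RecordingBundle(recordings=rec, geometry=geo, metadata=meta)
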