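"""Survey data model and delimited-text input/output.

A camera-trap survey is two tables:

* **deployments** — one row per station: when the camera was active and the
  land-cover class it sat in.  Effort is measured in trap-days, the interval
  length ``end - start`` in days.
* **detections** — one time-stamped species record per row (the raw unit;
  "human" is an ordinary species label here).

Deployment intervals are closed-open ``[start, end)``: a detection stamped at
exactly ``end`` falls outside the effort window and is rejected.  Timestamps
are timezone-naive local civil time; the analysis only ever uses differences
and time-of-day within one site and season, so no DST arithmetic is needed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LAND_COVERS",
    "SurveyDataset",
    "SurveyValidationError",
    "read_survey",
    "write_survey",
]

#: The six land-cover classes a deployment may carry.
LAND_COVERS = (
    "clearfell",
    "coniferous_plantation",
    "grassland",
    "heathland_shrubland",
    "wetland",
    "woodland",
)

DETECTION_COLUMNS = ["station_id", "species", "timestamp"]
DEPLOYMENT_COLUMNS = ["station_id", "start", "end", "land_cover"]

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"


class SurveyValidationError(ValueError):
    """Raised when an input table violates the survey data model."""


def _canonical_species(s: pd.Series) -> pd.Series:
    out = s.astype(str).str.strip().str.lower().str.replace(r"[\s\-]+", "_", regex=True)
    if (out == "").any() or out.isna().any():
        bad = int(((out == "") | out.isna()).sum())
        raise SurveyValidationError(f"{bad} detection rows have an empty species label")
    return out


@dataclasses.dataclass
class SurveyDataset:
    """A validated survey: deployments, in-window detections, and rejects.

    Parameters
    ----------
    deployments : DataFrame
        Columns ``station_id, start, end, land_cover`` plus derived
        ``duration_days``; one row per station.
    detections : DataFrame
        Columns ``station_id, species, timestamp``; every row lies inside its
        station's deployment window.
    rejects : DataFrame
        Detections that referenced a valid station but fell outside its
        ``[start, end)`` window, with a ``reason`` column.  Kept so that data
        problems are reported, never silently dropped.
    """

    deployments: pd.DataFrame
    detections: pd.DataFrame
    rejects: pd.DataFrame = dataclasses.field(
        default_factory=lambda: pd.DataFrame(columns=DETECTION_COLUMNS + ["reason"])
    )

    def __post_init__(self) -> None:
        self.deployments = _validate_deployments(self.deployments)
        self.detections, extra_rejects = _validate_detections(
            self.detections, self.deployments
        )
        if len(extra_rejects):
            self.rejects = (
                pd.concat([self.rejects, extra_rejects], ignore_index=True)
                if len(self.rejects)
                else extra_rejects
            )

    @property
    def total_trap_days(self) -> float:
        """Total survey effort: sum of deployment durations in days."""
        return float(self.deployments["duration_days"].sum())

    @property
    def species(self) -> list[str]:
        """Sorted species vocabulary observed in the detections."""
        return sorted(self.detections["species"].unique())

    def station_land_cover(self) -> pd.Series:
        return self.deployments.set_index("station_id")["land_cover"]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurveyDataset):
            return NotImplemented
        dep_a = self.deployments.sort_values("station_id").reset_index(drop=True)
        dep_b = other.deployments.sort_values("station_id").reset_index(drop=True)
        det_a = self.detections.sort_values(DETECTION_COLUMNS).reset_index(drop=True)
        det_b = other.detections.sort_values(DETECTION_COLUMNS).reset_index(drop=True)
        return dep_a.equals(dep_b) and det_a.equals(det_b)


def _validate_deployments(dep: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DEPLOYMENT_COLUMNS if c not in dep.columns]
    if missing:
        raise SurveyValidationError(f"deployments table missing columns: {missing}")
    dep = dep.loc[:, [c for c in dep.columns if c in DEPLOYMENT_COLUMNS]].copy()
    dep["station_id"] = dep["station_id"].astype(str)
    if dep["station_id"].duplicated().any():
        dups = sorted(dep.loc[dep["station_id"].duplicated(), "station_id"])
        raise SurveyValidationError(
            f"multiple deployment rows for station(s) {dups}; "
            "the data model allows one deployment per station"
        )
    for col in ("start", "end"):
        dep[col] = _parse_timestamps(dep[col], f"deployments.{col}")
    dep["land_cover"] = (
        dep["land_cover"].astype(str).str.strip().str.lower()
        .str.replace(r"[\s\-&]+", "_", regex=True).str.replace("__", "_", regex=False)
    )
    unknown = sorted(set(dep["land_cover"]) - set(LAND_COVERS))
    if unknown:
        raise SurveyValidationError(
            f"unknown land-cover label(s) {unknown}; allowed: {list(LAND_COVERS)}"
        )
    if (dep["end"] <= dep["start"]).any():
        bad = dep.loc[dep["end"] <= dep["start"], "station_id"].tolist()
        raise SurveyValidationError(f"deployment end <= start for station(s) {bad}")
    dep["duration_days"] = (
        (dep["end"] - dep["start"]).dt.total_seconds() / 86400.0
    )
    return dep.reset_index(drop=True)


def _validate_detections(
    det: pd.DataFrame, dep: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    missing = [c for c in DETECTION_COLUMNS if c not in det.columns]
    if missing:
        raise SurveyValidationError(f"detections table missing columns: {missing}")
    det = det.loc[:, DETECTION_COLUMNS].copy()
    det["station_id"] = det["station_id"].astype(str)
    det["species"] = _canonical_species(det["species"])
    det["timestamp"] = _parse_timestamps(det["timestamp"], "detections.timestamp")

    known = set(dep["station_id"])
    unknown = sorted(set(det["station_id"]) - known)
    if unknown:
        raise SurveyValidationError(
            f"detections reference unknown station(s) {unknown}"
        )

    windows = dep.set_index("station_id")[["start", "end"]]
    start = det["station_id"].map(windows["start"])
    end = det["station_id"].map(windows["end"])
    in_window = (det["timestamp"] >= start) & (det["timestamp"] < end)
    rejects = det.loc[~in_window].copy()
    rejects["reason"] = np.where(
        rejects["timestamp"] < start.loc[rejects.index],
        "before deployment start",
        "at or after deployment end",
    )
    det = det.loc[in_window].sort_values(DETECTION_COLUMNS).reset_index(drop=True)
    return det, rejects.reset_index(drop=True)


def _parse_timestamps(s: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(s, format="ISO8601", errors="coerce")
    if parsed.isna().any():
        rows = (np.flatnonzero(parsed.isna()) + 1).tolist()[:10]
        raise SurveyValidationError(
            f"unparseable ISO-8601 timestamp(s) in {what} at row(s) {rows}"
        )
    return parsed


def read_survey(detections_path, deployments_path) -> SurveyDataset:
    """Read and validate a survey from two CSV files.

    Out-of-window detections go to ``dataset.rejects``; structural problems
    (unknown station, unknown land cover, unparseable timestamp) raise
    :class:`SurveyValidationError`.
    """
    detections_path, deployments_path = Path(detections_path), Path(deployments_path)
    for p in (detections_path, deployments_path):
        if not p.exists():
            raise FileNotFoundError(p)
    det = pd.read_csv(detections_path, dtype=str)
    dep = pd.read_csv(deployments_path, dtype=str)
    return SurveyDataset(deployments=dep, detections=det)


def write_survey(dataset: SurveyDataset, out_dir) -> dict[str, Path]:
    """Write ``detections.csv``, ``deployments.csv`` and (if any) a rejects
    report under ``out_dir``.  ``read_survey`` round-trips the output exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "detections": out_dir / "detections.csv",
        "deployments": out_dir / "deployments.csv",
    }
    det = dataset.detections.copy()
    det["timestamp"] = det["timestamp"].dt.strftime(TIMESTAMP_FORMAT)
    det.to_csv(paths["detections"], index=False)

    dep = dataset.deployments[DEPLOYMENT_COLUMNS].copy()
    for col in ("start", "end"):
        dep[col] = dep[col].dt.strftime(TIMESTAMP_FORMAT)
    dep.to_csv(paths["deployments"], index=False)

    if len(dataset.rejects):
        rej = dataset.rejects.copy()
        rej["timestamp"] = pd.to_datetime(rej["timestamp"]).dt.strftime(TIMESTAMP_FORMAT)
        paths["rejects"] = out_dir / "rejects.csv"
        rej.to_csv(paths["rejects"], index=False)
    return paths
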