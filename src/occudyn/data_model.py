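"""Domain types and plumbing for camera-trap occupancy studies.

The study design is hierarchical: a set of camera stations, each described by
habitat covariates, is surveyed over one or more *seasons*; each season is
divided into short *secondary periods* (default four periods of five days)
that are collapsed to a single detected / not-detected record per station.
This module holds the containers for that structure (stations, detection
events, design, detection history), the delimited-text readers and writers,
and the deterministic data-preparation steps: the independence filter for
raw detections, detection-history construction, covariate standardization,
the collinearity screen, and effort-normalised detection rates.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

HABITATS = ("coast_shrubland", "forest", "meadow")

STATION_COLUMNS = (
    "id",
    "x",
    "y",
    "habitat",
    "elevation",
    "slope",
    "dist_coast",
    "dist_any_water",
    "dist_freshwater",
    "ground_cover",
)

#: station attributes usable as model covariates
COVARIATE_NAMES = (
    "elevation",
    "slope",
    "dist_coast",
    "dist_any_water",
    "dist_freshwater",
    "ground_cover",
)


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class DetectionEvent:
    """A single independent camera-trap detection."""

    station_id: str
    timestamp: dt.datetime


class StationTable:
    """Per-station coordinates, habitat class and covariates.

    Wraps a :class:`pandas.DataFrame` with the columns in
    :data:`STATION_COLUMNS`, indexed positionally; station ids must be
    unique. Distances are planar metres, elevation metres, slope degrees,
    ground cover a percentage in [0, 100].
    """

    def __init__(self, df: pd.DataFrame):
        missing = set(STATION_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"station table missing columns: {sorted(missing)}")
        df = df.loc[:, list(STATION_COLUMNS)].reset_index(drop=True)
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValidationError(f"duplicate station ids: {dupes}")
        bad_hab = set(df["habitat"]) - set(HABITATS)
        if bad_hab:
            raise ValidationError(f"unknown habitat classes: {sorted(bad_hab)}")
        for col in ("dist_coast", "dist_any_water", "dist_freshwater"):
            if (df[col] < 0).any():
                raise ValidationError(f"negative values in {col}")
        if ((df["ground_cover"] < 0) | (df["ground_cover"] > 100)).any():
            raise ValidationError("ground_cover outside [0, 100]")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return self.df["id"].tolist()

    @property
    def coords(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(float)

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        return self.df[list(names)].to_numpy(float)

    @classmethod
    def _from_frame(cls, df: pd.DataFrame) -> "StationTable":
        """Wrap without range validation (for standardized covariates)."""
        out = cls.__new__(cls)
        out.df = df.reset_index(drop=True)
        return out

    def subset(self, mask: np.ndarray | Sequence[bool]) -> "StationTable":
        return StationTable._from_frame(self.df.loc[np.asarray(mask)])

    def inland_subset(self) -> "StationTable":
        """Stations off the marine coast and closer to fresh water than to it.

        This is the site filter for the single-season inland analysis: coastal
        shrubland stations and stations nearer the coast than fresh water are
        excluded, so occupancy–distance relationships are not driven by
        animals commuting along the marine shore.
        """
        df = self.df
        mask = (df["habitat"] != "coast_shrubland") & (
            df["dist_freshwater"] < df["dist_coast"]
        )
        return self.subset(mask.to_numpy())

    @classmethod
    def from_csv(cls, path: str | Path) -> "StationTable":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        _write_csv(self.df, path, header_comment)


@dataclass(frozen=True)
class Season:
    label: str
    start: dt.date
    n_secondary: int = 4
    secondary_len: int = 5

    @property
    def length_days(self) -> int:
        return self.n_secondary * self.secondary_len


@dataclass
class StudyDesign:
    """Season definitions plus per-station operative flags.

    ``active`` maps season label -> set of operative station ids (``None``
    means every station). ``start_offset_days`` shifts a station's deployment
    window within a season; cameras run in sequential groups have non-zero
    offsets.
    """

    seasons: list[Season]
    active: dict[str, set[str] | None] = field(default_factory=dict)
    start_offset_days: dict[str, int] = field(default_factory=dict)

    @property
    def season_labels(self) -> list[str]:
        return [s.label for s in self.seasons]

    def season(self, label: str) -> Season:
        for s in self.seasons:
            if s.label == label:
                return s
        raise KeyError(f"unknown season {label!r}")

    def is_active(self, station_id: str, season_label: str) -> bool:
        ids = self.active.get(season_label)
        return True if ids is None else station_id in ids

    def window(self, station_id: str, season: Season) -> tuple[dt.datetime, dt.datetime]:
        """Half-open operative window [start, end) for one station-season."""
        off = self.start_offset_days.get(station_id, 0)
        start = dt.datetime.combine(season.start, dt.time()) + dt.timedelta(days=off)
        return start, start + dt.timedelta(days=season.length_days)

    def operative_dates(
        self, season_label: str, station_ids: Sequence[str] | None = None
    ) -> list[dt.date]:
        """All calendar dates on which any camera runs in the season."""
        season = self.season(season_label)
        days: set[dt.date] = set()
        ids = station_ids if station_ids is not None else [None]
        for sid in ids:
            if sid is not None and not self.is_active(sid, season_label):
                continue
            start, end = self.window(sid or "", season)
            d = start.date()
            while d < end.date() or (d == end.date() and end.time() != dt.time()):
                days.add(d)
                d += dt.timedelta(days=1)
        return sorted(days)

    def effort(self, station_ids: Sequence[str]) -> np.ndarray:
        """Trap-nights per (station, season); 0 where not operative."""
        out = np.zeros((len(station_ids), len(self.seasons)))
        for t, s in enumerate(self.seasons):
            for i, sid in enumerate(station_ids):
                if self.is_active(sid, s.label):
                    out[i, t] = s.length_days
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "StudyDesign":
        seasons = []
        for s in raw["seasons"]:
            start = s["start"]
            if isinstance(start, str):
                start = dt.date.fromisoformat(start)
            seasons.append(
                Season(
                    label=str(s["label"]),
                    start=start,
                    n_secondary=int(s.get("n_secondary", 4)),
                    secondary_len=int(s.get("secondary_len", 5)),
                )
            )
        active = {k: (set(v) if v is not None else None) for k, v in (raw.get("active") or {}).items()}
        offsets = {str(k): int(v) for k, v in (raw.get("start_offset_days") or {}).items()}
        return cls(seasons=seasons, active=active, start_offset_days=offsets)

    def to_dict(self) -> dict:
        return {
            "seasons": [
                {
                    "label": s.label,
                    "start": s.start.isoformat(),
                    "n_secondary": s.n_secondary,
                    "secondary_len": s.secondary_len,
                }
                for s in self.seasons
            ],
            "active": {k: (sorted(v) if v is not None else None) for k, v in self.active.items()},
            "start_offset_days": dict(self.start_offset_days),
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class DetectionHistory:
    """Site x season x secondary-period detection array with an effort mask.

    ``y`` holds 1.0 (detected), 0.0 (surveyed, not detected) or NaN (station
    not operative). ``effort`` is trap-nights per (site, season).
    """

    y: np.ndarray
    effort: np.ndarray
    site_ids: list[str]
    season_labels: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float)
        self.effort = np.asarray(self.effort, float)
        n, t, _ = self.y.shape
        if self.effort.shape != (n, t):
            raise ValidationError("effort shape does not match y")
        if len(self.site_ids) != n or len(self.season_labels) != t:
            raise ValidationError("labels do not match y dimensions")
        surveyed = self.effort[:, :, None] > 0
        vals = self.y[np.broadcast_to(surveyed, self.y.shape)]
        if not np.isin(vals[~np.isnan(vals)], [0.0, 1.0]).all():
            raise ValidationError("y must be 0/1 where surveyed")
        if not np.isnan(self.y[~np.broadcast_to(surveyed, self.y.shape)]).all():
            raise ValidationError("y must be missing where effort is zero")

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_seasons(self) -> int:
        return self.y.shape[1]

    @property
    def n_secondary(self) -> int:
        return self.y.shape[2]

    def season_slice(self, label: str) -> "DetectionHistory":
        t = self.season_labels.index(label)
        return DetectionHistory(
            y=self.y[:, [t], :],
            effort=self.effort[:, [t]],
            site_ids=list(self.site_ids),
            season_labels=[label],
        )

    def subset_seasons(self, labels: Sequence[str]) -> "DetectionHistory":
        idx = [self.season_labels.index(lab) for lab in labels]
        return DetectionHistory(
            y=self.y[:, idx, :], effort=self.effort[:, idx],
            site_ids=list(self.site_ids), season_labels=list(labels),
        )

    def subset_sites(self, keep_ids: Sequence[str]) -> "DetectionHistory":
        idx = [self.site_ids.index(s) for s in keep_ids]
        return DetectionHistory(
            y=self.y[idx], effort=self.effort[idx],
            site_ids=list(keep_ids), season_labels=list(self.season_labels),
        )

    def naive_occupancy(self) -> np.ndarray:
        """Fraction of surveyed sites with >=1 detection, per season."""
        det = np.nansum(self.y, axis=2) > 0
        surveyed = self.effort > 0
        return np.array(
            [det[surveyed[:, t], t].mean() if surveyed[:, t].any() else np.nan
             for t in range(self.n_seasons)]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        k = self.n_secondary
        for i, sid in enumerate(self.site_ids):
            for t, lab in enumerate(self.season_labels):
                row = {"station_id": sid, "season": lab, "effort": self.effort[i, t]}
                for j in range(k):
                    v = self.y[i, t, j]
                    row[f"k{j + 1}"] = "NA" if np.isnan(v) else int(v)
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        _write_csv(self.to_frame(), path, header_comment)


@dataclass
class CovariateScaling:
    """Mean/SD used to standardize covariates (sample SD, ddof=1)."""

    mean: dict[str, float]
    sd: dict[str, float]
    ddof: int = 1

    def transform(self, name: str, raw: np.ndarray) -> np.ndarray:
        return (np.asarray(raw, float) - self.mean[name]) / self.sd[name]

    def inverse(self, name: str, standardized: np.ndarray) -> np.ndarray:
        return np.asarray(standardized, float) * self.sd[name] + self.mean[name]


# ---------------------------------------------------------------------------
# readers / writers


def _write_csv(df: pd.DataFrame, path: str | Path, header_comment: str | None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_detections(
    path: str | Path, stations: StationTable | None = None
) -> list[DetectionEvent]:
    """Read detection events from CSV with columns station_id, timestamp.

    Timestamps are ISO 8601 at minute resolution. If ``stations`` is given,
    events at unknown stations are rejected.
    """
    df = pd.read_csv(path, comment="#", dtype={"station_id": str})
    if df.empty:
        return []
    known = set(stations.ids) if stations is not None else None
    events = []
    for row in df.itertuples():
        try:
            ts = dt.datetime.fromisoformat(str(row.timestamp))
        except ValueError as exc:
            raise ValidationError(
                f"row {row.Index + 1}: malformed timestamp {row.timestamp!r}"
            ) from exc
        if known is not None and row.station_id not in known:
            raise ValidationError(
                f"row {row.Index + 1}: unknown station id {row.station_id!r}"
            )
        events.append(DetectionEvent(station_id=row.station_id, timestamp=ts))
    return events


def write_detections(
    events: Iterable[DetectionEvent], path: str | Path, header_comment: str | None = None
) -> None:
    df = pd.DataFrame(
        {
            "station_id": [e.station_id for e in events],
            "timestamp": [e.timestamp.isoformat(timespec="minutes") for e in events],
        }
    )
    _write_csv(df, path, header_comment)


# ---------------------------------------------------------------------------
# data preparation


def filter_independent(
    events: Sequence[DetectionEvent],
    min_gap_minutes: float = 60.0,
    per_station: bool = True,
) -> list[DetectionEvent]:
    """Keep only detections separated by more than ``min_gap_minutes``.

    Greedy forward pass per station: an event is kept iff it is the first at
    its station or falls strictly more than the gap after the last *kept*
    event there. A gap of exactly ``min_gap_minutes`` is not independent.
    Stations never interact (set ``per_station=False`` to pool all stations
    into one stream instead). Idempotent.
    """
    if min_gap_minutes <= 0:
        raise ValueError("min_gap_minutes must be > 0")
    gap = dt.timedelta(minutes=min_gap_minutes)
    order = (
        (lambda e: (e.station_id, e.timestamp)) if per_station
        else (lambda e: (e.timestamp, e.station_id))
    )
    last_kept: dict[str, dt.datetime] = {}
    kept = []
    for ev in sorted(events, key=order):
        key = ev.station_id if per_station else ""
        prev = last_kept.get(key)
        if prev is None or ev.timestamp - prev > gap:
            kept.append(ev)
            last_kept[key] = ev.timestamp
    kept.sort(key=lambda e: (e.timestamp, e.station_id))
    return kept


def build_history(
    events: Sequence[DetectionEvent],
    design: StudyDesign,
    stations: StationTable,
) -> DetectionHistory:
    """Collapse events into the site x season x secondary detection array.

    An entry is 1 iff at least one event falls in the half-open 5-day period,
    0 if the station was operative without an event, and missing (NaN) if the
    station was not operative that season. Events outside every season window
    are a validation error.
    """
    ids = stations.ids
    idx = {sid: i for i, sid in enumerate(ids)}
    n = len(ids)
    n_seasons = len(design.seasons)
    k_max = max(s.n_secondary for s in design.seasons)
    y = np.full((n, n_seasons, k_max), np.nan)
    effort = design.effort(ids)
    for t, season in enumerate(design.seasons):
        for sid in ids:
            if design.is_active(sid, season.label):
                y[idx[sid], t, : season.n_secondary] = 0.0
    for ev in events:
        if ev.station_id not in idx:
            raise ValidationError(f"event at unknown station {ev.station_id!r}")
        placed = False
        for t, season in enumerate(design.seasons):
            if not design.is_active(ev.station_id, season.label):
                continue
            start, end = design.window(ev.station_id, season)
            if start <= ev.timestamp < end:
                k = int(
                    (ev.timestamp - start).total_seconds()
                    // (season.secondary_len * 86400)
                )
                y[idx[ev.station_id], t, k] = 1.0
                placed = True
                break
        if not placed:
            raise ValidationError(
                f"event at {ev.station_id} {ev.timestamp.isoformat()} falls outside "
                "every operative season window"
            )
    return DetectionHistory(
        y=y, effort=effort, site_ids=ids, season_labels=design.season_labels
    )


def standardize(
    stations: StationTable, covariate_names: Sequence[str]
) -> tuple[StationTable, CovariateScaling]:
    """Center each named covariate to mean 0 and scale to sample SD 1.

    Returns a new table plus the scaling needed to map response curves back
    to the raw scale. A constant covariate is an error.
    """
    df = stations.df.copy()
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for name in covariate_names:
        x = df[name].to_numpy(float)
        m, s = float(np.mean(x)), float(np.std(x, ddof=1))
        if not s > 0:
            raise ValidationError(f"covariate {name!r} has zero variance")
        means[name], sds[name] = m, s
        df[name] = (x - m) / s
    return StationTable._from_frame(df), CovariateScaling(mean=means, sd=sds)


def collinearity_screen(
    stations: StationTable,
    covariate_names: Sequence[str],
    threshold: float = 0.7,
) -> list[tuple[str, str, float]]:
    """Flag covariate pairs with |Spearman rho| at or above ``threshold``.

    Flagged pairs must not be used together in one model structure; the
    model-building layer refuses such specs unless explicitly overridden.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    flagged = []
    names = list(covariate_names)
    for a_i, a in enumerate(names):
        for b in names[a_i + 1:]:
            rho = stats.spearmanr(stations.df[a], stations.df[b]).statistic
            if abs(rho) >= threshold:
                flagged.append((a, b, float(rho)))
    return flagged


def capture_rate(n_events: int | Sequence, effort_trap_nights: float) -> float:
    """Detections per 100 trap-nights; the study's relative-abundance index."""
    if not np.isscalar(n_events):
        n_events = len(n_events)
    if effort_trap_nights <= 0:
        raise ValueError("effort must be > 0 trap-nights")
    return 100.0 * n_events / effort_trap_nights


def detection_rate_by_distance(
    events: Sequence[DetectionEvent],
    stations: StationTable,
    effort_trap_nights: Mapping[str, float],
    bin_width_m: float = 50.0,
) -> pd.DataFrame:
    """Detection rate per ``bin_width_m`` segment of distance to fresh water.

    Bins are half-open [b, b + width). Rate is detections per 100 trap-nights
    of the stations in the bin; a bin with zero trap-nights has an undefined
    (NaN) rate, not zero. Returns columns bin_left, bin_right, trap_nights,
    n_events, rate_per_100tn.
    """
    if bin_width_m <= 0:
        raise ValueError("bin_width_m must be > 0")
    dist = dict(zip(stations.ids, stations.df["dist_freshwater"]))
    max_d = max(
        [dist[s] for s in effort_trap_nights if s in dist]
        + [dist.get(e.station_id, 0.0) for e in events]
        + [0.0]
    )
    n_bins = int(max_d // bin_width_m) + 1
    effort_bins = np.zeros(n_bins)
    event_bins = np.zeros(n_bins, dtype=int)
    for sid, tn in effort_trap_nights.items():
        if sid in dist:
            effort_bins[int(dist[sid] // bin_width_m)] += tn
    for ev in events:
        if ev.station_id in dist:
            event_bins[int(dist[ev.station_id] // bin_width_m)] += 1
    rate = np.where(
        effort_bins > 0, 100.0 * event_bins / np.where(effort_bins > 0, effort_bins, 1), np.nan
    )
    return pd.DataFrame(
        {
            "bin_left": np.arange(n_bins) * bin_width_m,
            "bin_right": (np.arange(n_bins) + 1) * bin_width_m,
            "trap_nights": effort_bins,
            "n_events": event_bins,
            "rate_per_100tn": rate,
        }
    )
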