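"""Domain types, validation, and dataset I/O for cultivation runs.

Units are fixed package-wide: time in hours, viable cell concentration
(VCC) in 10^6 cells mL^-1, product titer and analyte concentrations in
g L^-1, volumes in L, specific rates internally in h^-1.

A dataset on disk is a directory with

- ``runs.csv``     -- long format, columns ``run_id,time_h,variable,value``
  (variables: ``vcc``, ``viability``, ``titer`` and the analyte names),
- ``designs.json`` -- per-run design, feed schedule and volume trace,
- ``manifest.yaml`` -- counts, run ids and provenance metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Analytes measured at every sampling point (supernatant concentrations, g/L).
ANALYTE_NAMES: tuple[str, ...] = (
    "glucose",
    "glutamine",
    "asparagine",
    "alanine",
    "aspartate",
    "glutamate",
    "serine",
    "glycine",
    "tyrosine",
    "hydroxyproline",
    "proline",
)

#: Feed glucose level -> added d-glucose on top of the base feed medium (g/L).
FEED_LEVEL_GLUCOSE: dict[str, float] = {"F1": 10.0, "F2": 20.0, "F3": 30.0}

#: Temperatures used in the factorial designs (one bioreactor run uses 36.3).
DESIGN_TEMPERATURES: tuple[float, ...] = (31.0, 34.0, 37.0, 36.3)

#: Seeding density common to every cultivation (10^6 cells/mL).
SEEDING_DENSITY: float = 0.25

#: End of the batch phase / start of fed-batch (h).
BATCH_END_H: float = 72.0


@dataclass(frozen=True)
class Segment:
    """One constant-CPP stretch of a design.

    Parameters
    ----------
    start_time : float
        Hours from inoculation at which the segment becomes active.
    temperature : float
        Cultivation temperature set point, degrees C.
    feed_level : str
        Feed glucose level, one of ``F1``, ``F2``, ``F3``.
    """

    start_time: float
    temperature: float
    feed_level: str


@dataclass
class Design:
    """Batch + fed-batch CPP profile of one cultivation.

    ``segments`` are the fed-batch segments; the batch phase (before
    ``batch_end``) is always run at 37 degrees C without feeding.  Static
    designs have exactly one fed-batch segment; intensified designs add
    intra-experimental CPP shifts as further segments.
    """

    doe_mode: str  # "static" | "intensified"
    segments: list[Segment]
    batch_end: float = BATCH_END_H
    planned_duration: float = 360.0

    @property
    def shift_times(self) -> list[float]:
        """Times of intra-experimental CPP shifts (excludes fed-batch onset)."""
        return [s.start_time for s in self.segments[1:]]

    def segment_at(self, t: float) -> Segment:
        """Active fed-batch segment at time ``t`` (right-continuous)."""
        active = self.segments[0]
        for seg in self.segments:
            if t >= seg.start_time:
                active = seg
        return active


@dataclass
class FeedSchedule:
    """Feeding mode and feed-medium composition.

    ``mode`` is ``"bolus"`` (daily additions, shake flasks; 3.3% v/v per
    day) or ``"continuous"`` (constant inflow, bioreactors).  For
    continuous mode an explicit flow profile may be given as step
    functions ``rate_times``/``rate_flows`` (L/h); if absent, a constant
    flow delivering the same cumulative v/v per day as the bolus fraction
    is assumed.  ``composition`` maps each feed level to the analyte
    concentrations of that feed medium (g/L).
    """

    mode: str  # "bolus" | "continuous"
    bolus_fraction: float = 0.033  # v/v per day
    rate_times: list[float] | None = None
    rate_flows: list[float] | None = None
    composition: dict[str, dict[str, float]] = field(default_factory=dict)

    def flow_at(self, t: float, initial_volume: float) -> float:
        """Continuous feed flow (L/h) at time ``t`` (0 before fed-batch)."""
        if self.mode != "continuous":
            return 0.0
        if self.rate_times is not None and self.rate_flows is not None:
            idx = int(np.searchsorted(self.rate_times, t, side="right")) - 1
            if idx < 0:
                return 0.0
            return float(self.rate_flows[idx])
        return self.bolus_fraction * initial_volume / 24.0


@dataclass
class SampleSeries:
    """Offline measurements of one run at the sampling times."""

    times: np.ndarray  # h, strictly increasing, starting at 0
    vcc: np.ndarray  # 10^6 cells/mL
    viability: np.ndarray  # percent
    titer: np.ndarray  # g/L
    analytes: dict[str, np.ndarray]  # name -> g/L

    def n_samples(self) -> int:
        return len(self.times)


@dataclass
class CultivationRun:
    """One cultivation experiment: design, feeding, and sampled series."""

    run_id: str
    scale: str  # "shake_flask" | "bioreactor"
    working_volume: float  # L (0.3 or 15)
    design: Design
    feed: FeedSchedule
    samples: SampleSeries
    seeding_density: float = SEEDING_DENSITY
    volume_times: np.ndarray | None = None  # h
    volume_l: np.ndarray | None = None  # L

    def volume_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Broth volume (L) at time ``t``, linearly interpolated."""
        if self.volume_times is None or self.volume_l is None:
            return np.broadcast_to(self.working_volume, np.shape(t)).astype(float) if np.ndim(t) else self.working_volume
        return np.interp(t, self.volume_times, self.volume_l)


@dataclass
class PredictionResult:
    """Ensemble-averaged prediction with per-time SD and CI bands."""

    times: np.ndarray
    x_hat: np.ndarray  # VCC, 10^6 cells/mL
    p_hat: np.ndarray  # titer, g/L
    sd_x: np.ndarray
    sd_p: np.ndarray
    ci_x_lower: np.ndarray
    ci_x_upper: np.ndarray
    ci_p_lower: np.ndarray
    ci_p_upper: np.ndarray


# ---------------------------------------------------------------------------
# validation


def _finite(a) -> bool:
    return bool(np.all(np.isfinite(np.asarray(a, dtype=float))))


def validate_run(run: CultivationRun) -> list[str]:
    """Check every type invariant of ``run``; never raises.

    Returns a list of human-readable violation descriptions, empty iff the
    run is well formed.  Each violation names the offending field and rule.
    """
    v: list[str] = []
    try:
        if run.scale not in ("shake_flask", "bioreactor"):
            v.append(f"scale: unknown scale {run.scale!r}")
        if run.scale == "shake_flask" and run.feed.mode != "bolus":
            v.append("feed.mode: shake_flask runs must use bolus feeding")
        if run.scale == "bioreactor" and run.feed.mode != "continuous":
            v.append("feed.mode: bioreactor runs must use continuous feeding")
        if not np.isclose(run.seeding_density, SEEDING_DENSITY):
            v.append(
                f"seeding_density: expected {SEEDING_DENSITY}, got {run.seeding_density}"
            )
        if run.working_volume <= 0:
            v.append("working_volume: must be positive")

        d = run.design
        if d.doe_mode not in ("static", "intensified"):
            v.append(f"design.doe_mode: unknown mode {d.doe_mode!r}")
        if not d.segments:
            v.append("design.segments: at least one fed-batch segment required")
        else:
            starts = [s.start_time for s in d.segments]
            if any(b <= a for a, b in zip(starts, starts[1:])):
                v.append("design.segments: start times must be strictly increasing")
            if abs(starts[0] - d.batch_end) > 1e-9:
                v.append(
                    "design.segments: first fed-batch segment must start at "
                    f"batch_end ({d.batch_end} h), got {starts[0]} h"
                )
            for seg in d.segments:
                if seg.temperature not in DESIGN_TEMPERATURES:
                    v.append(
                        f"design.segments: temperature {seg.temperature} not a "
                        f"design level {DESIGN_TEMPERATURES}"
                    )
                if seg.feed_level not in FEED_LEVEL_GLUCOSE:
                    v.append(
                        f"design.segments: unknown feed level {seg.feed_level!r}"
                    )
            if d.doe_mode == "static" and len(d.segments) != 1:
                v.append("design.segments: static designs have exactly one segment")

        f = run.feed
        if f.mode not in ("bolus", "continuous"):
            v.append(f"feed.mode: unknown mode {f.mode!r}")
        if not (0.0 < f.bolus_fraction < 0.1):
            v.append("feed.bolus_fraction: must lie in (0, 0.1)")
        if f.rate_flows is not None and any(q < 0 for q in f.rate_flows):
            v.append("feed.rate_flows: feed flow must be non-negative")
        used_levels = {s.feed_level for s in d.segments}
        missing = used_levels - set(f.composition)
        if f.composition and missing:
            v.append(
                "feed.composition: missing feed levels "
                + ", ".join(sorted(missing))
            )

        s = run.samples
        t = np.asarray(s.times, dtype=float)
        if len(t) == 0 or t[0] != 0.0:
            v.append("samples.times: must start at 0")
        if np.any(np.diff(t) <= 0):
            v.append("samples.times: must be strictly increasing")
        for name, arr in (("vcc", s.vcc), ("viability", s.viability), ("titer", s.titer)):
            arr = np.asarray(arr, dtype=float)
            if len(arr) != len(t):
                v.append(f"samples.{name}: length differs from samples.times")
            elif not _finite(arr):
                v.append(f"samples.{name}: missing or non-finite values")
        if _finite(s.vcc) and np.any(np.asarray(s.vcc) < 0):
            v.append("samples.vcc: must be non-negative")
        if _finite(s.viability) and (
            np.any(np.asarray(s.viability) < 0) or np.any(np.asarray(s.viability) > 100)
        ):
            v.append("samples.viability: must lie in [0, 100]")
        if _finite(s.titer) and np.any(np.asarray(s.titer) < 0):
            v.append("samples.titer: must be non-negative")
        for name in ANALYTE_NAMES:
            if name not in s.analytes:
                v.append(f"samples.analytes.{name}: missing series")
                continue
            arr = np.asarray(s.analytes[name], dtype=float)
            if len(arr) != len(t):
                v.append(f"samples.analytes.{name}: length differs from samples.times")
            elif not _finite(arr):
                v.append(f"samples.analytes.{name}: missing or non-finite values")
            elif np.any(arr < 0):
                v.append(f"samples.analytes.{name}: must be non-negative")

        if run.volume_l is not None:
            if np.any(np.asarray(run.volume_l) <= 0):
                v.append("volume_trace: volume must be positive")
    except Exception as exc:  # validation is total by contract
        v.append(f"validation: internal error while validating ({exc})")
    return v


# ---------------------------------------------------------------------------
# dataset I/O


class DatasetFormatError(ValueError):
    """Raised when a dataset file does not follow the expected dialect."""


def _design_to_dict(run: CultivationRun) -> dict:
    return {
        "run_id": run.run_id,
        "scale": run.scale,
        "working_volume": run.working_volume,
        "seeding_density": run.seeding_density,
        "design": {
            "doe_mode": run.design.doe_mode,
            "batch_end": run.design.batch_end,
            "planned_duration": run.design.planned_duration,
            "segments": [
                {
                    "start_time": s.start_time,
                    "temperature": s.temperature,
                    "feed_level": s.feed_level,
                }
                for s in run.design.segments
            ],
        },
        "feed": {
            "mode": run.feed.mode,
            "bolus_fraction": run.feed.bolus_fraction,
            "rate_times": run.feed.rate_times,
            "rate_flows": run.feed.rate_flows,
            "composition": run.feed.composition,
        },
        "volume_times": None if run.volume_times is None else list(map(float, run.volume_times)),
        "volume_l": None if run.volume_l is None else list(map(float, run.volume_l)),
    }


def _design_from_dict(d: dict, source: str) -> CultivationRun:
    try:
        segs = []
        for s in d["design"]["segments"]:
            if s["feed_level"] not in FEED_LEVEL_GLUCOSE:
                raise DatasetFormatError(
                    f"{source}: unknown feed level {s['feed_level']!r} in run "
                    f"{d.get('run_id')!r}"
                )
            segs.append(
                Segment(
                    start_time=float(s["start_time"]),
                    temperature=float(s["temperature"]),
                    feed_level=str(s["feed_level"]),
                )
            )
        starts = [s.start_time for s in segs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise DatasetFormatError(
                f"{source}: segment start times not strictly increasing in run "
                f"{d.get('run_id')!r} (Design invariant)"
            )
        design = Design(
            doe_mode=str(d["design"]["doe_mode"]),
            segments=segs,
            batch_end=float(d["design"]["batch_end"]),
            planned_duration=float(d["design"]["planned_duration"]),
        )
        feed = FeedSchedule(
            mode=str(d["feed"]["mode"]),
            bolus_fraction=float(d["feed"]["bolus_fraction"]),
            rate_times=d["feed"]["rate_times"],
            rate_flows=d["feed"]["rate_flows"],
            composition={
                lvl: {k: float(x) for k, x in comp.items()}
                for lvl, comp in d["feed"]["composition"].items()
            },
        )
        return CultivationRun(
            run_id=str(d["run_id"]),
            scale=str(d["scale"]),
            working_volume=float(d["working_volume"]),
            design=design,
            feed=feed,
            samples=SampleSeries(
                times=np.empty(0), vcc=np.empty(0), viability=np.empty(0),
                titer=np.empty(0), analytes={},
            ),
            seeding_density=float(d["seeding_density"]),
            volume_times=None if d.get("volume_times") is None else np.asarray(d["volume_times"], dtype=float),
            volume_l=None if d.get("volume_l") is None else np.asarray(d["volume_l"], dtype=float),
        )
    except KeyError as exc:
        raise DatasetFormatError(f"{source}: missing key {exc} in design record") from exc


def save_dataset(runs: list[CultivationRun], path: str | Path) -> Path:
    """Write ``runs`` to directory ``path`` (created if needed).

    Returns the dataset directory.  Numeric values are written with full
    precision so that ``load_dataset(save_dataset(runs))`` round-trips to
    within 1e-12.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    records = []
    for run in runs:
        s = run.samples
        for name, arr in (
            ("vcc", s.vcc),
            ("viability", s.viability),
            ("titer", s.titer),
            *((a, s.analytes[a]) for a in ANALYTE_NAMES if a in s.analytes),
        ):
            for t, val in zip(s.times, arr):
                records.append((run.run_id, float(t), name, float(val)))
    df = pd.DataFrame(records, columns=["run_id", "time_h", "variable", "value"])
    df.to_csv(path / "runs.csv", index=False, float_format="%.17g")

    with open(path / "designs.json", "w") as fh:
        json.dump([_design_to_dict(r) for r in runs], fh, indent=1)

    manifest = {
        "n_runs": len(runs),
        "run_ids": [r.run_id for r in runs],
        "format": "hybridoe-dataset-v1",
    }
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return path


def load_dataset(path: str | Path) -> list[CultivationRun]:
    """Load a dataset directory written by :func:`save_dataset`.

    Raises :class:`DatasetFormatError` naming the file, line and column of
    the first malformed value encountered.
    """
    path = Path(path)
    runs_csv = path / "runs.csv"
    designs_json = path / "designs.json"
    if not runs_csv.exists():
        raise DatasetFormatError(f"{runs_csv}: file not found")
    if not designs_json.exists():
        raise DatasetFormatError(f"{designs_json}: file not found")

    df = pd.read_csv(runs_csv, dtype={"run_id": str, "variable": str})
    expected = ["run_id", "time_h", "variable", "value"]
    if list(df.columns) != expected:
        raise DatasetFormatError(
            f"{runs_csv}: expected columns {expected}, got {list(df.columns)}"
        )
    for col in ("time_h", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based indexing
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise DatasetFormatError(
                f"{runs_csv}: line {line}: non-numeric value in column {col!r}"
            )
        df[col] = coerced

    with open(designs_json) as fh:
        design_dicts = json.load(fh)
    runs = [_design_from_dict(d, str(designs_json)) for d in design_dicts]

    by_id = {r.run_id: r for r in runs}
    for run_id, grp in df.groupby("run_id", sort=False):
        if run_id not in by_id:
            raise DatasetFormatError(
                f"{runs_csv}: run {run_id!r} has samples but no design record"
            )
        wide = grp.pivot_table(index="time_h", columns="variable", values="value")
        times = wide.index.to_numpy(dtype=float)
        run = by_id[run_id]

        def col(name: str) -> np.ndarray:
            if name not in wide.columns:
                raise DatasetFormatError(
                    f"{runs_csv}: run {run_id!r} is missing variable {name!r}"
                )
            return wide[name].to_numpy(dtype=float)

        run.samples = SampleSeries(
            times=times,
            vcc=col("vcc"),
            viability=col("viability"),
            titer=col("titer"),
            analytes={a: col(a) for a in ANALYTE_NAMES if a in wide.columns},
        )
    return runs
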