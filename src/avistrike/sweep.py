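"""Monte-Carlo parameter sweep over the full collision-model grid.

Every unique combination of escape speed, sensory-motor delay, distance to
safety, approach speed, light temporal benefit and light scenario is a
*cell*; each cell is evaluated with a fixed number of seeded Monte-Carlo
iterations in which the behavioral inputs (escape angle and flight-initiation
distance) are drawn afresh, the phase-one race is run, and phase two converts
the surviving interactions into collision probabilities.

Each cell's random stream is derived from ``SeedSequence(master_seed,
spawn_key=(cell_index,))``, so cells are statistically independent,
order-insensitive and individually re-runnable.  Cell statistics are either
the mean phase-two probability (expectation mode, default) or the fraction of
Bernoulli outcomes drawn from those probabilities.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from pathlib import Path
from typing import Iterator, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .behavior import LightScenario, sample_behavior
from .config import DEFAULT_CONFIG
from .kinematics import time_available_arrays
from .silhouette import FrontalSilhouette, length_to_pixels, window_probability

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterGrid",
    "PredictionRecord",
    "AggregatedCurve",
    "SweepResult",
    "build_grid",
    "run_cell",
    "run_sweep",
    "aggregate_by_cell",
    "aggregate_by_behavior",
    "write_outputs",
]

#: names of the systematically manipulated grid axes, in cell-enumeration order
GRID_AXES = ("sa", "delta", "d_min", "sv", "beta")


@dataclasses.dataclass(frozen=True)
class ParameterGrid:
    """The full factorial sweep definition."""

    escape_speeds: np.ndarray
    delays: np.ndarray
    d_mins: np.ndarray
    approach_speeds: np.ndarray
    betas: np.ndarray
    scenarios: Tuple[LightScenario, ...]
    iterations: int

    def __post_init__(self) -> None:
        for name in ("escape_speeds", "delays", "d_mins", "approach_speeds", "betas"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"{name} must be a non-empty 1-D sequence")
            object.__setattr__(self, name, arr)
        if not self.scenarios:
            raise ValueError("at least one light scenario is required")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def axis_lengths(self) -> Tuple[int, ...]:
        return (
            len(self.scenarios),
            self.escape_speeds.size,
            self.delays.size,
            self.d_mins.size,
            self.approach_speeds.size,
            self.betas.size,
        )

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.axis_lengths))

    @property
    def total_predictions(self) -> int:
        return self.n_cells * self.iterations

    def cells(self) -> Iterator[tuple]:
        """Yield ``(index, scenario, sa, delta, d_min, sv, beta)`` in canonical order."""
        combos = itertools.product(
            self.scenarios,
            self.escape_speeds,
            self.delays,
            self.d_mins,
            self.approach_speeds,
            self.betas,
        )
        for index, (sc, sa, delta, d_min, sv, beta) in enumerate(combos):
            yield index, sc, sa, delta, d_min, sv, beta

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for name in ("escape_speeds", "delays", "d_mins", "approach_speeds", "betas"):
            h.update(name.encode())
            h.update(np.asarray(getattr(self, name), dtype=float).tobytes())
        for sc in self.scenarios:
            h.update(repr(sc).encode())
        h.update(str(self.iterations).encode())
        return h.hexdigest()[:16]


def _linspace_axis(cfg: dict, key: str) -> np.ndarray:
    try:
        axis = cfg[key]
        start, stop, count = axis["start"], axis["stop"], axis["count"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed config for axis {key!r}") from exc
    if count < 1 or stop < start:
        raise ValueError(f"axis {key!r}: need count >= 1 and stop >= start")
    return np.linspace(float(start), float(stop), int(count))


def build_grid(config: Optional[dict] = None) -> ParameterGrid:
    """Construct the sweep grid from a config mapping (defaults if None).

    Axes are evenly spaced between their endpoints with the stated counts;
    the defaults reproduce the published grid exactly (e.g. ten d_min values
    from 1 to 14.35 m give the quoted 1.48-m increment, fifteen approach
    speeds from 70.47 to 270.97 m/s give the 14.32-m/s increment).
    """
    from .config import merge_config

    cfg = merge_config(DEFAULT_CONFIG, config)
    if config and "scenarios" in config:
        # scenario set is a selection, not a patch: replace wholesale
        cfg["scenarios"] = config["scenarios"]
    fid = cfg["fid"]
    scenarios = tuple(
        LightScenario(
            kind=kind,
            p_away=float(sc_cfg["p_away"]),
            fid_mean=float(fid["mean"]),
            fid_sd=float(fid["sd"]),
        )
        for kind, sc_cfg in cfg["scenarios"].items()
    )
    return ParameterGrid(
        escape_speeds=_linspace_axis(cfg, "escape_speed"),
        delays=_linspace_axis(cfg, "delay"),
        d_mins=_linspace_axis(cfg, "d_min"),
        approach_speeds=_linspace_axis(cfg, "approach_speed"),
        betas=_linspace_axis(cfg, "beta"),
        scenarios=scenarios,
        iterations=int(cfg["iterations"]),
    )


# ---------------------------------------------------------------------------
# Cell evaluation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PredictionRecord:
    """One model evaluation: sampled inputs, phase times, outcome."""

    scenario: str
    sa: float
    delta: float
    d_min: float
    sv: float
    beta: float
    theta: float
    d_fid: float
    away: bool
    t_a: float
    t_v: float
    collision_possible: bool
    d_collision: float
    p_collision: float
    outcome: Optional[bool] = None


RECORD_COLUMNS = [f.name for f in dataclasses.fields(PredictionRecord)]


def _cell_rng(master_seed: int, cell_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(cell_index,))
    )


def _simulate_cell(
    silhouette: FrontalSilhouette,
    body_length: float,
    sa: float,
    delta: float,
    d_min: float,
    sv: float,
    beta: float,
    scenario: LightScenario,
    n: int,
    rng: np.random.Generator,
    mode: str,
    lateral_term: str,
    alert_speed: str,
) -> dict:
    """Vectorized evaluation of one grid cell (n iterations)."""
    sc = scenario if scenario.beta == beta else dataclasses.replace(scenario, beta=beta)
    speed = sv if alert_speed == "vehicle" else sa
    theta, d_fid, away = sample_behavior(sc, speed, rng, size=n)
    rad = np.radians(theta)
    sin_t = np.sin(rad)
    cos_t = np.cos(rad)
    # phase one: race between clearing time and arrival time
    t_a = (d_min + body_length) / (sin_t * sa) + delta if sa > 0 else np.full(n, np.inf)
    t_v = time_available_arrays(d_fid, sv, sa, theta)
    possible = t_a >= t_v
    # phase two: drift within the trajectory, then window occupancy
    drift = (cos_t if lateral_term == "cos" else sin_t) * sa * t_v
    d_collision = (silhouette.width_m - d_min) + drift
    p = np.where(possible, window_probability(silhouette, d_collision, body_length), 0.0)
    out = {
        "theta": theta, "d_fid": d_fid, "away": away,
        "t_a": t_a, "t_v": t_v, "collision_possible": possible,
        "d_collision": d_collision, "p_collision": p,
    }
    if mode == "bernoulli":
        out["outcome"] = rng.random(n) < p
    elif mode != "expectation":
        raise ValueError("mode must be 'expectation' or 'bernoulli'")
    return out


def run_cell(
    silhouette: FrontalSilhouette,
    body_length: float,
    sa: float,
    delta: float,
    d_min: float,
    sv: float,
    beta: float,
    scenario: LightScenario,
    iterations: int,
    seed: int,
    mode: str = "expectation",
    lateral_term: str = "sin",
    alert_speed: str = "vehicle",
) -> list:
    """Evaluate one cell and return its per-iteration prediction records."""
    if d_min > silhouette.width_m:
        raise ValueError("d_min cannot exceed the trajectory width")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    arrays = _simulate_cell(
        silhouette, body_length, sa, delta, d_min, sv, beta, scenario,
        iterations, rng, mode, lateral_term, alert_speed,
    )
    outcomes = arrays.get("outcome")
    return [
        PredictionRecord(
            scenario=scenario.kind, sa=float(sa), delta=float(delta),
            d_min=float(d_min), sv=float(sv), beta=float(beta),
            theta=float(arrays["theta"][i]), d_fid=float(arrays["d_fid"][i]),
            away=bool(arrays["away"][i]), t_a=float(arrays["t_a"][i]),
            t_v=float(arrays["t_v"][i]),
            collision_possible=bool(arrays["collision_possible"][i]),
            d_collision=float(arrays["d_collision"][i]),
            p_collision=float(arrays["p_collision"][i]),
            outcome=None if outcomes is None else bool(outcomes[i]),
        )
        for i in range(iterations)
    ]


def records_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    if not records:
        raise ValueError("empty record set")
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# Sweep
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AggregatedCurve:
    """Mean collision probability along one axis, per light scenario."""

    axis: str
    table: pd.DataFrame  # columns: scenario, value, mean_p, sd_p, n


@dataclasses.dataclass
class SweepResult:
    """Streamed sweep output: per-cell statistics plus behavioral histograms."""

    grid: ParameterGrid
    cells: pd.DataFrame  # per cell: scenario, sa..beta, mean_p, sd_p, possible_frac, n
    fid_hist: dict  # scenario -> (p_sum, count) arrays over 0.1-m FID bins
    angle_hist: dict  # scenario -> (p_sum, count) arrays over 0.1-deg bins
    bin_width: float
    manifest: dict
    records: Optional[pd.DataFrame] = None

    def grand_means(self) -> pd.DataFrame:
        """Mean +- SD of the per-cell probabilities for each scenario."""
        g = self.cells.groupby("scenario", sort=False)["mean_p"]
        out = g.agg(mean_p="mean", sd_p="std", n="count").reset_index()
        return out

    def marginal(self, axis: str) -> AggregatedCurve:
        """Mean +- SD of cell probabilities at each value of one grid axis."""
        if axis not in GRID_AXES:
            raise ValueError(f"axis must be one of {GRID_AXES}")
        g = (
            self.cells.groupby(["scenario", axis], sort=True)["mean_p"]
            .agg(mean_p="mean", sd_p="std", n="count")
            .reset_index()
            .rename(columns={axis: "value"})
        )
        return AggregatedCurve(axis=axis, table=g)

    def behavior_curve(self, axis: str) -> AggregatedCurve:
        """Binned mean probability over a sampled behavioral variable.

        ``axis`` is ``"d_fid"`` (0.1-m bins) or ``"theta"`` (0.1-deg bins);
        bins that received no prediction are omitted.
        """
        hist = {"d_fid": self.fid_hist, "theta": self.angle_hist}[axis]
        frames = []
        for kind, (p_sum, count) in hist.items():
            nz = count > 0
            values = np.nonzero(nz)[0] * self.bin_width
            frames.append(
                pd.DataFrame(
                    {
                        "scenario": kind,
                        "value": values,
                        "mean_p": p_sum[nz] / count[nz],
                        "n": count[nz],
                    }
                )
            )
        return AggregatedCurve(axis=axis, table=pd.concat(frames, ignore_index=True))


def run_sweep(
    grid: ParameterGrid,
    silhouette: FrontalSilhouette,
    seed: int,
    body_length: float = DEFAULT_CONFIG["body_length"],
    mode: str = "expectation",
    lateral_term: str = "sin",
    alert_speed: str = "vehicle",
    bin_width: float = 0.1,
    collect_records: bool = False,
    log_every: int = 0,
) -> SweepResult:
    """Run the full grid with per-cell seeded Monte-Carlo iterations.

    Returns per-cell mean probabilities (expectation mode) or collision
    fractions (Bernoulli mode) plus streamed 0.1-unit histograms of
    probability against flight-initiation distance and escape angle.
    ``collect_records`` additionally keeps every prediction (memory grows
    with ``grid.total_predictions``; intended for small grids).
    """
    if float(np.max(grid.d_mins)) > silhouette.width_m + 1e-9:
        raise ValueError("grid d_min values exceed the trajectory width")
    n_cells = grid.n_cells
    n = grid.iterations
    stat_col = "outcome" if mode == "bernoulli" else "p_collision"

    scen_idx = np.empty(n_cells, dtype=np.int16)
    cell_params = {name: np.empty(n_cells) for name in GRID_AXES}
    mean_p = np.empty(n_cells)
    sd_p = np.empty(n_cells)
    possible_frac = np.empty(n_cells)

    # behavioral histograms: fixed bin count covering every reachable FID
    max_fid = max(
        float(np.max(grid.approach_speeds)) * float(np.max(grid.betas)),
        max(sc.fid_mean + 10 * sc.fid_sd for sc in grid.scenarios),
    )
    n_fid_bins = int(np.ceil(max_fid / bin_width)) + 1
    n_ang_bins = int(np.ceil(180.0 / bin_width)) + 1
    fid_hist = {
        sc.kind: (np.zeros(n_fid_bins), np.zeros(n_fid_bins, dtype=np.int64))
        for sc in grid.scenarios
    }
    angle_hist = {
        sc.kind: (np.zeros(n_ang_bins), np.zeros(n_ang_bins, dtype=np.int64))
        for sc in grid.scenarios
    }
    record_chunks = [] if collect_records else None
    scenario_kinds = [sc.kind for sc in grid.scenarios]

    for index, sc, sa, delta, d_min, sv, beta in grid.cells():
        rng = _cell_rng(seed, index)
        arrays = _simulate_cell(
            silhouette, body_length, sa, delta, d_min, sv, beta, sc,
            n, rng, mode, lateral_term, alert_speed,
        )
        stat = arrays[stat_col]
        mean_p[index] = stat.mean()
        sd_p[index] = stat.std()
        possible_frac[index] = arrays["collision_possible"].mean()
        s_i = scenario_kinds.index(sc.kind)
        scen_idx[index] = s_i
        for name, value in zip(GRID_AXES, (sa, delta, d_min, sv, beta)):
            cell_params[name][index] = value
        p = arrays["p_collision"]
        fsum, fcount = fid_hist[sc.kind]
        idx = np.minimum((arrays["d_fid"] / bin_width).astype(np.int64), n_fid_bins - 1)
        np.add.at(fsum, idx, p)
        np.add.at(fcount, idx, 1)
        asum, acount = angle_hist[sc.kind]
        idx = np.minimum((arrays["theta"] / bin_width).astype(np.int64), n_ang_bins - 1)
        np.add.at(asum, idx, p)
        np.add.at(acount, idx, 1)
        if record_chunks is not None:
            chunk = pd.DataFrame(arrays)
            for name, value in zip(GRID_AXES, (sa, delta, d_min, sv, beta)):
                chunk.insert(0, name, value)
            chunk.insert(0, "scenario", sc.kind)
            record_chunks.append(chunk)
        if log_every and (index + 1) % log_every == 0:
            done = mean_p[: index + 1]
            logger.info(
                "cell %d/%d (%s), running grand mean %.4f",
                index + 1, n_cells, sc.kind, done.mean(),
            )

    cells = pd.DataFrame(
        {"scenario": np.array(scenario_kinds, dtype=object)[scen_idx], **cell_params,
         "mean_p": mean_p, "sd_p": sd_p, "possible_frac": possible_frac, "n": n}
    )
    manifest = {
        "seed": int(seed),
        "mode": mode,
        "lateral_term": lateral_term,
        "alert_speed": alert_speed,
        "body_length": body_length,
        "iterations": n,
        "axis_lengths": list(grid.axis_lengths),
        "n_cells": n_cells,
        "total_predictions": grid.total_predictions,
        "grid_hash": grid.content_hash(),
        "silhouette": {
            "shape": list(silhouette.mask.shape),
            "width_m": silhouette.width_m,
            "height_m": silhouette.height_m,
            "occupied_pixels": int(silhouette.mask.sum()),
        },
        "bin_width": bin_width,
    }
    records = None
    if record_chunks is not None:
        records = pd.concat(record_chunks, ignore_index=True)
    return SweepResult(
        grid=grid, cells=cells, fid_hist=fid_hist, angle_hist=angle_hist,
        bin_width=bin_width, manifest=manifest, records=records,
    )


# ---------------------------------------------------------------------------
# Record-level aggregation (mirrors the streamed curves, for external CSVs)
# ---------------------------------------------------------------------------

def aggregate_by_cell(records: pd.DataFrame, axis: Optional[str] = None) -> AggregatedCurve:
    """Per-cell collision fractions, then marginal means along one grid axis.

    With ``axis=None`` the curve collapses to the per-scenario grand mean.
    Expectation mode uses the mean ``p_collision`` per cell; if Bernoulli
    outcomes are present they are used instead.
    """
    if records is None or len(records) == 0:
        raise ValueError("empty record set")
    stat = "outcome" if "outcome" in records and records["outcome"].notna().all() else "p_collision"
    cell_keys = ["scenario", *GRID_AXES]
    per_cell = records.groupby(cell_keys, sort=False)[stat].mean().reset_index(name="mean_p")
    group = ["scenario"] if axis is None else ["scenario", axis]
    table = (
        per_cell.groupby(group, sort=True)["mean_p"]
        .agg(mean_p="mean", sd_p="std", n="count")
        .reset_index()
    )
    if axis is not None:
        table = table.rename(columns={axis: "value"})
    return AggregatedCurve(axis=axis or "scenario", table=table)


def aggregate_by_behavior(
    records: pd.DataFrame, axis: str = "theta", bin_width: float = 0.1
) -> AggregatedCurve:
    """Mean probability in 0.1-unit bins of a sampled behavioral variable."""
    if axis not in ("theta", "d_fid"):
        raise ValueError("axis must be 'theta' or 'd_fid'")
    if records is None or len(records) == 0:
        raise ValueError("empty record set")
    stat = "outcome" if "outcome" in records and records["outcome"].notna().all() else "p_collision"
    binned = np.floor(records[axis].to_numpy() / bin_width) * bin_width
    df = records.assign(value=binned)
    table = (
        df.groupby(["scenario", "value"], sort=True)[stat]
        .agg(mean_p="mean", n="count")
        .reset_index()
    )
    return AggregatedCurve(axis=axis, table=table)


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------

def write_outputs(result: SweepResult, outdir: Union[str, Path]) -> dict:
    """Write per-cell, per-record and aggregated CSVs plus a JSON manifest.

    CSV dialect is fixed (comma separator, period decimal, UTF-8, header
    row) so identical seeds reproduce byte-identical files.  Returns a
    mapping of logical names to written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path

    _write("cells", result.cells)
    _write("grand_means", result.grand_means())
    for axis in GRID_AXES:
        _write(f"marginal_{axis}", result.marginal(axis).table)
    for axis in ("d_fid", "theta"):
        _write(f"behavior_{axis}", result.behavior_curve(axis).table)
    if result.records is not None:
        _write("records", result.records)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = manifest_path
    return paths
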