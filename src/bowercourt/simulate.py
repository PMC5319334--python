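"""Synthetic display courts and reconstruction sequences.

The generator emulates the structure of real great-bowerbird courts: objects
scattered over the wedge of ground visible from the avenue, with visible
extents increasing linearly with viewer distance (the positive size-distance
gradient) plus Gaussian noise, and time-stamped placement sequences under six
candidate reconstruction styles — size-ordered placement inward-out or
outward-in, random order with correct positions, dump-everything-then-sort,
centre-outward mosaic-style placement, and trial-and-error with decaying
position errors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .geometry import CourtGeometry, CourtObject, GeometryError
from .reconstruction import PlacementSequence

__all__ = [
    "CourtModel",
    "StrategySpec",
    "STRATEGY_STYLES",
    "generate_court",
    "generate_placement_sequence",
    "make_fixture_suite",
]

STRATEGY_STYLES = (
    "inward_out",
    "outward_in",
    "random_order",
    "dump_then_sort",
    "center_outward",
    "trial_and_error",
)

_EXTENT_FLOOR = 0.1  # cm; generated extents are floored here to stay physical


@dataclass(frozen=True)
class CourtModel:
    """Generative model of one court.

    Extents follow ``intercept + slope * distance + N(0, noise_sd)`` (cm),
    floored at 0.1 cm; positions are uniform by area over the field-of-view
    wedge between the avenue entrance and the far court edge.
    """

    n_objects: int = 60
    slope_width: float = 0.02
    slope_depth: float = 0.02
    intercept_width: float = 1.0
    intercept_depth: float = 1.0
    noise_sd: float = 0.3
    geometry: CourtGeometry = CourtGeometry()
    position_law: Literal["uniform_wedge", "clustered"] = "uniform_wedge"
    cluster_sd_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_objects < 3:
            raise ValueError("n_objects must be >= 3")
        if min(self.slope_width, self.slope_depth, self.noise_sd) < 0:
            raise ValueError("slopes and noise_sd must be non-negative")
        if min(self.intercept_width, self.intercept_depth) <= 0:
            raise ValueError("intercepts must be positive")


@dataclass(frozen=True)
class StrategySpec:
    """One reconstruction style plus its placement-timing law.

    Timing: first placement after an exponential latency (mean
    ``first_latency_minutes``, default 45 — the observed mean latency of wild
    males), then exponential gaps (mean ``inter_placement_minutes``).
    """

    style: str = "center_outward"
    inter_placement_minutes: float = 15.0
    first_latency_minutes: float = 45.0
    position_noise_sd: float = 15.0
    correction_rounds: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.style not in STRATEGY_STYLES:
            raise ValueError(
                f"unknown style {self.style!r}; choose from {STRATEGY_STYLES}"
            )
        if self.inter_placement_minutes <= 0 or self.first_latency_minutes <= 0:
            raise ValueError("time gaps must be positive")


def _sample_wedge(
    n: int, geom: CourtGeometry, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-by-area rejection sampling inside the court wedge."""
    a = geom.avenue_offset
    x_hi = a + geom.court_length
    tan_th = math.tan(math.radians(geom.fov_half_angle))
    y_max = min(x_hi * tan_th, geom.court_width / 2.0)
    if y_max <= 0:
        raise GeometryError("infeasible geometry: wedge has no area")
    xs = np.empty(0)
    ys = np.empty(0)
    while xs.size < n:
        m = max(4 * (n - xs.size), 16)
        x = rng.uniform(a, x_hi, m)
        y = rng.uniform(-y_max, y_max, m)
        ok = np.abs(y) <= np.minimum(x * tan_th, geom.court_width / 2.0)
        xs = np.concatenate([xs, x[ok]])
        ys = np.concatenate([ys, y[ok]])
    return xs[:n], ys[:n]


def _sample_clustered(
    n: int, geom: CourtGeometry, rng: np.random.Generator, sd_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian clusters around a few wedge-interior centres, rejected to the
    wedge.  Cluster scale is ``sd_frac`` of the court length."""
    k = max(2, n // 20)
    cx, cy = _sample_wedge(k, geom, rng)
    sd = sd_frac * geom.court_length
    a = geom.avenue_offset
    tan_th = math.tan(math.radians(geom.fov_half_angle))
    xs: list[float] = []
    ys: list[float] = []
    while len(xs) < n:
        j = rng.integers(0, k)
        x = cx[j] + rng.normal(0.0, sd)
        y = cy[j] + rng.normal(0.0, sd)
        if (
            a <= x <= a + geom.court_length
            and abs(y) <= min(x * tan_th, geom.court_width / 2.0)
        ):
            xs.append(x)
            ys.append(y)
    return np.array(xs), np.array(ys)


def generate_court(model: CourtModel) -> list[CourtObject]:
    """Draw one synthetic court from the generative model (seeded)."""
    rng = np.random.default_rng(model.seed)
    geom = model.geometry
    if model.position_law == "clustered":
        x, y = _sample_clustered(model.n_objects, geom, rng, model.cluster_sd_frac)
    else:
        x, y = _sample_wedge(model.n_objects, geom, rng)
    d = np.hypot(x, y)
    w = model.intercept_width + model.slope_width * d
    dp = model.intercept_depth + model.slope_depth * d
    if model.noise_sd > 0:
        w = w + rng.normal(0.0, model.noise_sd, model.n_objects)
        dp = dp + rng.normal(0.0, model.noise_sd, model.n_objects)
    w = np.maximum(w, _EXTENT_FLOOR)
    dp = np.maximum(dp, _EXTENT_FLOOR)
    pad = len(str(model.n_objects))
    return [
        CourtObject(
            id=f"obj{i + 1:0{pad}d}",
            x=float(x[i]),
            y=float(y[i]),
            visible_width=float(w[i]),
            visible_depth=float(dp[i]),
        )
        for i in range(model.n_objects)
    ]


def _clamp_to_wedge(
    x: float, y: float, geom: CourtGeometry
) -> tuple[float, float]:
    a = geom.avenue_offset
    x = min(max(x, a + 1e-6), a + geom.court_length)
    tan_th = math.tan(math.radians(geom.fov_half_angle))
    y_lim = min(x * tan_th, geom.court_width / 2.0)
    y = min(max(y, -y_lim), y_lim)
    return x, y


def _timestamps(n: int, spec: StrategySpec, rng: np.random.Generator) -> np.ndarray:
    first = rng.exponential(spec.first_latency_minutes)
    gaps = rng.exponential(spec.inter_placement_minutes, n - 1) if n > 1 else []
    return first + np.concatenate([[0.0], np.cumsum(gaps)])


def generate_placement_sequence(
    court: Sequence[CourtObject], spec: StrategySpec, geom: CourtGeometry
) -> PlacementSequence:
    """Simulate how a male replaces ``court``'s objects under one style.

    Every style ends with all objects back at their true positions; the
    styles differ in placement order and in whether objects pass through
    wrong positions first (``dump_then_sort`` starts from random positions
    and then sorts by size; ``trial_and_error`` perturbs each placement and
    corrects it over ``correction_rounds`` move rounds with halving noise).
    """
    objs = list(court)
    if not objs:
        raise ValueError("court must be nonempty")
    rng = np.random.default_rng(spec.seed)
    n = len(objs)
    dist = np.array([math.hypot(o.x, o.y) for o in objs])
    size = np.array([o.visible_width for o in objs])

    events: list[tuple[CourtObject, bool]] = []  # (state, is_final_position)
    if spec.style == "inward_out":
        order = np.argsort(dist, kind="stable")
        events = [(objs[i], True) for i in order]
    elif spec.style == "outward_in":
        order = np.argsort(-dist, kind="stable")
        events = [(objs[i], True) for i in order]
    elif spec.style == "random_order":
        order = rng.permutation(n)
        events = [(objs[i], True) for i in order]
    elif spec.style == "center_outward":
        # focal point on the female's line of sight, a quarter of the court
        # length beyond the entrance — the region males rebuild first
        fx = geom.avenue_offset + 0.25 * geom.court_length
        d_focal = np.array([math.hypot(o.x - fx, o.y) for o in objs])
        order = np.argsort(d_focal, kind="stable")
        events = [(objs[i], True) for i in order]
    elif spec.style == "dump_then_sort":
        order = rng.permutation(n)
        rx, ry = _sample_wedge(n, geom, rng)
        for j, i in enumerate(order):
            events.append(
                (replace(objs[i], x=float(rx[j]), y=float(ry[j])), False)
            )
        for i in np.argsort(size, kind="stable"):
            events.append((objs[i], True))
    elif spec.style == "trial_and_error":
        order = rng.permutation(n)
        sd = spec.position_noise_sd
        for i in order:
            x, y = _clamp_to_wedge(
                objs[i].x + rng.normal(0.0, sd),
                objs[i].y + rng.normal(0.0, sd),
                geom,
            )
            events.append((replace(objs[i], x=x, y=y), False))
        for r in range(1, spec.correction_rounds + 1):
            last = r == spec.correction_rounds
            sd_r = 0.0 if last else sd / (2.0**r)
            for i in order:
                x, y = objs[i].x, objs[i].y
                if sd_r > 0:
                    x, y = _clamp_to_wedge(
                        x + rng.normal(0.0, sd_r), y + rng.normal(0.0, sd_r), geom
                    )
                events.append((replace(objs[i], x=x, y=y), last))

    times = _timestamps(len(events), spec, rng)
    placements = [
        replace(state, placed_at=float(times[j]), placement_rank=j + 1)
        for j, (state, _) in enumerate(events)
    ]
    return PlacementSequence(
        court_before=objs, placements=placements, geom=geom
    )


def make_fixture_suite(out_dir: str | Path, *, base_seed: int = 20110901) -> dict:
    """Write a deterministic fixture set: tiny exhaustively testable courts
    (n = 4, 5, 6), one 14-bower cohort with per-bower gradient heterogeneity,
    and a manifest of every file with its seed.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    from .io import write_geometry, write_objects, write_placements

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = CourtGeometry()
    write_geometry(geom, out / "geometry.yaml")
    manifest: dict = {
        "base_seed": base_seed,
        "geometry": "geometry.yaml",
        "small_courts": [],
        "cohort": [],
    }
    for i, n in enumerate((4, 5, 6)):
        seed = base_seed + i
        court = generate_court(
            CourtModel(n_objects=n, geometry=geom, seed=seed)
        )
        name = f"small_court_n{n}.csv"
        write_objects(court, out / name)
        manifest["small_courts"].append({"file": name, "n": n, "seed": seed})
    rng = np.random.default_rng(base_seed + 100)
    for b in range(14):
        seed = base_seed + 1000 + b
        model = CourtModel(
            n_objects=int(rng.integers(40, 80)),
            slope_width=float(rng.uniform(0.01, 0.04)),
            slope_depth=float(rng.uniform(0.01, 0.04)),
            noise_sd=float(rng.uniform(0.2, 0.5)),
            geometry=geom,
            seed=seed,
        )
        court = generate_court(model)
        seq = generate_placement_sequence(
            court,
            StrategySpec(style="center_outward", seed=seed + 5000),
            geom,
        )
        before = f"bower{b + 1:02d}_before.csv"
        placed = f"bower{b + 1:02d}_placements.csv"
        write_objects(court, out / before)
        write_placements(seq.placements, out / placed)
        manifest["cohort"].append(
            {
                "bower": f"bower{b + 1:02d}",
                "before": before,
                "placements": placed,
                "n_objects": model.n_objects,
                "slope_width": model.slope_width,
                "slope_depth": model.slope_depth,
                "noise_sd": model.noise_sd,
                "seed": seed,
            }
        )
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
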