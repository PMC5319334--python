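"""Sequential court-reconstruction analyses.

After all objects are removed from a display court, the male rebuilds it; the
questions are where the first objects go, how quickly the size-distance
gradient and the even angular mosaic reappear, and whether the rebuilt
geometry matches the pre-removal court.

Three residual sets drive the comparison for each bower, dimension (width /
depth) and metric (gradient / angle):

* ``R1`` — residuals of the original objects from the original fit: the
  quality of the pre-removal geometry.
* ``R2`` — residuals of the first 10 replaced objects from their own fresh
  fit: how carefully those objects were placed relative to each other.
* ``R3`` — residuals of the first 10 objects from the *original* fit: how
  well the original geometry was recovered.

R1 vs R2 and R1 vs R3 are compared by a permutation test on the difference of
group RMS values, with Holm's sequential Bonferroni across the test family
and an exact sign test on the signed differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations as _iter_combinations
from typing import Literal, Sequence

import numpy as np
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .geometry import (
    AngleConvention,
    CourtGeometry,
    CourtObject,
    Dimension,
    GradientFit,
    InsufficientDataError,
    SdConvention,
    angle_summary,
    distance_from_viewer,
    fit_gradient,
    visible_objects,
)
from .illusion import PermutationPlan, effect_size

__all__ = [
    "PlacementSequence",
    "RelativePosition",
    "FirstKSummary",
    "ResidualSets",
    "ResidualComparison",
    "TrajectoryPoint",
    "court_footprint",
    "relative_position",
    "first_k_objects",
    "first_k_summary",
    "rms_trajectory",
    "residual_sets",
    "compare_residual_sets",
    "sequential_bonferroni",
    "sign_test",
    "time_binned_trajectory",
]

Metric = Literal["gradient", "angle"]
Pair = Literal["R1R2", "R1R3"]

DAY_START_MIN = 5 * 60 + 30   # 05:30 — camera window start
DAY_END_MIN = 18 * 60         # 18:00 — camera window end


@dataclass(frozen=True)
class PlacementSequence:
    """A pre-removal court plus the time-ordered replacement events.

    ``placements`` may contain several events for one object id (the object
    was moved); the court state at any time is the latest event per id.
    ``placement_rank`` numbers events contiguously from 1 and ``placed_at``
    (minutes since court clearance) must be non-decreasing with rank.
    """

    court_before: tuple[CourtObject, ...]
    placements: tuple[CourtObject, ...]
    geom: CourtGeometry

    def __init__(
        self,
        court_before: Sequence[CourtObject],
        placements: Sequence[CourtObject],
        geom: CourtGeometry,
    ) -> None:
        placements = tuple(placements)
        ranks = [p.placement_rank for p in placements]
        if any(r is None for r in ranks):
            raise ValueError("every placement event needs a placement_rank")
        if sorted(ranks) != list(range(1, len(placements) + 1)):
            raise ValueError("placement_rank values must be contiguous 1..k")
        times = [p.placed_at for p in placements]
        if any(t is None for t in times):
            raise ValueError("every placement event needs a placed_at time")
        ordered = sorted(placements, key=lambda p: p.placement_rank)
        ts = [p.placed_at for p in ordered]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("placed_at must be non-decreasing with placement_rank")
        object.__setattr__(self, "court_before", tuple(court_before))
        object.__setattr__(self, "placements", tuple(ordered))
        object.__setattr__(self, "geom", geom)

    def state_at(self, t_min: float) -> list[CourtObject]:
        """Court state (latest event per object id) at ``t_min`` minutes."""
        latest: dict[str, CourtObject] = {}
        for ev in self.placements:
            if ev.placed_at <= t_min:
                latest[ev.id] = ev
        return list(latest.values())

    def n_distinct(self) -> int:
        return len({p.id for p in self.placements})


@dataclass(frozen=True)
class RelativePosition:
    """Position normalised to the original court footprint.

    ``x_rel`` runs from 0 at the avenue entrance to 1 at the far court edge;
    ``y_rel`` puts the female's central line of sight at 0.5.  Values outside
    [0, 1] mean the object lies outside the original footprint.
    """

    x_rel: float
    y_rel: float

    @property
    def inside_footprint(self) -> bool:
        return 0.0 <= self.x_rel <= 1.0 and 0.0 <= self.y_rel <= 1.0


@dataclass(frozen=True)
class FirstKSummary:
    """Relative-placement summary of the first k objects replaced."""

    k: int
    mean_x_rel: float
    se_x_rel: float
    mean_y_rel: float
    se_y_rel: float
    frac_closest_third: float
    frac_middle_lateral_third: float


@dataclass(frozen=True)
class ResidualSets:
    bower_id: str
    dimension: Dimension
    metric: Metric
    R1: np.ndarray
    R2: np.ndarray
    R3: np.ndarray


@dataclass(frozen=True)
class ResidualComparison:
    """Signed RMS difference between a comparison set and R1, with its
    label-permutation p-value."""

    pair: Pair
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    exhaustive: bool


@dataclass(frozen=True)
class TrajectoryPoint:
    """Court summary in one daylight time bin during reconstruction."""

    day: int
    bin_start_clock_min: int
    t_since_clearance_min: float
    n_objects: int
    mean_x_rel: float
    se_x_rel: float
    mean_y_rel: float
    se_y_rel: float
    sd_width_angle: float
    sd_depth_angle: float
    slope_width: float
    slope_depth: float
    effect_size_width: float
    effect_size_depth: float


def court_footprint(
    court_before: Sequence[CourtObject], geom: CourtGeometry
) -> tuple[float, float]:
    """``(length, width)`` of the original court from its occupied positions.

    Length is the maximum axial distance beyond the avenue entrance; width is
    twice the maximum lateral offset (the footprint is symmetric about the
    female's line of sight).
    """
    if not court_before:
        raise InsufficientDataError("footprint undefined: empty original court")
    a = geom.avenue_offset
    length = max(o.x - a for o in court_before)
    width = 2.0 * max(abs(o.y) for o in court_before)
    if length <= 0 or width <= 0:
        raise InsufficientDataError("degenerate original footprint")
    return length, width


def relative_position(
    obj: CourtObject,
    court_before: Sequence[CourtObject],
    geom: CourtGeometry,
) -> RelativePosition:
    """Object position relative to the original court length and width."""
    length, width = court_footprint(court_before, geom)
    x_rel = (obj.x - geom.avenue_offset) / length
    y_rel = 0.5 + obj.y / width
    return RelativePosition(x_rel=float(x_rel), y_rel=float(y_rel))


def first_k_objects(seq: PlacementSequence, k: int = 10) -> list[CourtObject]:
    """First-placement events of the first ``k`` distinct objects replaced."""
    seen: dict[str, CourtObject] = {}
    for ev in seq.placements:
        if ev.id not in seen:
            seen[ev.id] = ev
            if len(seen) == k:
                break
    if len(seen) < k:
        raise InsufficientDataError(
            f"need >= {k} distinct placed objects, got {len(seen)}"
        )
    return list(seen.values())


def _mean_se(v: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(v))
    se = float(np.std(v, ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0
    return m, se


def first_k_summary(seq: PlacementSequence, k: int = 10) -> FirstKSummary:
    """Where the first ``k`` objects went, relative to the original court.

    Reports mean +/- s.e. of the relative axial and lateral positions, the
    fraction placed in the third of the court closest to the avenue and the
    fraction in the middle lateral third (the female's line of sight).
    """
    objs = first_k_objects(seq, k)
    rel = [relative_position(o, seq.court_before, seq.geom) for o in objs]
    x = np.array([r.x_rel for r in rel])
    y = np.array([r.y_rel for r in rel])
    mean_x, se_x = _mean_se(x)
    mean_y, se_y = _mean_se(y)
    return FirstKSummary(
        k=k,
        mean_x_rel=mean_x,
        se_x_rel=se_x,
        mean_y_rel=mean_y,
        se_y_rel=se_y,
        frac_closest_third=float(np.mean(x < 1.0 / 3.0)),
        frac_middle_lateral_third=float(
            np.mean((y >= 1.0 / 3.0) & (y < 2.0 / 3.0))
        ),
    )


def rms_trajectory(
    seq: PlacementSequence,
    original_fit: GradientFit,
    geom: CourtGeometry,
    dimension: Dimension,
    *,
    first_step: int = 4,
    last_step: int = 10,
) -> np.ndarray:
    """RMS residual from the *original* gradient as objects 4..10 are added.

    At the moment the k-th distinct object appears, residuals of all objects
    then on the court from the pre-removal regression line are computed and
    their RMS recorded.  A bird reproducing its original gradient keeps this
    series near the original noise level from the start; dump-then-sort or
    trial-and-error placement starts high and falls as objects are moved into
    place.
    """
    if original_fit is None:
        raise ValueError("original_fit is required")
    n = seq.n_distinct()
    if n < first_step:
        raise InsufficientDataError(
            f"need >= {first_step} distinct placements, got {n}"
        )
    out = []
    seen: set[str] = set()
    for ev in seq.placements:
        new = ev.id not in seen
        seen.add(ev.id)
        k = len(seen)
        if new and first_step <= k <= last_step:
            state = visible_objects(seq.state_at(ev.placed_at), geom)
            d = np.array([distance_from_viewer(o, geom) for o in state])
            y = np.array([o.extent(dimension) for o in state])
            resid = y - original_fit.predict(d)
            out.append(float(np.sqrt(np.mean(resid**2))))
        if k > last_step:
            break
    return np.array(out)


def residual_sets(
    court_before: Sequence[CourtObject],
    first10: Sequence[CourtObject],
    geom: CourtGeometry,
    dimension: Dimension,
    metric: Metric,
    *,
    bower_id: str = "",
    angle_convention: AngleConvention = "exact",
    sd_convention: SdConvention = "sample",
) -> ResidualSets:
    """Build the R1/R2/R3 residual sets for one bower, dimension and metric.

    Gradient metric: residuals (cm) from the OLS size-distance regression.
    Angle metric: deviations (degrees) of per-object visual angles from the
    group mean angle — the original court's mean for R1 and R3, the
    first-10's own mean for R2.
    """
    before = visible_objects(court_before, geom)
    after = visible_objects(first10, geom)
    if len(before) < 3 or len(after) < 3:
        raise InsufficientDataError("need >= 3 visible objects in each group")
    if metric == "gradient":
        fit1 = fit_gradient(before, geom, dimension, restrict_fov=False)
        fit2 = fit_gradient(after, geom, dimension, restrict_fov=False)
        d3 = np.array([distance_from_viewer(o, geom) for o in after])
        y3 = np.array([o.extent(dimension) for o in after])
        r1 = fit1.residuals
        r2 = fit2.residuals
        r3 = y3 - fit1.predict(d3)
    else:
        s1 = angle_summary(
            before, geom, dimension,
            angle_convention=angle_convention, sd_convention=sd_convention,
            restrict_fov=False,
        )
        s2 = angle_summary(
            after, geom, dimension,
            angle_convention=angle_convention, sd_convention=sd_convention,
            restrict_fov=False,
        )
        r1 = s1.angles - s1.mean_angle
        r2 = s2.angles - s2.mean_angle
        r3 = s2.angles - s1.mean_angle
    return ResidualSets(
        bower_id=bower_id, dimension=dimension, metric=metric,
        R1=np.asarray(r1, dtype=float),
        R2=np.asarray(r2, dtype=float),
        R3=np.asarray(r3, dtype=float),
    )


def _rms(v: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(v))))


def compare_residual_sets(
    sets: ResidualSets,
    pair: Pair,
    plan: PermutationPlan | None = None,
    *,
    exhaustive_total: int = 12,
) -> ResidualComparison:
    """Permutation test of RMS(comparison set) - RMS(R1).

    Individual residuals are shuffled between the two groups (group sizes
    fixed); the two-sided p-value uses the add-one estimator with ties
    counted.  When the pooled size is at most ``exhaustive_total`` all
    distinct label assignments are enumerated instead of sampled.
    """
    plan = plan or PermutationPlan()
    a = np.asarray(sets.R1, dtype=float)
    b = np.asarray(sets.R2 if pair == "R1R2" else sets.R3, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each residual group needs >= 2 values")
    observed = _rms(b) - _rms(a)
    pooled_sq = np.concatenate([a, b]) ** 2
    n_tot, n_a = pooled_sq.size, a.size
    ss_tot = float(pooled_sq.sum())
    if n_tot <= exhaustive_total:
        idx = np.array(
            list(_iter_combinations(range(n_tot), n_a)), dtype=np.intp
        )
        exhaustive = True
    else:
        rng = np.random.default_rng(plan.seed)
        rows = np.tile(np.arange(n_tot, dtype=np.intp), (plan.n_permutations, 1))
        idx = rng.permuted(rows, axis=1)[:, :n_a]
        exhaustive = False
    ss_a = pooled_sq[idx].sum(axis=1)
    stat = np.sqrt((ss_tot - ss_a) / b.size) - np.sqrt(ss_a / n_a)
    tol = 1e-12 * max(1.0, abs(observed))
    n_ge = int(np.sum(np.abs(stat) >= abs(observed) - tol))
    n_perm = int(stat.size)
    p = (1 + n_ge) / (n_perm + 1)
    return ResidualComparison(
        pair=pair,
        statistic=float(observed),
        p_value=float(min(p, 1.0)),
        n_permutations=n_perm,
        seed=plan.seed,
        exhaustive=exhaustive,
    )


def sequential_bonferroni(
    p_values: Sequence[float], alpha: float = 0.05
) -> np.ndarray:
    """Holm step-down rejection flags at family-wise level ``alpha``.

    Sort ascending and reject while ``p_(i) <= alpha / (m - i + 1)``;
    rejection is monotone (uniformly more powerful than plain Bonferroni,
    never more liberal than the unadjusted tests).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return reject


def sign_test(differences: Sequence[float]) -> float:
    """Two-sided exact binomial sign test on the signs of ``differences``.

    Zeros are dropped (standard convention); the null is an equal chance of
    positive and negative differences.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise InsufficientDataError("sign test undefined: all differences zero")
    n_pos = int(np.sum(d > 0))
    return float(binomtest(n_pos, int(d.size), 0.5, alternative="two-sided").pvalue)


def _daylight_bins(
    horizon_min: float,
    bin_min: int,
    day_start: int,
    day_end: int,
) -> list[tuple[int, int, float]]:
    """(day, bin-start clock minutes, bin-end minutes since clearance).

    Clearance is taken to happen at ``day_start`` on day 0, so minutes since
    clearance = day*1440 + clock - day_start.
    """
    out = []
    n_days = int(math.ceil(horizon_min / 1440.0))
    for day in range(n_days):
        start = day_start
        while start < day_end:
            end_clock = min(start + bin_min, day_end)
            t_end = day * 1440.0 + end_clock - day_start
            if t_end <= horizon_min + 1e-9:
                out.append((day, start, t_end))
            start += bin_min
    return out


def time_binned_trajectory(
    seq: PlacementSequence,
    geom: CourtGeometry,
    *,
    bin_minutes: int = 120,
    horizon_minutes: float = 72 * 60,
    day_start_min: int = DAY_START_MIN,
    day_end_min: int = DAY_END_MIN,
    plan: PermutationPlan | None = None,
    angle_convention: AngleConvention = "exact",
    sd_convention: SdConvention = "sample",
) -> list[TrajectoryPoint]:
    """Court summaries at 2-hour daylight intervals over the rebuild horizon.

    At the end of each daylight bin the court state (latest position per
    object) is summarised: mean +/- s.e. relative positions, visual-angle
    s.d., gradient slopes and permutation effect sizes per dimension.
    Statistics needing more objects than are present are reported as NaN.
    """
    plan = plan or PermutationPlan(n_permutations=1000)
    if not seq.placements or seq.placements[0].placed_at > horizon_minutes:
        warnings.warn("no placements before the horizon; empty trajectory")
        return []
    points: list[TrajectoryPoint] = []
    for day, clock, t_end in _daylight_bins(
        horizon_minutes, bin_minutes, day_start_min, day_end_min
    ):
        state = visible_objects(seq.state_at(t_end), geom)
        n = len(state)
        nan = float("nan")
        mean_x = se_x = mean_y = se_y = nan
        sd_w = sd_d = slope_w = slope_d = es_w = es_d = nan
        if n >= 1:
            rel = [relative_position(o, seq.court_before, geom) for o in state]
            mean_x, se_x = _mean_se(np.array([r.x_rel for r in rel]))
            mean_y, se_y = _mean_se(np.array([r.y_rel for r in rel]))
        if n >= 2:
            sd_w = angle_summary(
                state, geom, "width",
                angle_convention=angle_convention, sd_convention=sd_convention,
                restrict_fov=False,
            ).sd_angle
            sd_d = angle_summary(
                state, geom, "depth",
                angle_convention=angle_convention, sd_convention=sd_convention,
                restrict_fov=False,
            ).sd_angle
        if n >= 3:
            slope_w = fit_gradient(state, geom, "width", restrict_fov=False).slope
            slope_d = fit_gradient(state, geom, "depth", restrict_fov=False).slope
            es_w = effect_size(
                state, geom, "width", plan,
                angle_convention=angle_convention, sd_convention=sd_convention,
            ).effect_size
            es_d = effect_size(
                state, geom, "depth", plan,
                angle_convention=angle_convention, sd_convention=sd_convention,
            ).effect_size
        points.append(
            TrajectoryPoint(
                day=day,
                bin_start_clock_min=clock,
                t_since_clearance_min=t_end,
                n_objects=n,
                mean_x_rel=mean_x,
                se_x_rel=se_x,
                mean_y_rel=mean_y,
                se_y_rel=se_y,
                sd_width_angle=sd_w,
                sd_depth_angle=sd_d,
                slope_width=slope_w,
                slope_depth=slope_d,
                effect_size_width=es_w,
                effect_size_depth=es_d,
            )
        )
    return points
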