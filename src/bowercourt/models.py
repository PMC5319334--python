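"""Model / Results objects tying the pipeline together.

Two fitted-model entry points, in the spirit of statsmodels:

``CourtIllusionModel``
    Built from one court's object table plus the viewing geometry; ``fit()``
    runs the gradient regressions, visual-angle summaries and permutation
    effect sizes for width and depth and returns a
    :class:`CourtIllusionResults` with a ``summary()`` table.

``CourtReconstructionModel``
    Built from a pre-removal court and the timed placement sequence after
    clearance; ``fit()`` runs the first-10 placement summary, the step-4..10
    RMS trajectories, the R1/R2/R3 residual comparisons with Holm correction
    and sign tests, and (optionally) the 2-h binned trajectory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import (
    AngleConvention,
    CourtGeometry,
    CourtObject,
    Dimension,
    GradientFit,
    SdConvention,
    VisualAngleSummary,
    angle_summary,
    fit_gradient,
    visible_objects,
)
from .illusion import EffectSizeResult, PermutationPlan, effect_size
from .reconstruction import (
    FirstKSummary,
    Metric,
    Pair,
    PlacementSequence,
    ResidualComparison,
    ResidualSets,
    TrajectoryPoint,
    compare_residual_sets,
    first_k_objects,
    first_k_summary,
    residual_sets,
    rms_trajectory,
    sequential_bonferroni,
    sign_test,
    time_binned_trajectory,
)

__all__ = [
    "CourtIllusionModel",
    "CourtIllusionResults",
    "CourtReconstructionModel",
    "CourtReconstructionResults",
]

DIMENSIONS: tuple[Dimension, ...] = ("width", "depth")
METRICS: tuple[Metric, ...] = ("gradient", "angle")
PAIRS: tuple[Pair, ...] = ("R1R2", "R1R3")


class CourtIllusionModel:
    """Forced-perspective geometry of one display court.

    Parameters
    ----------
    objects : sequence of CourtObject
        The court's decorations in viewer coordinates.
    geometry : CourtGeometry
        Viewing frame; objects outside the field-of-view wedge are excluded
        from every statistic and listed in ``excluded_ids``.
    angle_convention, sd_convention : str
        Visual-angle formula ('exact' subtense or 'small_angle') and the
        s.d. denominator ('sample' = n-1 or 'population').
    """

    def __init__(
        self,
        objects: Sequence[CourtObject],
        geometry: CourtGeometry,
        *,
        angle_convention: AngleConvention = "exact",
        sd_convention: SdConvention = "sample",
    ) -> None:
        self.geometry = geometry
        self.objects = list(objects)
        self.visible = visible_objects(self.objects, geometry)
        self.excluded_ids = [
            o.id for o in self.objects if o not in self.visible
        ]
        self.angle_convention = angle_convention
        self.sd_convention = sd_convention

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, geometry: CourtGeometry, **kwargs
    ) -> "CourtIllusionModel":
        from .io import objects_from_dataframe

        return cls(objects_from_dataframe(df), geometry, **kwargs)

    @classmethod
    def from_csv(
        cls, objects_path, geometry_path, **kwargs
    ) -> "CourtIllusionModel":
        from .io import read_geometry, read_objects

        return cls(read_objects(objects_path), read_geometry(geometry_path), **kwargs)

    def fit(
        self,
        n_permutations: int = 20_000,
        seed: int = 0,
        dimensions: Sequence[Dimension] = DIMENSIONS,
    ) -> "CourtIllusionResults":
        """Run gradients, angle summaries and permutation effect sizes."""
        plan = PermutationPlan(n_permutations=n_permutations, seed=seed)
        gradients: dict[Dimension, GradientFit] = {}
        angles: dict[Dimension, VisualAngleSummary] = {}
        effects: dict[Dimension, EffectSizeResult] = {}
        for dim in dimensions:
            gradients[dim] = fit_gradient(self.visible, self.geometry, dim,
                                          restrict_fov=False)
            angles[dim] = angle_summary(
                self.visible, self.geometry, dim,
                angle_convention=self.angle_convention,
                sd_convention=self.sd_convention,
                restrict_fov=False,
            )
            effects[dim] = effect_size(
                self.visible, self.geometry, dim, plan,
                angle_convention=self.angle_convention,
                sd_convention=self.sd_convention,
            )
        return CourtIllusionResults(
            model=self,
            gradients=gradients,
            angles=angles,
            effects=effects,
            seed=seed,
        )


@dataclass
class CourtIllusionResults:
    """Estimates for one court: gradients, angle regularity, effect sizes."""

    model: CourtIllusionModel
    gradients: dict[Dimension, GradientFit]
    angles: dict[Dimension, VisualAngleSummary]
    effects: dict[Dimension, EffectSizeResult]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """One row per dimension with every headline statistic."""
        rows = []
        for dim in self.gradients:
            g, a, e = self.gradients[dim], self.angles[dim], self.effects[dim]
            rows.append(
                {
                    "dimension": dim,
                    "n_objects": g.n,
                    "slope_cm_per_cm": g.slope,
                    "intercept_cm": g.intercept,
                    "r_squared": g.r_squared,
                    "rms_residual_cm": g.rms,
                    "mean_angle_deg": a.mean_angle,
                    "sd_angle_deg": a.sd_angle,
                    "effect_size": e.effect_size,
                    "p_value": e.p_value,
                    "n_permutations": e.n_permutations,
                }
            )
        return pd.DataFrame(rows).set_index("dimension")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "excluded_ids": self.model.excluded_ids,
            "gradients": self.gradients,
            "angles": {
                k: dataclasses.replace(v) for k, v in self.angles.items()
            },
            "effects": self.effects,
        }

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Court illusion analysis",
            "=" * 70,
            f"objects in field of view: "
            f"{len(self.model.visible)} "
            f"(excluded: {len(self.model.excluded_ids)})",
            f"angle convention: {self.model.angle_convention}; "
            f"sd convention: {self.model.sd_convention}; seed: {self.seed}",
            "-" * 70,
            df.round(4).to_string(),
            "-" * 70,
            "positive effect size: arrangement more regular than random",
            "re-assignment of the same objects to the same positions.",
        ]
        return "\n".join(lines)


class CourtReconstructionModel:
    """Sequential reconstruction of one court after object removal."""

    def __init__(
        self,
        sequence: PlacementSequence,
        *,
        bower_id: str = "",
        angle_convention: AngleConvention = "exact",
        sd_convention: SdConvention = "sample",
    ) -> None:
        self.sequence = sequence
        self.geometry = sequence.geom
        self.bower_id = bower_id
        self.angle_convention = angle_convention
        self.sd_convention = sd_convention

    @classmethod
    def from_csv(
        cls, before_path, placements_path, geometry_path, **kwargs
    ) -> "CourtReconstructionModel":
        from .io import read_geometry, read_objects

        geom = read_geometry(geometry_path)
        seq = PlacementSequence(
            court_before=read_objects(before_path),
            placements=read_objects(placements_path),
            geom=geom,
        )
        return cls(seq, **kwargs)

    def fit(
        self,
        n_permutations: int = 20_000,
        seed: int = 0,
        *,
        k: int = 10,
        alpha: float = 0.05,
        trajectory: bool = False,
        trajectory_permutations: int = 1000,
    ) -> "CourtReconstructionResults":
        """Run every reconstruction analysis for this bower.

        ``alpha`` sets the family-wise level of the Holm correction across
        the 8 residual comparisons (2 dimensions x 2 metrics x 2 pairs).
        """
        seq = self.sequence
        plan = PermutationPlan(n_permutations=n_permutations, seed=seed)
        first10 = first_k_objects(seq, k)
        placement = first_k_summary(seq, k)
        original_fits = {
            dim: fit_gradient(seq.court_before, self.geometry, dim)
            for dim in DIMENSIONS
        }
        rms_traj = {
            dim: rms_trajectory(seq, original_fits[dim], self.geometry, dim,
                                last_step=k)
            for dim in DIMENSIONS
        }
        sets: dict[tuple[Dimension, Metric], ResidualSets] = {}
        comparisons: list[dict] = []
        for dim in DIMENSIONS:
            for metric in METRICS:
                rs = residual_sets(
                    seq.court_before, first10, self.geometry, dim, metric,
                    bower_id=self.bower_id,
                    angle_convention=self.angle_convention,
                    sd_convention=self.sd_convention,
                )
                sets[(dim, metric)] = rs
                for pair in PAIRS:
                    cmp_ = compare_residual_sets(rs, pair, plan)
                    comparisons.append(
                        {
                            "bower": self.bower_id,
                            "dimension": dim,
                            "metric": metric,
                            "pair": pair,
                            "statistic": cmp_.statistic,
                            "p": cmp_.p_value,
                            "n_permutations": cmp_.n_permutations,
                            "exhaustive": cmp_.exhaustive,
                        }
                    )
        table = pd.DataFrame(comparisons)
        table["reject_holm"] = sequential_bonferroni(table["p"], alpha=alpha)
        sign_p = sign_test(table["statistic"].to_numpy())
        traj = (
            time_binned_trajectory(
                seq, self.geometry,
                plan=PermutationPlan(
                    n_permutations=trajectory_permutations, seed=seed
                ),
                angle_convention=self.angle_convention,
                sd_convention=self.sd_convention,
            )
            if trajectory
            else None
        )
        return CourtReconstructionResults(
            model=self,
            k=k,
            placement=placement,
            original_fits=original_fits,
            rms_trajectories=rms_traj,
            residual_sets=sets,
            comparisons=table,
            sign_test_p=sign_p,
            trajectory=traj,
            seed=seed,
            alpha=alpha,
        )


@dataclass
class CourtReconstructionResults:
    """Per-bower reconstruction estimates and tests."""

    model: CourtReconstructionModel
    k: int
    placement: FirstKSummary
    original_fits: dict[Dimension, GradientFit]
    rms_trajectories: dict[Dimension, np.ndarray]
    residual_sets: dict[tuple[Dimension, Metric], ResidualSets]
    comparisons: pd.DataFrame
    sign_test_p: float
    trajectory: list[TrajectoryPoint] | None
    seed: int
    alpha: float

    def to_dict(self) -> dict:
        return {
            "bower": self.model.bower_id,
            "seed": self.seed,
            "k": self.k,
            "placement": self.placement,
            "original_fits": {k: v for k, v in self.original_fits.items()},
            "rms_trajectories": {
                k: v.tolist() for k, v in self.rms_trajectories.items()
            },
            "comparisons": self.comparisons.to_dict(orient="records"),
            "sign_test_p": self.sign_test_p,
            "trajectory": self.trajectory,
        }

    def summary(self) -> str:
        p = self.placement
        lines = [
            f"Court reconstruction analysis — bower {self.model.bower_id or '?'}",
            "=" * 72,
            f"first {self.k} objects: "
            f"x_rel {p.mean_x_rel:.3f} ± {p.se_x_rel:.3f}, "
            f"y_rel {p.mean_y_rel:.3f} ± {p.se_y_rel:.3f}",
            f"  fraction in closest third: {p.frac_closest_third:.2f}; "
            f"in middle lateral third: {p.frac_middle_lateral_third:.2f}",
            "-" * 72,
            "RMS residual from original gradient, steps 4..%d:" % self.k,
        ]
        for dim, tr in self.rms_trajectories.items():
            lines.append(
                f"  {dim:>6}: " + "  ".join(f"{v:.3f}" for v in tr) + " cm"
            )
        lines += [
            "-" * 72,
            "Residual comparisons (RMS difference vs R1, permutation p, Holm):",
            self.comparisons.round(4).to_string(index=False),
            f"sign test on signed differences: p = {self.sign_test_p:.4f}",
        ]
        if self.trajectory is not None:
            lines.append("-" * 72)
            lines.append(f"time-binned trajectory: {len(self.trajectory)} bins")
        return "\n".join(lines)
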