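"""Orchestration of single- and multi-stage landmark detection.

A *plan* describes how one landmark's three world coordinates are
assembled:

* ``single``  -- one DRL pass on one view fixes the two in-plane
  coordinates; the depth along the pixel's ray comes from the
  gradient-based bone-boundary estimator.
* ``two_stage`` / ``three_stage`` -- successive DRL passes; each cutaway
  stage is instantiated with its cut plane positioned at a coordinate
  predicted by an earlier stage (a first-stage cut view cuts at the
  volume median).  Coordinates predicted more than once are resolved
  latest-stage-wins: later views are cutaways localised by earlier
  stages, hence better conditioned.

Landmarks that sit in empty 3D space (a cavity centre, a foramen) have no
single-stage plan: no bone boundary lies at the landmark along any ray.

Plans are data, not code: YAML files with schema
``{landmark, type, mode, stages: [view codes]}``; the packaged libraries
cover the 16 clinical landmarks and the phantom landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .boundary_estimation import BoundaryConfig, NoBoundaryError, detect_boundary, sample_profile
from .dqn_agent import infer_landmark
from .mdp_env import EnvConfig
from .rendering import (
    ProjectedImage,
    RenderError,
    TransferFunction,
    ViewSpec,
    _VIEW_TABLE,
    render_view,
)
from .volume_io import LandmarkSet, Volume

MODES = ("single", "two_stage", "three_stage")
_N_STAGES = {"single": 1, "two_stage": 2, "three_stage": 3}


class PlanError(ValueError):
    pass


@dataclass(frozen=True)
class StagePlan:
    view: str

    def __post_init__(self) -> None:
        if self.view not in _VIEW_TABLE:
            raise PlanError(f"unknown view code {self.view!r}")

    @property
    def cut_axis(self) -> int | None:
        return _VIEW_TABLE[self.view][6]

    @property
    def inplane_axes(self) -> tuple[int, int]:
        t = _VIEW_TABLE[self.view]
        return (t[2], t[4])

    @property
    def ray_axis(self) -> int:
        return _VIEW_TABLE[self.view][0]


@dataclass(frozen=True)
class LandmarkPlan:
    """Per-landmark detection strategy: mode plus ordered view sequence."""

    landmark: str
    mode: str
    stages: tuple[StagePlan, ...]
    type_tag: int | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise PlanError(f"mode must be one of {MODES}")
        if len(self.stages) != _N_STAGES[self.mode]:
            raise PlanError(
                f"{self.mode} plan needs {_N_STAGES[self.mode]} stages, got {len(self.stages)}"
            )
        covered = set()
        for i, st in enumerate(self.stages):
            covered |= set(st.inplane_axes)
            if i >= 1 and st.cut_axis is not None:
                prior = set()
                for prev in self.stages[:i]:
                    prior |= set(prev.inplane_axes)
                if st.cut_axis not in prior:
                    raise PlanError(
                        f"stage {i + 1} view {st.view!r} cuts along axis {st.cut_axis} "
                        "which no earlier stage predicts"
                    )
        if self.mode == "single":
            covered.add(self.stages[0].ray_axis)
        if covered != {0, 1, 2}:
            raise PlanError(f"plan covers axes {sorted(covered)}, needs all three")
        if self.name is None:
            object.__setattr__(self, "name", self.landmark)

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkPlan":
        return cls(
            landmark=d["landmark"],
            mode=d["mode"],
            stages=tuple(StagePlan(v) for v in d["stages"]),
            type_tag=d.get("type"),
            name=d.get("name"),
        )


def load_plans(source) -> list[LandmarkPlan]:
    """Load a plan library from a YAML file path or a packaged library name
    (``"paper"`` for the 16 clinical landmarks, ``"phantom"``)."""
    if source in ("paper", "phantom"):
        text = (resources.files("cephalorl") / "data" / f"plans_{source}.yaml").read_text()
    else:
        text = Path(source).read_text()
    return [LandmarkPlan.from_dict(d) for d in yaml.safe_load(text)]


@dataclass
class StageRecord:
    view: str
    pixel: tuple[float, float]
    world_coords: dict[int, float]
    cut_position: float | None = None


@dataclass
class Prediction3D:
    """Assembled landmark prediction with per-stage provenance."""

    landmark: str
    point: np.ndarray
    mode: str
    stages: list[StageRecord] = field(default_factory=list)
    #: per-axis index of the stage that produced the final coordinate
    provenance: dict[int, int] = field(default_factory=dict)


@dataclass
class DetectionFailure:
    landmark: str
    stage: int
    reason: str


def _policy_for(models, plan: LandmarkPlan, stage: StagePlan, img: ProjectedImage):
    if callable(models) and not hasattr(models, "q_values"):
        return models(plan.landmark, stage.view, img)
    if isinstance(models, dict):
        key = (plan.landmark, stage.view)
        if key not in models:
            raise KeyError(f"no trained model for landmark/view pair {key}")
        return models[key]
    return models  # single policy object shared across stages


def build_next_view(
    v: Volume,
    plan: LandmarkPlan,
    stage_index: int,
    prior: dict[int, float],
    view_size: int = 512,
) -> ViewSpec:
    """Instantiate the ViewSpec of one stage.

    Cut views at stage >= 2 position their plane at the coordinate an
    earlier stage predicted along the cut axis; a first-stage cut view
    cuts at the volume median.
    """
    stage = plan.stages[stage_index]
    if stage.cut_axis is None:
        return ViewSpec.from_code(stage.view, size=view_size)
    if stage_index == 0:
        pos = float(v.world_center[stage.cut_axis])
    else:
        if stage.cut_axis not in prior:
            raise PlanError(
                f"stage {stage_index + 1} of plan {plan.name!r} cuts along axis "
                f"{stage.cut_axis} but no earlier stage produced that coordinate"
            )
        pos = float(prior[stage.cut_axis])
    return ViewSpec.from_code(stage.view, size=view_size, cut_position=pos)


def _run_stage(
    v: Volume,
    plan: LandmarkPlan,
    stage_index: int,
    prior: dict[int, float],
    models,
    view_size: int,
    env_cfg: EnvConfig,
    tf: TransferFunction,
) -> tuple[StageRecord, ProjectedImage]:
    stage = plan.stages[stage_index]
    spec = build_next_view(v, plan, stage_index, prior, view_size)
    img = render_view(v, spec, tf)
    policy = _policy_for(models, plan, stage, img)
    pixel, _trace = infer_landmark(img, policy, env_cfg)
    coords = img.geometry.pixel_to_inplane_world(float(pixel[0]), float(pixel[1]))
    return (
        StageRecord(
            view=stage.view,
            pixel=(float(pixel[0]), float(pixel[1])),
            world_coords=coords,
            cut_position=None if spec.cut is None else spec.cut.position,
        ),
        img,
    )


def run_single_stage(
    v: Volume,
    plan: LandmarkPlan,
    models,
    view_size: int = 512,
    env_cfg: EnvConfig | None = None,
    tf: TransferFunction | None = None,
    boundary_cfg: BoundaryConfig | None = None,
) -> Prediction3D | DetectionFailure:
    """One DRL pass + boundary-depth estimation along the pixel's ray."""
    if plan.mode != "single":
        raise PlanError(f"plan {plan.name!r} is not single-stage")
    env_cfg = env_cfg or EnvConfig()
    tf = tf or TransferFunction()
    record, img = _run_stage(v, plan, 0, {}, models, view_size, env_cfg, tf)
    origin, direction = img.pixel_to_world_ray(*record.pixel)
    try:
        profile = sample_profile(v, origin, direction)
        _, world_pt = detect_boundary(profile, boundary_cfg)
    except NoBoundaryError as exc:
        return DetectionFailure(landmark=plan.landmark, stage=1, reason=str(exc))
    ray_axis = plan.stages[0].ray_axis
    point = np.empty(3)
    provenance = {}
    for ax, val in record.world_coords.items():
        point[ax] = val
        provenance[ax] = 0
    point[ray_axis] = world_pt[ray_axis]
    provenance[ray_axis] = 0
    if not (np.all(np.isfinite(point)) and v.contains(point)):
        return DetectionFailure(plan.landmark, 1, f"assembled point {point} outside volume")
    return Prediction3D(
        landmark=plan.landmark, point=point, mode="single", stages=[record],
        provenance=provenance,
    )


def run_multi_stage(
    v: Volume,
    plan: LandmarkPlan,
    models,
    view_size: int = 512,
    env_cfg: EnvConfig | None = None,
    tf: TransferFunction | None = None,
) -> Prediction3D | DetectionFailure:
    """Sequential DRL passes on dynamically built cutaway views."""
    if plan.mode not in ("two_stage", "three_stage"):
        raise PlanError(f"plan {plan.name!r} is not multi-stage")
    env_cfg = env_cfg or EnvConfig()
    tf = tf or TransferFunction()
    prior: dict[int, float] = {}
    provenance: dict[int, int] = {}
    records: list[StageRecord] = []
    for i in range(len(plan.stages)):
        try:
            record, _img = _run_stage(v, plan, i, prior, models, view_size, env_cfg, tf)
        except (RenderError, KeyError, NoBoundaryError) as exc:
            return DetectionFailure(plan.landmark, i + 1, str(exc))
        records.append(record)
        for ax, val in record.world_coords.items():
            prior[ax] = val  # latest stage wins on duplicated axes
            provenance[ax] = i
    point = np.array([prior[0], prior[1], prior[2]])
    if not (np.all(np.isfinite(point)) and v.contains(point)):
        return DetectionFailure(plan.landmark, len(records), f"point {point} outside volume")
    return Prediction3D(
        landmark=plan.landmark, point=point, mode=plan.mode, stages=records,
        provenance=provenance,
    )


def run_plan(v: Volume, plan: LandmarkPlan, models, **kw) -> Prediction3D | DetectionFailure:
    if plan.mode == "single":
        return run_single_stage(v, plan, models, **kw)
    return run_multi_stage(v, plan, models, **kw)


def detect_all(
    v: Volume, plans: list[LandmarkPlan], models, **kw
) -> tuple[LandmarkSet, list[Prediction3D | DetectionFailure]]:
    """Run every plan independently; aggregate successes and failures."""
    reports: list[Prediction3D | DetectionFailure] = []
    entries: dict[str, np.ndarray] = {}
    types: dict[str, int] = {}
    for plan in plans:
        result = run_plan(v, plan, models, **kw)
        reports.append(result)
        if isinstance(result, Prediction3D):
            entries[result.landmark] = result.point
            if plan.type_tag is not None:
                types[result.landmark] = plan.type_tag
    return LandmarkSet(entries=entries, types=types), reports


def make_stage_envs(
    cohort,
    plan: LandmarkPlan,
    stage_index: int,
    view_size: int = 512,
    tf: TransferFunction | None = None,
) -> list[tuple[ProjectedImage, np.ndarray]]:
    """Training environments for one (landmark, stage) pair.

    Each cutaway at stage >= 2 is built from the *ground-truth* coordinate
    (teacher forcing), since at training time the earlier stages' targets
    are known exactly.  Returns (image, target pixel) pairs.
    """
    tf = tf or TransferFunction()
    envs = []
    stage = plan.stages[stage_index]
    for vol, lms in cohort:
        truth = lms[plan.landmark]
        prior = {ax: float(truth[ax]) for ax in range(3)} if stage_index > 0 else {}
        spec = build_next_view(vol, plan, stage_index, prior, view_size)
        img = render_view(vol, spec, tf)
        target = img.project_point(truth)
        if not img.geometry.in_view(truth):
            raise RenderError(
                f"truth for {plan.landmark!r} projects outside the {stage.view} view"
            )
        envs.append((img, target))
    return envs
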