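"""Plan validation, cutaway construction, and oracle-driven pipelines."""

import numpy as np
import pytest

from cephalorl import (
    DetectionFailure,
    EnvConfig,
    LandmarkPlan,
    OraclePolicy,
    Prediction3D,
    StagePlan,
    build_next_view,
    detect_all,
    load_plans,
    run_multi_stage,
    run_plan,
    run_single_stage,
    save_landmarks,
    load_landmarks,
)
from cephalorl.staging import PlanError, make_stage_envs

ENV = EnvConfig(patch_size=16, history=1, scales=(4, 2, 1), max_steps=60)


def oracle_models(truth_lookup):
    """Model factory returning an oracle policy aimed at the projected truth."""

    def factory(landmark, view, img):
        return OraclePolicy(img.project_point(truth_lookup[landmark]))

    return factory


# -- plan validation -------------------------------------------------------


def test_packaged_plan_libraries_load():
    paper = load_plans("paper")
    assert len(paper) == 16
    assert {p.mode for p in paper} == {"single", "two_stage", "three_stage"}
    phantom = load_plans("phantom")
    assert {p.landmark for p in phantom} == {"proto_ans", "proto_sella", "proto_foramen"}


def test_cavity_landmarks_have_no_single_stage_plan():
    for lib in ("paper", "phantom"):
        for p in load_plans(lib):
            if p.landmark in ("sella", "cfm", "proto_sella", "proto_foramen"):
                assert p.mode != "single"


def test_plan_axis_coverage_enforced():
    with pytest.raises(PlanError, match="axes"):
        # av + pv both read (x, z); y never predicted
        LandmarkPlan(landmark="x", mode="two_stage", stages=(StagePlan("av"), StagePlan("pv")))


def test_plan_cut_must_reference_earlier_axis():
    with pytest.raises(PlanError, match="cut"):
        # actv cuts along z but stage 1 (tv) reads (x, y)
        LandmarkPlan(landmark="x", mode="two_stage", stages=(StagePlan("tv"), StagePlan("actv")))


def test_plan_stage_count_must_match_mode():
    with pytest.raises(PlanError):
        LandmarkPlan(landmark="x", mode="three_stage", stages=(StagePlan("av"),))


# -- cutaway construction --------------------------------------------------


def test_stage2_cut_positioned_at_predicted_coordinate(clean_phantom):
    vol, _ = clean_phantom
    plan = LandmarkPlan(
        landmark="r_orbitale", mode="two_stage", stages=(StagePlan("av"), StagePlan("sclv"))
    )
    spec = build_next_view(vol, plan, 1, prior={0: 31.5, 2: 40.0})
    assert spec.code == "sclv"
    assert spec.cut.axis == 0 and spec.cut.position == pytest.approx(31.5)

    sella = LandmarkPlan(
        landmark="sella", mode="two_stage", stages=(StagePlan("sclv"), StagePlan("actv"))
    )
    spec2 = build_next_view(vol, sella, 1, prior={1: 30.0, 2: 24.5})
    assert spec2.cut.axis == 2 and spec2.cut.position == pytest.approx(24.5)


def test_stage1_cut_view_cuts_at_median(clean_phantom):
    vol, _ = clean_phantom
    sella = LandmarkPlan(
        landmark="sella", mode="two_stage", stages=(StagePlan("sclv"), StagePlan("actv"))
    )
    spec = build_next_view(vol, sella, 0, prior={})
    assert spec.cut.position == pytest.approx(vol.world_center[0])


def test_missing_prior_coordinate_errors(clean_phantom):
    vol, _ = clean_phantom
    plan = LandmarkPlan(
        landmark="r_orbitale", mode="two_stage", stages=(StagePlan("av"), StagePlan("sclv"))
    )
    with pytest.raises(PlanError, match="earlier stage"):
        build_next_view(vol, plan, 1, prior={2: 40.0})  # x missing


# -- oracle end-to-end -----------------------------------------------------


def _phantom_plans():
    plans = {p.name: p for p in load_plans("phantom")}
    return plans


def test_single_stage_oracle_recovers_surface_landmark(clean_phantom):
    vol, lms = clean_phantom
    plan = _phantom_plans()["proto_ans_single"]
    result = run_single_stage(
        vol, plan, oracle_models(lms.entries), view_size=128, env_cfg=ENV
    )
    assert isinstance(result, Prediction3D)
    assert np.linalg.norm(result.point - lms["proto_ans"]) <= 1.0  # 1 voxel
    assert result.mode == "single"
    assert set(result.provenance) == {0, 1, 2}


def test_two_stage_oracle_recovers_cavity_landmark(clean_phantom):
    vol, lms = clean_phantom
    plan = _phantom_plans()["proto_sella_two_stage"]
    result = run_multi_stage(
        vol, plan, oracle_models(lms.entries), view_size=128, env_cfg=ENV
    )
    assert isinstance(result, Prediction3D)
    assert np.linalg.norm(result.point - lms["proto_sella"]) <= 1.0
    assert len(result.stages) == 2


def test_two_stage_oracle_recovers_foramen_landmark(clean_phantom):
    vol, lms = clean_phantom
    plan = _phantom_plans()["proto_foramen_two_stage"]
    result = run_multi_stage(
        vol, plan, oracle_models(lms.entries), view_size=128, env_cfg=ENV
    )
    assert isinstance(result, Prediction3D)
    assert np.linalg.norm(result.point - lms["proto_foramen"]) <= 1.0


def test_three_stage_oracle_and_stage_bookkeeping(clean_phantom):
    """A three-stage plan runs exactly three inferences, assembles all
    axes, and still recovers the landmark with oracle agents."""
    vol, lms = clean_phantom
    plan = LandmarkPlan(
        landmark="proto_ans",
        mode="three_stage",
        stages=(StagePlan("av"), StagePlan("sclv"), StagePlan("actv")),
    )
    result = run_multi_stage(vol, plan, oracle_models(lms.entries), view_size=128, env_cfg=ENV)
    assert isinstance(result, Prediction3D)
    assert len(result.stages) == 3
    assert np.linalg.norm(result.point - lms["proto_ans"]) <= 1.5


def test_latest_stage_wins_on_duplicate_axes(clean_phantom):
    vol, lms = clean_phantom
    plan = _phantom_plans()["proto_ans_two_stage"]  # av (x,z) then sclv (y,z)
    result = run_multi_stage(vol, plan, oracle_models(lms.entries), view_size=128, env_cfg=ENV)
    assert result.provenance[0] == 0  # x only predicted by stage 1
    assert result.provenance[1] == 1  # y only by stage 2
    assert result.provenance[2] == 1  # z duplicated: stage 2 wins


def test_single_stage_failure_on_air_ray(clean_phantom):
    """An agent stuck in an all-air corner produces a failure record, not
    a fabricated coordinate."""
    vol, _ = clean_phantom

    class CornerPolicy:
        def q_values(self, state, pos, step_px):
            return np.array([0.0, 1.0, 1.0, 0.0])  # always left+up -> corner

    plan = _phantom_plans()["proto_ans_single"]
    result = run_single_stage(vol, plan, CornerPolicy(), view_size=128, env_cfg=ENV)
    assert isinstance(result, DetectionFailure)
    assert any(w in result.reason for w in ("boundary", "bone", "misses"))


def test_detect_all_aggregates_and_round_trips(tmp_path, clean_phantom):
    vol, lms = clean_phantom
    plans = list(_phantom_plans().values())
    lmset, reports = detect_all(
        vol, plans, oracle_models(lms.entries), view_size=128, env_cfg=ENV
    )
    assert len(lmset) == 3  # three distinct landmarks
    assert sum(isinstance(r, Prediction3D) for r in reports) == len(plans)
    path = tmp_path / "pred.csv"
    save_landmarks(lmset, path)
    back = load_landmarks(path)
    for name in lmset.names():
        assert np.allclose(back[name], lmset[name])


def test_detection_deterministic(clean_phantom):
    vol, lms = clean_phantom
    plan = _phantom_plans()["proto_sella_two_stage"]
    r1 = run_plan(vol, plan, oracle_models(lms.entries), view_size=128, env_cfg=ENV)
    r2 = run_plan(vol, plan, oracle_models(lms.entries), view_size=128, env_cfg=ENV)
    assert np.array_equal(r1.point, r2.point)


def test_make_stage_envs_targets_projected_truth(clean_phantom):
    cohort = [clean_phantom]
    plan = _phantom_plans()["proto_sella_two_stage"]
    envs = make_stage_envs(cohort, plan, 1, view_size=128)
    (img, target) = envs[0]
    _, lms = clean_phantom
    assert np.allclose(target, img.project_point(lms["proto_sella"]))
    # stage-2 cut positioned from ground truth (teacher forcing)
    assert img.spec.cut.position == pytest.approx(lms["proto_sella"][2])
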