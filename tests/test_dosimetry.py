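"""DVH computation, dosimetric metrics, and the 150-point scoring system,
checked against sort-and-count brute force."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import replanrl as rl
from replanrl.dosimetry import (
    ClinicalGoal,
    GoalConfigError,
    compute_dvh,
    default_goals,
    metric_value,
    score_goal,
    score_plan,
)
from replanrl.phantom import PhantomConfig, StructureSpec


def make_line_geom(n_voxels: int, spacing=(2.0, 2.0, 2.0), extra=None):
    """A 1xNx1 geometry whose single CTV covers every voxel."""
    import replanrl.phantom as ph

    masks = {"CTV1": np.ones((1, n_voxels, 1), dtype=bool)}
    roles = {"CTV1": "CTV1"}
    if extra:
        for name, mask in extra.items():
            masks[name] = mask
            roles[name] = "OAR"
    return ph.PhantomGeometry(
        grid_shape=(1, n_voxels, 1),
        spacing=spacing,
        masks=masks,
        structure_roles=roles,
        prescriptions={"CTV1": 70.0},
    )


def test_uniform_prescription_dose_gives_full_coverage():
    geom = make_line_geom(10)
    dose = np.full(10, 70.0)
    goal = ClinicalGoal("CTV1", "V", limit=98.0, direction="at_least",
                        max_points=15.0, param=70.0)
    assert metric_value(dose, geom, goal) == 100.0
    dvh = compute_dvh(dose, geom)
    # V at the prescription bin is still 1 (dose >= axis value)
    assert dvh.row("CTV1")[0] == 1.0


def test_zero_dose_dvh_is_one_then_zero():
    geom = make_line_geom(6)
    dvh = compute_dvh(np.zeros(6), geom, n_bins=20)
    row = dvh.row("CTV1")
    assert row[0] == 1.0
    assert np.all(row[1:] == 0.0)


def test_dvh_matches_direct_count():
    geom = make_line_geom(4)
    dose = np.array([10.0, 20.0, 30.0, 40.0])
    dvh = compute_dvh(dose, geom, n_bins=50, dose_max=50.0)
    for b, edge in enumerate(dvh.dose_axis):
        assert dvh.matrix[0, b] == np.count_nonzero(dose >= edge) / 4.0
    # V at 25 GyRBE: exactly half the voxels
    goal = ClinicalGoal("CTV1", "V", limit=98.0, direction="at_least",
                        max_points=1.0, param=25.0)
    assert metric_value(dose, geom, goal) == 50.0


def test_dvh_rows_are_monotone_non_increasing(geom_small, dinf_small):
    rng = np.random.default_rng(3)
    dose = rl.compute_dose(dinf_small, rng.uniform(0, 50, dinf_small.n_beamlets))
    dvh = compute_dvh(dose, geom_small)
    assert np.all(np.diff(dvh.matrix, axis=1) <= 0)
    assert dvh.matrix.min() >= 0 and dvh.matrix.max() <= 1
    assert dvh.shape == (15, 100)


def test_dmean_from_dvh_trapezoid_agrees_with_voxel_mean():
    geom = make_line_geom(200)
    rng = np.random.default_rng(5)
    dose = rng.uniform(0, 80, 200)
    n_bins = 400
    dvh = compute_dvh(dose, geom, n_bins=n_bins, dose_max=84.0)
    width = dvh.dose_axis[1] - dvh.dose_axis[0]
    # mean dose = integral of the cumulative DVH over the dose axis
    est = np.trapezoid(dvh.row("CTV1"), dvh.dose_axis)
    assert abs(est - dose.mean()) <= width


def test_mean_and_max_metrics():
    geom = make_line_geom(4)
    dose = np.array([10.0, 20.0, 30.0, 40.0])
    dmean = ClinicalGoal("CTV1", "Dmean", limit=45.0, direction="at_most",
                         max_points=7.5)
    d0 = ClinicalGoal("CTV1", "D_pct", limit=77.0, direction="at_most",
                      max_points=15.0, param=0.0)
    assert metric_value(dose, geom, dmean) == 25.0
    assert metric_value(dose, geom, d0) == 40.0


def test_hot_volume_metric_uses_rank_of_sorted_doses():
    """D_0.03cc with 0.008 cc voxels is the 4th hottest voxel's dose."""
    n = 50
    geom = make_line_geom(n)  # 2 mm spacing -> 0.008 cc voxels
    assert geom.voxel_volume == pytest.approx(0.008)
    dose = np.arange(50.0, 0.0, -1.0)  # 50, 49, ..., 1
    goal = ClinicalGoal("CTV1", "D_cc", limit=30.0, direction="at_most",
                        max_points=7.5, param=0.03)
    rank = math.ceil(0.03 / 0.008)
    assert rank == 4
    assert metric_value(dose, geom, goal) == sorted(dose, reverse=True)[rank - 1]


@given(
    doses=st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=60),
    v_cc=st.floats(0.001, 1.0),
)
@settings(max_examples=60, deadline=None)
def test_hot_volume_metric_matches_brute_force(doses, v_cc):
    dose = np.asarray(doses)
    geom = make_line_geom(len(doses))
    goal = ClinicalGoal("CTV1", "D_cc", limit=30.0, direction="at_most",
                        max_points=7.5, param=v_cc)
    rank = min(max(math.ceil(v_cc / geom.voxel_volume), 1), len(doses))
    assert metric_value(dose, geom, goal) == sorted(doses, reverse=True)[rank - 1]


def test_empty_structure_raises():
    geom = make_line_geom(4, extra={"ESO": np.zeros((1, 4, 1), dtype=bool)})
    goal = ClinicalGoal("ESO", "Dmean", limit=40.0, direction="at_most",
                        max_points=7.5)
    with pytest.raises(ValueError, match="empty"):
        metric_value(np.zeros(4), geom, goal)


# -- scoring curves ------------------------------------------------------


def test_score_at_the_goal_is_full_points():
    g = ClinicalGoal("PARL", "Dmean", limit=26.0, direction="at_most",
                     max_points=7.5)
    assert score_goal(26.0, g) == 7.5
    assert score_goal(10.0, g) == 7.5


def test_coverage_better_than_goal_is_full_points():
    g = ClinicalGoal("CTV1", "V", limit=98.0, direction="at_least",
                     max_points=15.0, param=70.0)
    assert score_goal(100.0, g) == 15.0
    assert score_goal(93.0, g) == 0.0
    assert score_goal(95.5, g) == pytest.approx(7.5)


def test_linear_interpolation_halfway_to_zero_level():
    g = ClinicalGoal("PARL", "Dmean", limit=26.0, direction="at_most",
                     max_points=7.5)
    assert g.resolved_zero_level() == pytest.approx(32.5)
    assert score_goal(29.25, g) == pytest.approx(3.75)


def test_zero_level_on_wrong_side_is_a_configuration_error():
    with pytest.raises(GoalConfigError):
        ClinicalGoal("PARL", "Dmean", limit=26.0, direction="at_most",
                     max_points=7.5, zero_level=20.0)
    with pytest.raises(GoalConfigError):
        ClinicalGoal("CTV1", "V", limit=98.0, direction="at_least",
                     max_points=15.0, param=70.0, zero_level=99.0)


def test_default_allocation_sums_to_150(geom):
    goals = default_goals(geom.prescriptions)
    assert len(goals) == 16
    assert sum(g.max_points for g in goals) == 150.0


def test_dose_meeting_every_goal_scores_exactly_150(geom):
    dose = np.zeros(geom.n_voxels)
    for name in geom.ctv_names:  # prescription dose on targets, zero elsewhere
        dose[geom.structure_indices(name)] = geom.prescriptions[name]
    score = score_plan(dose, geom, default_goals(geom.prescriptions))
    assert score.total == 150.0
    assert all(v > 0 for v in score.per_goal.values())


def test_zero_dose_spares_oars_but_fails_coverage(geom):
    score = score_plan(np.zeros(geom.n_voxels), geom,
                       default_goals(geom.prescriptions))
    for g in default_goals(geom.prescriptions):
        expected = 0.0 if g.metric == "V" and g.direction == "at_least" else g.max_points
        assert score.per_goal[g.label] == expected


def test_score_is_monotone_in_single_voxel_changes(geom):
    goals = default_goals(geom.prescriptions)
    rng = np.random.default_rng(11)
    dose = rng.uniform(0, 80, geom.n_voxels)
    base = score_plan(dose, geom, goals).total
    # lowering an OAR voxel dose never decreases the total score
    oar_idx = geom.structure_indices("PARL")[0]
    lowered = dose.copy()
    lowered[oar_idx] *= 0.5
    assert score_plan(lowered, geom, goals).total >= base
    # raising an underdosed CTV voxel toward prescription never decreases it
    ctv_idx = geom.structure_indices("CTV1")
    under = ctv_idx[dose[ctv_idx] < 70.0][0]
    raised = dose.copy()
    raised[under] = 70.0
    assert score_plan(raised, geom, goals).total >= base
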