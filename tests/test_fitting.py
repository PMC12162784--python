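import math

import numpy as np
import pytest

from hyperfiber.fitting import (
    FlatObjectiveWarning,
    TensileCurve,
    compare_models,
    fit_fiber_stage,
    fit_matrix_stage,
    fit_single_set,
    fit_two_stage_fiber,
    pool_mean_curve,
    rmse_percent,
)
from hyperfiber.models import (
    FiberParams,
    NeoHookeanParams,
    YeohParams,
    nominal_stress_curve,
)
from hyperfiber.synthetic import SyntheticSpec, generate_curves

GRID = np.arange(0.0, 0.5001, 0.01)


def _curves_from(params, grid=GRID, noise=None, sigma=0.0, n=1, seed=None):
    spec = SyntheticSpec(ground_truth=params, strain_grid=grid,
                         noise_model=noise or "none", sigma_frac=sigma,
                         n_specimens_per_orientation=n, seed=seed)
    return generate_curves(spec)


# ---------------------------------------------------------------------------
# RMSE metric
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pred, obs, expected", [
    ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0),
    ([1.0, 1.0], [2.0, 2.0], 50.0),
    ([0.0, 2.0], [1.0, 1.0], 100.0),
])
def test_rmse_percent_hand_values(pred, obs, expected):
    assert rmse_percent(np.array(pred), np.array(obs)) == pytest.approx(expected)


@pytest.mark.parametrize("normalization", ["mean_abs", "range", "max"])
def test_rmse_scale_invariance(normalization):
    rng = np.random.default_rng(7)
    obs = np.cumsum(rng.random(20)) + 1.0
    pred = obs + rng.normal(0, 0.1, 20)
    base = rmse_percent(pred, obs, normalization)
    scaled = rmse_percent(37.5 * pred, 37.5 * obs, normalization)
    assert scaled == pytest.approx(base, rel=1e-12)


def test_rmse_rejects_degenerate_observed():
    with pytest.raises(ValueError):
        rmse_percent(np.array([1.0, 2.0]), np.array([0.0, 0.0]))
    with pytest.raises(ValueError):
        rmse_percent(np.array([1.0]), np.array([1.0]))


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def test_pooling_averages_resampled_curves():
    grid = np.linspace(0.0, 0.5, 51)
    c1 = TensileCurve(grid, 10.0 * grid, "circumferential", "a")
    c2 = TensileCurve(np.linspace(0.0, 0.55, 23), 20.0 * np.linspace(0.0, 0.55, 23),
                      "circumferential", "b")
    g, mean = pool_mean_curve([c1, c2], grid)
    np.testing.assert_allclose(mean, 15.0 * grid, atol=1e-12)


def test_pooling_rejects_short_curves():
    short = TensileCurve(np.linspace(0, 0.3, 10), np.linspace(0, 1, 10),
                         "circumferential", "s")
    with pytest.raises(ValueError, match="short of the pooling grid"):
        pool_mean_curve([short], np.linspace(0, 0.5, 51))


# ---------------------------------------------------------------------------
# two-stage protocol
# ---------------------------------------------------------------------------

def test_matrix_stage_recovers_yeoh_truth(tissue_yeoh, yeoh_curves):
    circ = [c for c in yeoh_curves if c.orientation == "circumferential"]
    stage = fit_matrix_stage(circ, grid=GRID)
    assert stage.converged
    for name in ("C1", "C2", "C3"):
        got, want = getattr(stage.params, name), getattr(tissue_yeoh, name)
        assert got == pytest.approx(want, rel=1e-3)


def test_matrix_stage_recovers_nested_neo_hookean():
    curves = _curves_from(YeohParams(5.0, 0.0, 0.0))
    stage = fit_matrix_stage([c for c in curves if c.orientation == "circumferential"],
                             grid=GRID)
    assert stage.params.C1 == pytest.approx(5.0, rel=1e-3)
    assert abs(stage.params.C2) < 1e-3
    assert abs(stage.params.C3) < 1e-3


def test_matrix_stage_rejects_empty_input():
    with pytest.raises(ValueError):
        fit_matrix_stage([])


def test_fiber_stage_recovers_stiffening_exponent(tissue_yeoh):
    truth = FiberParams(matrix=tissue_yeoh, E_f=100.0, phi=0.2, k_stiffening=3.0)
    curves = _curves_from(truth)
    stage = fit_fiber_stage([c for c in curves if c.orientation == "longitudinal"],
                            fixed_matrix=tissue_yeoh, E_f=100.0, phi=0.2, grid=GRID)
    assert stage.converged
    assert stage.params.k_stiffening == pytest.approx(3.0, rel=1e-2)


def test_fiber_stage_warns_on_unidentifiable_exponent(tissue_yeoh, yeoh_curves):
    long = [c for c in yeoh_curves if c.orientation == "longitudinal"]
    with pytest.warns(FlatObjectiveWarning):
        stage = fit_fiber_stage(long, fixed_matrix=tissue_yeoh, phi=0.0, grid=GRID)
    # the returned exponent is the untouched initial value, not an estimate
    assert stage.params.k_stiffening == pytest.approx(2.0)
    assert stage.n_iterations == 0


def test_fiber_stage_flags_boundary_hit(tissue_yeoh):
    truth = FiberParams(matrix=tissue_yeoh, E_f=100.0, phi=0.2, k_stiffening=3.0)
    curves = _curves_from(truth)
    stage = fit_fiber_stage([c for c in curves if c.orientation == "longitudinal"],
                            fixed_matrix=tissue_yeoh, E_f=100.0, phi=0.2,
                            bounds={"k": (0.1, 1.0)}, init={"k": 0.5}, grid=GRID)
    assert stage.boundary_hit
    assert stage.params.k_stiffening == pytest.approx(1.0, rel=1e-6)


def test_two_stage_round_trip_on_fiber_truth(emulation_params, anisotropic_curves):
    fit = fit_two_stage_fiber(anisotropic_curves, E_f=emulation_params.E_f,
                              phi=emulation_params.phi,
                              grid=np.linspace(0.0, 0.5, 51))
    assert fit.converged
    assert fit.rmse_circ < 0.5 and fit.rmse_long < 0.5
    assert fit.params.k_stiffening == pytest.approx(
        emulation_params.k_stiffening, rel=1e-2)


# ---------------------------------------------------------------------------
# single-set protocol
# ---------------------------------------------------------------------------

def test_single_set_self_consistency_on_fiber_data(emulation_params, anisotropic_curves):
    fit = fit_single_set("fiber", anisotropic_curves, seed=1,
                         grid=np.linspace(0.0, 0.5, 51),
                         fixed={"E_f": emulation_params.E_f,
                                "phi": emulation_params.phi})
    assert fit.converged
    assert fit.rmse_circ < 0.5
    assert fit.rmse_long < 0.5


def test_single_set_isotropic_cannot_match_anisotropy(emulation_params,
                                                      anisotropic_curves):
    grid = np.linspace(0.0, 0.5, 51)
    fixed = {"E_f": emulation_params.E_f, "phi": emulation_params.phi}
    fiber = fit_single_set("fiber", anisotropic_curves, seed=1, grid=grid,
                           fixed=fixed)
    neo = fit_single_set("neo", anisotropic_curves, seed=1, grid=grid)
    assert neo.rmse_long > fiber.rmse_long


def test_single_set_is_deterministic(anisotropic_curves):
    a = fit_single_set("yeoh", anisotropic_curves, seed=11,
                       grid=np.linspace(0.0, 0.5, 51))
    b = fit_single_set("yeoh", anisotropic_curves, seed=11,
                       grid=np.linspace(0.0, 0.5, 51))
    assert a == b


def test_single_set_unknown_model_lists_supported(anisotropic_curves):
    with pytest.raises(ValueError, match="neo, yeoh, ogden, goh, fiber"):
        fit_single_set("mooney", anisotropic_curves)


def test_optimum_no_better_than_truth_on_noise_free_data(tissue_yeoh, yeoh_curves):
    circ = [c for c in yeoh_curves if c.orientation == "circumferential"]
    stage = fit_matrix_stage(circ, grid=GRID)
    grid, obs = pool_mean_curve(circ, GRID)
    sse_truth = float(np.sum((nominal_stress_curve(tissue_yeoh, grid) - obs) ** 2))
    assert stage.objective_value <= sse_truth + 1e-9


def test_noisy_median_recovery_of_yeoh_constants(tissue_yeoh):
    recovered = []
    for rep in range(20):
        curves = _curves_from(tissue_yeoh, noise="gaussian_additive",
                              sigma=0.02, seed=1000 + rep)
        circ = [c for c in curves if c.orientation == "circumferential"]
        stage = fit_matrix_stage(circ, grid=GRID, n_starts=3)
        recovered.append([stage.params.C1, stage.params.C2, stage.params.C3])
    med = np.median(np.array(recovered), axis=0)
    truth = np.array([tissue_yeoh.C1, tissue_yeoh.C2, tissue_yeoh.C3])
    assert np.all(np.abs(med - truth) / np.abs(truth) < 0.10)


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

def test_compare_ranks_generating_model_first(yeoh_curves):
    results = compare_models(yeoh_curves, ["yeoh"], seed=1, grid=GRID)
    assert results[0].model_name == "yeoh"
    assert results[0].rmse_circ < 0.5


def test_compare_rejects_empty_model_list(yeoh_curves):
    with pytest.raises(ValueError):
        compare_models(yeoh_curves, [])


def test_compare_isolates_per_model_failures(yeoh_curves):
    results = compare_models(yeoh_curves, ["yeoh", "mooney"], seed=1, grid=GRID)
    by_name = {r.model_name: r for r in results}
    assert by_name["mooney"].error is not None
    assert not by_name["mooney"].converged
    assert by_name["yeoh"].converged
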