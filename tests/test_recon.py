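"""Homogeneous and two-region fitting."""

import numpy as np
import pytest

from usdot.forward import (
    MeasurementSet,
    ProbeGeometry,
    TimeGrid,
    apply_noise,
    default_probe,
    gaussian_irf,
    run_forward,
)
from usdot.optics import homogeneous_maps, two_region_maps
from usdot.preprocess import NTW_DEFAULT
from usdot.priors import PriorMask
from usdot.recon import (
    MIN_SD_DISTANCE_MM,
    ReconError,
    TwoRegionParams,
    fit_homogeneous,
    fit_two_region,
    predict_two_region,
    semi_infinite_reflectance,
    used_pairs,
)


def test_distance_filter(probe):
    pairs = used_pairs(probe)
    dist = probe.distances()
    assert all(dist[i, j] > MIN_SD_DISTANCE_MM for i, j in pairs)
    assert 0 < len(pairs) < probe.n_sources * probe.n_detectors
    assert len(pairs) == (dist > MIN_SD_DISTANCE_MM).sum()


def test_parameter_box_validation():
    with pytest.raises(ReconError):
        TwoRegionParams(0.07, 0.01, 1.0, 1.0)
    with pytest.raises(ReconError):
        TwoRegionParams(0.01, 0.01, 2.5, 1.0)
    with pytest.raises(ReconError):
        TwoRegionParams(0.01, 0.01, 1.0, 1.0, tshift=30.0)


def test_homogeneous_fit_recovers_analytic_self_data(probe):
    """Inverse crime: data generated by the analytic model itself."""
    tg = TimeGrid(dt=25.0, n_steps=160)
    dist = probe.distances()
    truth = (0.01, 1.0)
    curves = np.zeros((1, probe.n_sources, probe.n_detectors, tg.n_steps))
    for i in range(probe.n_sources):
        for j in range(probe.n_detectors):
            curves[0, i, j] = semi_infinite_reflectance(
                np.array([dist[i, j]]), tg.times, *truth)[0]
    ms = MeasurementSet(wavelengths=np.array([785.0]), times=tg.times, curves=curves,
                        geometry=probe)
    fit = fit_homogeneous(ms, 0)
    assert fit.params.mua_bulk == pytest.approx(truth[0], rel=0.01)
    assert fit.params.musp_bulk == pytest.approx(truth[1], rel=0.01)
    # identical data -> identical fit (determinism)
    fit2 = fit_homogeneous(ms, 0)
    assert fit2.params.mua_bulk == fit.params.mua_bulk


@pytest.fixture(scope="module")
def homogeneous_noisy(probe):
    maps = homogeneous_maps(0.008, 1.1, (32, 29, 15), 2.0)
    tg = TimeGrid(dt=25.0, n_steps=200)
    ms = run_forward(maps, probe, tg, irf=gaussian_irf(400.0, dt=5.0))
    return apply_noise(ms, 1.0e6, rng_seed=3)


def test_homogeneous_fit_cross_model_recovery(homogeneous_noisy):
    """Numerical slab data fitted with the analytic semi-infinite model."""
    fit = fit_homogeneous(homogeneous_noisy, 0)
    assert fit.params.mua_bulk == pytest.approx(0.008, rel=0.10)
    assert fit.params.musp_bulk == pytest.approx(1.1, rel=0.15)


@pytest.fixture(scope="module")
def desk_scale_two_region(probe, coarse_grid):
    shape, h, (X, Y, Z) = coarse_grid
    ball = (X**2 + Y**2 + (Z - 15.0) ** 2) <= 8.0**2
    truth = TwoRegionParams(0.02, 0.008, 0.9, 1.1)
    maps = two_region_maps(ball, truth.mua_in, truth.mua_bulk, truth.musp_in,
                           truth.musp_bulk, h)
    tg = TimeGrid(dt=50.0, n_steps=80)
    irf = gaussian_irf(400.0, dt=10.0)
    ms = run_forward(maps, probe, tg, irf=irf)
    prior = PriorMask(ball, h, np.array([-30.0, -27.5, 0.0]))
    return ms, prior, truth, tg, irf


def test_two_region_degenerate_equals_homogeneous(desk_scale_two_region, probe):
    ms, prior, truth, tg, irf = desk_scale_two_region
    p = TwoRegionParams(0.008, 0.008, 1.1, 1.1)
    pred_masked = predict_two_region(p, prior, probe, tg, 785.0, irf)
    other = PriorMask(np.roll(prior.mask, 2, axis=0), prior.spacing, prior.origin)
    pred_other = predict_two_region(p, other, probe, tg, 785.0, irf)
    assert np.allclose(pred_masked, pred_other, rtol=1e-9)


def test_tshift_moves_the_curve(desk_scale_two_region, probe):
    ms, prior, truth, tg, irf = desk_scale_two_region
    base = predict_two_region(truth, prior, probe, tg, 785.0, irf)
    shifted = predict_two_region(
        TwoRegionParams(truth.mua_in, truth.mua_bulk, truth.musp_in, truth.musp_bulk,
                        tshift=25.0), prior, probe, tg, 785.0, irf)
    # evaluating at t + 25 ps advances the curve: earlier apparent peak
    i, j = 0, 4
    assert np.argmax(shifted[i, j]) <= np.argmax(base[i, j])
    a = base[i, j] / base[i, j].max()
    b = shifted[i, j] / base[i, j].max()
    assert np.max(np.abs(a - b)) > 0.01


def test_absorbing_inclusion_lowers_late_counts(desk_scale_two_region, probe):
    ms, prior, truth, tg, irf = desk_scale_two_region
    lo = predict_two_region(TwoRegionParams(0.008, 0.008, 1.1, 1.1), prior, probe, tg,
                            785.0, irf)
    hi = predict_two_region(TwoRegionParams(0.03, 0.008, 1.1, 1.1), prior, probe, tg,
                            785.0, irf)
    pairs = used_pairs(probe)
    i, j = pairs[0]
    late = slice(tg.n_steps // 2, None)
    assert hi[i, j][late].sum() < lo[i, j][late].sum()


def test_two_region_fit_noiseless_recovery_and_bounds(desk_scale_two_region):
    ms, prior, truth, tg, irf = desk_scale_two_region
    init = TwoRegionParams(0.009, 0.009, 1.0, 1.0)
    fit = fit_two_region(ms, prior, 0, init=init, max_nfev=40)
    p = fit.params
    assert p.mua_in == pytest.approx(truth.mua_in, rel=0.05)
    assert p.musp_in == pytest.approx(truth.musp_in, rel=0.15)
    for v in (p.mua_in, p.mua_bulk):
        assert 0 < v <= 0.06
    for v in (p.musp_in, p.musp_bulk):
        assert 0 < v <= 2.2
    assert abs(p.tshift) <= 25.0
    assert all(ms.geometry.distances()[i, j] > MIN_SD_DISTANCE_MM
               for i, j in fit.pairs_used)


def test_two_region_fit_requires_nonempty_prior(desk_scale_two_region):
    ms, prior, truth, tg, irf = desk_scale_two_region
    empty = PriorMask(np.zeros_like(prior.mask), prior.spacing, prior.origin)
    with pytest.raises(ReconError):
        fit_two_region(ms, empty, 0)


def test_distance_filter_can_remove_everything(desk_scale_two_region):
    ms, prior, truth, tg, irf = desk_scale_two_region
    with pytest.raises(ReconError):
        fit_two_region(ms, prior, 0, min_distance=1000.0)
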