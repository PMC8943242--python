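"""Forward solver: physics sanity, IRF handling, photon-counting noise."""

import numpy as np
import pytest

from usdot.forward import (
    IRF,
    ForwardError,
    MeasurementSet,
    ProbeGeometry,
    TPSF,
    TimeGrid,
    apply_noise,
    boundary_constant,
    convolve_irf,
    detect,
    gaussian_irf,
    propagate_fluence,
    run_forward,
    solve_td_diffusion,
)
from usdot.optics import homogeneous_maps

C = 0.299792458 / 1.4  # mm/ps in tissue


def test_boundary_constant_reasonable_for_tissue():
    # internal reflection raises A well above the matched-boundary value 1
    assert 2.0 < boundary_constant(1.4) < 4.0
    assert boundary_constant(1.0) == pytest.approx(1.0, abs=0.15)


def test_zero_source_stays_zero():
    maps = homogeneous_maps(0.01, 1.0, (8, 8, 8), 4.0)
    movie = propagate_fluence(maps, np.zeros((8, 8, 8)), TimeGrid(dt=25, n_steps=10))
    assert np.all(movie == 0)


def test_fluence_nonnegative_and_decaying(probe):
    maps = homogeneous_maps(0.01, 1.0, (12, 11, 6), 5.0)
    movie = solve_td_diffusion(maps, probe, source=0, timegrid=TimeGrid(dt=50, n_steps=40))
    assert movie.min() >= -1e-9 * movie.max()
    total = movie.sum(axis=(1, 2, 3))
    assert total[-1] < total[5]


def test_absorption_scaling_law_deep_interior():
    """Raising mu_a by d multiplies the interior fluence by exp(-d c t)."""
    shape, h = (20, 20, 20), 4.0
    tg = TimeGrid(dt=5.0, n_steps=300)
    ax = (np.arange(20) - 9.5) * h
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    init = np.exp(-(X**2 + Y**2 + Z**2) / (2 * 4.0**2))
    obs = lambda f: f[8:13, 8:13, 8:13].sum()
    lo = propagate_fluence(homogeneous_maps(0.005, 1.0, shape, h), init, tg, observe=obs)
    hi = propagate_fluence(homogeneous_maps(0.010, 1.0, shape, h), init, tg, observe=obs)
    expected = np.exp(-0.005 * C * tg.times)
    ratio = np.array(hi) / np.array(lo)
    assert np.allclose(ratio, expected, rtol=0.02)


def test_photon_conservation_reflective_lossless():
    shape, h = (10, 10, 10), 4.0
    maps = homogeneous_maps(1e-9, 1.0, shape, h)
    init = np.zeros(shape)
    init[5, 5, 5] = 1.0
    tg = TimeGrid(dt=50.0, n_steps=40)
    totals = propagate_fluence(maps, init, tg, boundary="reflective",
                               observe=lambda f: f.sum())
    totals = np.array(totals)
    assert np.all(np.abs(totals / totals[0] - 1.0) < 0.01)


def test_detector_symmetry_and_peak_ordering():
    """Symmetric detectors see identical curves; farther detectors peak later."""
    maps = homogeneous_maps(0.008, 1.1, (16, 16, 8), 4.0)
    geom = ProbeGeometry(
        sources=np.array([[0.0, 0.0, 0.0]]),
        detectors=np.array([[-16.0, 0.0, 0.0], [16.0, 0.0, 0.0], [24.0, 0.0, 0.0]]),
    )
    tg = TimeGrid(dt=25.0, n_steps=120)
    ms = run_forward(maps, geom, tg)
    left, right, far = ms.curves[0, 0]
    assert np.allclose(left, right, rtol=1e-6, atol=1e-12 * right.max())
    assert np.argmax(far) > np.argmax(right)


def test_detect_matches_run_forward(probe):
    maps = homogeneous_maps(0.008, 1.1, (12, 11, 6), 5.0)
    tg = TimeGrid(dt=50.0, n_steps=40)
    movie = solve_td_diffusion(maps, probe, source=2, timegrid=tg)
    tpsf = detect(movie, maps, probe, detector=3, timegrid=tg)
    ms = run_forward(maps, probe, tg)
    assert np.allclose(tpsf.counts, ms.curves[0, 2, 3], rtol=1e-8)


def test_detector_width_changes_counts_smoothly(probe):
    from dataclasses import replace

    maps = homogeneous_maps(0.008, 1.1, (12, 11, 6), 5.0)
    tg = TimeGrid(dt=50.0, n_steps=40)
    totals = []
    for w in (0.8, 1.0, 1.2):
        geom = replace(probe, detector_width=w)
        ms = run_forward(maps, geom, tg)
        totals.append(ms.curves[0, 0, 0].sum())
    assert abs(totals[2] - totals[0]) / totals[1] < 0.2


def test_reciprocity_source_detector_swap():
    maps = homogeneous_maps(0.008, 1.1, (24, 24, 10), 4.0)
    tg = TimeGrid(dt=25.0, n_steps=120)
    a = np.array([-14.0, 2.0, 0.0])  # on voxel centers: profile sampling is
    b = np.array([14.0, -6.0, 0.0])  # then identical for source and detector
    ms1 = run_forward(maps, ProbeGeometry(sources=[a], detectors=[b]), tg)
    ms2 = run_forward(maps, ProbeGeometry(sources=[b], detectors=[a]), tg)
    y1, y2 = ms1.curves[0, 0, 0], ms2.curves[0, 0, 0]
    sel = y1 > 1e-3 * y1.max()
    assert np.linalg.norm(y1[sel] - y2[sel]) / np.linalg.norm(y1[sel]) < 0.03


def test_time_step_refinement_converges():
    maps = homogeneous_maps(0.01, 1.0, (12, 11, 6), 5.0)
    geom = ProbeGeometry(sources=[[-14.0, 0.0, 0.0]], detectors=[[14.0, 0.0, 0.0]])
    coarse = run_forward(maps, geom, TimeGrid(dt=12.5, n_steps=240)).curves[0, 0, 0]
    fine = run_forward(maps, geom, TimeGrid(dt=6.25, n_steps=480)).curves[0, 0, 0]
    fine_on_coarse = fine[1::2]  # samples at matching times
    sel = coarse > 1e-3 * coarse.max()
    rel = np.linalg.norm(coarse[sel] - fine_on_coarse[sel]) / np.linalg.norm(coarse[sel])
    assert rel < 0.02


def test_irf_delta_identity_and_area_conservation():
    t = 25.0 * np.arange(1, 120)
    y = np.exp(-0.5 * ((t - 800) / 200.0) ** 2)
    tpsf = TPSF(0, 0, 785.0, t, y)
    delta = IRF(times=np.array([0.0, 25.0]), amplitude=np.array([1.0, 0.0]))
    out = convolve_irf(tpsf, delta)
    assert np.allclose(out.counts[:-1], y[:-1] * (delta.resample(25.0).sum() * 25.0),
                       rtol=1e-6)
    g = gaussian_irf(fwhm=300.0, dt=5.0)
    out_g = convolve_irf(tpsf, g)
    assert out_g.counts.sum() == pytest.approx(y.sum(), rel=0.01)


def test_broader_irf_widens_curve():
    t = 25.0 * np.arange(1, 160)
    y = np.exp(-0.5 * ((t - 900) / 150.0) ** 2)
    tpsf = TPSF(0, 0, 785.0, t, y)

    def fwhm(c):
        above = np.nonzero(c >= c.max() / 2)[0]
        return above[-1] - above[0]

    narrow = convolve_irf(tpsf, gaussian_irf(fwhm=200.0, dt=5.0))
    broad = convolve_irf(tpsf, gaussian_irf(fwhm=600.0, dt=5.0))
    assert fwhm(broad.counts) >= fwhm(narrow.counts)


@pytest.fixture(scope="module")
def noiseless_set(probe):
    maps = homogeneous_maps(0.008, 1.1, (12, 11, 6), 5.0)
    return run_forward(maps, probe, TimeGrid(dt=50.0, n_steps=80),
                       irf=gaussian_irf(400.0, dt=10.0))


def test_noise_anchors_largest_separation_pair(noiseless_set):
    n_exp = 1.0e6
    noisy = apply_noise(noiseless_set, n_exp, rng_seed=0)
    dist = noisy.geometry.distances()
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    total = noisy.curves[0, i, j].sum()
    assert abs(total - n_exp) <= 3.0 * np.sqrt(n_exp)
    # other pairs keep their integral ratios (up to Poisson fluctuation)
    k, l = 0, 0
    ratio_true = noiseless_set.curves[0, k, l].sum() / noiseless_set.curves[0, i, j].sum()
    ratio_noisy = noisy.curves[0, k, l].sum() / total
    assert ratio_noisy == pytest.approx(ratio_true, rel=0.01)


def test_noise_determinism_and_large_count_limit(noiseless_set):
    a = apply_noise(noiseless_set, 1e6, rng_seed=42)
    b = apply_noise(noiseless_set, 1e6, rng_seed=42)
    assert np.array_equal(a.curves, b.curves)
    big = apply_noise(noiseless_set, 1e9, rng_seed=1)
    y = noiseless_set.curves[0, 0, 0]
    shape_true = y / y.sum()
    z = big.curves[0, 0, 0]
    shape_noisy = z / z.sum()
    sel = shape_true > 1e-4
    assert np.max(np.abs(shape_noisy[sel] / shape_true[sel] - 1.0)) < 0.01


def test_noise_rejects_double_application_and_bad_nexpect(noiseless_set):
    noisy = apply_noise(noiseless_set, 1e5, rng_seed=0)
    with pytest.raises(ForwardError):
        apply_noise(noisy, 1e5)
    with pytest.raises(ForwardError):
        apply_noise(noiseless_set, -1.0)


def test_probe_layout_matches_design(probe):
    assert probe.n_sources == 8 and probe.n_detectors == 8
    assert set(np.round(np.abs(probe.sources[:, 1]), 1)) == {17.5}
    assert set(np.round(np.abs(probe.detectors[:, 1]), 1)) == {10.8}
    xs = sorted(set(probe.sources[:, 0]))
    assert np.allclose(np.diff(xs), 12.0)
    assert np.allclose(probe.sources.mean(axis=0), [0, 0, 0])
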