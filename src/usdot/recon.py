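"""Homogeneous and two-region nonlinear fitting of time-resolved curves.

The homogeneous fit recovers one (mu_a, mu_s') per wavelength by matching a
semi-infinite analytic time-domain reflectance model (extrapolated-boundary
dipole solution) to the preprocessed data; it provides the effective bulk
coefficients and the initialization of the two-region fit.

The two-region fit is the core inversion: given a morphological prior mask,
the domain is split into inclusion and bulk, each homogeneous, and the five
parameters (mu_a_in, mu_a_bulk, mu_s'_in, mu_s'_bulk, tshift) are estimated
by bounded trust-region least squares on the binned, self-normalized,
Poisson-weighted curves.  Only source-detector separations above 27 mm enter
the objective (long paths favor absorption convergence and suppress local
perturbations).  Box bounds: 0 < mu_a < 0.06 mm^-1, 0 < mu_s' < 2.2 mm^-1,
|tshift| <= 25 ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from usdot.forward import (
    C_VACUUM_MM_PS,
    IRF,
    MeasurementSet,
    ProbeGeometry,
    TimeGrid,
    boundary_constant,
    run_forward,
)
from usdot.optics import two_region_maps
from usdot.preprocess import BinnedCurve, NTW_DEFAULT, bin_normalize, poisson_weights, select_roi
from usdot.priors import PriorMask

__all__ = [
    "MUA_BOUNDS",
    "MUSP_BOUNDS",
    "TSHIFT_BOUND_PS",
    "MIN_SD_DISTANCE_MM",
    "TwoRegionParams",
    "FitResult",
    "used_pairs",
    "semi_infinite_reflectance",
    "fit_homogeneous",
    "predict_two_region",
    "fit_two_region",
]

MUA_BOUNDS = (1.0e-4, 0.06)  # mm^-1
MUSP_BOUNDS = (0.05, 2.2)  # mm^-1
TSHIFT_BOUND_PS = 25.0
MIN_SD_DISTANCE_MM = 27.0


class ReconError(ValueError):
    pass


@dataclass
class TwoRegionParams:
    """Parameters of the two-region model (mm^-1; tshift in ps)."""

    mua_in: float
    mua_bulk: float
    musp_in: float
    musp_bulk: float
    tshift: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.mua_in, self.mua_bulk):
            if not 0 < v <= MUA_BOUNDS[1]:
                raise ReconError(f"mu_a {v} outside (0, {MUA_BOUNDS[1]}] mm^-1")
        for v in (self.musp_in, self.musp_bulk):
            if not 0 < v <= MUSP_BOUNDS[1]:
                raise ReconError(f"mu_s' {v} outside (0, {MUSP_BOUNDS[1]}] mm^-1")
        if abs(self.tshift) > TSHIFT_BOUND_PS + 1e-9:
            raise ReconError(f"|tshift| > {TSHIFT_BOUND_PS} ps")

    def as_array(self) -> np.ndarray:
        return np.array([self.mua_in, self.mua_bulk, self.musp_in, self.musp_bulk,
                         self.tshift])


@dataclass
class FitResult:
    """Outcome of a per-wavelength fit."""

    params: TwoRegionParams
    objective: float
    n_evaluations: int
    converged: bool
    pairs_used: list[tuple[int, int]]
    wavelength: float
    message: str = ""


def used_pairs(geometry: ProbeGeometry, min_distance: float = MIN_SD_DISTANCE_MM
               ) -> list[tuple[int, int]]:
    """Source-detector pairs with separation above the distance filter."""
    dist = geometry.distances()
    return [tuple(p) for p in np.argwhere(dist > min_distance)]


def semi_infinite_reflectance(
    rho: np.ndarray, t: np.ndarray, mua: float, musp: float, refractive_index: float = 1.4
) -> np.ndarray:
    """Analytic TD reflectance of a homogeneous semi-infinite medium.

    Extrapolated-boundary dipole solution: an isotropic source at depth
    z0 = 1/mu_s' and its negative image mirrored across the extrapolated
    boundary at z = -2 A D.  rho in mm, t in ps; output shape
    (len(rho), len(t)).
    """
    rho = np.atleast_1d(np.asarray(rho, dtype=float))[:, None]
    t = np.atleast_1d(np.asarray(t, dtype=float))[None, :]
    c = C_VACUUM_MM_PS / refractive_index
    D = 1.0 / (3.0 * musp)
    z0 = 1.0 / musp
    zb = 2.0 * boundary_constant(refractive_index) * D
    with np.errstate(divide="ignore", invalid="ignore"):
        q = 4.0 * D * c * t
        pref = 0.5 * (4.0 * np.pi * D * c) ** (-1.5) * t ** (-2.5)
        body = z0 * np.exp(-(z0**2) / q) + (z0 + 2 * zb) * np.exp(-((z0 + 2 * zb) ** 2) / q)
        out = pref * np.exp(-mua * c * t - rho**2 / q) * body
    return np.where(t > 0, out, 0.0)


def _binned_data(
    ms: MeasurementSet, lam_idx: int, pairs: list[tuple[int, int]], ntw: int
) -> list[BinnedCurve]:
    out = []
    for i, j in pairs:
        b = bin_normalize(ms.tpsf(lam_idx, i, j), ntw=ntw)
        poisson_weights(b)
        out.append(b)
    return out


def _bin_model_curve(times: np.ndarray, y: np.ndarray, edges: np.ndarray,
                     tshift: float = 0.0) -> np.ndarray:
    """Bin a model curve on the data's edges, evaluating at t + tshift."""
    if tshift != 0.0:
        y = np.interp(times + tshift, times, y, left=0.0, right=0.0)
    from usdot.preprocess import _cumulative_integral

    raw = np.diff(_cumulative_integral(times, y, edges))
    total = raw.sum()
    if total <= 0:
        return np.full(len(edges) - 1, np.nan)
    return raw / total


def fit_homogeneous(
    ms: MeasurementSet,
    lam_idx: int = 0,
    init: tuple[float, float] = (0.01, 1.0),
    ntw: int = NTW_DEFAULT,
    min_distance: float = MIN_SD_DISTANCE_MM,
    max_nfev: int = 100,
) -> FitResult:
    """Global homogeneous fit of (mu_a, mu_s') for one wavelength.

    The analytic semi-infinite model, convolved with the measurement IRF, is
    matched to the preprocessed data over all pairs passing the distance
    filter.  A fictitious time shift (same +-25 ps box as the two-region
    model) is fitted alongside to absorb timing offsets between model and
    data.
    """
    pairs = used_pairs(ms.geometry, min_distance)
    if not pairs:
        raise ReconError("distance filter removed every source-detector pair")
    binned = _binned_data(ms, lam_idx, pairs, ntw)
    dist = ms.geometry.distances()
    rho = np.array([dist[i, j] for i, j in pairs])
    times = ms.times
    kernel = ms.irf.resample(ms.dt) if ms.irf is not None else None

    p_data = np.concatenate([b.p for b in binned])
    sig = np.sqrt(np.concatenate([b.sigma2 for b in binned]))

    def residuals(x: np.ndarray) -> np.ndarray:
        mua, musp, tshift = x
        model = semi_infinite_reflectance(rho, times, mua, musp, 1.4)
        if kernel is not None:
            model = np.apply_along_axis(
                lambda y: np.convolve(y, kernel)[: len(times)] * ms.dt, 1, model
            )
        p_model = np.concatenate(
            [_bin_model_curve(times, model[k], binned[k].edges, tshift)
             for k in range(len(pairs))]
        )
        r = (p_data - p_model) / sig
        return np.where(np.isfinite(r), r, 1e3)

    res = least_squares(
        residuals,
        x0=np.array([init[0], init[1], 0.0]),
        bounds=([MUA_BOUNDS[0], MUSP_BOUNDS[0], -TSHIFT_BOUND_PS],
                [MUA_BOUNDS[1], MUSP_BOUNDS[1], TSHIFT_BOUND_PS]),
        x_scale=[0.01, 1.0, 10.0],
        max_nfev=max_nfev,
    )
    params = TwoRegionParams(
        mua_in=res.x[0], mua_bulk=res.x[0], musp_in=res.x[1], musp_bulk=res.x[1],
        tshift=res.x[2],
    )
    return FitResult(
        params=params,
        objective=float(res.cost),
        n_evaluations=int(res.nfev),
        converged=bool(res.status > 0),
        pairs_used=pairs,
        wavelength=float(ms.wavelengths[lam_idx]),
        message=res.message,
    )


def predict_two_region(
    params: TwoRegionParams,
    prior: PriorMask,
    geometry: ProbeGeometry,
    timegrid: TimeGrid,
    wavelength: float = 785.0,
    irf: IRF | None = None,
    refractive_index: float = 1.4,
) -> np.ndarray:
    """Model curves (n_sources, n_detectors, n_steps) for the two-region map.

    Builds piecewise-constant optical maps from the prior mask (inclusion
    voxels take the in-values, all others the bulk values), runs the forward
    solver, convolves with the IRF, and evaluates at t + tshift by linear
    interpolation on the native grid.
    """
    if not prior.mask.any():
        raise ReconError("empty prior mask")
    maps = two_region_maps(
        prior.mask, params.mua_in, params.mua_bulk, params.musp_in, params.musp_bulk,
        prior.spacing, wavelength, refractive_index,
    )
    maps.origin = prior.origin  # keep the probe frame of the prior grid
    ms = run_forward(maps, geometry, timegrid, irf=irf)
    curves = ms.curves[0]
    if params.tshift != 0.0:
        t = timegrid.times
        curves = np.stack(
            [
                np.stack(
                    [np.interp(t + params.tshift, t, curves[i, j], left=0.0, right=0.0)
                     for j in range(curves.shape[1])]
                )
                for i in range(curves.shape[0])
            ]
        )
    return curves


def fit_two_region(
    ms: MeasurementSet,
    prior: PriorMask,
    lam_idx: int = 0,
    init: TwoRegionParams | None = None,
    ntw: int = NTW_DEFAULT,
    min_distance: float = MIN_SD_DISTANCE_MM,
    max_nfev: int = 60,
    timegrid: TimeGrid | None = None,
    refractive_index: float = 1.4,
    xtol: float = 1e-4,
    ftol: float = 1e-6,
) -> FitResult:
    """Bounded least-squares fit of the five two-region parameters.

    Residuals are the Poisson-weighted differences between binned data and
    binned model curves over the distance-filtered pairs; the Jacobian is
    built by forward differences (each column costs one forward solve).
    Deterministic given the initialization.
    """
    if not prior.mask.any():
        raise ReconError("empty prior mask")
    pairs = used_pairs(ms.geometry, min_distance)
    if not pairs:
        raise ReconError("distance filter removed every source-detector pair")
    if timegrid is None:
        dt = ms.dt
        timegrid = TimeGrid(dt=dt, n_steps=len(ms.times), t0=float(ms.times[0]) - dt)
    binned = _binned_data(ms, lam_idx, pairs, ntw)
    p_data = np.concatenate([b.p for b in binned])
    sig = np.sqrt(np.concatenate([b.sigma2 for b in binned]))
    lam = float(ms.wavelengths[lam_idx])
    times = timegrid.times

    if init is None:
        init = TwoRegionParams(mua_in=0.01, mua_bulk=0.01, musp_in=1.0, musp_bulk=1.0)

    from usdot.optics import two_region_maps as _maps

    # forward curves depend on the four optical parameters only; cache them so
    # the tshift direction of the Jacobian costs no extra solve
    cache: dict[tuple, np.ndarray] = {}

    def curves_for(x4: tuple) -> np.ndarray:
        if x4 not in cache:
            if len(cache) > 16:
                cache.clear()
            maps = _maps(prior.mask, x4[0], x4[1], x4[2], x4[3], prior.spacing, lam,
                         refractive_index)
            maps.origin = prior.origin
            cache[x4] = run_forward(maps, ms.geometry, timegrid, irf=ms.irf).curves[0]
        return cache[x4]

    def residuals(x: np.ndarray) -> np.ndarray:
        curves = curves_for(tuple(np.round(x[:4], 12)))
        tshift = x[4]
        p_model = []
        for k, (i, j) in enumerate(pairs):
            y = curves[i, j]
            if tshift != 0.0:
                y = np.interp(times + tshift, times, y, left=0.0, right=0.0)
            p_model.append(_bin_model_curve(times, y, binned[k].edges))
        r = (p_data - np.concatenate(p_model)) / sig
        r0 = residuals_init_cache["r0"]
        return np.where(np.isfinite(r), r, 1e3 if r0 is None else r0)

    residuals_init_cache: dict = {"r0": None}
    r_init = residuals(init.as_array())
    if not np.all(np.isfinite(r_init)):
        raise ReconError("objective non-finite at the initial point")
    residuals_init_cache["r0"] = r_init

    lb = np.array([MUA_BOUNDS[0], MUA_BOUNDS[0], MUSP_BOUNDS[0], MUSP_BOUNDS[0],
                   -TSHIFT_BOUND_PS])
    ub = np.array([MUA_BOUNDS[1], MUA_BOUNDS[1], MUSP_BOUNDS[1], MUSP_BOUNDS[1],
                   TSHIFT_BOUND_PS])
    steps = np.array([1e-4, 1e-4, 5e-3, 5e-3, 0.5])  # forward-difference steps

    def jacobian(x: np.ndarray) -> np.ndarray:
        f0 = residuals(x)
        J = np.empty((f0.size, 5))
        for m in range(5):
            h = steps[m] if x[m] + steps[m] <= ub[m] else -steps[m]
            xp = x.copy()
            xp[m] += h
            J[:, m] = (residuals(xp) - f0) / h
        return J

    res = least_squares(
        residuals,
        x0=np.clip(init.as_array(), lb, ub),
        jac=jacobian,
        bounds=(lb, ub),
        x_scale=[0.01, 0.01, 0.5, 0.5, 10.0],
        xtol=xtol,
        ftol=ftol,
        max_nfev=max_nfev,
    )
    params = TwoRegionParams(*res.x)
    return FitResult(
        params=params,
        objective=float(res.cost),
        n_evaluations=int(res.nfev),
        converged=bool(res.status > 0),
        pairs_used=pairs,
        wavelength=lam,
        message=res.message,
    )
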