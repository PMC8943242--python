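"""Time-domain diffusion forward model for a reflectance probe.

Photon migration is modeled by the time-domain diffusion equation

    (1/c) dPhi/dt - div(kappa grad Phi) + mu_a Phi = 0,   kappa = 1/(3 mu_s')

with Robin boundary condition Phi + 2 A kappa dPhi/dn = 0, discretized by
cell-centered finite differences (harmonic averaging of kappa at faces) and
implicit Euler time stepping.  The pulsed source is an initial condition: a
unit-integral Gaussian of width 0.5 mm deposited one transport mean free path
below the source site.  Detectors read the boundary exitance through a
Gaussian surface profile of width 1 mm.  Model curves are convolved with an
instrument response function; photon-counting noise is Poisson, anchored by
the expected number of counts at the largest source-detector separation.

Units: mm, ps, mm^-1.  Default time grid: 400 steps of 25 ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.special import erf

from usdot.optics import OpticalMaps

__all__ = [
    "C_VACUUM_MM_PS",
    "ProbeGeometry",
    "TimeGrid",
    "TPSF",
    "IRF",
    "MeasurementSet",
    "default_probe",
    "boundary_constant",
    "gaussian_irf",
    "load_irf",
    "propagate_fluence",
    "solve_td_diffusion",
    "detect",
    "convolve_irf",
    "run_forward",
    "apply_noise",
]

C_VACUUM_MM_PS = 0.299792458  # speed of light in vacuum, mm/ps


class ForwardError(ValueError):
    pass


def boundary_constant(n: float = 1.4) -> float:
    """Robin constant A = (1+R)/(1-R) via the diffuse Fresnel-mismatch
    polynomial approximation for the internal reflection coefficient."""
    r_d = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_d) / (1.0 - r_d)


@dataclass
class ProbeGeometry:
    """Optode layout on the z=0 surface (mm, probe frame).

    Default layout: sources in two rows of four at y = +-17.5 mm with 12 mm
    in-row spacing; detectors in two rows of four at y = +-10.8 mm; the
    pattern is centered on the origin and the ultrasound imaging plane is
    y = 0.
    """

    sources: np.ndarray
    detectors: np.ndarray
    source_width: float = 0.5  # mm, Gaussian profile width
    detector_width: float = 1.0  # mm

    def __post_init__(self) -> None:
        self.sources = np.atleast_2d(np.asarray(self.sources, dtype=float))
        self.detectors = np.atleast_2d(np.asarray(self.detectors, dtype=float))
        if np.any(self.sources[:, 2] != 0) or np.any(self.detectors[:, 2] != 0):
            raise ForwardError("all optodes must lie on the z=0 surface")

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_detectors(self) -> int:
        return len(self.detectors)

    def distances(self) -> np.ndarray:
        """(n_sources, n_detectors) matrix of optode separations in mm."""
        d = self.sources[:, None, :] - self.detectors[None, :, :]
        return np.linalg.norm(d, axis=-1)


def default_probe() -> ProbeGeometry:
    xs = np.array([-18.0, -6.0, 6.0, 18.0])
    sources = np.array([[x, y, 0.0] for y in (17.5, -17.5) for x in xs])
    detectors = np.array([[x, y, 0.0] for y in (10.8, -10.8) for x in xs])
    return ProbeGeometry(sources=sources, detectors=detectors)


@dataclass
class TimeGrid:
    """Uniform time grid; samples are at t = t0 + k*dt for k = 1..n_steps."""

    dt: float = 25.0  # ps
    n_steps: int = 400
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_steps < 1:
            raise ForwardError("dt must be positive and n_steps >= 1")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(1, self.n_steps + 1)


@dataclass
class TPSF:
    """A time-resolved photon-count curve for one source-detector pair."""

    source: int
    detector: int
    wavelength: float
    times: np.ndarray
    counts: np.ndarray
    noisy: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if not np.all(np.isfinite(self.counts)):
            raise ForwardError("TPSF contains non-finite values")
        if np.any(self.counts < -1e-12):
            raise ForwardError("TPSF contains negative counts")


@dataclass
class IRF:
    """Instrument response function, normalized to unit area."""

    times: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        amp = np.asarray(self.amplitude, dtype=float)
        if amp.size == 0:
            raise ForwardError("empty IRF")
        if np.any(amp < 0):
            raise ForwardError("IRF must be non-negative")
        area = np.trapezoid(amp, self.times) if amp.size > 1 else float(amp.sum())
        if area <= 0:
            raise ForwardError("IRF has zero area")
        self.amplitude = amp / area

    def resample(self, dt: float) -> np.ndarray:
        """Sample on a uniform dt grid from t=0, unit discrete area (sum*dt=1)."""
        tmax = self.times[-1]
        n = max(int(np.ceil(tmax / dt)) + 1, 1)
        t = np.arange(n) * dt
        a = np.interp(t, self.times, self.amplitude, left=0.0, right=0.0)
        s = a.sum() * dt
        if s <= 0:  # narrower than one sample: delta on the nearest bin
            a = np.zeros(n)
            a[int(round(self.times[np.argmax(self.amplitude)] / dt))] = 1.0 / dt
            return a
        return a / s


def gaussian_irf(fwhm: float = 400.0, dt: float = 5.0, t_center: float | None = None) -> IRF:
    """Synthetic Gaussian IRF of the given FWHM (ps), unit area, causal."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if t_center is None:
        t_center = 4.0 * sigma
    t = np.arange(0.0, t_center + 5.0 * sigma, dt)
    amp = np.exp(-0.5 * ((t - t_center) / sigma) ** 2)
    return IRF(times=t, amplitude=amp)


def load_irf(path: str) -> IRF:
    """Read a measured IRF from two-column ASCII (time ps, amplitude)."""
    data = np.loadtxt(path)
    return IRF(times=data[:, 0], amplitude=data[:, 1])


# ----------------------------------------------------------------------------
# spatial discretization


def _assemble_system(
    mua: np.ndarray,
    musp: np.ndarray,
    h: float,
    A: float,
    boundary: str = "robin",
) -> sparse.csr_matrix:
    """Assemble S = -div(kappa grad) + mu_a with Robin (or reflective) faces.

    Cell-centered finite differences on the voxel grid; kappa is averaged
    harmonically at interior faces; each domain-boundary face contributes the
    Robin loss (2 kappa/h)/(1 + 4 A kappa/h) / h to the diagonal.
    """
    if np.any(mua <= 0) or np.any(musp <= 0):
        raise ForwardError("optical coefficients must be positive")
    nx, ny, nz = mua.shape
    n = nx * ny * nz
    kappa = 1.0 / (3.0 * musp)
    idx = np.arange(n).reshape(nx, ny, nz)

    diag = mua.ravel().astype(float).copy()
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        k1 = kappa[tuple(sl_lo)]
        k2 = kappa[tuple(sl_hi)]
        kf = 2.0 * k1 * k2 / (k1 + k2) / h**2
        i1 = idx[tuple(sl_lo)].ravel()
        i2 = idx[tuple(sl_hi)].ravel()
        w = kf.ravel()
        rows += [i1, i2]
        cols += [i2, i1]
        vals += [-w, -w]
        np.add.at(diag, i1, w)
        np.add.at(diag, i2, w)

        if boundary == "robin":
            for end in (0, -1):
                sl = [slice(None)] * 3
                sl[axis] = end
                kb = kappa[tuple(sl)]
                beta = (2.0 * kb / h) / (1.0 + 4.0 * A * kb / h) / h
                np.add.at(diag, idx[tuple(sl)].ravel(), beta.ravel())

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    S = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return S


def _axis_gaussian_weights(centers: np.ndarray, pos: float, sigma: float, h: float) -> np.ndarray:
    """Per-voxel weights of a 1D Gaussian integrated over voxel extents."""
    lo = centers - h / 2.0
    hi = centers + h / 2.0
    s = max(sigma, 1e-6) * np.sqrt(2.0)
    return 0.5 * (erf((hi - pos) / s) - erf((lo - pos) / s))


def _source_vector(optics: OpticalMaps, geometry: ProbeGeometry, i_src: int, lam_idx: int,
                   centers: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
    """Unit-integral initial fluence: Gaussian at one transport mfp depth."""
    h = optics.spacing
    xs, ys, _ = geometry.sources[i_src]
    cx, cy, cz = centers
    ixs = int(np.clip(np.argmin(np.abs(cx - xs)), 0, len(cx) - 1))
    iys = int(np.clip(np.argmin(np.abs(cy - ys)), 0, len(cy) - 1))
    z0 = 1.0 / optics.musp[lam_idx, ixs, iys, 0]  # one transport mean free path
    sig = geometry.source_width
    wx = _axis_gaussian_weights(cx, xs, sig, h)
    wy = _axis_gaussian_weights(cy, ys, sig, h)
    wz = _axis_gaussian_weights(cz, z0, sig, h)
    w = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
    total = w.sum()
    if total <= 0:
        raise ForwardError("source profile does not overlap the grid")
    return (w / (total * h**3)).ravel()  # fluence density, unit spatial integral


def _surface_gamma(optics: OpticalMaps, lam_idx: int, A: float, h: float) -> np.ndarray:
    """Exitance coefficient on the z=0 surface: J_out = gamma * Phi(top voxel)."""
    kb = 1.0 / (3.0 * optics.musp[lam_idx, :, :, 0])
    return (2.0 * kb / h) / (1.0 + 4.0 * A * kb / h)


def propagate_fluence(
    optics: OpticalMaps,
    initial_field: np.ndarray,
    timegrid: TimeGrid,
    wavelength_index: int = 0,
    boundary: str = "robin",
    linear_solver: str = "direct",
    observe=None,
):
    """Implicit-Euler propagation of an arbitrary initial fluence field.

    ``linear_solver`` is "direct" (sparse LU, best for the small optical
    grids) or "cg" (conjugate gradients warm-started from the previous step,
    preferable on large verification grids).  When ``observe`` is given it is
    called with the 3D field after every step and the list of its results is
    returned; otherwise the full movie (n_steps, nx, ny, nz) is returned.
    """
    shape = optics.mua.shape[1:]
    if initial_field.shape != shape:
        raise ForwardError("initial field shape mismatch")
    h = optics.spacing
    c = C_VACUUM_MM_PS / optics.refractive_index
    A = boundary_constant(optics.refractive_index)
    S = _assemble_system(optics.mua[wavelength_index], optics.musp[wavelength_index], h, A,
                         boundary)
    n = S.shape[0]
    M = sparse.identity(n, format="csr") + (c * timegrid.dt) * S
    if linear_solver == "direct":
        lu = splu(M.tocsc())

        def step(v: np.ndarray) -> np.ndarray:
            return lu.solve(v)

    elif linear_solver == "cg":
        from scipy.sparse.linalg import cg

        Mcsr = M.tocsr()

        def step(v: np.ndarray) -> np.ndarray:
            out, info = cg(Mcsr, v, x0=v, rtol=1e-9)
            if info != 0:
                raise ForwardError("conjugate-gradient step failed to converge")
            return out

    else:
        raise ForwardError(f"unknown linear_solver {linear_solver!r}")

    phi = initial_field.ravel().astype(float)
    out = [] if observe is not None else np.empty((timegrid.n_steps,) + shape)
    for k in range(timegrid.n_steps):
        phi = step(phi)
        if observe is not None:
            out.append(observe(phi.reshape(shape)))
        else:
            out[k] = phi.reshape(shape)
    return out


def solve_td_diffusion(
    optics: OpticalMaps,
    geometry: ProbeGeometry,
    source: int,
    timegrid: TimeGrid,
    wavelength_index: int = 0,
    boundary: str = "robin",
) -> np.ndarray:
    """Implicit-Euler solution of the TD diffusion equation for one source.

    Returns the fluence movie with shape (n_steps, nx, ny, nz) sampled at
    ``timegrid.times``.  Intended for inspection and verification; the
    measurement fast path is :func:`run_forward`.
    """
    shape = optics.mua.shape[1:]
    h = optics.spacing
    centers = tuple(
        (np.arange(shape[ax]) + 0.5) * h + _origin(optics, ax) for ax in range(3)
    )
    phi0 = _source_vector(optics, geometry, source, wavelength_index, centers).reshape(shape)
    return propagate_fluence(optics, phi0, timegrid, wavelength_index, boundary)


def _origin(optics: OpticalMaps, axis: int) -> float:
    origin = getattr(optics, "origin", None)
    if origin is not None:
        return float(origin[axis])
    # centered in x/y, z=0 at the top surface
    n = optics.mua.shape[1 + axis]
    return -n * optics.spacing / 2.0 if axis < 2 else 0.0


def detect(
    movie: np.ndarray,
    optics: OpticalMaps,
    geometry: ProbeGeometry,
    detector: int,
    timegrid: TimeGrid,
    wavelength_index: int = 0,
) -> TPSF:
    """Gaussian-weighted surface readout of the exitance at one detector."""
    h = optics.spacing
    nx, ny = movie.shape[1], movie.shape[2]
    cx = (np.arange(nx) + 0.5) * h + _origin(optics, 0)
    cy = (np.arange(ny) + 0.5) * h + _origin(optics, 1)
    xd, yd, _ = geometry.detectors[detector]
    if not (cx[0] - h <= xd <= cx[-1] + h) or not (cy[0] - h <= yd <= cy[-1] + h):
        raise ForwardError("detector outside the grid surface")
    wx = _axis_gaussian_weights(cx, xd, geometry.detector_width, h)
    wy = _axis_gaussian_weights(cy, yd, geometry.detector_width, h)
    w = wx[:, None] * wy[None, :]
    w /= w.sum()
    A = boundary_constant(optics.refractive_index)
    gamma = _surface_gamma(optics, wavelength_index, A, h)
    flux = movie[:, :, :, 0] * gamma[None, :, :]
    counts = np.einsum("tij,ij->t", flux, w)
    lam = float(optics.wavelengths[wavelength_index])
    return TPSF(source=-1, detector=detector, wavelength=lam, times=timegrid.times,
                counts=np.maximum(counts, 0.0))


@dataclass
class MeasurementSet:
    """Per source-detector-wavelength time-resolved curves.

    ``curves`` has shape (n_wavelengths, n_sources, n_detectors, n_steps);
    before noise the values are exitance samples (arbitrary units), after
    :func:`apply_noise` they are photon counts per time bin.
    """

    wavelengths: np.ndarray
    times: np.ndarray
    curves: np.ndarray
    geometry: ProbeGeometry
    irf: IRF | None = None
    noisy: bool = False
    nexpect: float | None = None

    def __post_init__(self) -> None:
        expected = (len(self.wavelengths), self.geometry.n_sources,
                    self.geometry.n_detectors, len(self.times))
        if self.curves.shape != expected:
            raise ForwardError(f"curves shape {self.curves.shape} != {expected}")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 1.0

    def tpsf(self, lam_idx: int, i_src: int, j_det: int) -> TPSF:
        return TPSF(
            source=i_src,
            detector=j_det,
            wavelength=float(self.wavelengths[lam_idx]),
            times=self.times,
            counts=self.curves[lam_idx, i_src, j_det],
            noisy=self.noisy,
        )


def run_forward(
    optics: OpticalMaps,
    geometry: ProbeGeometry | None = None,
    timegrid: TimeGrid | None = None,
    irf: IRF | None = None,
    wavelength_indices: list[int] | None = None,
) -> MeasurementSet:
    """Simulate noiseless TPSFs for all source-detector pairs and wavelengths.

    One sparse factorization per wavelength; all sources are propagated
    simultaneously as a block right-hand side and only the top-surface
    exitance is retained.  When an IRF is given, every curve is convolved
    with it.
    """
    if geometry is None:
        geometry = default_probe()
    if timegrid is None:
        timegrid = TimeGrid()
    lam_sel = wavelength_indices if wavelength_indices is not None else list(
        range(len(optics.wavelengths))
    )
    shape = optics.mua.shape[1:]
    nx, ny, nz = shape
    h = optics.spacing
    c = C_VACUUM_MM_PS / optics.refractive_index
    A = boundary_constant(optics.refractive_index)
    centers = tuple((np.arange(shape[ax]) + 0.5) * h + _origin(optics, ax) for ax in range(3))

    # detector weights on the surface grid
    wdet = np.empty((geometry.n_detectors, nx, ny))
    for j in range(geometry.n_detectors):
        xd, yd, _ = geometry.detectors[j]
        wx = _axis_gaussian_weights(centers[0], xd, geometry.detector_width, h)
        wy = _axis_gaussian_weights(centers[1], yd, geometry.detector_width, h)
        w = wx[:, None] * wy[None, :]
        wdet[j] = w / w.sum()

    top = np.arange(nx * ny * nz).reshape(shape)[:, :, 0].ravel()
    irf_kernel = irf.resample(timegrid.dt) if irf is not None else None

    curves = np.empty((len(lam_sel), geometry.n_sources, geometry.n_detectors,
                       timegrid.n_steps))
    for out_k, lam_idx in enumerate(lam_sel):
        S = _assemble_system(optics.mua[lam_idx], optics.musp[lam_idx], h, A)
        M = sparse.identity(S.shape[0], format="csr") + (c * timegrid.dt) * S
        lu = splu(M.tocsc())
        gamma = _surface_gamma(optics, lam_idx, A, h).ravel()
        phi = np.stack(
            [_source_vector(optics, geometry, i, lam_idx, centers)
             for i in range(geometry.n_sources)],
            axis=1,
        )
        surf = np.empty((timegrid.n_steps, nx * ny, geometry.n_sources))
        for k in range(timegrid.n_steps):
            phi = lu.solve(phi)
            surf[k] = phi[top] * gamma[:, None]
        # (t, surface, src) x (det, surface) -> (src, det, t)
        sig = np.einsum("tps,jp->sjt", surf, wdet.reshape(geometry.n_detectors, -1))
        if irf_kernel is not None:
            sig = _convolve_block(sig, irf_kernel, timegrid.dt)
        curves[out_k] = np.maximum(sig, 0.0)

    return MeasurementSet(
        wavelengths=np.asarray(optics.wavelengths)[lam_sel],
        times=timegrid.times,
        curves=curves,
        geometry=geometry,
        irf=irf,
        noisy=False,
    )


def _convolve_block(sig: np.ndarray, kernel: np.ndarray, dt: float) -> np.ndarray:
    """Causal discrete convolution of the trailing time axis, truncated."""
    n = sig.shape[-1]
    flat = sig.reshape(-1, n)
    out = np.empty_like(flat)
    for i in range(flat.shape[0]):
        out[i] = np.convolve(flat[i], kernel)[:n] * dt
    return out.reshape(sig.shape)


def convolve_irf(tpsf: TPSF, irf: IRF) -> TPSF:
    """Convolve one TPSF with an IRF (discrete causal, truncated)."""
    dt = float(tpsf.times[1] - tpsf.times[0])
    kernel = irf.resample(dt)
    counts = np.convolve(tpsf.counts, kernel)[: len(tpsf.counts)] * dt
    return replace(tpsf, counts=counts)


def apply_noise(ms: MeasurementSet, nexpect: float = 1.0e6,
                rng_seed: int = 0) -> MeasurementSet:
    """Photon-budget Poisson noise.

    Per wavelength, curves are rescaled by a single factor chosen so that the
    pair at the largest source-detector separation integrates to ``nexpect``
    counts (all other pairs keep their integral ratios); each time bin is then
    replaced by a Poisson draw with that mean.
    """
    if ms.noisy:
        raise ForwardError("measurement set is already noisy")
    if nexpect <= 0:
        raise ForwardError("nexpect must be positive")
    rng = np.random.default_rng(rng_seed)
    dist = ms.geometry.distances()
    i_far, j_far = np.unravel_index(np.argmax(dist), dist.shape)
    counts = np.empty_like(ms.curves)
    for k in range(len(ms.wavelengths)):
        ref = ms.curves[k, i_far, j_far].sum() * ms.dt
        if ref <= 0:
            raise ForwardError("reference pair has zero integral")
        scale = nexpect / ref
        mean = np.maximum(ms.curves[k] * ms.dt * scale, 0.0)
        counts[k] = rng.poisson(mean)
    return MeasurementSet(
        wavelengths=ms.wavelengths.copy(),
        times=ms.times.copy(),
        curves=counts,
        geometry=ms.geometry,
        irf=ms.irf,
        noisy=True,
        nexpect=nexpect,
    )
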