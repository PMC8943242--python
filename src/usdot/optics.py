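"""Spectral model: chromophore concentrations -> per-wavelength optical maps.

Absorption is the linear spectral model ``mu_a(r, lambda) = sum_i
epsilon_i(lambda) * C_i(r)`` over the five breast chromophores (Hb, HbO2,
lipid, water, collagen); reduced scattering follows the Mie-type power law
``mu_s'(lambda) = a * (lambda/lambda0)^(-b)`` with an optional per-wavelength
Gaussian perturbation (10% of the value by default) acting as model noise.
Optical coefficients are piecewise constant per tissue: one concentration
vector and one (a, b) pair is drawn per tissue per phantom, with no
intra-tissue spatial variation.

Default wavelengths: 635, 670, 685, 785, 905, 930, 975, 1060 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from usdot.phantom import LabelVolume, TISSUE_INDEX, TISSUE_NAMES

__all__ = [
    "WAVELENGTHS_NM",
    "CHROMOPHORES",
    "ChromophorePanel",
    "TissueComposition",
    "OpticalMaps",
    "load_default_panel",
    "load_tissue_priors",
    "mua_from_chromophores",
    "musp_power_law",
    "assign_optical_properties",
]

WAVELENGTHS_NM: tuple[float, ...] = (635.0, 670.0, 685.0, 785.0, 905.0, 930.0, 975.0, 1060.0)
CHROMOPHORES: tuple[str, ...] = ("Hb", "HbO2", "lipid", "water", "collagen")

#: floor applied to mu_s' after noise, mm^-1 (keeps the diffusion model valid)
MUSP_FLOOR = 0.05


class OpticsError(ValueError):
    pass


@dataclass
class ChromophorePanel:
    """Specific-absorption table: rows = chromophores, columns = wavelengths.

    ``epsilon[c][k]`` is the absorption (mm^-1) contributed per unit
    concentration of chromophore ``c`` at ``wavelengths[k]``.
    """

    wavelengths: np.ndarray
    epsilon: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise OpticsError("wavelengths must be strictly increasing")
        for c, row in self.epsilon.items():
            row = np.asarray(row, dtype=float)
            if row.shape != self.wavelengths.shape:
                raise OpticsError(f"epsilon row {c!r} has wrong length")
            if np.any(row < 0):
                raise OpticsError(f"negative specific absorption for {c!r}")
            self.epsilon[c] = row

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths)


def load_default_panel() -> ChromophorePanel:
    """Bundled specific-absorption table at the 8 default wavelengths."""
    text = resources.files("usdot.data").joinpath("chromophores.yaml").read_text()
    raw = yaml.safe_load(text)
    return ChromophorePanel(
        wavelengths=np.asarray(raw["wavelengths_nm"], dtype=float),
        epsilon={c: np.asarray(v, dtype=float) for c, v in raw["epsilon"].items()},
    )


@dataclass
class TissueComposition:
    """A realized tissue composition: concentrations plus scattering law."""

    concentrations: dict[str, float]
    a: float  # mm^-1 at lambda0
    b: float
    lambda0: float = 600.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.concentrations.values()):
            raise OpticsError("concentrations must be non-negative")
        if self.a <= 0:
            raise OpticsError("scatter amplitude a must be positive")


def load_tissue_priors() -> dict:
    """Bundled per-tissue distribution parameters (means/SDs of the draws)."""
    text = resources.files("usdot.data").joinpath("tissues.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class OpticalMaps:
    """Per-wavelength absorption and reduced-scattering voxel fields.

    ``mua`` and ``musp`` have shape (n_wavelengths, nx, ny, nz) in mm^-1.
    """

    wavelengths: np.ndarray
    mua: np.ndarray
    musp: np.ndarray
    spacing: float
    refractive_index: float = 1.4
    tissue_values: dict | None = None  # per-tissue (mua(λ), musp(λ)) used to build maps
    origin: np.ndarray | None = None  # mm, probe frame; centered in x/y when None

    def __post_init__(self) -> None:
        if np.any(self.mua <= 0) or np.any(self.musp <= 0):
            raise OpticsError("optical coefficients must be positive everywhere")

    def diffusive_ratio(self) -> float:
        """min(mu_s'/mu_a) over the volume; < 10 warns of a non-diffusive regime."""
        return float(np.min(self.musp / self.mua))

    def lesion_spectra(self) -> tuple[np.ndarray, np.ndarray]:
        """Ground-truth (mua(λ), musp(λ)) of the lesion tissue."""
        if not self.tissue_values or TISSUE_INDEX["lesion"] not in self.tissue_values:
            raise OpticsError("maps carry no lesion")
        mua, musp = self.tissue_values[TISSUE_INDEX["lesion"]]
        return np.asarray(mua), np.asarray(musp)


def mua_from_chromophores(C: dict[str, float], panel: ChromophorePanel) -> np.ndarray:
    """Linear spectral model: mu_a(lambda) = sum_i epsilon_i(lambda) C_i."""
    out = np.zeros(panel.n_wavelengths)
    for c, conc in C.items():
        if conc < 0:
            raise OpticsError(f"negative concentration for {c!r}")
        if c not in panel.epsilon:
            raise OpticsError(f"chromophore {c!r} not in panel")
        out += panel.epsilon[c] * conc
    return out


def musp_power_law(
    a: float,
    b: float,
    lam: np.ndarray | float,
    lam0: float = 600.0,
    noise_sd_frac: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Mie power law mu_s' = a (lambda/lambda0)^(-b), with optional noise.

    The noise term is drawn per wavelength from N(0, noise_sd_frac * mu_s')
    and the result is clipped at the positivity floor.
    """
    if a <= 0:
        raise OpticsError("a must be positive")
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    musp = a * (lam / lam0) ** (-b)
    if noise_sd_frac > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        musp = musp + rng.normal(0.0, noise_sd_frac * musp)
    return np.maximum(musp, MUSP_FLOOR)


def _draw_composition(
    dist: dict, panel: ChromophorePanel, rng: np.random.Generator, lambda0: float
) -> TissueComposition:
    """Draw one tissue composition from its (mean, sd) normal parameters."""
    thb = max(rng.normal(*dist["tHb"]), 0.1)
    so2 = float(np.clip(rng.normal(*dist["so2"]), 0.0, 1.0))
    conc = {
        "Hb": thb * (1.0 - so2),
        "HbO2": thb * so2,
        "water": max(rng.normal(*dist["water"]), 0.0),
        "lipid": max(rng.normal(*dist["lipid"]), 0.0),
        "collagen": max(rng.normal(*dist["collagen"]), 0.0),
    }
    a = max(rng.normal(*dist["a"]), MUSP_FLOOR)
    b = float(rng.normal(*dist["b"]))
    return TissueComposition(concentrations=conc, a=a, b=b, lambda0=lambda0)


def draw_lesion_class(
    lesion_class: str, priors: dict, rng: np.random.Generator
) -> tuple[str, dict]:
    """Resolve the drawn lesion sub-class (cyst branch among benign)."""
    if lesion_class == "benign" and rng.uniform() < priors.get("cyst_fraction_of_benign", 0.25):
        lesion_class = "cyst"
    return lesion_class, priors["lesions"][lesion_class]


def assign_optical_properties(
    volume: LabelVolume,
    lesion_class: str = "benign",
    panel: ChromophorePanel | None = None,
    priors: dict | None = None,
    rng_seed: int = 0,
    musp_noise_frac: float = 0.10,
    resolve_cyst: bool = True,
) -> OpticalMaps:
    """Build per-wavelength optical maps for a labeled phantom.

    One composition is drawn per tissue (no intra-tissue spatial variation).
    The lesion scattering amplitude is drawn from the class-specific normal;
    when ``resolve_cyst`` is true, a benign lesion is re-drawn as a cyst with
    probability 25%.  Returns maps whose ``tissue_values`` record the exact
    spectra assigned to each tissue (the ground truth for classification).
    """
    if panel is None:
        panel = load_default_panel()
    if priors is None:
        priors = load_tissue_priors()
    rng = np.random.default_rng(rng_seed)
    lam = panel.wavelengths
    lambda0 = float(priors.get("lambda0_nm", 600.0))

    present = [int(i) for i in np.unique(volume.labels)]
    tissue_values: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for i in sorted(present):
        name = TISSUE_NAMES.get(i, None)
        if name == "air":
            raise OpticsError("optical maps cannot contain air; downsample/fill first")
        if name == "lesion":
            cls = lesion_class
            if resolve_cyst:
                cls, dist = draw_lesion_class(lesion_class, priors, rng)
            else:
                dist = priors["lesions"][lesion_class]
        else:
            if name not in priors["tissues"]:
                raise OpticsError(f"no composition configured for tissue {name!r}")
            dist = priors["tissues"][name]
        comp = _draw_composition(dist, panel, rng, lambda0)
        mua = np.maximum(mua_from_chromophores(comp.concentrations, panel), 1e-4)
        musp = musp_power_law(comp.a, comp.b, lam, lambda0, musp_noise_frac, rng)
        tissue_values[i] = (mua, musp)

    nlam = panel.n_wavelengths
    mua_field = np.empty((nlam,) + volume.shape)
    musp_field = np.empty((nlam,) + volume.shape)
    for i, (mua, musp) in tissue_values.items():
        sel = volume.labels == i
        for k in range(nlam):
            mua_field[k][sel] = mua[k]
            musp_field[k][sel] = musp[k]

    return OpticalMaps(
        wavelengths=lam.copy(),
        mua=mua_field,
        musp=musp_field,
        spacing=volume.spacing,
        refractive_index=float(priors.get("refractive_index", 1.4)),
        tissue_values=tissue_values,
        origin=volume.origin.copy(),
    )


def homogeneous_maps(
    mua: float,
    musp: float,
    shape: tuple[int, int, int],
    spacing: float,
    wavelengths: np.ndarray | None = None,
    refractive_index: float = 1.4,
) -> OpticalMaps:
    """Constant-coefficient maps (single wavelength unless given)."""
    lam = np.asarray(wavelengths if wavelengths is not None else [785.0], dtype=float)
    n = len(lam)
    return OpticalMaps(
        wavelengths=lam,
        mua=np.full((n,) + shape, mua),
        musp=np.full((n,) + shape, musp),
        spacing=spacing,
        refractive_index=refractive_index,
    )


def two_region_maps(
    inclusion: np.ndarray,
    mua_in: float,
    mua_bulk: float,
    musp_in: float,
    musp_bulk: float,
    spacing: float,
    wavelength: float = 785.0,
    refractive_index: float = 1.4,
) -> OpticalMaps:
    """Piecewise-constant maps for the two-region model at one wavelength."""
    shape = inclusion.shape
    mua = np.where(inclusion, mua_in, mua_bulk)[None, ...]
    musp = np.where(inclusion, musp_in, musp_bulk)[None, ...]
    return OpticalMaps(
        wavelengths=np.array([wavelength]),
        mua=mua,
        musp=musp,
        spacing=spacing,
        refractive_index=refractive_index,
    )
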