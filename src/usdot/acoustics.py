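"""Dual-scale stochastic acoustic media for B-mode contrast emulation.

A B-mode breast image shows contrast on two scales: macroscopic jumps at
tissue interfaces and a microscopic texture from sub-resolution impedance
fluctuations.  Per tissue i the speed of sound is modeled as a stationary
Gaussian field: one tissue-level mean ``vbar_i ~ N(mu_i, sigma_macro_i)`` per
phantom, plus zero-mean per-voxel fluctuations with standard deviation
``sigma_micro_i``.  Lesions receive a micro texture strictly below every
surrounding tissue's (hypoechoic appearance).

Wave propagation/beamforming is out of scope here; the module only builds the
medium and exports it (with the transducer configuration) for an external
k-space wave simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from usdot.phantom import LabelVolume, TISSUE_INDEX

__all__ = [
    "AcousticTissueParams",
    "AcousticMap",
    "TRANSDUCER_PARAMS",
    "default_acoustic_params",
    "assign_acoustic_properties",
    "export_wave_medium",
    "import_wave_medium",
]


class AcousticsError(ValueError):
    pass


#: linear-array transducer configuration exported alongside the medium
TRANSDUCER_PARAMS: dict[str, float | int | str] = {
    "fc_hz": 7.0e6,
    "focus_mm": 15.0,
    "elevation_focus_mm": 16.0,
    "fractional_bandwidth": 0.80,
    "n_elements": 256,
    "n_active_elements": 42,
    "element_height_mm": 4.0,
    "pitch_mm": 0.2,
    "kerf_mm": 0.001,
    "element_width_mm": 0.198,
    "scan_lines": 200,
    "beamforming_speed_m_s": 1465.0,  # reference speed used in image formation
}


@dataclass
class AcousticTissueParams:
    """Per-tissue speed-of-sound statistics (m/s).

    ``mu``: tissue mean; ``sigma_macro``: between-phantom spread of the tissue
    mean; ``sigma_micro``: within-tissue texture level.  ``sigma_micro`` may
    be the string ``"auto"`` to draw it uniformly in [1%, 5%] of the mean
    (lesions instead get half the minimum of the other tissues' levels).
    """

    mu: dict[int, float]
    sigma_macro: dict[int, float]
    sigma_micro: dict[int, float | str] = field(default_factory=dict)

    def validate(self, labels_present: set[int]) -> None:
        missing = labels_present - set(self.mu)
        if missing:
            raise AcousticsError(f"missing acoustic parameters for tissues {sorted(missing)}")
        if any(v <= 0 for v in self.mu.values()):
            raise AcousticsError("all mean speeds must be positive")


def default_acoustic_params() -> AcousticTissueParams:
    """Placeholder defaults: adipose slow, glandular-like tissues intermediate,
    lesions fast; remaining tissues share the glandular distribution."""
    gl = 1515.0
    mu = {
        TISSUE_INDEX["air"]: 340.0,
        TISSUE_INDEX["skin"]: gl,
        TISSUE_INDEX["adipose"]: 1470.0,
        TISSUE_INDEX["glandular"]: gl,
        TISSUE_INDEX["muscle"]: gl,
        TISSUE_INDEX["duct"]: gl,
        TISSUE_INDEX["TDLU"]: gl,
        TISSUE_INDEX["ligament"]: gl,
        TISSUE_INDEX["artery"]: gl,
        TISSUE_INDEX["vein"]: gl,
        TISSUE_INDEX["nipple"]: gl,
        TISSUE_INDEX["lesion"]: 1550.0,
    }
    sigma_macro = {i: (12.0 if i != TISSUE_INDEX["air"] else 0.0) for i in mu}
    sigma_micro = {i: "auto" for i in mu}
    sigma_micro[TISSUE_INDEX["air"]] = 0.0
    return AcousticTissueParams(mu=mu, sigma_macro=sigma_macro, sigma_micro=sigma_micro)


@dataclass
class AcousticMap:
    """Realized acoustic medium on the phantom grid."""

    vbar: dict[int, float]  # per-tissue drawn mean speeds, m/s
    vs_field: np.ndarray  # 3D speed of sound, m/s
    sigma_micro_field: np.ndarray  # 3D texture level, m/s
    density: np.ndarray | None = None  # kg/m^3 (constant unless configured)
    spacing: float = 0.5  # mm

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vs_field)) or np.any(self.vs_field <= 0):
            raise AcousticsError("vs_field must be finite and positive everywhere")


def assign_acoustic_properties(
    volume: LabelVolume,
    params: AcousticTissueParams | None = None,
    rng_seed: int = 0,
    correlation_length: float = 0.0,
    density: float = 1000.0,
) -> AcousticMap:
    """Draw the dual-scale speed-of-sound field for a labeled phantom.

    Per tissue one mean is drawn from N(mu, sigma_macro); per-voxel
    fluctuations are white Gaussian with the tissue's sigma_micro (a
    correlated field of the given length in mm can be requested instead;
    default is the white field).  Deterministic for a given seed.
    """
    if params is None:
        params = default_acoustic_params()
    present = set(int(i) for i in np.unique(volume.labels))
    params.validate(present)
    rng = np.random.default_rng(rng_seed)

    vbar: dict[int, float] = {}
    micro: dict[int, float] = {}
    for i in sorted(present):
        vbar[i] = float(rng.normal(params.mu[i], params.sigma_macro.get(i, 0.0)))
        sm = params.sigma_micro.get(i, 0.0)
        if sm == "auto":
            micro[i] = -1.0  # resolved below
        else:
            micro[i] = float(sm)
    # auto texture: 1-5% of the mean speed; lesion below all surrounding tissues
    auto = [i for i in sorted(present) if micro[i] < 0 and i != TISSUE_INDEX["lesion"]]
    for i in auto:
        micro[i] = float(rng.uniform(0.01, 0.05) * params.mu[i])
    if TISSUE_INDEX["lesion"] in present and micro.get(TISSUE_INDEX["lesion"], 0.0) < 0:
        others = [
            micro[i]
            for i in present
            if i not in (TISSUE_INDEX["lesion"], TISSUE_INDEX["air"]) and micro[i] > 0
        ]
        micro[TISSUE_INDEX["lesion"]] = 0.5 * min(others) if others else 1.0

    lab = volume.labels
    vs = np.zeros(lab.shape, dtype=float)
    sig = np.zeros(lab.shape, dtype=float)
    for i in present:
        sel = lab == i
        vs[sel] = vbar[i]
        sig[sel] = micro[i]

    fluct = rng.standard_normal(lab.shape)
    if correlation_length > 0:
        fluct = ndimage.gaussian_filter(fluct, sigma=correlation_length / volume.spacing)
        fluct /= max(fluct.std(), 1e-12)
    vs = vs + sig * fluct
    vs = np.maximum(vs, 1.0)

    rho = np.full(lab.shape, density, dtype=float)
    return AcousticMap(vbar=vbar, vs_field=vs, sigma_micro_field=sig, density=rho,
                       spacing=volume.spacing)


def export_wave_medium(amap: AcousticMap, path: str) -> None:
    """Write the medium as HDF5 (SI units) plus a YAML transducer sidecar."""
    import h5py
    import yaml

    with h5py.File(path, "w") as f:
        d = f.create_dataset("sound_speed", data=amap.vs_field)
        d.attrs["units"] = "m/s"
        d = f.create_dataset("density", data=amap.density)
        d.attrs["units"] = "kg/m^3"
        d = f.create_dataset("sigma_micro", data=amap.sigma_micro_field)
        d.attrs["units"] = "m/s"
        f.attrs["grid_spacing"] = amap.spacing * 1e-3
        f.attrs["grid_spacing_units"] = "m"
        g = f.create_group("vbar")
        for i, v in amap.vbar.items():
            g.attrs[str(i)] = v
    with open(str(path) + ".yaml", "w") as yf:
        yaml.safe_dump({"transducer": TRANSDUCER_PARAMS}, yf)


def import_wave_medium(path: str) -> AcousticMap:
    import h5py

    with h5py.File(path, "r") as f:
        vs = f["sound_speed"][...]
        rho = f["density"][...]
        sig = f["sigma_micro"][...]
        spacing = float(f.attrs["grid_spacing"]) * 1e3
        vbar = {int(k): float(v) for k, v in f["vbar"].attrs.items()}
    return AcousticMap(vbar=vbar, vs_field=vs, sigma_micro_field=sig, density=rho,
                       spacing=spacing)
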