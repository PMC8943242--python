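"""End-to-end study orchestration.

One study = generate phantoms -> insert lesions -> assign optical properties
-> simulate noisy time-resolved data -> build ground-truth and degraded
(ultrasound-quality) priors -> per-wavelength homogeneous and two-region
fits -> feature tables -> benign/malignant classification, with per-phantom
seeding, a provenance manifest and per-phantom resumability.

Two preset configurations are provided: :func:`full_study_config` mirrors
the full-resolution acquisition (2 mm optical grid, 400 x 25 ps time steps)
and :func:`scaled_study_config` is a desk-scale variant (4 mm grid,
160 x 25 ps) that keeps the physics and the statistical structure while
running orders of magnitude faster; docs/methods.md discusses the choice.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from usdot import classify as _classify
from usdot.forward import TimeGrid, apply_noise, default_probe, gaussian_irf, run_forward
from usdot.optics import assign_optical_properties, load_tissue_priors
from usdot.phantom import (
    LesionSpec,
    PhantomConfig,
    PhantomError,
    TISSUE_INDEX,
    compress,
    downsample_labels,
    extract_cuboid,
    generate_lesion_shape,
    generate_phantom,
    insert_lesion,
)
from usdot.priors import PriorMask, degrade_prior
from usdot.recon import ReconError, TwoRegionParams, fit_homogeneous, fit_two_region

__all__ = ["StudyConfig", "StudyResult", "full_study_config", "scaled_study_config",
           "run_study", "ground_truth_feature_table"]

BENIGN_COUNT, MALIGNANT_COUNT = 349, 379  # reference class mix


@dataclass
class StudyConfig:
    """Configuration of an end-to-end study."""

    n_phantoms: int = 100
    malignant_fraction: float = MALIGNANT_COUNT / (BENIGN_COUNT + MALIGNANT_COUNT)
    prior_modes: tuple[str, ...] = ("ground_truth", "degraded")
    nexpect: float = 1.0e6
    seed: int = 0
    out_dir: str | None = None
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    optical_domain: tuple[float, float, float] = (64.0, 58.0, 30.0)
    dt_ps: float = 25.0
    n_steps: int = 400
    irf_fwhm_ps: float = 400.0
    lesion_radius_range: tuple[float, float] = (6.0, 13.5)
    lesion_irregularity: float = 0.3
    lesion_z_range: tuple[float, float] | None = (2.0, 29.0)  # depth band, mm
    ntw: int = 80
    fit_max_nfev: int = 60
    fit_xtol: float = 1e-4
    degrade_dv_tol: float = 0.05
    methods: tuple[str, ...] = ("logreg", "svm", "fcn")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def full_study_config(**overrides) -> StudyConfig:
    """Full-resolution acquisition: 0.5 mm phantom, 2 mm optics, 400 steps."""
    cfg = StudyConfig(
        phantom=PhantomConfig(fine_spacing=0.5, coarse_spacing=2.0),
        dt_ps=25.0,
        n_steps=400,
    )
    return replace(cfg, **overrides)


def scaled_study_config(**overrides) -> StudyConfig:
    """Desk-scale study: 1 mm phantom grid, 4 mm optics, 160 x 25 ps steps."""
    cfg = StudyConfig(
        phantom=PhantomConfig(fine_spacing=1.0, coarse_spacing=5.0, texture_scale=6.0),
        optical_domain=(60.0, 55.0, 30.0),
        dt_ps=50.0,
        n_steps=80,
        fit_max_nfev=25,
        fit_xtol=1e-3,
        degrade_dv_tol=0.15,
        lesion_radius_range=(7.0, 11.5),
    )
    return replace(cfg, **overrides)


@dataclass
class StudyResult:
    config: StudyConfig
    records: list
    feature_tables: dict  # provenance -> DataFrame
    reports: dict  # provenance -> method -> ClassReport
    error_summary: dict  # prior mode -> {"median_abs_eps_mua": ..., ...}
    manifest: dict


def _phantom_seeds(master: int, index: int, n: int = 8) -> np.ndarray:
    return np.random.SeedSequence([master, index]).generate_state(n) % (2**31)


def _simulate_one(config: StudyConfig, index: int) -> dict:
    """Simulate, reconstruct and score a single phantom; returns a record."""
    seeds = _phantom_seeds(config.seed, index)
    rng = np.random.default_rng(seeds[0])
    requested = "malignant" if rng.uniform() < config.malignant_fraction else "benign"

    volume = generate_phantom(config.phantom, rng_seed=int(seeds[1]))
    volume = compress(volume, config.phantom.target_thickness)
    radius = rng.uniform(*config.lesion_radius_range)
    spec = LesionSpec(mean_radius=radius, irregularity=config.lesion_irregularity,
                      malignancy_class=requested, rng_seed=int(seeds[2]))
    mask = generate_lesion_shape(spec, config.phantom.fine_spacing)
    volume = insert_lesion(volume, mask, rng_seed=int(seeds[3]),
                           z_range=config.lesion_z_range)

    factor = int(round(config.phantom.coarse_spacing / config.phantom.fine_spacing))
    coarse = downsample_labels(volume, factor)
    coarse = extract_cuboid(coarse, config.optical_domain)
    lesion_vox = coarse.labels == TISSUE_INDEX["lesion"]
    if not lesion_vox.any():
        raise PhantomError("lesion lost in downsampling/extraction")

    maps = assign_optical_properties(coarse, lesion_class=requested,
                                     rng_seed=int(seeds[4]))
    mua_truth, musp_truth = maps.lesion_spectra()

    geometry = default_probe()
    timegrid = TimeGrid(dt=config.dt_ps, n_steps=config.n_steps)
    irf = gaussian_irf(fwhm=config.irf_fwhm_ps, dt=config.dt_ps / 5.0)
    ms = run_forward(maps, geometry, timegrid, irf=irf)
    ms = apply_noise(ms, nexpect=config.nexpect, rng_seed=int(seeds[5]))

    truth_prior = PriorMask(mask=lesion_vox, spacing=coarse.spacing,
                            origin=coarse.origin, provenance="ground_truth")
    priors = {"ground_truth": truth_prior}
    if "degraded" in config.prior_modes:
        priors["degraded"] = degrade_prior(truth_prior, rng_seed=int(seeds[6]),
                                           dv_tol=config.degrade_dv_tol)

    record: dict = {
        "index": index,
        "label": "malignant" if requested == "malignant" else "benign",
        "requested_class": requested,
        "lesion_radius_mm": radius,
        "lesion_voxels": int(lesion_vox.sum()),
        "seeds": [int(s) for s in seeds],
        "wavelengths": [float(l) for l in maps.wavelengths],
        "truth": {"mua_in": mua_truth.tolist(), "musp_in": musp_truth.tolist()},
        "fits": {mode: [] for mode in config.prior_modes},
        "bulk_fits": [],
    }

    warm: dict[str, TwoRegionParams] = {}
    for k in range(len(maps.wavelengths)):
        hom = fit_homogeneous(ms, k, ntw=config.ntw)
        record["bulk_fits"].append(
            {"mua": hom.params.mua_bulk, "musp": hom.params.musp_bulk,
             "converged": hom.converged})
        init = TwoRegionParams(
            mua_in=hom.params.mua_bulk, mua_bulk=hom.params.mua_bulk,
            musp_in=hom.params.musp_bulk, musp_bulk=hom.params.musp_bulk, tshift=0.0)
        for mode in config.prior_modes:
            # warm start from the neighboring wavelength, re-anchoring the
            # bulk at the current homogeneous fit
            mode_init = init
            if mode in warm:
                prev = warm[mode]
                mode_init = TwoRegionParams(
                    mua_in=float(np.clip(prev.mua_in * hom.params.mua_bulk
                                         / max(prev.mua_bulk, 1e-6), 1e-4, 0.06)),
                    mua_bulk=hom.params.mua_bulk,
                    musp_in=float(np.clip(prev.musp_in * hom.params.musp_bulk
                                          / max(prev.musp_bulk, 1e-3), 0.05, 2.2)),
                    musp_bulk=hom.params.musp_bulk,
                    tshift=prev.tshift,
                )
            fit = fit_two_region(ms, priors[mode], k, init=mode_init, ntw=config.ntw,
                                 max_nfev=config.fit_max_nfev, xtol=config.fit_xtol,
                                 ftol=10.0 * config.fit_xtol**2)
            warm[mode] = fit.params
            record["fits"][mode].append(
                {
                    "wavelength": fit.wavelength,
                    "mua_in": fit.params.mua_in,
                    "mua_bulk": fit.params.mua_bulk,
                    "musp_in": fit.params.musp_in,
                    "musp_bulk": fit.params.musp_bulk,
                    "tshift": fit.params.tshift,
                    "objective": fit.objective,
                    "converged": fit.converged,
                    "n_evaluations": fit.n_evaluations,
                }
            )
    return record


_PROVENANCE_BY_MODE = {"ground_truth": "recon_gt_prior", "degraded": "recon_us_prior"}


def _collect_tables(config: StudyConfig, records: list) -> dict:
    """Feature tables per provenance from the per-phantom records."""
    tables = {}
    labels = {r["index"]: r["label"] for r in records}
    gt_fits = {
        r["index"]: {
            lam: (r["truth"]["mua_in"][k], r["truth"]["musp_in"][k])
            for k, lam in enumerate(r["wavelengths"])
        }
        for r in records
    }
    tables["ground_truth"] = _classify.build_features(gt_fits, labels, "ground_truth")
    for mode, prov in _PROVENANCE_BY_MODE.items():
        if mode not in config.prior_modes:
            continue
        fits = {
            r["index"]: {
                f["wavelength"]: (f["mua_in"], f["musp_in"]) for f in r["fits"][mode]
            }
            for r in records
        }
        tables[prov] = _classify.build_features(fits, labels, prov)
    return tables


def _error_summary(config: StudyConfig, records: list) -> dict:
    out = {}
    for mode in config.prior_modes:
        eps_mua, eps_musp = [], []
        for r in records:
            for k, f in enumerate(r["fits"][mode]):
                mt = r["truth"]["mua_in"][k]
                st = r["truth"]["musp_in"][k]
                eps_mua.append((f["mua_in"] - mt) / mt)
                eps_musp.append((f["musp_in"] - st) / st)
        eps_mua = np.asarray(eps_mua)
        eps_musp = np.asarray(eps_musp)
        out[mode] = {
            "mean_eps_mua": float(np.mean(eps_mua)),
            "median_abs_eps_mua": float(np.median(np.abs(eps_mua))),
            "frac_abs_eps_mua_gt_0.5": float(np.mean(np.abs(eps_mua) > 0.5)),
            "mean_eps_musp": float(np.mean(eps_musp)),
            "median_abs_eps_musp": float(np.median(np.abs(eps_musp))),
        }
    return out


def run_study(config: StudyConfig, progress: bool = False) -> StudyResult:
    """Execute the full study; per-phantom failures are logged, not fatal.

    With ``config.out_dir`` set, per-phantom records are persisted as JSON
    keyed by the config hash, and a rerun resumes from completed phantoms.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    chash = config.config_hash()
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    records, failures = [], []
    for i in range(config.n_phantoms):
        cache = out_dir / f"{chash}_phantom{i:04d}.json" if out_dir else None
        if cache and cache.exists():
            records.append(json.loads(cache.read_text()))
            continue
        try:
            rec = _simulate_one(config, i)
        except (PhantomError, ReconError, ValueError) as exc:
            failures.append({"index": i, "error": str(exc)})
            continue
        records.append(rec)
        if cache:
            cache.write_text(json.dumps(rec))
        if progress:
            print(f"phantom {i + 1}/{config.n_phantoms} done")

    if not records:
        raise RuntimeError("every phantom failed")

    tables = _collect_tables(config, records)
    reports: dict = {}
    for prov, table in tables.items():
        reports[prov] = {}
        if table["label"].nunique() < 2:
            continue  # degenerate tiny runs: nothing to classify
        for method in config.methods:
            try:
                reports[prov][method] = _classify.train_eval(table, method,
                                                             rng_seed=config.seed)
            except ValueError:
                # too few lesions per class for a stratified split
                continue

    err = _error_summary(config, records)
    manifest = {
        "config_hash": chash,
        "n_phantoms": config.n_phantoms,
        "n_completed": len(records),
        "failures": failures,
        "seed": config.seed,
        "record_checksum": hashlib.sha256(
            json.dumps(records, sort_keys=True).encode()
        ).hexdigest(),
        "fits_per_phantom": {
            mode: len(records[0]["fits"][mode]) for mode in config.prior_modes
        },
        "reports": {
            prov: {m: reports[prov][m].metrics for m in reports[prov]}
            for prov in reports
        },
    }
    if out_dir:
        (out_dir / f"{chash}_manifest.json").write_text(json.dumps(manifest, indent=2))
    return StudyResult(config=config, records=records, feature_tables=tables,
                       reports=reports, error_summary=err, manifest=manifest)


def ground_truth_feature_table(
    n_lesions: int = BENIGN_COUNT + MALIGNANT_COUNT,
    malignant_fraction: float = MALIGNANT_COUNT / (BENIGN_COUNT + MALIGNANT_COUNT),
    rng_seed: int = 0,
):
    """Ground-truth 16-feature table drawn directly from the lesion model.

    Draws each lesion's chromophore concentrations and scattering law from
    the class-conditional distributions (including the cyst branch among
    benign lesions) and evaluates mu_a / mu_s' at the 8 wavelengths -- the
    no-reconstruction reference for classification.
    """
    from usdot.optics import (
        _draw_composition,
        draw_lesion_class,
        load_default_panel,
        mua_from_chromophores,
        musp_power_law,
    )

    rng = np.random.default_rng(rng_seed)
    panel = load_default_panel()
    priors = load_tissue_priors()
    lam0 = float(priors.get("lambda0_nm", 600.0))
    n_mal = int(round(n_lesions * malignant_fraction))
    fits, labels = {}, {}
    for i in range(n_lesions):
        requested = "malignant" if i < n_mal else "benign"
        cls, dist = draw_lesion_class(requested, priors, rng)
        comp = _draw_composition(dist, panel, rng, lam0)
        mua = np.maximum(mua_from_chromophores(comp.concentrations, panel), 1e-4)
        musp = musp_power_law(comp.a, comp.b, panel.wavelengths, lam0, 0.10, rng)
        fits[i] = {float(l): (mua[k], musp[k]) for k, l in enumerate(panel.wavelengths)}
        labels[i] = "benign" if cls == "cyst" else requested
    return _classify.build_features(fits, labels, "ground_truth")
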