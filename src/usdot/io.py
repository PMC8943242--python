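"""HDF5 persistence for the pipeline's domain objects."""

from __future__ import annotations

import json

import h5py
import numpy as np

from usdot.forward import IRF, MeasurementSet, ProbeGeometry
from usdot.optics import OpticalMaps
from usdot.phantom import LabelVolume
from usdot.priors import PriorMask

__all__ = [
    "save_label_volume", "load_label_volume",
    "save_optical_maps", "load_optical_maps",
    "save_measurements", "load_measurements",
    "save_prior", "load_prior",
]


def save_label_volume(volume: LabelVolume, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=volume.labels.astype(np.int16))
        f.attrs["spacing_mm"] = volume.spacing
        f.attrs["origin_mm"] = volume.origin
        f.attrs["tissue_table"] = json.dumps({int(k): v for k, v in volume.tissue_names.items()})


def load_label_volume(path: str) -> LabelVolume:
    with h5py.File(path, "r") as f:
        return LabelVolume(
            labels=f["labels"][...],
            spacing=float(f.attrs["spacing_mm"]),
            origin=np.asarray(f.attrs["origin_mm"]),
            tissue_names={int(k): v for k, v in json.loads(f.attrs["tissue_table"]).items()},
        )


def save_optical_maps(maps: OpticalMaps, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("wavelengths_nm", data=maps.wavelengths)
        f.create_dataset("mua", data=maps.mua)
        f.create_dataset("musp", data=maps.musp)
        f.attrs["spacing_mm"] = maps.spacing
        f.attrs["refractive_index"] = maps.refractive_index
        if maps.origin is not None:
            f.attrs["origin_mm"] = maps.origin


def load_optical_maps(path: str) -> OpticalMaps:
    with h5py.File(path, "r") as f:
        origin = np.asarray(f.attrs["origin_mm"]) if "origin_mm" in f.attrs else None
        return OpticalMaps(
            wavelengths=f["wavelengths_nm"][...],
            mua=f["mua"][...],
            musp=f["musp"][...],
            spacing=float(f.attrs["spacing_mm"]),
            refractive_index=float(f.attrs["refractive_index"]),
            origin=origin,
        )


def save_measurements(ms: MeasurementSet, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("wavelengths_nm", data=ms.wavelengths)
        f.create_dataset("times_ps", data=ms.times)
        f.create_dataset("curves", data=ms.curves)
        f.create_dataset("sources_mm", data=ms.geometry.sources)
        f.create_dataset("detectors_mm", data=ms.geometry.detectors)
        f.attrs["source_width_mm"] = ms.geometry.source_width
        f.attrs["detector_width_mm"] = ms.geometry.detector_width
        f.attrs["noisy"] = ms.noisy
        if ms.nexpect is not None:
            f.attrs["nexpect"] = ms.nexpect
        if ms.irf is not None:
            f.create_dataset("irf_times_ps", data=ms.irf.times)
            f.create_dataset("irf_amplitude", data=ms.irf.amplitude)


def load_measurements(path: str) -> MeasurementSet:
    with h5py.File(path, "r") as f:
        geometry = ProbeGeometry(
            sources=f["sources_mm"][...],
            detectors=f["detectors_mm"][...],
            source_width=float(f.attrs["source_width_mm"]),
            detector_width=float(f.attrs["detector_width_mm"]),
        )
        irf = None
        if "irf_times_ps" in f:
            irf = IRF(times=f["irf_times_ps"][...], amplitude=f["irf_amplitude"][...])
        return MeasurementSet(
            wavelengths=f["wavelengths_nm"][...],
            times=f["times_ps"][...],
            curves=f["curves"][...],
            geometry=geometry,
            irf=irf,
            noisy=bool(f.attrs["noisy"]),
            nexpect=float(f.attrs["nexpect"]) if "nexpect" in f.attrs else None,
        )


def save_prior(prior: PriorMask, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mask", data=prior.mask.astype(np.uint8))
        f.attrs["spacing_mm"] = prior.spacing
        f.attrs["origin_mm"] = prior.origin
        f.attrs["provenance"] = prior.provenance


def load_prior(path: str) -> PriorMask:
    with h5py.File(path, "r") as f:
        return PriorMask(
            mask=f["mask"][...].astype(bool),
            spacing=float(f.attrs["spacing_mm"]),
            origin=np.asarray(f.attrs["origin_mm"]),
            provenance=str(f.attrs["provenance"]),
        )
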