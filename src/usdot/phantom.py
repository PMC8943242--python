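"""Voxelized breast digital phantoms with tissue labels and embedded lesions.

The phantom is a slab of breast tissue held between two flat paddles (mild
compression by a handheld probe).  Each voxel carries a tissue index
(adipose, glandular, skin, muscle, duct, TDLU, ligament, artery, vein,
nipple, lesion).  Morphology is generated procedurally: skin layers on the
paddle surfaces, an adipose/glandular parenchyma obtained by thresholding a
smoothed Gaussian random field at the requested fat fraction, and sparse
tubular vessels/ducts.  Lesions are star-convex solids (sphere perturbed by
low-order spherical harmonics) inserted near the ultrasound imaging plane.

Coordinate convention: probe frame, z=0 is the top (probe) surface with z
increasing into the tissue; y=0 is the ultrasound imaging plane; x/y are
centered on the probe.  Voxel centers sit at ``origin + (i + 0.5) * spacing``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "TISSUE_NAMES",
    "TISSUE_INDEX",
    "LabelVolume",
    "LesionSpec",
    "PhantomConfig",
    "generate_phantom",
    "generate_lesion_shape",
    "insert_lesion",
    "compress",
    "downsample_labels",
]

#: index -> tissue name registry (0 is background air outside the breast slab)
TISSUE_NAMES: dict[int, str] = {
    0: "air",
    1: "skin",
    2: "adipose",
    3: "glandular",
    4: "muscle",
    5: "duct",
    6: "TDLU",
    7: "ligament",
    8: "artery",
    9: "vein",
    10: "nipple",
    11: "lesion",
}

TISSUE_INDEX: dict[str, int] = {v: k for k, v in TISSUE_NAMES.items()}


class PhantomError(ValueError):
    """Raised for invalid phantom configurations or impossible placements."""


@dataclass
class LabelVolume:
    """A voxelized tissue-index map.

    Parameters
    ----------
    labels
        3D integer array of tissue indices, axes ordered (x, y, z).
    spacing
        Isotropic voxel edge length in mm.
    origin
        mm offset of the grid corner in the probe frame (voxel centers at
        ``origin + (i + 0.5) * spacing``).
    tissue_names
        Index -> name map; defaults to :data:`TISSUE_NAMES`.
    """

    labels: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    tissue_names: dict[int, str] = field(default_factory=lambda: dict(TISSUE_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise PhantomError("voxel spacing must be positive")
        if self.labels.ndim != 3:
            raise PhantomError("labels must be a 3D grid")
        unknown = set(np.unique(self.labels)) - set(self.tissue_names)
        if unknown:
            raise PhantomError(f"unregistered tissue indices: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.labels.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing

    def copy(self) -> "LabelVolume":
        return LabelVolume(
            self.labels.copy(), self.spacing, self.origin.copy(), dict(self.tissue_names)
        )

    def breast_mask(self) -> np.ndarray:
        return self.labels != TISSUE_INDEX["air"]


@dataclass
class LesionSpec:
    """Parameters of a synthetic lesion shape.

    mean_radius is the equivalent-sphere radius in mm; irregularity >= 0
    scales the low-order spherical-harmonic perturbation of the radius
    (0 gives a digitized sphere).
    """

    mean_radius: float
    irregularity: float = 0.0
    malignancy_class: str = "benign"  # benign | malignant | cyst
    rng_seed: int = 0

    # admissible radius range, mm
    RADIUS_BOUNDS = (2.0, 20.0)

    def __post_init__(self) -> None:
        lo, hi = self.RADIUS_BOUNDS
        if not lo <= self.mean_radius <= hi:
            raise PhantomError(
                f"mean_radius {self.mean_radius} mm outside bounds {self.RADIUS_BOUNDS}"
            )
        if self.irregularity < 0:
            raise PhantomError("irregularity must be >= 0")
        if self.malignancy_class not in ("benign", "malignant", "cyst"):
            raise PhantomError(f"unknown class {self.malignancy_class!r}")

    @property
    def binary_label(self) -> str:
        """Classification label: cysts count as benign."""
        return "benign" if self.malignancy_class == "cyst" else self.malignancy_class


@dataclass
class PhantomConfig:
    """Configuration of the procedural breast phantom generator."""

    fat_fraction: float = 0.66
    target_thickness: float = 45.0  # mm, mild probe compression
    domain_size: tuple[float, float, float] = (64.0, 58.0, 60.0)  # mm
    fine_spacing: float = 0.5  # mm
    coarse_spacing: float = 2.0  # mm, optical grid
    skin_thickness: float = 1.5  # mm on each paddle surface
    structure_fraction: float = 0.01  # target volume fraction of ducts+vessels
    texture_scale: float = 5.0  # mm, correlation length of the parenchyma field
    enable_structures: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.fat_fraction <= 1.0:
            raise PhantomError("fat_fraction must be in (0, 1]")
        ratio = self.coarse_spacing / self.fine_spacing
        if abs(ratio - round(ratio)) > 1e-9:
            raise PhantomError("coarse_spacing must be an integer multiple of fine_spacing")


def _grid_shape(config: PhantomConfig) -> tuple[int, int, int]:
    return tuple(
        int(round(s / config.fine_spacing)) for s in config.domain_size
    )  # type: ignore[return-value]


def generate_phantom(config: PhantomConfig, rng_seed: int = 0) -> LabelVolume:
    """Generate a breast slab phantom at the fine grid resolution.

    The slab fills the whole domain in z (thickness = domain_size[2]); skin
    covers the top and bottom surfaces; the interior is an adipose/glandular
    mixture whose adipose fraction matches ``config.fat_fraction``; thin
    tubular ducts and vessels are sprinkled when structures are enabled.

    Deterministic for a given (config, rng_seed).
    """
    rng = np.random.default_rng(rng_seed)
    nx, ny, nz = _grid_shape(config)
    h = config.fine_spacing
    n_skin = int(round(config.skin_thickness / h))
    if nz <= 2 * n_skin + 2:
        raise PhantomError("domain too small along z to contain the skin layers")

    # elliptical lateral footprint with an air margin (the compressed breast
    # is smaller than the domain; lateral dilation under compression has
    # room to grow into)
    x = (np.arange(nx) - (nx - 1) / 2.0) * h
    y = (np.arange(ny) - (ny - 1) / 2.0) * h
    ax_x = 0.42 * config.domain_size[0]
    ax_y = 0.42 * config.domain_size[1]
    footprint = (x[:, None] / ax_x) ** 2 + (y[None, :] / ax_y) ** 2 <= 1.0
    rim = ndimage.distance_transform_edt(footprint, sampling=h) < config.skin_thickness

    labels = np.full((nx, ny, nz), TISSUE_INDEX["air"], dtype=np.int16)
    labels[footprint, :] = TISSUE_INDEX["adipose"]
    labels[footprint, :n_skin] = TISSUE_INDEX["skin"]
    labels[footprint, nz - n_skin :] = TISSUE_INDEX["skin"]
    labels[rim & footprint, :] = TISSUE_INDEX["skin"]
    interior = np.zeros((nx, ny, nz), dtype=bool)
    interior[footprint & ~rim, n_skin : nz - n_skin] = True

    if config.fat_fraction < 1.0:
        # smoothed Gaussian field thresholded at the glandular quantile
        noise = rng.standard_normal((nx, ny, nz))
        smooth = ndimage.gaussian_filter(noise, sigma=config.texture_scale / h)
        thr = np.quantile(smooth[interior], 1.0 - config.fat_fraction)
        glandular = interior & (smooth < thr)
        labels[glandular] = TISSUE_INDEX["glandular"]

    if config.enable_structures and config.structure_fraction > 0:
        _add_tubes(labels, interior, config, rng)

    origin = np.array(
        [-config.domain_size[0] / 2.0, -config.domain_size[1] / 2.0, 0.0]
    )
    return LabelVolume(labels, h, origin)


def _add_tubes(
    labels: np.ndarray, interior: np.ndarray, config: PhantomConfig, rng: np.random.Generator
) -> None:
    """Sprinkle thin tubular ducts/arteries/veins through the interior."""
    nx, ny, nz = labels.shape
    h = config.fine_spacing
    target_vox = config.structure_fraction * interior.sum()
    tube_labels = [TISSUE_INDEX["duct"], TISSUE_INDEX["artery"], TISSUE_INDEX["vein"]]
    placed = 0
    n_tubes = 0
    while placed < target_vox and n_tubes < 40:
        n_tubes += 1
        lab = tube_labels[n_tubes % len(tube_labels)]
        p0 = rng.uniform([0, 0, 0.15 * nz], [nx, ny, 0.85 * nz])
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(10.0, 30.0) / h
        radius = rng.uniform(0.5, 1.2) / h
        t = np.arange(0.0, length, 0.5)
        pts = p0[None, :] + t[:, None] * direction[None, :]
        pts = np.round(pts).astype(int)
        ok = np.all((pts >= 0) & (pts < [nx, ny, nz]), axis=1)
        pts = pts[ok]
        r = max(1, int(round(radius)))
        for px, py, pz in pts:
            sl = (
                slice(max(px - r, 0), px + r + 1),
                slice(max(py - r, 0), py + r + 1),
                slice(max(pz - r, 0), pz + r + 1),
            )
            sub = labels[sl]
            ins = interior[sl]
            placed += int(np.count_nonzero(ins & (sub != lab)))
            sub[ins] = lab


def generate_lesion_shape(spec: LesionSpec, spacing: float) -> np.ndarray:
    """Generate a binary lesion mask: a sphere perturbed by spherical harmonics.

    The radial perturbation uses real spherical harmonics of degree 2..4 with
    random coefficients scaled by ``spec.irregularity``; the radius field is
    rescaled so that the continuous volume matches the equivalent sphere of
    ``spec.mean_radius``.  Returns a tight binary 3D array (single 6-connected
    component).
    """
    if spec.mean_radius < 2.0 * spacing:
        raise PhantomError(
            f"mean_radius {spec.mean_radius} mm not resolvable at spacing {spacing} mm"
        )
    rng = np.random.default_rng(spec.rng_seed)
    r0 = spec.mean_radius
    half = int(np.ceil((r0 * (1.0 + spec.irregularity + 0.5)) / spacing)) + 2
    ax = (np.arange(2 * half + 1) - half) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    dist = np.sqrt(X**2 + Y**2 + Z**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(dist > 0, Z / np.maximum(dist, 1e-12), 1.0), -1, 1))
        phi = np.arctan2(Y, X)

    # low-order smooth angular perturbation
    pert = np.zeros_like(dist)
    if spec.irregularity > 0:
        from scipy.special import sph_harm_y

        for ell in (2, 3, 4):
            for m in range(-ell, ell + 1):
                c = rng.standard_normal() / (2 * ell + 1)
                ylm = sph_harm_y(ell, abs(m), theta, phi)
                basis = np.real(ylm) if m >= 0 else np.imag(ylm)
                pert += c * basis
        pert *= spec.irregularity / max(np.std(pert), 1e-12) * 0.5

    radius_field = r0 * np.clip(1.0 + pert, 0.35, 2.0)
    # volume-match: scale so <r^3> equals r0^3
    scale = r0 / np.cbrt(np.mean(np.clip(1.0 + pert, 0.35, 2.0) ** 3))
    radius_field *= scale / r0
    mask = dist <= radius_field

    lab, n = ndimage.label(mask)
    if n > 1:  # keep the central (largest) component; star-convexity makes this rare
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    # trim to tight bounding box
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]


def equivalent_radius(mask: np.ndarray, spacing: float) -> float:
    """Equivalent-sphere radius (mm) from the voxelized volume."""
    vol = float(mask.sum()) * spacing**3
    return float((3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0))


def insert_lesion(
    volume: LabelVolume,
    mask: np.ndarray,
    rng_seed: int = 0,
    max_tries: int = 200,
    y_frac: float = 0.3,
    z_range: tuple[float, float] | None = None,
) -> LabelVolume:
    """Insert a lesion mask into the breast near the ultrasound imaging plane.

    The lesion center of mass must satisfy |y_com| <= y_frac * l, where l is
    the mask's maximum y extent, and the lesion must lie fully inside breast
    tissue (no air or skin overlap).  ``z_range`` optionally confines the
    lesion's z extent (mm from the probe surface) to the depth band covered
    by the imaging view.  Placement is randomized; raises
    :class:`PhantomError` when no admissible placement is found.
    """
    rng = np.random.default_rng(rng_seed)
    h = volume.spacing
    mx, my, mz = mask.shape
    nx, ny, nz = volume.shape
    if mx >= nx or my >= ny or mz >= nz:
        raise PhantomError("lesion mask larger than the phantom domain")
    iz_lo, iz_hi = 0, nz - mz  # inclusive corner bounds along z
    if z_range is not None:
        iz_lo = max(iz_lo, int(np.ceil(z_range[0] / h)))
        iz_hi = min(iz_hi, int(np.floor(z_range[1] / h)) - mz)
        if iz_hi < iz_lo:
            raise PhantomError("lesion too thick for the requested depth band")

    soft = (volume.labels != TISSUE_INDEX["air"]) & (volume.labels != TISSUE_INDEX["skin"])
    if not soft.any():
        raise PhantomError("phantom has no interior tissue to host a lesion")

    l_mm = my * h  # maximum elongation of the lesion along y
    y_tol = y_frac * l_mm
    ycen = volume.voxel_centers(1)
    # center-of-mass offset of the mask (voxels, relative to its corner)
    com = np.array(ndimage.center_of_mass(mask))

    for _ in range(max_tries):
        ix = rng.integers(0, nx - mx)
        iz = rng.integers(iz_lo, iz_hi + 1)
        # draw the corner so the mask COM lands near the y=0 plane
        y_com_target = rng.uniform(-0.8 * y_tol, 0.8 * y_tol)
        # continuous corner position solving origin_y + (iy + com_y + 0.5)*h = target
        iy = int(round((y_com_target - volume.origin[1]) / h - com[1] - 0.5))
        if iy < 0 or iy + my > ny:
            continue
        region = soft[ix : ix + mx, iy : iy + my, iz : iz + mz]
        if not region[mask].all():
            continue
        y_com = float(
            np.sum(ycen[iy : iy + my][None, :, None] * mask) / mask.sum()
        )
        if abs(y_com) > y_tol:
            continue
        out = volume.copy()
        sub = out.labels[ix : ix + mx, iy : iy + my, iz : iz + mz]
        sub[mask] = TISSUE_INDEX["lesion"]
        return out

    raise PhantomError("no admissible lesion placement found")


def compress(volume: LabelVolume, target_thickness: float) -> LabelVolume:
    """Compress the breast slab along z with a volume-preserving affine rescale.

    z is compressed so the breast extent equals ``target_thickness``; x and y
    are dilated by 1/sqrt(sz) to approximately conserve volume.  Nearest
    neighbor resampling on the same grid; material pushed outside the lateral
    domain is lost (kept < 10% by construction for typical configurations).
    """
    breast = volume.breast_mask()
    zidx = np.nonzero(breast.any(axis=(0, 1)))[0]
    if zidx.size == 0:
        raise PhantomError("empty phantom")
    thickness = (zidx[-1] - zidx[0] + 1) * volume.spacing
    if thickness < target_thickness - volume.spacing / 2:
        import warnings

        warnings.warn("breast already thinner than target; compression is a no-op")
        return volume.copy()
    if abs(thickness - target_thickness) <= volume.spacing / 2:
        return volume.copy()

    sz = target_thickness / thickness
    sxy = 1.0 / np.sqrt(sz)
    nx, ny, nz = volume.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ix = (np.arange(nx) - cx) / sxy + cx
    iy = (np.arange(ny) - cy) / sxy + cy
    iz = np.arange(nz) / sz + zidx[0] * (1 - 1 / sz)  # z=top stays fixed
    IX, IY, IZ = np.meshgrid(ix, iy, iz, indexing="ij")
    coords = np.stack([IX, IY, IZ])
    # lateral dilation samples beyond the field of view: clamp to the edge
    # (the breast extends past the simulated domain); beyond the compressed
    # extent in z the volume is air
    out = ndimage.map_coordinates(volume.labels, coords, order=0, mode="nearest")
    out[:, :, IZ[0, 0] > zidx[-1] + 0.5] = TISSUE_INDEX["air"]
    return LabelVolume(out, volume.spacing, volume.origin.copy(), dict(volume.tissue_names))


def downsample_labels(volume: LabelVolume, factor: int) -> LabelVolume:
    """Majority-vote downsampling to the coarse (optical) grid.

    Each coarse voxel takes the most frequent fine label in its block (ties
    broken toward the smaller index).  Because the optical solver cannot
    represent void, air voxels are then assigned to adipose or glandular
    tissue, whichever is prevalent in the remainder of the breast.
    """
    if factor < 1:
        raise PhantomError("factor must be >= 1")
    lab = volume.labels
    pad = [(0, (-s) % factor) for s in lab.shape]
    if any(p[1] for p in pad):
        lab = np.pad(lab, pad, mode="edge")
    nx, ny, nz = (s // factor for s in lab.shape)
    blocks = lab.reshape(nx, factor, ny, factor, nz, factor)
    blocks = blocks.transpose(0, 2, 4, 1, 3, 5).reshape(nx, ny, nz, factor**3)
    n_lab = max(TISSUE_NAMES) + 1
    counts = np.zeros((nx, ny, nz, n_lab), dtype=np.int32)
    for i in range(n_lab):
        counts[..., i] = (blocks == i).sum(axis=-1)
    coarse = counts.argmax(axis=-1).astype(np.int16)

    air = coarse == TISSUE_INDEX["air"]
    if air.any():
        n_adip = int(np.count_nonzero(coarse == TISSUE_INDEX["adipose"]))
        n_glan = int(np.count_nonzero(coarse == TISSUE_INDEX["glandular"]))
        fill = TISSUE_INDEX["adipose"] if n_adip >= n_glan else TISSUE_INDEX["glandular"]
        coarse[air] = fill
    return LabelVolume(
        coarse, volume.spacing * factor, volume.origin.copy(), dict(volume.tissue_names)
    )


def extract_cuboid(volume: LabelVolume, size_mm: tuple[float, float, float]) -> LabelVolume:
    """Extract the centered (in x, y) cuboid of the given size starting at z=0."""
    n = tuple(int(round(s / volume.spacing)) for s in size_mm)
    nx, ny, nz = volume.shape
    if any(m > s for m, s in zip(n, volume.shape)):
        raise PhantomError("requested cuboid larger than the phantom")
    x0 = (nx - n[0]) // 2
    y0 = (ny - n[1]) // 2
    sub = volume.labels[x0 : x0 + n[0], y0 : y0 + n[1], : n[2]]
    origin = volume.origin + np.array([x0, y0, 0]) * volume.spacing
    return LabelVolume(sub.copy(), volume.spacing, origin, dict(volume.tissue_names))
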