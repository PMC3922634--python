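"""Synthetic phantoms of the glomerular filtration barrier with ground truth.

The study's raw electron-microscopy volumes are not available, so every
quantitative stage is exercised on phantoms that emulate their statistical
structure: a fibre-matrix glycocalyx of controllable mean nearest-neighbour
fibre spacing above a fenestrated endothelium, blank resin for threshold
calibration, 10 nm gold fiducial beads on both section surfaces, and labelled
urinary-space geometries in the schema of the sub-podocyte-space morphometry
table.  All generators are pure functions of ``(spec, seed)``.

Geometry convention: the membrane plane is normal to z.  Going down the z axis
the layers are capillary lumen, glycocalyx slab, fenestrated endothelium,
basement membrane and podocyte foot processes.  Glycocalyx fibres are rendered
as quasi-parallel cylinders along z (normal to the membrane, tilt-jittered by
a few degrees), so a reconstruction slice (an x-y plane) cuts the fibre forest
transversely and the membrane-parallel autocorrelation profile carries the
spacing signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import ImageVolume, LabelVolume, MorphometryRecord, MorphometryTable

__all__ = [
    "GfbPhantomSpec",
    "FiducialSet",
    "SpacePhantomSpec",
    "LABEL_LEGEND",
    "generate_gfb_phantom",
    "generate_blank_resin",
    "add_fiducials",
    "generate_space_phantom",
]

# one shared legend so label volumes from different generators compose
LABEL_LEGEND = {
    0: "resin",
    1: "lumen",
    2: "glycocalyx",
    3: "endothelium",
    4: "GBM",
    5: "podocyte",
    6: "SPS",
    7: "IPS",
    8: "PUS",
}
_NAME_TO_LABEL = {v: k for k, v in LABEL_LEGEND.items()}

# nominal stain-free intensity levels (arbitrary backscatter-inverted units):
# stain > membrane > cytoplasm > resin, emulating inverted contrast
INTENSITY = {
    "resin": 50.0,
    "lumen": 50.0,
    "matrix": 60.0,  # unstained glycocalyx ground substance
    "cytoplasm": 100.0,
    "membrane": 130.0,
}


@dataclass
class GfbPhantomSpec:
    """Geometry, contrast and noise of the layered filtration-barrier phantom.

    Defaults emulate the tomography study conditions: a 300 nm thick section,
    a 150 nm glycocalyx with 20 nm mean fibre spacing (coefficient of
    variation 0.2, no long-range lattice), and a fenestrated endothelium.
    Lengths in nm, intensities in arbitrary units.
    """

    volume_shape: tuple[int, int, int] = (128, 160, 160)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)  # nm
    fibre_spacing_mean: float = 20.0  # nm, nearest-neighbour centre-to-centre
    fibre_spacing_cv: float = 0.2
    fibre_radius: float = 3.0  # nm
    fibre_tilt_max_deg: float = 15.0
    glycocalyx_thickness: float = 120.0  # nm, within the 100-400 nm staining range
    fenestration_diameter: float = 60.0  # nm
    fenestration_pitch: float = 130.0  # nm
    endothelium_thickness: float = 20.0  # nm
    gbm_thickness: float = 20.0  # nm
    slit_width: float = 40.0  # nm, filtration slit between foot processes
    foot_process_pitch: float = 250.0  # nm
    stain_contrast: float = 150.0  # stained fibre intensity above resin
    noise_gaussian_sd: float = 5.0
    noise_poisson_scale: float = 0.05  # counts per intensity unit per s of exposure
    membrane_plane: float = 150.0  # nm, z of the glycocalyx/endothelium boundary

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.volume_shape):
            raise ValueError("volume_shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.fibre_spacing_mean <= 2 * self.fibre_radius:
            raise ValueError(
                f"fibre spacing {self.fibre_spacing_mean} nm infeasible for radius "
                f"{self.fibre_radius} nm (need d > 2r)"
            )
        for name in ("fibre_spacing_mean", "fibre_radius", "glycocalyx_thickness",
                     "fenestration_diameter", "fenestration_pitch", "membrane_plane"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.glycocalyx_thickness > self.membrane_plane:
            raise ValueError("glycocalyx slab does not fit above the membrane plane")
        if self.membrane_plane >= self.section_thickness_nm:
            raise ValueError("membrane plane lies outside the section")

    @property
    def section_thickness_nm(self) -> float:
        return self.volume_shape[0] * self.voxel_size[0]


def scaled_section_spec(volume_shape: tuple[int, int, int],
                        voxel_nm: float = 1.5, **overrides) -> "GfbPhantomSpec":
    """Default layer geometry rescaled along z to fit ``volume_shape``.

    Layer thicknesses and the membrane plane scale with the section
    thickness so arbitrary (smaller or larger) sections keep the default
    layer proportions.
    """
    default = GfbPhantomSpec()
    factor = (volume_shape[0] * voxel_nm) / default.section_thickness_nm
    params = dict(
        volume_shape=tuple(volume_shape),
        voxel_size=(voxel_nm,) * 3,
        glycocalyx_thickness=default.glycocalyx_thickness * factor,
        membrane_plane=default.membrane_plane * factor,
        endothelium_thickness=default.endothelium_thickness * factor,
        gbm_thickness=default.gbm_thickness * factor,
    )
    params.update(overrides)
    return GfbPhantomSpec(**params)


@dataclass
class FiducialSet:
    """Gold beads on the two section surfaces; positions are ground truth (nm)."""

    beads: list[dict] = field(default_factory=list)  # surface, position (z,y,x) nm, diameter

    def positions(self, surface: str | None = None) -> np.ndarray:
        rows = [b["position"] for b in self.beads if surface is None or b["surface"] == surface]
        return np.asarray(rows, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.beads)


@dataclass
class SpacePhantomSpec:
    """Urinary-space phantom: per-SPS (exit width nm, length um, depth nm)."""

    sps_geometries: Sequence[tuple[float, float, float]] = (
        (200.0, 9.0, 200.0),
        (1200.0, 6.0, 400.0),
        (0.0, 6.0, 500.0),
    )
    voxel_size: tuple[float, float, float] = (25.0, 41.0, 41.0)  # nm (z, y, x)
    shape: tuple[int, int, int] = (120, 160, 320)  # (z, y, x) voxels
    noise_gaussian_sd: float = 0.0

    def __post_init__(self) -> None:
        vz = self.voxel_size[0]
        for w, length_um, depth in self.sps_geometries:
            if w < 0 or length_um <= 0 or depth <= 0:
                raise ValueError("SPS geometry values must be positive (exit width may be 0)")
            if depth < vz:
                raise ValueError(
                    f"requested depth {depth} nm is below one voxel ({vz} nm): sub-resolution"
                )


# ---------------------------------------------------------------------------
# fibre point process
# ---------------------------------------------------------------------------


def mean_nn_spacing(points: np.ndarray) -> float:
    """Mean nearest-neighbour distance of a 2D point set (the ground-truth d)."""
    if len(points) < 2:
        raise ValueError("need at least two points")
    dist, _ = cKDTree(points).query(points, k=2)
    return float(dist[:, 1].mean())


def _hardcore_points(n_target: int, r0: float, extent_y: float, extent_x: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing (Poisson hard-core) sample with minimum distance ``r0``."""
    pts: list[np.ndarray] = []
    attempts = 0
    arr = np.empty((0, 2))
    while len(pts) < n_target and attempts < 60 * n_target:
        attempts += 1
        p = np.array([rng.uniform(-r0, extent_y + r0), rng.uniform(-r0, extent_x + r0)])
        if len(pts) == 0 or (((arr - p) ** 2).sum(axis=1) >= r0 * r0).all():
            pts.append(p)
            arr = np.asarray(pts)
    return arr


def fibre_centres(extent_y: float, extent_x: float, d: float, cv: float,
                  rng: np.random.Generator, n_calibration_iters: int = 10) -> np.ndarray:
    """Sample fibre base positions with mean nearest-neighbour spacing ``d``.

    A Poisson hard-core (dart-throwing) process: the exclusion radius is set
    from the disorder parameter (``r0 = d (1 - 1.5 cv)``) and the point count
    is calibrated numerically so the empirical mean nearest-neighbour
    distance matches ``d``.  The process has a single predominant spacing and
    no long-range lattice order; the realised spacing coefficient of
    variation tracks ``cv`` approximately.
    """
    r0 = float(np.clip(d * (1.0 - 1.5 * cv), 0.2 * d, 0.95 * d))
    n = max(int(round(extent_y * extent_x / d**2)), 4)
    pts = _hardcore_points(n, r0, extent_y, extent_x, rng)
    best, best_err = pts, abs(mean_nn_spacing(pts) - d)
    for _ in range(n_calibration_iters):
        m = mean_nn_spacing(pts)
        if abs(m - d) / d < 0.005:
            return pts
        n = max(int(round(n * (m / d) ** 2)), 4)
        pts = _hardcore_points(n, r0, extent_y, extent_x, rng)
        err = abs(mean_nn_spacing(pts) - d)
        if err < best_err:
            best, best_err = pts, err
    return best


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _layer_bounds(spec: GfbPhantomSpec) -> dict[str, tuple[float, float]]:
    """z intervals (nm) of the five layers, top of section at z = 0."""
    g1 = spec.membrane_plane  # glycocalyx / endothelium boundary
    g0 = g1 - spec.glycocalyx_thickness
    e1 = g1 + spec.endothelium_thickness
    b1 = e1 + spec.gbm_thickness
    return {
        "lumen": (0.0, g0),
        "glycocalyx": (g0, g1),
        "endothelium": (g1, e1),
        "GBM": (e1, b1),
        "podocyte": (b1, spec.section_thickness_nm),
    }


def generate_gfb_phantom(spec: GfbPhantomSpec, seed: int
                         ) -> tuple[ImageVolume, LabelVolume, np.ndarray]:
    """Layered filtration-barrier phantom with a fibre-matrix glycocalyx.

    Returns the stained-intensity volume, the per-layer label volume, and the
    ground-truth fibre base centres as an ``(n, 2)`` array of (y, x) in nm.
    Deterministic for fixed ``(spec, seed)``.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.volume_shape
    vz, vy, vx = spec.voxel_size
    ext_y, ext_x = ny * vy, nx * vx
    bounds = _layer_bounds(spec)

    z_centres = (np.arange(nz) + 0.5) * vz
    labels = np.zeros((nz, ny, nx), dtype=np.int16)
    vol = np.zeros((nz, ny, nx), dtype=np.float64)
    layer_level = {
        "lumen": INTENSITY["lumen"],
        "glycocalyx": INTENSITY["matrix"],
        "endothelium": INTENSITY["cytoplasm"],
        "GBM": INTENSITY["membrane"],
        "podocyte": INTENSITY["cytoplasm"],
    }
    for name, (z0, z1) in bounds.items():
        sel = (z_centres >= z0) & (z_centres < z1)
        labels[sel] = _NAME_TO_LABEL[name]
        vol[sel] = layer_level[name]

    # --- glycocalyx fibres: tilted cylinders through the slab ----------------
    centres = fibre_centres(ext_y, ext_x, spec.fibre_spacing_mean, spec.fibre_spacing_cv, rng)
    tilt = np.abs(rng.normal(0.0, np.deg2rad(5.0), size=len(centres)))
    tilt = np.minimum(tilt, np.deg2rad(spec.fibre_tilt_max_deg))
    azim = rng.uniform(0.0, 2 * np.pi, size=len(centres))
    slope = np.tan(tilt)
    slope_yx = np.column_stack([slope * np.sin(azim), slope * np.cos(azim)])  # d(y,x)/dz

    g0, g1 = bounds["glycocalyx"]
    z_mid = 0.5 * (g0 + g1)
    stain = INTENSITY["resin"] + spec.stain_contrast
    r_pix = spec.fibre_radius / vx  # assume square in-plane voxels for the disc stamp
    stamp = _disc_offsets(r_pix)
    glyco_slices = np.nonzero((z_centres >= g0) & (z_centres < g1))[0]
    for iz in glyco_slices:
        dz = z_centres[iz] - z_mid
        pos = centres + slope_yx * dz  # (n, 2) in nm (y, x)
        iy = np.round(pos[:, 0] / vy - 0.5).astype(int)
        ix = np.round(pos[:, 1] / vx - 0.5).astype(int)
        yy = (iy[:, None] + stamp[:, 0][None, :]).ravel()
        xx = (ix[:, None] + stamp[:, 1][None, :]).ravel()
        ok = (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx)
        vol[iz, yy[ok], xx[ok]] = stain

    # --- fenestrations: cylindrical holes through the endothelium ------------
    e_sel = labels == _NAME_TO_LABEL["endothelium"]
    fen = _hole_mask(ny, nx, vy, vx, spec.fenestration_pitch, spec.fenestration_diameter / 2.0)
    vol[e_sel & fen[None, :, :].repeat(nz, axis=0)] = INTENSITY["lumen"]

    # --- filtration slits between foot processes ------------------------------
    p_sel = labels == _NAME_TO_LABEL["podocyte"]
    x_nm = (np.arange(nx) + 0.5) * vx
    slit = (x_nm % spec.foot_process_pitch) < spec.slit_width
    vol[p_sel & slit[None, None, :].repeat(nz, axis=0).repeat(ny, axis=1)] = INTENSITY["lumen"]

    if spec.noise_gaussian_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_gaussian_sd, size=vol.shape)

    image = ImageVolume(vol, spec.voxel_size, meta={"seed": seed, "phantom": "gfb"})
    label_vol = LabelVolume(labels, dict(LABEL_LEGEND), spec.voxel_size)
    return image, label_vol, centres


def _disc_offsets(r_pix: float) -> np.ndarray:
    r = int(np.ceil(r_pix))
    dy, dx = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    keep = dy**2 + dx**2 <= r_pix**2
    return np.column_stack([dy[keep], dx[keep]])


def _hole_mask(ny: int, nx: int, vy: float, vx: float, pitch: float, radius: float) -> np.ndarray:
    y_nm = (np.arange(ny) + 0.5) * vy
    x_nm = (np.arange(nx) + 0.5) * vx
    ry = (y_nm % pitch) - pitch / 2.0
    rx = (x_nm % pitch) - pitch / 2.0
    return (ry[:, None] ** 2 + rx[None, :] ** 2) <= radius**2


def generate_blank_resin(shape: tuple[int, int, int],
                         voxel_size: tuple[float, float, float],
                         background: float = INTENSITY["resin"],
                         noise_gaussian_sd: float = 5.0,
                         seed: int = 0) -> ImageVolume:
    """Structureless resin: voxel-independent Gaussian noise about ``background``."""
    if noise_gaussian_sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    data = np.full(shape, float(background))
    if noise_gaussian_sd > 0:
        data += rng.normal(0.0, noise_gaussian_sd, size=shape)
    return ImageVolume(data, voxel_size, meta={"seed": seed, "phantom": "blank_resin"})


def add_fiducials(vol: ImageVolume, n_per_surface: int, seed: int,
                  diameter_nm: float = 10.0, intensity: float = 2.0e4,
                  margin_nm: float | None = None,
                  max_retries: int = 200) -> tuple[ImageVolume, FiducialSet]:
    """Render gold beads as bright spheres on both z surfaces of the section.

    Bead centres sit half a diameter inside each surface; positions are
    returned as ground truth.  Beads are kept at least two diameters apart in
    plane so projections resolve them individually.  ``margin_nm`` keeps bead
    centres away from the lateral field edges (useful so beads stay in the
    field of view when the section is tilted); default one bead diameter.
    """
    nz, ny, nx = vol.shape
    vz, vy, vx = vol.voxel_size
    thickness = nz * vz
    if thickness < diameter_nm:
        raise ValueError(f"section thickness {thickness} nm < bead diameter {diameter_nm} nm")
    rng = np.random.default_rng(seed)
    data = vol.data.astype(np.float64, copy=True)
    beads: list[dict] = []
    r = diameter_nm / 2.0
    min_sep = 2.0 * diameter_nm
    margin = diameter_nm if margin_nm is None else margin_nm
    placed: list[tuple[float, float]] = []  # in-plane, across both surfaces
    for surface, z_nm in (("top", r), ("bottom", thickness - r)):
        for _ in range(n_per_surface):
            for attempt in range(max_retries + 1):
                y = rng.uniform(margin, ny * vy - margin)
                x = rng.uniform(margin, nx * vx - margin)
                if all((y - py) ** 2 + (x - px) ** 2 >= min_sep**2 for py, px in placed):
                    placed.append((y, x))
                    beads.append({"surface": surface, "position": (z_nm, y, x),
                                  "diameter": diameter_nm})
                    break
            else:
                raise RuntimeError(
                    f"could not place bead without overlap after {max_retries} retries; "
                    "reduce n_per_surface"
                )
        # rasterize this surface's beads
    for bead in beads:
        bz, by, bx = bead["position"]
        _stamp_sphere(data, (vz, vy, vx), (bz, by, bx), r, intensity)
    out = ImageVolume(data, vol.voxel_size, origin=vol.origin, meta=dict(vol.meta))
    return out, FiducialSet(beads)


def _stamp_sphere(data: np.ndarray, voxel: tuple[float, float, float],
                  centre_nm: tuple[float, float, float], radius_nm: float,
                  intensity: float) -> None:
    vz, vy, vx = voxel
    cz, cy, cx = centre_nm
    iz0, iz1 = int((cz - radius_nm) / vz) - 1, int((cz + radius_nm) / vz) + 2
    iy0, iy1 = int((cy - radius_nm) / vy) - 1, int((cy + radius_nm) / vy) + 2
    ix0, ix1 = int((cx - radius_nm) / vx) - 1, int((cx + radius_nm) / vx) + 2
    iz0, iy0, ix0 = max(iz0, 0), max(iy0, 0), max(ix0, 0)
    iz1 = min(iz1, data.shape[0]); iy1 = min(iy1, data.shape[1]); ix1 = min(ix1, data.shape[2])
    zc = (np.arange(iz0, iz1) + 0.5) * vz - cz
    yc = (np.arange(iy0, iy1) + 0.5) * vy - cy
    xc = (np.arange(ix0, ix1) + 0.5) * vx - cx
    dist = np.sqrt(zc[:, None, None] ** 2 + yc[None, :, None] ** 2 + xc[None, None, :] ** 2)
    # antialiased edge: fractional coverage over one voxel width
    voxel = min(vz, vy, vx)
    frac = np.clip((radius_nm - dist) / voxel + 0.5, 0.0, 1.0)
    block = data[iz0:iz1, iy0:iy1, ix0:ix1]
    np.maximum(block, frac * intensity + (1.0 - frac) * block, out=block)


# ---------------------------------------------------------------------------
# urinary-space phantom
# ---------------------------------------------------------------------------


def generate_space_phantom(spec: SpacePhantomSpec, seed: int
                           ) -> tuple[ImageVolume, LabelVolume, MorphometryTable]:
    """Labelled urinary-space phantom mirroring the SPS morphometry schema.

    Each requested sub-podocyte space is a cavity of the given (exit width,
    length, depth) under a podocyte body, connected (unless sealed) through an
    aperture of the requested height to a common exterior urinary space.  The
    ground-truth table is returned for recovery testing.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.shape
    vz, vy, vx = spec.voxel_size

    POD, SPS, PUS, GBM = (_NAME_TO_LABEL[n] for n in ("podocyte", "SPS", "PUS", "GBM"))
    labels = np.full((nz, ny, nx), POD, dtype=np.int16)

    gbm_vox = 4
    labels[-gbm_vox:] = GBM  # barrier at the bottom of the stack
    pus_top = 6
    labels[:pus_top] = PUS  # exterior urinary space sheet at the top
    # a PUS shaft along x = 0 connecting the top sheet down to cavity level
    shaft_x = 4
    labels[:-gbm_vox, :, :shaft_x] = PUS

    wall = 3  # podocyte wall thickness, voxels
    records: list[MorphometryRecord] = []
    # lay SPS cavities out in y lanes above the GBM
    y_cursor = wall
    for i, (exit_w_nm, length_um, depth_nm) in enumerate(spec.sps_geometries, start=1):
        d_vox = max(int(round(depth_nm / vz)), 1)
        l_vox = max(int(round(length_um * 1000.0 / vx)), 1)
        w_vox = int(round(exit_w_nm / vz))
        breadth = max(int(np.ceil(exit_w_nm / vy)) + 2 * wall, 16)
        z1 = nz - gbm_vox  # cavity floor sits on the GBM
        z0 = z1 - d_vox
        x0 = shaft_x + wall
        x1 = x0 + l_vox
        y0 = y_cursor
        y1 = y0 + breadth
        if x1 + wall > nx or y1 + wall > ny or z0 <= pus_top:
            raise ValueError(
                f"SPS {i} with (exit {exit_w_nm} nm, length {length_um} um, depth "
                f"{depth_nm} nm) does not fit the {spec.shape} volume"
            )
        labels[z0:z1, y0:y1, x0:x1] = SPS
        sub_res = 0 < exit_w_nm < vz
        n_exits = 0
        if w_vox >= 1:
            # aperture through the wall to the shaft, height = exit width along z;
            # flare the adjacent SPS column so the full aperture meets SPS
            a0 = min(z0, z1 - w_vox)
            a0 = max(a0, pus_top)
            labels[a0:a0 + w_vox, y0:y1, shaft_x:x0] = PUS
            labels[a0:a0 + w_vox, y0:y1, x0:x0 + 1] = SPS
            n_exits = 1
        records.append(
            MorphometryRecord(
                sps_id=i,
                exit_width_nm=float(w_vox * vz) if w_vox >= 1 else 0.0,
                length_um=l_vox * vx / 1000.0,
                depth_nm=d_vox * vz,
                n_exits=n_exits,
                sub_resolution=sub_res,
            )
        )
        y_cursor = y1 + wall

    level = {
        POD: INTENSITY["cytoplasm"], GBM: INTENSITY["membrane"],
        SPS: INTENSITY["lumen"], PUS: INTENSITY["lumen"],
    }
    vol = np.zeros_like(labels, dtype=np.float64)
    for lab, value in level.items():
        vol[labels == lab] = value
    if spec.noise_gaussian_sd > 0:
        vol += rng.normal(0.0, spec.noise_gaussian_sd, size=vol.shape)

    image = ImageVolume(vol, spec.voxel_size, meta={"seed": seed, "phantom": "spaces"})
    label_vol = LabelVolume(labels, dict(LABEL_LEGEND), spec.voxel_size)
    table = MorphometryTable(records, provenance=f"space phantom seed={seed}")
    return image, label_vol, table
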