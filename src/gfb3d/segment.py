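"""Stain segmentation, compartment labelling and urinary-space morphometry.

Backscattered-electron micrographs carry atomic-number contrast; inverting
them yields TEM-like images in which the lanthanide-stained glycocalyx is the
brightest compartment, so a global intensity threshold isolates the stain.
Connected-component labelling turns binary urinary-space masks into
compartment label volumes, and the morphometry operations reproduce the
tracked sub-podocyte-space (SPS) table schema: per space, the width of its
exit region(s) to neighbouring urinary spaces (nm), its longest in-plane
extent (um) and its depth normal to the filtration barrier (nm).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from .io_formats import ImageVolume, LabelVolume, MorphometryRecord, MorphometryTable

__all__ = [
    "LabelVolume",
    "MorphometryRecord",
    "MorphometryTable",
    "invert_backscatter",
    "threshold_stain",
    "label_spaces",
    "thickness_map",
    "measure_sps",
    "sps_coverage",
    "URINARY_SPACE_NAMES",
]

URINARY_SPACE_NAMES = ("SPS", "IPS", "PUS")


def invert_backscatter(data: ImageVolume | np.ndarray) -> ImageVolume | np.ndarray:
    """Invert intensity about the volume's range: ``out = min + max - in``.

    Involutive; turns backscatter contrast into TEM-like contrast.
    """
    arr = data.data if isinstance(data, ImageVolume) else np.asarray(data)
    if not np.all(np.isfinite(arr)):
        raise ValueError("intensities must be finite")
    out = (arr.min() + arr.max()) - arr
    if isinstance(data, ImageVolume):
        return ImageVolume(out, data.voxel_size, origin=data.origin, meta=dict(data.meta))
    return out


def threshold_stain(vol: ImageVolume, method: str = "otsu",
                    level: float | None = None) -> tuple[np.ndarray, float]:
    """Binary stain mask by global intensity threshold.

    ``method='otsu'`` picks the threshold automatically from the intensity
    histogram; ``method='fixed'`` requires ``level``.  Returns the mask
    (True where intensity >= threshold) and the threshold used.
    """
    data = vol.data
    if method == "otsu":
        if np.ptp(data) == 0:
            raise ValueError("constant volume: Otsu threshold undefined")
        thr = float(threshold_otsu(np.asarray(data, dtype=float)))
    elif method == "fixed":
        if level is None:
            raise ValueError("fixed thresholding requires level=")
        thr = float(level)
    else:
        raise ValueError(f"unknown method {method!r}")
    return data >= thr, thr


def label_spaces(mask: np.ndarray, connectivity: int = 26,
                 voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> LabelVolume:
    """Connected components of a binary mask, labelled in decreasing size.

    ``connectivity`` is 6 (faces) or 26 (faces, edges and corners).
    Label 0 is background; the partition is deterministic and independent of
    voxel traversal order.
    """
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    mask = np.asarray(mask, dtype=bool)
    raw = sk_label(mask, connectivity=1 if connectivity == 6 else 3)
    n = raw.max()
    legend = {0: "background"}
    if n == 0:
        return LabelVolume(raw.astype(np.int32), legend, voxel_size)
    sizes = np.bincount(raw.ravel())[1:]
    order = np.argsort(-sizes, kind="stable") + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
        legend[new] = f"space_{new}"
    return LabelVolume(remap[raw], legend, voxel_size)


def thickness_map(stain_mask: np.ndarray, surface_z: int,
                  voxel_size: tuple[float, float, float],
                  direction: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """Stain thickness and unstained gap along the surface normal, in nm.

    For each in-plane point of the axis-aligned membrane surface at z index
    ``surface_z``, walk along the normal (``direction`` -1 towards smaller z,
    +1 towards larger z): the gap is the unstained distance before the first
    stained voxel, the thickness the contiguous stained run from there.
    Points with no stain report zero thickness and a gap spanning the volume.
    """
    mask = np.asarray(stain_mask, dtype=bool)
    nz = mask.shape[0]
    if not 0 <= surface_z < nz:
        raise ValueError(f"surface z index {surface_z} outside volume of {nz} slices")
    vz = voxel_size[0]
    if direction == -1:
        column = mask[surface_z::-1]  # from the surface towards z = 0
    elif direction == 1:
        column = mask[surface_z:]
    else:
        raise ValueError("direction must be -1 or +1")
    n = column.shape[0]
    any_stain = column.any(axis=0)
    first = np.where(any_stain, column.argmax(axis=0), n)
    # run length of contiguous stain starting at `first`
    idx = np.arange(n)[:, None, None]
    beyond = (~column) & (idx >= first[None])
    stop = np.where(beyond.any(axis=0), beyond.argmax(axis=0), n)
    thickness = np.where(any_stain, stop - first, 0) * vz
    gap = first.astype(float) * vz
    return thickness.astype(float), gap


def _exit_width_nm(patch_mask: np.ndarray, sampling: tuple[float, float]) -> float:
    """Largest inscribed-circle diameter of a planar aperture patch (nm)."""
    padded = np.pad(patch_mask, 1)
    edt = ndimage.distance_transform_edt(padded, sampling=sampling)
    return float(2.0 * edt.max())


def measure_sps(labels: LabelVolume, connectivity: int = 26) -> MorphometryTable:
    """Morphometry of every sub-podocyte space in a label volume.

    Per connected SPS component: the number of distinct exit interfaces to
    other urinary-space compartments, the width of the widest exit (largest
    inscribed-sphere diameter at the interface, nm), the longest in-plane
    extent (um) and the median normal (z) extent (nm).  Values below one
    voxel are flagged sub-resolution.
    """
    if "SPS" not in labels.legend.values():
        return MorphometryTable([], provenance="no SPS label present")
    vz, vy, vx = labels.voxel_size
    sps_mask = labels.mask("SPS")
    other_urinary = np.zeros(labels.labels.shape, dtype=bool)
    for name in URINARY_SPACE_NAMES[1:]:
        if name in labels.legend.values():
            other_urinary |= labels.mask(name)

    comps = sk_label(sps_mask, connectivity=1 if connectivity == 6 else 3)
    records: list[MorphometryRecord] = []
    # face-adjacency to another urinary space marks exit interface voxels
    struct = ndimage.generate_binary_structure(3, 1)
    near_urinary = ndimage.binary_dilation(other_urinary, structure=struct)
    for comp_id in range(1, comps.max() + 1):
        comp = comps == comp_id
        zz, yy, xx = np.nonzero(comp)
        extent_y = (yy.max() - yy.min() + 1) * vy
        extent_x = (xx.max() - xx.min() + 1) * vx
        length_um = max(extent_y, extent_x) / 1000.0
        # depth: z run per occupied column, median over columns
        col_counts = comp.sum(axis=0)
        depth_nm = float(np.median(col_counts[col_counts > 0]) * vz)

        interface = comp & near_urinary
        n_exits = 0
        widest = 0.0
        if interface.any():
            exit_comps = sk_label(interface, connectivity=3)
            n_exits = int(exit_comps.max())
            for ex_id in range(1, n_exits + 1):
                ex = exit_comps == ex_id
                ezz, eyy, exx = np.nonzero(ex)
                # project the interface patch onto its dominant plane
                spans = (np.ptp(ezz), np.ptp(eyy), np.ptp(exx))
                flat_axis = int(np.argmin(spans))
                if flat_axis == 0:
                    patch = ex.any(axis=0)
                    width = _exit_width_nm(patch, (vy, vx))
                elif flat_axis == 1:
                    patch = ex.any(axis=1)
                    width = _exit_width_nm(patch, (vz, vx))
                else:
                    patch = ex.any(axis=2)
                    width = _exit_width_nm(patch, (vz, vy))
                widest = max(widest, width)
        records.append(
            MorphometryRecord(
                sps_id=comp_id,
                exit_width_nm=widest if n_exits else 0.0,
                length_um=length_um,
                depth_nm=depth_nm,
                n_exits=n_exits,
                sub_resolution=bool(0.0 < widest < min(vz, vy, vx)),
            )
        )
    return MorphometryTable(records, provenance="measure_sps")


def sps_coverage(labels: LabelVolume, surface_z: int, direction: int = -1) -> float:
    """Fraction of barrier surface points whose outward normal first meets SPS.

    Rays are cast from the axis-aligned surface at z index ``surface_z``
    along the normal; tissue labels are skipped and the first urinary-space
    compartment met decides.  Columns meeting no urinary space count against
    coverage.
    """
    nz = labels.labels.shape[0]
    if not 0 <= surface_z < nz:
        raise ValueError("surface outside volume")
    urinary = {name: labels.mask(name) for name in URINARY_SPACE_NAMES
               if name in labels.legend.values()}
    if "SPS" not in urinary:
        return 0.0
    any_urinary = np.zeros(labels.labels.shape, dtype=bool)
    for m in urinary.values():
        any_urinary |= m
    if direction == -1:
        col_any = any_urinary[surface_z::-1]
        col_sps = urinary["SPS"][surface_z::-1]
    elif direction == 1:
        col_any = any_urinary[surface_z:]
        col_sps = urinary["SPS"][surface_z:]
    else:
        raise ValueError("direction must be -1 or +1")
    ny, nx = col_any.shape[1:]
    if ny * nx == 0:
        raise ValueError("empty surface")
    hits = col_any.any(axis=0)
    first = np.where(hits, col_any.argmax(axis=0), 0)
    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    first_is_sps = hits & col_sps[first, iy, ix]
    return float(first_is_sps.sum() / (ny * nx))
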