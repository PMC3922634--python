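"""Pre-shrink measurement: beam shrinkage from fiducial movement at fixed tilt.

Before acquiring a tilt series the section is deliberately exposed: it is
tilted to 45 degrees and 60 one-second micrographs are taken at the intended
beam intensity, during which the resin section loses a substantial fraction
(around a quarter) of its thickness anisotropically along z.  Gold beads on
the two surfaces project, at tilt theta, to in-image positions separated along
the tilt direction by ``t sin(theta)`` for a section of thickness ``t``; as
the section thins the top- and bottom-surface beads drift towards each other.
Tracking the beads therefore yields both the shrinkage fraction
``s = 1 - final separation / initial separation`` and the original thickness
``initial separation / sin(theta)``.

The shrinkage fraction is reported relative to the original thickness
(final = original x (1 - s)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .io_formats import ImageVolume
from .phantom import FiducialSet
from .tomo import project

__all__ = [
    "FiducialTracks",
    "ShrinkageEstimate",
    "simulate_preshrink_series",
    "track_fiducials",
    "estimate_shrinkage",
    "write_tracks_csv",
]


@dataclass
class FiducialTracks:
    """Per-bead image trajectories across an exposure series.

    ``tracks`` maps bead id -> dict with keys ``surface`` ('top'/'bottom' or
    'unknown'), ``frames`` (exposure indices), ``positions_nm`` ((n, 2) array
    of (y, x) image positions) and ``score`` (mean detection intensity).
    """

    tracks: dict[int, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for bead_id, tr in self.tracks.items():
            pos = np.asarray(tr["positions_nm"], dtype=float)
            if len(pos) < 2:
                raise ValueError(f"track {bead_id} covers fewer than 2 exposures")
            if not np.all(np.isfinite(pos)):
                raise ValueError(f"track {bead_id} has non-finite positions")
            tr["positions_nm"] = pos

    def surface_ids(self, surface: str) -> list[int]:
        return [i for i, tr in self.tracks.items() if tr["surface"] == surface]

    def __len__(self) -> int:
        return len(self.tracks)


@dataclass
class ShrinkageEstimate:
    fraction: float  # s in [0, 1)
    original_thickness_nm: float
    se: float  # standard error of s across bead pairs
    n_pairs: int

    @property
    def final_thickness_nm(self) -> float:
        return self.original_thickness_nm * (1.0 - self.fraction)


def simulate_preshrink_series(vol: ImageVolume, beads: FiducialSet,
                              n_exposures: int = 60, theta_deg: float = 45.0,
                              shrinkage_total: float = 0.25, seed: int = 0,
                              noise_gaussian_sd: float = 0.0,
                              noise_poisson_scale: float = 0.0,
                              ) -> tuple[np.ndarray, dict]:
    """Fixed-tilt exposure series of a fiducial-decorated section.

    The section's z extent shrinks linearly in exposure index from the full
    thickness at frame 0 to ``1 - shrinkage_total`` of it at the last frame.
    Returns the frame stack ``(n, ny, nx)`` and a ground-truth dict with the
    per-frame z-scale factors and projected bead positions (nm).
    """
    if not 0.0 <= shrinkage_total < 1.0:
        raise ValueError("shrinkage_total must be in [0, 1)")
    if n_exposures < 2:
        raise ValueError("need at least 2 exposures")
    rng = np.random.default_rng(seed)
    nz, ny, nx = vol.shape
    vz, vy, vx = vol.voxel_size
    th = np.deg2rad(theta_deg)
    scales = 1.0 - shrinkage_total * np.arange(n_exposures) / (n_exposures - 1)

    frames = np.empty((n_exposures, ny, nx))
    truth_positions = np.empty((n_exposures, len(beads), 2))  # (y, x) nm
    cz_nm, cx_nm = nz * vz / 2.0, nx * vx / 2.0
    pos = beads.positions()
    for i, scale in enumerate(scales):
        p = project(vol, theta_deg, axis_id=0, z_scale=float(scale))
        if noise_poisson_scale > 0:
            c = noise_poisson_scale
            p = rng.poisson(np.clip(p, 0.0, None) * c) / c
        if noise_gaussian_sd > 0:
            p = p + rng.normal(0.0, noise_gaussian_sd, size=p.shape)
        frames[i] = p
        # detector coordinate: u = (x - cx) cos + (cz - z*scale ... ) about centre
        z_rel = (pos[:, 0] - cz_nm) * scale
        u = (pos[:, 2] - cx_nm) * np.cos(th) - z_rel * np.sin(th) + cx_nm
        truth_positions[i, :, 0] = pos[:, 1]
        truth_positions[i, :, 1] = u
    truth = {
        "scales": scales,
        "positions_nm": truth_positions,
        "surfaces": [b["surface"] for b in beads.beads],
        "theta_deg": theta_deg,
        "shrinkage_total": shrinkage_total,
    }
    return frames, truth


def track_fiducials(frames: np.ndarray, pixel_size_nm: float,
                    expected_diameter_nm: float = 10.0,
                    min_rel_intensity: float = 0.3) -> FiducialTracks:
    """Detect and link gold beads across an exposure series.

    Beads are localised per frame as intensity peaks of the background-
    subtracted image (Gaussian high-pass at three bead diameters) with
    centroid refinement, then linked frame-to-frame by nearest neighbour.
    Surfaces are assigned from the sense of each track's displacement along
    the tilt direction: at fixed positive tilt, shrinkage moves top-surface
    beads one way and bottom-surface beads the other.  With no shrinkage (no
    movement) the assignment is genuinely undetermined and is left 'unknown'.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be (n, ny, nx)")
    diam_px = max(expected_diameter_nm / pixel_size_nm, 1.0)

    detections: list[np.ndarray] = []
    for fr in frames:
        bg = ndimage.gaussian_filter(fr, 3.0 * diam_px)
        hp = fr - bg
        coords = peak_local_max(hp, min_distance=max(int(round(diam_px)), 1),
                                threshold_abs=min_rel_intensity * hp.max())
        refined = np.array([_centroid(hp, c, int(np.ceil(1.5 * diam_px))) for c in coords]
                           ).reshape(-1, 2)
        # pixel index i covers physical coordinate (i + 0.5) * pixel size
        detections.append((refined + 0.5) * pixel_size_nm)
    if len(detections[0]) == 0:
        raise ValueError("no detectable beads; increase bead contrast or count")

    # nearest-neighbour linking from frame 0
    n_beads = len(detections[0])
    positions = np.full((len(frames), n_beads, 2), np.nan)
    positions[0] = detections[0]
    for i in range(1, len(frames)):
        prev = positions[i - 1]
        cur = detections[i]
        if len(cur) == 0:
            positions[i] = prev
            continue
        d2 = ((prev[:, None, :] - cur[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        # gate: a bead moves far less than its diameter between exposures;
        # if the match is farther the bead was lost (left the field, merged)
        gate = (2.0 * expected_diameter_nm) ** 2
        matched = np.take_along_axis(d2, nearest[:, None], axis=1)[:, 0] <= gate
        positions[i] = np.where(matched[:, None], cur[nearest], prev)

    # surface assignment from displacement along the tilt direction (x)
    dx = positions[-1, :, 1] - positions[0, :, 1]
    move_scale = np.median(np.abs(dx))
    tracks: dict[int, dict] = {}
    for b in range(n_beads):
        if move_scale < 0.2 * pixel_size_nm:
            surface = "unknown"
        else:
            surface = "top" if dx[b] < 0 else "bottom"
        tracks[b] = {
            "surface": surface,
            "frames": np.arange(len(frames)),
            "positions_nm": positions[:, b, :],
            "score": 1.0,
        }
    return FiducialTracks(tracks)


def _centroid(img: np.ndarray, coord: np.ndarray, radius_px: int,
              n_iter: int = 3) -> np.ndarray:
    """Iterative intensity-weighted centroid around a peak.

    Background is suppressed by thresholding at 20% of the local maximum so
    the negative moat of the high-pass filter does not bias the estimate; the
    window is recentred between iterations to remove integer-peak bias.
    """
    ny, nx = img.shape
    pos = coord.astype(float)
    for _ in range(n_iter):
        y0, x0 = int(round(pos[0])), int(round(pos[1]))
        ys = slice(max(y0 - radius_px, 0), min(y0 + radius_px + 1, ny))
        xs = slice(max(x0 - radius_px, 0), min(x0 + radius_px + 1, nx))
        patch = img[ys, xs]
        w = np.clip(patch - 0.2 * patch.max(), 0.0, None)
        if w.sum() == 0:
            return pos
        yy, xx = np.mgrid[ys, xs]
        pos = np.array([(w * yy).sum() / w.sum(), (w * xx).sum() / w.sum()])
    return pos


def write_tracks_csv(tracks: FiducialTracks, path) -> None:
    """Export tracks as CSV with columns bead_id,surface,frame,y_nm,x_nm."""
    import pandas as pd

    rows = []
    for bead_id, tr in tracks.tracks.items():
        for frame, (y, x) in zip(tr["frames"], tr["positions_nm"]):
            rows.append({"bead_id": bead_id, "surface": tr["surface"],
                         "frame": int(frame), "y_nm": y, "x_nm": x})
    pd.DataFrame(rows).to_csv(path, index=False)


def estimate_shrinkage(tracks: FiducialTracks, theta_deg: float,
                       nominal_thickness_nm: float | None = None) -> ShrinkageEstimate:
    """Shrinkage fraction and original thickness from top/bottom bead pairs.

    Top and bottom beads are paired by nearest in-plane neighbour at exposure
    0.  For each pair the projected separation along the tilt direction is
    ``t sin(theta)``, so ``s = 1 - final/initial separation`` (averaged over
    pairs) and ``original thickness = mean initial separation / sin(theta)``.
    """
    sin_t = np.sin(np.deg2rad(theta_deg))
    cos_t = np.cos(np.deg2rad(theta_deg))
    if abs(sin_t) < 0.1:
        raise ValueError(f"tilt {theta_deg} degrees is ill-conditioned (|sin| < 0.1)")
    top = tracks.surface_ids("top")
    bottom = tracks.surface_ids("bottom")
    if not top or not bottom:
        raise ValueError("need at least one bead on each surface "
                         "(tracks must carry top/bottom labels)")

    top_pos0 = np.array([tracks.tracks[i]["positions_nm"][0] for i in top])
    bot_pos0 = np.array([tracks.tracks[i]["positions_nm"][0] for i in bottom])
    # de-project image x to in-plane x before pairing: the two surfaces are
    # offset along the tilt direction by +/- (t/2) sin(theta) in the image
    if nominal_thickness_nm is not None:
        half_shift = 0.5 * nominal_thickness_nm * abs(sin_t)
    else:
        half_shift = 0.5 * (top_pos0[:, 1].mean() - bot_pos0[:, 1].mean())
    top_plane = top_pos0.copy()
    bot_plane = bot_pos0.copy()
    top_plane[:, 1] = (top_pos0[:, 1] - half_shift) / cos_t
    bot_plane[:, 1] = (bot_pos0[:, 1] + half_shift) / cos_t
    d2 = ((top_plane[:, None, :] - bot_plane[None, :, :]) ** 2).sum(axis=2)
    partner = np.argmin(d2, axis=1)

    sep0_list, sep1_list = [], []
    for it, ib in zip(top, (bottom[j] for j in partner)):
        pt = tracks.tracks[it]["positions_nm"]
        pb = tracks.tracks[ib]["positions_nm"]
        sep0_list.append(pt[0, 1] - pb[0, 1])
        sep1_list.append(pt[-1, 1] - pb[-1, 1])
    sep0 = np.asarray(sep0_list)
    sep1 = np.asarray(sep1_list)
    if np.all(sep0 == 0):
        raise ValueError("no usable bead pairs")
    # aggregate as a ratio of mean separations: the per-pair in-plane offset
    # between partners cancels in sep0 - sep1 and averages out in sep0, which
    # avoids the upward Jensen bias of averaging per-pair ratios
    mean_sep0 = float(sep0.mean())
    s = float((sep0 - sep1).mean() / mean_sep0)
    per_pair = (sep0 - sep1) / mean_sep0
    se = float(per_pair.std(ddof=1) / np.sqrt(len(per_pair))) if len(per_pair) > 1 else 0.0
    original = float(abs(mean_sep0) / abs(sin_t))
    return ShrinkageEstimate(fraction=s, original_thickness_nm=original,
                             se=se, n_pairs=len(per_pair))
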