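"""Glycocalyx fibre-spacing estimation by windowed FFT autocorrelation.

The headline statistic of the analysis chain.  Square windows (150 nm by
150 nm by default) containing glycocalyx are extracted at fixed in-plane
coordinates from every reconstruction slice.  Each window is tapered to its
intensity mean, autocorrelated through the power spectrum (Wiener-Khinchin,
zero-padded to suppress wrap-around), and reduced to a radial correlation
profile in the direction parallel to the membrane.  Positive profile peaks
are located through the discrete second differential; a peak is accepted only
if its curvature magnitude exceeds a threshold calibrated on control (blank
resin) windows, and the smallest accepted peak radius is the window's
predominant spacing.  The estimator is invariant to global intensity scaling
and offset of the input volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import ImageVolume, LabelVolume

__all__ = [
    "RoiWindow",
    "SpacingProfile",
    "SpacingResult",
    "SpacingParams",
    "sample_rois",
    "extract_window",
    "autocorrelation_map",
    "radial_profile",
    "detect_peaks",
    "calibrate_threshold",
    "estimate_spacing",
]


@dataclass
class RoiWindow:
    """One square analysis window in one reconstruction slice."""

    slice_index: int
    origin_nm: tuple[float, float]  # (y, x) of the window corner, nm
    side_nm: float = 150.0
    direction: tuple[float, float] = (0.0, 1.0)  # membrane-parallel unit (y, x)

    def __post_init__(self) -> None:
        if self.side_nm <= 0:
            raise ValueError("window side must be positive")
        n = float(np.hypot(*self.direction))
        if not np.isclose(n, 1.0):
            self.direction = (self.direction[0] / n, self.direction[1] / n)


@dataclass
class SpacingProfile:
    """Membrane-parallel radial correlation profile of one window.

    ``origin_power`` is the raw intensity variance of the source window; peak
    acceptance compares curvatures in absolute covariance units
    (``second_differential * origin_power``) so that a threshold calibrated
    on low-variance blank windows acts as a noise floor.
    """

    radii_nm: np.ndarray
    correlation: np.ndarray
    second_differential: np.ndarray
    origin_power: float = 1.0
    peaks_nm: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.radii_nm = np.asarray(self.radii_nm, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if np.any(np.diff(self.radii_nm) <= 0) or np.any(self.radii_nm < 0):
            raise ValueError("radii must be non-negative and strictly increasing")


@dataclass
class SpacingResult:
    """Aggregate spacing statistics over all analysed windows."""

    per_roi_peaks_nm: list[np.ndarray]
    predominant_nm: np.ndarray  # smallest accepted peak per contributing ROI
    n_areas: int
    n_slices: int
    threshold: float

    @property
    def mean_predominant_spacing_nm(self) -> float:
        return float(self.predominant_nm.mean()) if len(self.predominant_nm) else float("nan")

    @property
    def mean_all_peaks_nm(self) -> float:
        allp = np.concatenate([p for p in self.per_roi_peaks_nm if len(p)] or [np.empty(0)])
        return float(allp.mean()) if len(allp) else float("nan")

    def histogram(self, bin_nm: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
        if not len(self.predominant_nm):
            return np.empty(0), np.empty(0)
        top = np.ceil(self.predominant_nm.max() / bin_nm) * bin_nm
        edges = np.arange(0.0, top + bin_nm, bin_nm)
        counts, edges = np.histogram(self.predominant_nm, bins=edges)
        return counts, edges


@dataclass
class SpacingParams:
    roi_nm: float = 150.0
    stride_nm: float = 150.0
    sector_half_angle_deg: float = 15.0
    min_mask_fraction: float = 0.8
    taper_fraction: float = 0.1
    smooth_bins: int = 3
    threshold: float | None = None  # calibrated on blanks when None
    blank_percentile: float = 95.0
    max_radius_fraction: float = 1 / 3  # a window supports >= 3 repeats up to side/3
    min_radius_nm: float = 8.0  # ignore lags below ~2x the depth resolution
    slice_block: int = 16  # average profiles over blocks of consecutive slices


# ---------------------------------------------------------------------------
# ROI sampling
# ---------------------------------------------------------------------------


def sample_rois(vol: ImageVolume, glycocalyx_mask: LabelVolume | np.ndarray,
                roi_nm: float = 150.0, stride_nm: float = 150.0,
                min_mask_fraction: float = 0.8) -> list[RoiWindow]:
    """Fixed grid of window origins, emitted per slice where the window is
    sufficiently glycocalyx.

    The x-y origin grid is chosen once from the volume extent; a (window,
    slice) pair qualifies iff at least ``min_mask_fraction`` of its pixels
    carry the glycocalyx label, so window coordinates are identical across
    slices.  The membrane-parallel direction is taken from the in-slice
    orientation of the mask boundary; for a slab normal to z the boundary has
    no in-plane signature and the x axis is used.
    """
    mask = glycocalyx_mask.mask("glycocalyx") if isinstance(glycocalyx_mask, LabelVolume) \
        else np.asarray(glycocalyx_mask, dtype=bool)
    if mask.shape != vol.shape:
        raise ValueError("mask not aligned with volume")
    nz, ny, nx = vol.shape
    vz, vy, vx = vol.voxel_size
    side_y = max(int(round(roi_nm / vy)), 1)
    side_x = max(int(round(roi_nm / vx)), 1)
    step_y = max(int(round(stride_nm / vy)), 1)
    step_x = max(int(round(stride_nm / vx)), 1)
    origins = [(oy, ox)
               for oy in range(0, ny - side_y + 1, step_y)
               for ox in range(0, nx - side_x + 1, step_x)]
    windows: list[RoiWindow] = []
    for iz in range(nz):
        sl = mask[iz]
        for oy, ox in origins:
            frac = sl[oy:oy + side_y, ox:ox + side_x].mean()
            if frac >= min_mask_fraction:
                direction = _boundary_direction(sl)
                windows.append(RoiWindow(iz, (oy * vy, ox * vx), side_nm=roi_nm,
                                         direction=direction))
    if not windows:
        import warnings

        warnings.warn("no qualifying glycocalyx windows found", stacklevel=2)
    return windows


def _boundary_direction(slice_mask: np.ndarray) -> tuple[float, float]:
    """Membrane-parallel direction from the in-slice mask boundary normal."""
    gy, gx = np.gradient(slice_mask.astype(float))
    # structure tensor of the boundary: dominant gradient direction = normal
    jyy, jxx, jyx = (gy * gy).sum(), (gx * gx).sum(), (gy * gx).sum()
    if jyy + jxx < 1e-12:
        return (0.0, 1.0)
    # eigenvector of the larger eigenvalue of [[jyy, jyx], [jyx, jxx]]
    half_tr = 0.5 * (jyy + jxx)
    det = jyy * jxx - jyx * jyx
    lam = half_tr + np.sqrt(max(half_tr**2 - det, 0.0))
    normal = np.array([lam - jxx, jyx]) if abs(lam - jxx) > abs(lam - jyy) \
        else np.array([jyx, lam - jyy])
    n = np.hypot(*normal)
    if n < 1e-12:
        return (0.0, 1.0)
    normal /= n
    return (float(-normal[1]), float(normal[0]))  # parallel = normal rotated 90 deg


def extract_window(vol: ImageVolume, roi: RoiWindow) -> np.ndarray:
    vz, vy, vx = vol.voxel_size
    oy = int(round(roi.origin_nm[0] / vy))
    ox = int(round(roi.origin_nm[1] / vx))
    side_y = max(int(round(roi.side_nm / vy)), 1)
    side_x = max(int(round(roi.side_nm / vx)), 1)
    return np.asarray(vol.data[roi.slice_index, oy:oy + side_y, ox:ox + side_x], dtype=float)


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------


def _taper_window(n: int, fraction: float) -> np.ndarray:
    """1D raised-cosine edge taper over the outer ``fraction`` of each edge."""
    w = np.ones(n)
    edge = int(np.floor(fraction * n))
    if edge > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(edge) + 0.5) / edge))
        w[:edge] = ramp
        w[-edge:] = ramp[::-1]
    return w


def autocorrelation_map(window: np.ndarray, taper_fraction: float = 0.1) -> np.ndarray:
    """Normalised real-space autocorrelation of a square window.

    The window is blended toward its mean by a raised-cosine taper over the
    outer 10% of each edge, mean-subtracted, zero-padded to twice its size
    and autocorrelated through the power spectrum.  The returned map has the
    zero-lag value 1 at its centre and is centro-symmetric.
    """
    win = np.asarray(window, dtype=float)
    if win.ndim != 2 or win.shape[0] != win.shape[1]:
        raise ValueError(f"window must be square 2D, got {win.shape}")
    n = win.shape[0]
    mean = win.mean()
    t = _taper_window(n, taper_fraction)
    g = (win - mean) * (t[:, None] * t[None, :])
    if np.allclose(g, 0.0):
        raise ValueError("zero variance: window is constant")
    n_pad = 2 * n
    spec = np.fft.rfft2(g, s=(n_pad, n_pad))
    acf = np.fft.irfft2(np.abs(spec) ** 2, s=(n_pad, n_pad))
    acf = np.fft.fftshift(acf)
    return acf / acf[n_pad // 2, n_pad // 2]


def radial_profile(corr_map: np.ndarray, direction: tuple[float, float],
                   sector_half_angle_deg: float = 15.0,
                   pixel_size_nm: float = 1.0,
                   max_radius_px: int | None = None,
                   origin_power: float = 1.0) -> SpacingProfile:
    """Mean correlation binned by radius within a sector about +/-direction.

    Radii are binned at one-pixel width and converted to nm.  A half-angle of
    90 degrees reduces to the full rotational average.  Bins whose sector
    contains no pixel are dropped.
    """
    dy, dx = direction
    n = float(np.hypot(dy, dx))
    if not np.isfinite(n) or n == 0:
        raise ValueError("direction must be a nonzero 2-vector")
    dy, dx = dy / n, dx / n
    ny, nx = corr_map.shape
    cy, cx = ny // 2, nx // 2
    yy = np.arange(ny)[:, None] - cy
    xx = np.arange(nx)[None, :] - cx
    r = np.hypot(yy, xx)
    along = np.abs(yy * dy + xx * dx)  # |projection| folds +/-direction together
    cos_ang = np.ones_like(r)
    nonzero = r > 0
    cos_ang[nonzero] = along[nonzero] / r[nonzero]
    in_sector = cos_ang >= np.cos(np.deg2rad(sector_half_angle_deg)) - 1e-9
    max_r = max_radius_px if max_radius_px is not None else min(cy, cx) - 1
    rbin = np.round(r).astype(int)
    keep = in_sector & (rbin <= max_r)
    sums = np.bincount(rbin[keep], weights=corr_map[keep], minlength=max_r + 1)
    counts = np.bincount(rbin[keep], minlength=max_r + 1)
    valid = counts > 0
    radii = np.nonzero(valid)[0].astype(float) * pixel_size_nm
    prof = sums[valid] / counts[valid]
    second = _second_differential(prof)
    return SpacingProfile(radii, prof, second, origin_power=origin_power)


def _second_differential(profile: np.ndarray, smooth_bins: int = 3) -> np.ndarray:
    """Central-difference curvature of the moving-average-smoothed profile."""
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        padded = np.pad(profile, smooth_bins // 2, mode="edge")
        sm = np.convolve(padded, kernel, mode="valid")
    else:
        sm = profile
    d2 = np.zeros_like(sm)
    d2[1:-1] = sm[2:] - 2 * sm[1:-1] + sm[:-2]
    return d2


def detect_peaks(profile: SpacingProfile, threshold: float,
                 smooth_bins: int = 3, min_radius_nm: float = 0.0) -> np.ndarray:
    """Accepted positive peak radii (nm), smallest first.

    Local maxima of the smoothed profile where the second differential is
    negative; accepted iff the curvature magnitude (in absolute covariance
    units, i.e. scaled by the window's intensity variance) exceeds
    ``threshold`` and the radius exceeds ``min_radius_nm``.  The smallest
    accepted radius is the window's predominant spacing.
    """
    if len(profile.correlation) < 5:
        raise ValueError("profile needs at least 5 bins")
    sm = _smooth(profile.correlation, smooth_bins)
    d2 = profile.second_differential
    bin_nm = float(np.median(np.diff(profile.radii_nm)))
    accepted = []
    for i in range(1, len(sm) - 1):
        if profile.radii_nm[i] <= 0 or profile.radii_nm[i] < min_radius_nm:
            continue
        if (sm[i] > sm[i - 1] and sm[i] >= sm[i + 1] and d2[i] < 0
                and abs(d2[i]) * profile.origin_power > threshold):
            # parabolic sub-bin refinement of the peak position
            denom = sm[i - 1] - 2 * sm[i] + sm[i + 1]
            delta = 0.5 * (sm[i - 1] - sm[i + 1]) / denom if denom < 0 else 0.0
            accepted.append(profile.radii_nm[i] + float(np.clip(delta, -0.5, 0.5)) * bin_nm)
    return np.asarray(accepted)


def _smooth(profile: np.ndarray, smooth_bins: int) -> np.ndarray:
    if smooth_bins <= 1:
        return profile
    kernel = np.ones(smooth_bins) / smooth_bins
    return np.convolve(np.pad(profile, smooth_bins // 2, mode="edge"), kernel, mode="valid")


def _candidate_curvatures(profile: SpacingProfile, smooth_bins: int = 3,
                          min_radius_nm: float = 0.0) -> np.ndarray:
    """Absolute curvature magnitudes at candidate maxima of one profile."""
    sm = _smooth(profile.correlation, smooth_bins)
    d2 = profile.second_differential
    vals = [abs(d2[i]) * profile.origin_power for i in range(1, len(sm) - 1)
            if profile.radii_nm[i] > 0 and profile.radii_nm[i] >= min_radius_nm
            and sm[i] > sm[i - 1] and sm[i] >= sm[i + 1] and d2[i] < 0]
    return np.asarray(vals)


def _taper_acf_radial(n: int, taper_fraction: float, direction,
                      sector_half_angle_deg: float, pixel_size_nm: float,
                      max_radius_px=None) -> np.ndarray:
    """Radial profile of the taper window's own autocorrelation.

    The plain correlogram is the true autocovariance multiplied by this
    geometric factor, which decays with lag and drags peak positions down;
    dividing it out gives the unbiased estimate.
    """
    t = _taper_window(n, taper_fraction)
    w2 = np.outer(t, t)
    n_pad = 2 * n
    acf = np.fft.fftshift(np.fft.irfft2(
        np.abs(np.fft.rfft2(w2, s=(n_pad, n_pad))) ** 2, s=(n_pad, n_pad)))
    acf /= acf[n_pad // 2, n_pad // 2]
    prof = radial_profile(acf, direction, sector_half_angle_deg, pixel_size_nm,
                          max_radius_px=max_radius_px)
    return np.clip(prof.correlation, 0.05, None)


def _window_profile(win: np.ndarray, direction, sector_half_angle_deg, pixel_size_nm,
                    taper_fraction, max_radius_px=None,
                    noise_profile: np.ndarray | None = None) -> SpacingProfile | None:
    """Profile of a 2D window, or the slice-averaged profile of a 3D stack.

    Consecutive reconstruction slices through a fibre matrix share the same
    fibres, so averaging their correlation profiles suppresses acquisition
    noise without inflating the fibre sample.  ``noise_profile`` is the mean
    absolute autocovariance profile of control (blank) windows under the same
    imaging model: the noise autocovariance is a deterministic bias (it does
    not average out) and is subtracted before renormalisation.  Returns None
    for windows with no variance.
    """
    win = np.asarray(win, dtype=float)
    slices = win[None] if win.ndim == 2 else win
    profs, powers = [], []
    for sl in slices:
        try:
            acf = autocorrelation_map(sl, taper_fraction)
        except ValueError:
            continue  # constant slice
        profs.append(radial_profile(acf, direction, sector_half_angle_deg,
                                    pixel_size_nm, max_radius_px=max_radius_px))
        powers.append(np.var(sl))
    if not profs:
        return None
    corr = np.mean([p.correlation for p in profs], axis=0)
    geom = _taper_acf_radial(slices.shape[-1], taper_fraction, direction,
                             sector_half_angle_deg, pixel_size_nm,
                             max_radius_px=max_radius_px)
    corr = corr / geom[: len(corr)]
    power = float(np.mean(powers))
    if noise_profile is not None:
        absolute = corr * power
        k = min(len(absolute), len(noise_profile))
        absolute[:k] = absolute[:k] - noise_profile[:k]
        if absolute[0] <= 0:
            return None
        power = float(absolute[0])
        corr = absolute / absolute[0]
    return SpacingProfile(profs[0].radii_nm, corr, _second_differential(corr),
                          origin_power=power)


def mean_noise_profile(blank_windows: Sequence[np.ndarray],
                       direction=(0.0, 1.0), sector_half_angle_deg: float = 15.0,
                       pixel_size_nm: float = 1.0,
                       taper_fraction: float = 0.1) -> np.ndarray:
    """Mean absolute autocovariance profile of control windows.

    Estimates the deterministic noise autocovariance of the imaging model
    (e.g. the ringing of ramp-filtered reconstruction noise), which is then
    subtracted from tissue profiles before peak detection.
    """
    acc = None
    n = 0
    for win in blank_windows:
        prof = _window_profile(win, direction, sector_half_angle_deg,
                               pixel_size_nm, taper_fraction)
        if prof is None:
            continue
        contrib = prof.correlation * prof.origin_power
        acc = contrib if acc is None else acc + contrib
        n += 1
    if acc is None:
        raise ValueError("no usable blank windows")
    return acc / n


def calibrate_threshold(blank_windows: Sequence[np.ndarray],
                        direction: tuple[float, float] = (0.0, 1.0),
                        sector_half_angle_deg: float = 15.0,
                        pixel_size_nm: float = 1.0,
                        percentile: float = 95.0,
                        smooth_bins: int = 3,
                        taper_fraction: float = 0.1,
                        min_radius_nm: float = 0.0,
                        min_windows: int = 20,
                        noise_profile: np.ndarray | None = None) -> float:
    """Peak-acceptance threshold from control (blank resin) windows.

    Every blank window (a 2D window or a z-stack of the same window through
    consecutive slices) is run through the same autocorrelation and radial
    profiling as a glycocalyx window; the threshold is the given percentile
    of the per-window maximum curvature magnitude at candidate peaks, so at
    the default 95th percentile at most ~5% of blank windows can yield any
    accepted peak.  Constant (zero-noise) blanks contribute no candidates.
    """
    if len(blank_windows) < min_windows:
        raise ValueError(f"need at least {min_windows} blank windows, got {len(blank_windows)}")
    per_window_max = []
    for win in blank_windows:
        prof = _window_profile(win, direction, sector_half_angle_deg, pixel_size_nm,
                               taper_fraction, noise_profile=noise_profile)
        if prof is None:
            continue
        cand = _candidate_curvatures(prof, smooth_bins, min_radius_nm)
        if len(cand):
            per_window_max.append(cand.max())
    if not per_window_max:
        return 0.0
    return float(np.percentile(per_window_max, percentile))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _tile_blank_windows(vol: ImageVolume, blank_mask: np.ndarray, side_px: int,
                        max_windows: int = 200, slice_block: int = 1,
                        stride_px: int | None = None) -> list[np.ndarray]:
    """Windows fully inside the blank region, across slices.

    With ``slice_block`` > 1 each returned element is a (block, side, side)
    stack of the same in-plane window through consecutive slices, mirroring
    how tissue windows are block-averaged.  ``stride_px`` defaults to half a
    side (overlapping tiling) so a small control volume still yields enough
    windows for a stable threshold percentile.
    """
    nz, ny, nx = vol.shape
    stride = stride_px or max(side_px // 2, 1)
    out: list[np.ndarray] = []
    for iz in range(0, nz - slice_block + 1, slice_block):
        sl = blank_mask[iz:iz + slice_block]
        for oy in range(0, ny - side_px + 1, stride):
            for ox in range(0, nx - side_px + 1, stride):
                if sl[:, oy:oy + side_px, ox:ox + side_px].all():
                    block = np.asarray(
                        vol.data[iz:iz + slice_block, oy:oy + side_px, ox:ox + side_px],
                        dtype=float)
                    out.append(block[0] if slice_block == 1 else block)
                    if len(out) >= max_windows:
                        return out
    return out


def estimate_spacing(vol: ImageVolume, glycocalyx_mask: LabelVolume | np.ndarray,
                     blank_region: LabelVolume | np.ndarray | Sequence[np.ndarray] | None,
                     params: SpacingParams | None = None) -> SpacingResult:
    """Full spacing pipeline: calibrate, sample, correlate, profile, aggregate.

    ``blank_region`` is either a boolean mask of control (blank resin) voxels
    in ``vol``, a LabelVolume whose ``resin``/``lumen`` compartments serve as
    control, or an explicit sequence of blank 2D windows.  When it is None,
    ``params.threshold`` must be given.
    """
    params = params or SpacingParams()
    vz, vy, vx = vol.voxel_size
    side_px = max(int(round(params.roi_nm / vx)), 1)

    rois = sample_rois(vol, glycocalyx_mask, params.roi_nm, params.stride_nm,
                       params.min_mask_fraction)

    threshold = params.threshold
    noise_prof = None
    if threshold is None:
        if blank_region is None:
            raise ValueError("either a blank region or an explicit threshold is required")
        if isinstance(blank_region, LabelVolume):
            bmask = np.zeros(vol.shape, dtype=bool)
            for name in ("resin", "lumen"):
                try:
                    bmask |= blank_region.mask(name)
                except KeyError:
                    pass
        elif isinstance(blank_region, np.ndarray) and blank_region.shape == vol.shape:
            bmask = blank_region.astype(bool)
        else:
            bmask = None
        blanks = (_tile_blank_windows(vol, bmask, side_px,
                                      slice_block=params.slice_block)
                  if bmask is not None
                  else [np.asarray(b, dtype=float) for b in blank_region])
        direction = rois[0].direction if rois else (0.0, 1.0)
        noise_prof = mean_noise_profile(blanks, direction,
                                        params.sector_half_angle_deg, vx,
                                        params.taper_fraction)
        threshold = calibrate_threshold(
            blanks, direction, params.sector_half_angle_deg, vx,
            percentile=params.blank_percentile, smooth_bins=params.smooth_bins,
            taper_fraction=params.taper_fraction, min_radius_nm=params.min_radius_nm,
            noise_profile=noise_prof)

    # group the (window, slice) pairs of each origin into consecutive-slice
    # blocks; each block's profiles are averaged before peak detection
    max_r_px = int(params.max_radius_fraction * side_px)
    groups: dict = {}
    slices = set()
    for roi in rois:
        slices.add(roi.slice_index)
        key = (roi.origin_nm, roi.slice_index // max(params.slice_block, 1))
        groups.setdefault(key, []).append(roi)

    per_roi: list[np.ndarray] = []
    predominant: list[float] = []
    for key in sorted(groups):
        block_rois = groups[key]
        stack = np.stack([extract_window(vol, roi) for roi in block_rois])
        prof = _window_profile(stack, block_rois[0].direction,
                               params.sector_half_angle_deg, vx,
                               params.taper_fraction, max_radius_px=max_r_px,
                               noise_profile=noise_prof)
        if prof is None:
            per_roi.append(np.empty(0))
            continue
        peaks = detect_peaks(prof, threshold, params.smooth_bins, params.min_radius_nm)
        per_roi.append(peaks)
        if len(peaks):
            predominant.append(peaks[0])
    return SpacingResult(
        per_roi_peaks_nm=per_roi,
        predominant_nm=np.asarray(predominant),
        n_areas=len(rois),
        n_slices=len(slices),
        threshold=float(threshold),
    )
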