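"""Microbubble localization, tracking and super-resolved map rendering.

Localization uses the two-threshold scheme: an amplitude threshold on 3D
local maxima suppresses random noise and grating lobes, then a correlation
gate against a modelled Gaussian point-spread function rejects candidates
whose neighbourhood does not look like an isolated bubble echo (elongated
grating-lobe ringing in particular).  Survivors are refined to sub-voxel
positions by an intensity-weighted centroid, linked frame-to-frame by
optimal assignment with a distance gate, and rendered into density, speed
and axial-direction volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import maximum_filter, minimum_filter
from scipy.optimize import linear_sum_assignment

from .grids import ScalarVolume, VolumeGrid

__all__ = [
    "Localization",
    "MicrobubbleTrack",
    "ULMMaps",
    "robust_noise",
    "detect_candidates",
    "gaussian_psf_model",
    "psf_correlation_gate",
    "subvoxel_localize",
    "localize_volume",
    "link_tracks",
    "tracks_to_maps",
    "fwhm_to_sigma",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma from full width at half maximum."""
    return fwhm * FWHM_TO_SIGMA


@dataclass(frozen=True)
class Localization:
    position: tuple[float, float, float]  # mm, sub-voxel
    frame_index: int
    amplitude: float
    psf_correlation: float
    edge_clipped: bool = False

    def __post_init__(self) -> None:
        if self.psf_correlation > 1.0 + 1e-9:
            raise ValueError("correlation cannot exceed 1")


@dataclass
class MicrobubbleTrack:
    localizations: list[Localization]
    velocities: np.ndarray  # (n-1, 3) mm/s
    track_id: int
    block_index: int = 0

    def __post_init__(self) -> None:
        frames = [l.frame_index for l in self.localizations]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("frame indices must be strictly increasing")
        if len(self.velocities) != max(len(self.localizations) - 1, 0):
            raise ValueError("velocity count must be localization count - 1")

    def positions(self) -> np.ndarray:
        return np.asarray([l.position for l in self.localizations])

    def speeds(self) -> np.ndarray:
        return np.linalg.norm(self.velocities, axis=1) if len(self.velocities) else np.empty(0)

    def with_positions(self, new_positions: np.ndarray) -> "MicrobubbleTrack":
        """Copy with moved geometry; frame indices/ids/velocity magnitudes
        recomputed from the moved points are NOT touched (rigid moves only
        rotate velocities, handled by the caller when needed)."""
        locs = [
            replace(l, position=tuple(p)) for l, p in zip(self.localizations, new_positions)
        ]
        return MicrobubbleTrack(locs, self.velocities.copy(), self.track_id, self.block_index)


@dataclass
class ULMMaps:
    density: ScalarVolume  # visit counts
    speed: ScalarVolume  # mean |v| (mm/s) of traversing steps
    axial_direction: ScalarVolume  # sign of mean axial velocity, 0 where empty


def robust_noise(values: np.ndarray) -> float:
    """Robust noise scale: 1.4826 * median absolute deviation."""
    v = np.abs(np.asarray(values)).ravel()
    med = np.median(v)
    return float(1.4826 * np.median(np.abs(v - med)))


def detect_candidates(volume: ScalarVolume, amplitude_threshold: float) -> np.ndarray:
    """3D local maxima (26-connectivity) with amplitude >= threshold.

    Returns integer voxel indices (k, 3).  Flat plateaus (constant
    neighbourhoods) are not maxima.
    """
    if amplitude_threshold <= 0:
        raise ValueError("amplitude threshold must be positive")
    vals = np.abs(np.asarray(volume.values, dtype=float))
    mx = maximum_filter(vals, size=3, mode="constant", cval=-np.inf)
    mn = minimum_filter(vals, size=3, mode="constant", cval=np.inf)
    peaks = (vals >= mx) & (mx > mn) & (vals >= amplitude_threshold)
    return np.argwhere(peaks)


def gaussian_psf_model(sigma_vox: np.ndarray, half: np.ndarray) -> np.ndarray:
    """Sampled isotropic-axes Gaussian PSF on a (2*half+1)^3 window."""
    ax = [np.arange(-h, h + 1) for h in half]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    s = np.asarray(sigma_vox, dtype=float)
    return np.exp(-0.5 * ((xx / s[0]) ** 2 + (yy / s[1]) ** 2 + (zz / s[2]) ** 2))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    if den == 0:
        return 0.0
    return float(np.clip((a * b).sum() / den, -1.0, 1.0))


def psf_correlation_gate(
    candidates: np.ndarray,
    volume: ScalarVolume,
    psf_sigma_vox: np.ndarray,
    correlation_threshold: float = 0.6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered correlation between candidate neighbourhoods and a Gaussian PSF.

    The window spans twice the PSF FWHM per axis.  Returns
    ``(kept_indices, correlations, edge_clipped)`` for candidates at or
    above the threshold; windows clipped by the volume edge are evaluated
    on the valid intersection and flagged.
    """
    if not 0 <= correlation_threshold <= 1:
        raise ValueError("correlation threshold must be in [0, 1]")
    sigma = np.asarray(psf_sigma_vox, dtype=float)
    fwhm = sigma / FWHM_TO_SIGMA
    half = np.maximum(np.round(fwhm).astype(int), 1)
    model = gaussian_psf_model(sigma, half)
    vals = np.abs(np.asarray(volume.values, dtype=float))
    shape = np.asarray(vals.shape)
    kept, corrs, clipped = [], [], []
    for idx in np.atleast_2d(candidates):
        lo = idx - half
        hi = idx + half + 1
        lo_c = np.maximum(lo, 0)
        hi_c = np.minimum(hi, shape)
        win = vals[lo_c[0] : hi_c[0], lo_c[1] : hi_c[1], lo_c[2] : hi_c[2]]
        msel = model[
            lo_c[0] - lo[0] : model.shape[0] - (hi[0] - hi_c[0]),
            lo_c[1] - lo[1] : model.shape[1] - (hi[1] - hi_c[1]),
            lo_c[2] - lo[2] : model.shape[2] - (hi[2] - hi_c[2]),
        ]
        r = _pearson(win, msel)
        if r >= correlation_threshold:
            kept.append(idx)
            corrs.append(r)
            clipped.append(bool(np.any(lo < 0) or np.any(hi > shape)))
    return (
        np.asarray(kept).reshape(-1, 3),
        np.asarray(corrs),
        np.asarray(clipped, dtype=bool),
    )


def subvoxel_localize(
    neighbourhood: np.ndarray, method: str = "parabolic"
) -> tuple[np.ndarray, bool]:
    """Sub-voxel offset of a peak-centred neighbourhood.

    ``"parabolic"`` (default) fits a log-parabola through the three samples
    along each axis — exact for Gaussian peaks, immune to the PSF pedestal.
    ``"centroid"`` uses the background-subtracted intensity-weighted
    centroid.  Offsets are clamped to (-0.5, 0.5) voxel per axis; returns
    ``(offset, ok)`` with ``ok`` False for an all-zero (degenerate) window.
    """
    w = np.abs(np.asarray(neighbourhood, dtype=float))
    if w.sum() <= 0:
        return np.zeros(3), False
    # subtract the surrounding background level (median of the window
    # boundary) so nearby-scatterer glow does not drag the estimate
    edge = np.ones(w.shape, dtype=bool)
    if all(s > 2 for s in w.shape):
        edge[1:-1, 1:-1, 1:-1] = False
    bg = float(np.median(w[edge]))
    w = np.clip(w - bg, 0.0, None)
    if w.sum() <= 0:
        return np.zeros(3), False
    shape = np.asarray(w.shape)
    peak = np.asarray(np.unravel_index(int(np.argmax(w)), w.shape))
    off = np.zeros(3)
    if (
        method == "parabolic"
        and np.all(peak >= 1)
        and np.all(peak <= shape - 2)
    ):
        lw = np.log(np.maximum(w, 1e-6 * w.max()))
        for ax in range(3):
            sl = list(peak)
            sl[ax] = slice(peak[ax] - 1, peak[ax] + 2)
            a, b, c = lw[tuple(sl)]
            denom = a - 2 * b + c
            off[ax] = 0.5 * (a - c) / denom if denom < 0 else 0.0
        # clamp the refinement to half a voxel around the peak sample,
        # then report relative to the continuous window centre
        off = np.clip(off, -0.4999, 0.4999) + peak - (shape - 1) / 2
        return off, True
    w = w - w.min()
    total = w.sum()
    if total <= 0:
        return np.zeros(3), False
    idx = np.indices(w.shape).reshape(3, -1)
    centroid = (idx * w.ravel()).sum(axis=1) / total
    off = centroid - (np.asarray(w.shape) - 1) / 2
    return np.clip(off, -0.4999, 0.4999), True


def localize_volume(
    volume: ScalarVolume,
    frame_index: int,
    psf_sigma_vox: np.ndarray,
    amplitude_threshold: float | None = None,
    noise_multiple: float = 4.0,
    correlation_threshold: float = 0.6,
    centroid_half: int = 1,
    exclusion_fwhm: float = 2.0,
    rel_max_db: float | None = None,
) -> list[Localization]:
    """Full single-volume localization: detect, gate, sub-voxel refine.

    When ``amplitude_threshold`` is None it defaults to ``noise_multiple``
    times the volume's robust noise estimate (median absolute deviation);
    ``rel_max_db`` additionally floors the threshold at that many dB below
    the volume maximum, suppressing side- and grating-lobe ghosts of
    bright bubbles (the amplitude leg of the two-threshold scheme).
    ``exclusion_fwhm`` applies intensity-sorted non-maximum suppression:
    weaker candidates within that many PSF FWHMs (ellipsoidal metric) of a
    brighter one are discarded; set 0 to disable.
    """
    vals = np.abs(np.asarray(volume.values, dtype=float))
    if amplitude_threshold is None:
        amplitude_threshold = noise_multiple * max(robust_noise(vals), 1e-30)
        if rel_max_db is not None and vals.size:
            amplitude_threshold = max(
                amplitude_threshold, float(vals.max()) * 10 ** (rel_max_db / 20)
            )
    cands = detect_candidates(volume, amplitude_threshold)
    if cands.size == 0:
        return []
    if exclusion_fwhm > 0 and len(cands) > 1:
        fwhm = np.asarray(psf_sigma_vox) / FWHM_TO_SIGMA
        scale = exclusion_fwhm * fwhm
        amps = vals[tuple(cands.T)]
        order = np.argsort(amps)[::-1]
        kept_idx: list[int] = []
        for i in order:
            ok = True
            for j in kept_idx:
                if np.sum(((cands[i] - cands[j]) / scale) ** 2) <= 1.0:
                    ok = False
                    break
            if ok:
                kept_idx.append(i)
        cands = cands[sorted(kept_idx)]
    kept, corrs, clipped = psf_correlation_gate(
        cands, volume, psf_sigma_vox, correlation_threshold
    )
    out: list[Localization] = []
    shape = np.asarray(vals.shape)
    # the refinement window spans the PSF so its boundary samples the
    # local background rather than the peak's own shoulder
    half = np.maximum(
        centroid_half,
        np.ceil(np.asarray(psf_sigma_vox) / FWHM_TO_SIGMA).astype(int) + 1,
    )
    for idx, r, cl in zip(kept, corrs, clipped):
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, shape)
        win = vals[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        off, ok = subvoxel_localize(win)
        # centroid offset is relative to the (possibly clipped) window centre
        centre = (lo + hi - 1) / 2.0 + off if ok else idx.astype(float)
        pos = volume.grid.index_to_world(centre)[0]
        out.append(
            Localization(tuple(pos), frame_index, float(vals[tuple(idx)]), float(r), bool(cl))
        )
    return out


def _smooth_positions(pos: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average along a track (shrinking window at the ends)."""
    if window <= 1 or len(pos) < 3:
        return pos
    half = window // 2
    out = np.empty_like(pos)
    for i in range(len(pos)):
        a, b = max(0, i - half), min(len(pos), i + half + 1)
        out[i] = pos[a:b].mean(axis=0)
    return out


def link_tracks(
    localizations_per_frame: list[list[Localization]],
    max_link_distance: float,
    frame_times: np.ndarray,
    max_gap_frames: int = 0,
    min_track_length: int = 3,
    block_index: int = 0,
    smooth_window: int = 5,
    velocity_lag: int = 2,
) -> list[MicrobubbleTrack]:
    """Link per-frame localizations into tracks by optimal assignment.

    Frame-to-frame pairing minimizes total squared displacement
    (Hungarian assignment) under a hard distance gate; tracks missing more
    than ``max_gap_frames`` consecutive frames are closed, and tracks
    shorter than ``min_track_length`` localizations are discarded.

    Track positions are smoothed with a centred ``smooth_window``-point
    moving average and per-step velocities are central differences over up
    to ``velocity_lag`` steps on the smoothed track — both standard ULM
    jitter suppression (set ``smooth_window=1, velocity_lag=1`` for raw
    step displacements over elapsed frame time).
    """
    if max_link_distance <= 0:
        raise ValueError("max link distance must be positive")
    frame_times = np.asarray(frame_times, dtype=float)
    BIG = 1e12
    active: list[dict] = []
    finished: list[dict] = []
    for f, locs in enumerate(localizations_per_frame):
        det = np.asarray([l.position for l in locs]).reshape(-1, 3)
        matched_det = set()
        if active and len(locs):
            last = np.asarray([a["locs"][-1].position for a in active])
            d2 = ((last[:, None, :] - det[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= max_link_distance**2, d2, BIG)
            rows, cols = linear_sum_assignment(cost)
            for r_i, c_i in zip(rows, cols):
                if cost[r_i, c_i] < BIG:
                    active[r_i]["locs"].append(locs[c_i])
                    matched_det.add(c_i)
        # close stale tracks
        still = []
        for a in active:
            if f - a["locs"][-1].frame_index > max_gap_frames:
                finished.append(a)
            else:
                still.append(a)
        active = still
        for c_i, loc in enumerate(locs):
            if c_i not in matched_det:
                active.append({"locs": [loc]})
    finished.extend(active)

    tracks: list[MicrobubbleTrack] = []
    tid = 0
    for a in finished:
        locs = a["locs"]
        if len(locs) < min_track_length:
            continue
        raw = np.asarray([l.position for l in locs])
        tt = frame_times[[l.frame_index for l in locs]]
        pos = _smooth_positions(raw, smooth_window)
        locs = [replace(l, position=tuple(p)) for l, p in zip(locs, pos)]
        n = len(raw)
        vel = np.empty((n - 1, 3))
        for i in range(n - 1):
            # local linear regression on raw positions: unbiased for
            # uniform motion even at track ends
            a_i = max(0, i - velocity_lag + 1)
            b_i = min(n, i + velocity_lag + 1)
            tw = tt[a_i:b_i] - tt[a_i:b_i].mean()
            denom = float((tw**2).sum())
            if denom > 0:
                vel[i] = (raw[a_i:b_i] * tw[:, None]).sum(axis=0) / denom
            else:
                vel[i] = (raw[i + 1] - raw[i]) / (tt[i + 1] - tt[i])
        tracks.append(MicrobubbleTrack(locs, vel, tid, block_index))
        tid += 1
    return tracks


def tracks_to_maps(tracks: list[MicrobubbleTrack], grid: VolumeGrid) -> ULMMaps:
    """Render tracks into density / mean-speed / axial-direction volumes.

    Track polylines are resampled at steps of half the smallest voxel side;
    each resampled point deposits one density count and its step's speed
    and axial velocity into the voxel it falls in.
    """
    density = np.zeros(grid.shape)
    speed_sum = np.zeros(grid.shape)
    vz_sum = np.zeros(grid.shape)
    step_max = min(grid.spacing) / 2.0
    for tr in tracks:
        pos = tr.positions()
        if len(pos) < 2:
            continue
        for i in range(len(pos) - 1):
            seg = pos[i + 1] - pos[i]
            seg_len = np.linalg.norm(seg)
            n = max(int(np.ceil(seg_len / step_max)), 1)
            # include the segment start; the final track point closes the last segment
            pts = pos[i] + np.outer(np.arange(n) / n, seg)
            if i == len(pos) - 2:
                pts = np.vstack([pts, pos[i + 1]])
            v = tr.velocities[i]
            sp = np.linalg.norm(v)
            idx = np.round(grid.world_to_index(pts)).astype(int)
            ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
            for ix in idx[ok]:
                t = tuple(ix)
                density[t] += 1
                speed_sum[t] += sp
                vz_sum[t] += v[2]
    with np.errstate(invalid="ignore", divide="ignore"):
        speed = np.where(density > 0, speed_sum / np.maximum(density, 1), 0.0)
    direction = np.sign(np.where(density > 0, vz_sum, 0.0))
    return ULMMaps(
        ScalarVolume(grid, density, "counts"),
        ScalarVolume(grid, speed, "mm/s"),
        ScalarVolume(grid, direction, "sign"),
    )
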