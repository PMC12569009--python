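"""3D diverging-wave delay-and-sum beamforming, clutter filtering, power Doppler.

Per voxel, receive channels are summed coherently over all transmits of one
volume with the two-way delay (|source - voxel| + |voxel - element|)/c plus
the lens apex delay on both paths; RF is converted to its analytic signal
and band-limited-upsampled first, so linear interpolation between samples is
accurate, and the envelope is taken after compounding (standard synthetic
aperture practice).  No receive apodization is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


from .arrays import ArrayLayout, lens_apex_delay, lens_virtual_source
from .fields import MM_PER_S
from .grids import ScalarVolume, VolumeGrid
from .phantoms import RFBlock

__all__ = ["BeamformedSeries", "das_beamform", "svd_clutter_filter", "power_doppler"]


@dataclass
class BeamformedSeries:
    """Complex beamformed volumes per frame on a shared grid."""

    grid: VolumeGrid
    volumes: np.ndarray  # (n_frames, nx, ny, nz) complex
    frame_times: np.ndarray  # (n_frames,) s
    out_of_record: int = 0  # delay requests beyond the RF record

    def __post_init__(self) -> None:
        if self.volumes.shape[1:] != tuple(self.grid.shape):
            raise ValueError("volume shape does not match grid")
        if len(self.frame_times) != self.volumes.shape[0]:
            raise ValueError("frame_times length mismatch")
        if len(self.frame_times) > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be increasing")

    @property
    def n_frames(self) -> int:
        return self.volumes.shape[0]

    def envelope(self, frame: int) -> ScalarVolume:
        return ScalarVolume(self.grid, np.abs(self.volumes[frame]), "a.u.")


@njit(cache=True, fastmath=True)
def _das_kernel(rf, dist, tx_src, fs, t0, inv_c, apex, out):  # pragma: no cover
    nt, ne, ntx = rf.shape
    m = dist.shape[0]
    missed = 0
    for i in range(m):
        acc = complex(0.0, 0.0)
        for k in range(ntx):
            s = tx_src[k]
            ttx = dist[i, s] * inv_c + apex
            for e in range(ne):
                tau = ttx + dist[i, e] * inv_c + apex
                x = (tau - t0) * fs
                j = int(x)
                if 0 <= j < nt - 1:
                    f = x - j
                    acc += rf[j, e, k] * (1.0 - f) + rf[j + 1, e, k] * f
                else:
                    missed += 1
        out[i] += acc
    return missed


def _analytic_upsample(rf: np.ndarray, upsample: int) -> np.ndarray:
    """Analytic signal of the RF record, band-limited-upsampled along axis 0.

    Complex input is taken as already-analytic (bandpass/IQ) data; real
    input is converted by one-sided spectral masking first.
    """
    nt = rf.shape[0]
    spec = np.fft.fft(rf, axis=0)
    if not np.iscomplexobj(rf):
        h = np.zeros(nt)
        h[0] = 1.0
        if nt % 2 == 0:
            h[nt // 2] = 1.0
            h[1 : nt // 2] = 2.0
        else:
            h[1 : (nt + 1) // 2] = 2.0
        spec *= h.reshape((-1,) + (1,) * (rf.ndim - 1))
    if upsample > 1:
        up = np.zeros((nt * upsample,) + rf.shape[1:], dtype=spec.dtype)
        up[:nt] = spec  # analytic spectrum is one-sided; pad above it
        spec = up
    return (np.fft.ifft(spec, axis=0) * upsample).astype(np.complex64)


def das_beamform(
    block: RFBlock,
    layout: ArrayLayout,
    grid: VolumeGrid,
    c: float = 1540.0,
    upsample: int = 4,
    frames: np.ndarray | None = None,
    lens_model: str = "virtual_source",
    event_chunk: int = 32,
) -> BeamformedSeries:
    """Delay-and-sum beamform one RF block onto ``grid``.

    Returns complex (pre-envelope) volumes, one per acquired volume frame.
    Delays falling beyond the record end contribute zero and are counted in
    ``out_of_record``.  Lens handling (``lens_model``): ``"virtual_source"``
    treats each lensed element as a point source behind its face (keeps the
    full aperture coherent); ``"apex"`` applies only the constant apex
    delay per element.
    """
    if c <= 0:
        raise ValueError("speed of sound must be positive")
    c_mm = c * MM_PER_S
    centers = layout.element_centers.copy()
    if layout.lens is not None:
        if lens_model == "virtual_source":
            f_virt, offset = lens_virtual_source(layout.lens, layout.element_spec)
            centers[:, 2] -= f_virt
        elif lens_model == "apex":
            offset = lens_apex_delay(layout.lens)
        else:
            raise ValueError(f"unknown lens model {lens_model!r}")
    else:
        offset = 0.0
    vox = grid.voxel_centers().astype(np.float64)
    dist = np.sqrt(
        ((vox[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    ).astype(np.float32)
    n_tx = block.n_transmits_per_volume
    frame_list = np.arange(block.n_volumes) if frames is None else np.asarray(frames)
    fs_up = block.fs * upsample
    out_frames = np.zeros((len(frame_list),) + tuple(grid.shape), dtype=np.complex64)
    missed_total = 0
    for oi, f in enumerate(frame_list):
        acc = np.zeros(vox.shape[0], dtype=np.complex64)
        for e0 in range(f * n_tx, (f + 1) * n_tx, event_chunk):
            ev = slice(e0, min(e0 + event_chunk, (f + 1) * n_tx))
            chunk = block.samples[:, :, ev]
            chunk = chunk.astype(
                np.complex64 if np.iscomplexobj(chunk) else np.float32
            )
            analytic = np.ascontiguousarray(_analytic_upsample(chunk, upsample))
            missed = _das_kernel(
                analytic,
                dist,
                np.ascontiguousarray(block.transmit_sources[ev].astype(np.int64)),
                np.float64(fs_up),
                np.float64(block.t0),
                np.float64(1.0 / c_mm),
                np.float64(offset),
                acc,
            )
            missed_total += int(missed)
        out_frames[oi] = acc.reshape(grid.shape)
    return BeamformedSeries(
        grid, out_frames, block.frame_times[frame_list], missed_total
    )


def svd_clutter_filter(
    series: BeamformedSeries, low_rank_cut: int, high_rank_cut: int | None = None
) -> BeamformedSeries:
    """Spatiotemporal SVD filter: zero singular components outside
    [low_rank_cut, high_rank_cut).

    The series is cast as a (space x time) Casorati matrix; cutting the
    first components removes stationary/slowly-varying clutter, cutting the
    last removes noise-dominated ones.
    """
    n = series.n_frames
    if high_rank_cut is None:
        high_rank_cut = n
    if not 0 <= low_rank_cut < high_rank_cut <= n:
        raise ValueError("rank cuts out of range")
    X = series.volumes.reshape(n, -1).T  # space x time
    U, s, Vh = np.linalg.svd(X, full_matrices=False)
    s_f = s.copy()
    s_f[:low_rank_cut] = 0.0
    s_f[high_rank_cut:] = 0.0
    Xf = (U * s_f) @ Vh
    vols = np.ascontiguousarray(Xf.T).reshape(series.volumes.shape)
    return BeamformedSeries(series.grid, vols.astype(series.volumes.dtype), series.frame_times, series.out_of_record)


def power_doppler(series: BeamformedSeries) -> ScalarVolume:
    """Per-voxel sum of squared envelope over frames."""
    if series.n_frames < 1:
        raise ValueError("need at least one frame")
    pd = np.sum(np.abs(series.volumes) ** 2, axis=0)
    return ScalarVolume(series.grid, pd, "a.u.")
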