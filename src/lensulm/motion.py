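"""Rigid motion correction driven by power Doppler volumes.

Inter-block motion (breathing drift, probe slip) is estimated by maximizing
the normalized cross-correlation between each block's power Doppler volume
and a reference block (the one with the most tracked microbubbles), using a
coarse-to-fine pyramid and derivative-free local optimization.  The
recovered 6-dof transform is then applied to that block's microbubble track
points — geometry only, never track topology.  An intra-block variant splits
a block into three temporal sub-blocks and registers their power Doppler
volumes to the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, zoom
from scipy.optimize import minimize

from .grids import ScalarVolume, VolumeGrid

__all__ = [
    "RigidTransform",
    "BlockRegistrationResult",
    "select_reference_block",
    "register_rigid",
    "apply_to_points",
    "interblock_correct",
    "intrablock_correct",
    "split_subblocks",
]


def _euler_zyx(angles: np.ndarray) -> np.ndarray:
    """Rotation matrix from intrinsic z-y-x Euler angles (rad)."""
    az, ay, ax = angles
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return rz @ ry @ rx


@dataclass(frozen=True)
class RigidTransform:
    """6-dof rigid transform: p -> R (p - center) + center + translation.

    ``rotation`` holds intrinsic z-y-x Euler angles in radians; lengths mm.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def rotation_matrix(self) -> np.ndarray:
        return _euler_zyx(np.asarray(self.rotation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.center)
        return (pts - c) @ self.rotation_matrix().T + c + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        R = self.rotation_matrix().T
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        # inverse as a matrix+offset pair re-expressed about the same center
        az = np.arctan2(R[1, 0], R[0, 0])
        ay = np.arcsin(np.clip(-R[2, 0], -1, 1))
        ax = np.arctan2(R[2, 1], R[2, 2])
        new_t = -R @ t
        return RigidTransform((az, ay, ax), tuple(new_t), tuple(c))

    @staticmethod
    def identity(center: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> "RigidTransform":
        return RigidTransform(center=center)


def apply_to_points(transform: RigidTransform, points: np.ndarray) -> np.ndarray:
    """R (p - center) + center + t for each point."""
    return transform.apply(points)


@dataclass
class BlockRegistrationResult:
    transform: RigidTransform
    similarity: float  # normalized correlation at the optimum, in [-1, 1]
    converged: bool
    block_index: int = -1


def select_reference_block(blocks: list[tuple[object, int]]) -> int:
    """Index of the block with the most tracked microbubbles (ties -> lowest index)."""
    if not blocks:
        raise ValueError("no blocks given")
    counts = [int(c) for _, c in blocks]
    return int(np.argmax(counts))


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _resample(
    values: np.ndarray,
    grid_spacing: np.ndarray,
    transform: RigidTransform,
    origin: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``values`` at transformed voxel positions (trilinear).

    Returns the resampled array and the mask of voxels whose source
    position fell inside the volume (similarity is computed on the valid
    overlap only).
    """
    shape = values.shape
    idx = np.indices(shape).reshape(3, -1).T
    world = origin + idx * grid_spacing
    moved = transform.apply(world)
    coords = ((moved - origin) / grid_spacing).T
    out = map_coordinates(values, coords, order=1, mode="constant", cval=0.0).reshape(shape)
    valid = np.all(
        (coords >= 0) & (coords <= (np.asarray(shape) - 1)[:, None]), axis=0
    ).reshape(shape)
    return out, valid


def register_rigid(
    moving: ScalarVolume,
    reference: ScalarVolume,
    multiresolution_levels: int = 3,
    max_iter: int = 120,
) -> BlockRegistrationResult:
    """Estimate the rigid transform aligning ``moving`` onto ``reference``.

    Maximizes normalized cross-correlation under trilinear resampling with
    a Gaussian-pyramid coarse-to-fine search (Powell's method per level).
    The rotation center is the reference volume's intensity centroid.
    """
    if moving.grid != reference.grid:
        raise ValueError("volumes must share a grid")
    ref_vals = np.asarray(reference.values, dtype=float)
    mov_vals = np.asarray(moving.values, dtype=float)
    if not (np.all(np.isfinite(ref_vals)) and np.all(np.isfinite(mov_vals))):
        raise ValueError("volumes contain non-finite voxels")
    spacing = np.asarray(reference.grid.spacing)
    origin = np.asarray(reference.grid.origin)
    total = ref_vals.sum()
    if total > 0:
        idx = np.indices(ref_vals.shape).reshape(3, -1)
        centroid = origin + (idx * ref_vals.ravel()).sum(axis=1) / total * spacing
    else:
        centroid = origin + (np.asarray(ref_vals.shape) - 1) / 2 * spacing

    # candidate starts: identity, and phase-correlation translation
    from skimage.registration import phase_cross_correlation

    starts = [np.zeros(6)]
    try:
        shift, _, _ = phase_cross_correlation(ref_vals, mov_vals, normalization=None)
        pcc = np.zeros(6)
        pcc[3:] = -np.asarray(shift) * spacing
        starts.append(pcc)
    except (ValueError, ZeroDivisionError):
        pass
    params = None
    converged = True
    for level in range(multiresolution_levels - 1, -1, -1):
        factor = 2**level
        if factor > 1:
            ref_l = zoom(ref_vals, 1 / factor, order=1)
            mov_l = zoom(mov_vals, 1 / factor, order=1)
            sp_l = spacing * np.asarray(ref_vals.shape) / np.asarray(ref_l.shape)
        else:
            ref_l, mov_l, sp_l = ref_vals, mov_vals, spacing
        if min(ref_l.shape) < 4:
            continue

        def cost(p: np.ndarray) -> float:
            tr = RigidTransform(tuple(p[:3]), tuple(p[3:]), tuple(centroid))
            res, valid = _resample(mov_l, sp_l, tr, origin)
            if valid.mean() < 0.25:  # degenerate overlap
                return 1.0
            return -_ncc(res[valid], ref_l[valid])

        # search directions scaled to the problem: ~1 voxel steps in
        # translation, ~2 degree steps in rotation
        direc = np.diag([0.03, 0.03, 0.03, sp_l[0], sp_l[1], sp_l[2]])
        inits = [params] if params is not None else starts
        best_cost = np.inf
        for p0 in inits:
            res = minimize(
                cost,
                p0,
                method="Powell",
                options={"maxiter": max_iter, "xtol": 1e-5, "ftol": 1e-9, "direc": direc},
            )
            if res.fun < best_cost:
                best_cost = res.fun
                params = res.x
                converged = converged and bool(res.success)
    best = RigidTransform(tuple(params[:3]), tuple(params[3:]), tuple(centroid))
    res, valid = _resample(mov_vals, spacing, best, origin)
    sim = _ncc(res[valid], ref_vals[valid]) if valid.any() else 0.0
    return BlockRegistrationResult(best, sim, converged)


def interblock_correct(
    power_dopplers: list[ScalarVolume],
    tracks_per_block: list[list],
    reference_index: int | None = None,
    levels: int = 3,
) -> tuple[list[list], list[BlockRegistrationResult]]:
    """Register every block's power Doppler to the reference block and move
    that block's track points accordingly.

    ``tracks_per_block[k]`` is a list of :class:`~lensulm.ulm.MicrobubbleTrack`;
    corrected copies are returned (track counts and frame indices untouched).
    The registration maps reference-space positions onto each moving block,
    so its inverse is what carries block-k points back to reference space.
    """
    if len(power_dopplers) < 2:
        raise ValueError("need at least two blocks")
    if reference_index is None:
        reference_index = select_reference_block(
            [(pd, sum(len(t.localizations) for t in trk)) for pd, trk in zip(power_dopplers, tracks_per_block)]
        )
    results: list[BlockRegistrationResult] = []
    corrected: list[list] = []
    ref = power_dopplers[reference_index]
    for k, (pd, tracks) in enumerate(zip(power_dopplers, tracks_per_block)):
        if k == reference_index:
            tr = RigidTransform.identity()
            results.append(BlockRegistrationResult(tr, 1.0, True, k))
            corrected.append([t for t in tracks])
            continue
        reg = register_rigid(pd, ref, levels)
        reg.block_index = k
        results.append(reg)
        inv = reg.transform.inverse()
        moved = []
        for t in tracks:
            moved.append(t.with_positions(inv.apply(t.positions())))
        corrected.append(moved)
    return corrected, results


def split_subblocks(n_frames: int, n_sub: int = 3) -> list[tuple[int, int]]:
    """Contiguous equal frame segments; the remainder goes to the last one."""
    if n_frames < n_sub:
        raise ValueError(f"need at least {n_sub} frames")
    base = n_frames // n_sub
    bounds = []
    start = 0
    for i in range(n_sub):
        end = start + base if i < n_sub - 1 else n_frames
        bounds.append((start, end))
        start = end
    return bounds


def intrablock_correct(
    envelope_frames: np.ndarray,
    grid: VolumeGrid,
    localizations_per_frame: list[np.ndarray],
    n_sub: int = 3,
    levels: int = 2,
) -> tuple[list[np.ndarray], list[BlockRegistrationResult]]:
    """Correct motion inside one block via three temporal sub-blocks.

    ``envelope_frames`` is (n_frames, nx, ny, nz); per-sub-block power
    Doppler volumes are registered to the first sub-block and each
    sub-block's localization positions are moved by the inverse transform.
    """
    n_frames = envelope_frames.shape[0]
    bounds = split_subblocks(n_frames, n_sub)
    pds = []
    for a, b in bounds:
        pd = np.sum(np.abs(envelope_frames[a:b]) ** 2, axis=0)
        pds.append(ScalarVolume(grid, pd, "a.u."))
    results = [BlockRegistrationResult(RigidTransform.identity(), 1.0, True, 0)]
    corrected = [p.copy() for p in localizations_per_frame]
    for si in range(1, n_sub):
        reg = register_rigid(pds[si], pds[0], levels)
        reg.block_index = si
        results.append(reg)
        inv = reg.transform.inverse()
        a, b = bounds[si]
        for f in range(a, b):
            if corrected[f].size:
                corrected[f] = inv.apply(corrected[f])
    return corrected, results
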