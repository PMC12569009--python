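"""Synthetic phantoms, microbubble kinematics and raw RF generation.

This module is the package's stand-in for experimental acquisitions: an
870 um Poiseuille tube (75-200 mL/h), Murray-law branching trees with radii
in the tens-to-hundreds of microns, microbubble advection along streamlines,
single-element diverging-wave transmissions at 5 kHz PRF in 256-volume
blocks, inter-block rigid motion, and ECG/respiratory gating traces.

Microbubbles are ideal linear point scatterers: each contributes a delayed,
directivity- and spreading-weighted replica of the transmit pulse on every
receive channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arrays import ArrayLayout, SequenceSpec, lens_apex_delay
from .fields import MM_PER_S, ElementPattern, element_pattern, hann_pulse
from .motion import RigidTransform

__all__ = [
    "Polyline",
    "FlowPhantom",
    "VesselTree",
    "MBPopulation",
    "PhysioTrace",
    "RFBlock",
    "flow_mlh_to_mm3s",
    "poiseuille_vmax",
    "make_tube_phantom",
    "make_vessel_tree",
    "advect_microbubbles",
    "block_frame_times",
    "simulate_rf",
    "apply_rigid_motion",
    "generate_physio",
]


def flow_mlh_to_mm3s(q_mlh: float) -> float:
    """mL/h -> mm^3/s."""
    return q_mlh * 1000.0 / 3600.0


def poiseuille_vmax(q_mlh: float, radius_mm: float) -> float:
    """Centerline speed (mm/s) of Poiseuille flow: v_max = 2 Q / (pi R^2)."""
    return 2.0 * flow_mlh_to_mm3s(q_mlh) / (np.pi * radius_mm**2)


class Polyline:
    """Arc-length parameterized 3D polyline with parallel-transported frames."""

    def __init__(self, points: np.ndarray):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[0] < 2:
            raise ValueError("polyline needs at least two points")
        self.points = pts
        seg = np.diff(pts, axis=0)
        self._seg_len = np.linalg.norm(seg, axis=1)
        if np.any(self._seg_len <= 0):
            raise ValueError("degenerate polyline segment")
        self._cum = np.concatenate([[0.0], np.cumsum(self._seg_len)])
        self._tangents = seg / self._seg_len[:, None]
        # parallel transport an initial normal along the segments
        t0 = self._tangents[0]
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, t0)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        n = ref - np.dot(ref, t0) * t0
        n /= np.linalg.norm(n)
        normals = [n]
        for i in range(1, len(self._tangents)):
            t_prev, t_cur = self._tangents[i - 1], self._tangents[i]
            v = normals[-1]
            axis = np.cross(t_prev, t_cur)
            s = np.linalg.norm(axis)
            if s > 1e-12:
                axis = axis / s
                ang = np.arctan2(s, np.clip(np.dot(t_prev, t_cur), -1, 1))
                v = (
                    v * np.cos(ang)
                    + np.cross(axis, v) * np.sin(ang)
                    + axis * np.dot(axis, v) * (1 - np.cos(ang))
                )
                v = v - np.dot(v, t_cur) * t_cur
                v /= np.linalg.norm(v)
            normals.append(v)
        self._normals = np.asarray(normals)

    @property
    def length(self) -> float:
        return float(self._cum[-1])

    def frame_at(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Position, tangent and two transverse unit vectors at arc length s."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        i = np.clip(np.searchsorted(self._cum, s, side="right") - 1, 0, len(self._seg_len) - 1)
        f = (s - self._cum[i]) / self._seg_len[i]
        pos = self.points[i] + f[:, None] * (self.points[i + 1] - self.points[i])
        t = self._tangents[i]
        n1 = self._normals[i]
        n2 = np.cross(t, n1)
        return pos, t, n1, n2


@dataclass
class FlowPhantom:
    """Tube(s) carrying Poiseuille flow.

    ``segments`` is a list of (Polyline, radius mm); every segment carries
    ``flow_rate`` mL/h (parallel inlets, no junctions).
    """

    segments: list[tuple[Polyline, float]]
    flow_rate: float  # mL/h per inlet

    def __post_init__(self) -> None:
        if self.flow_rate < 0:
            raise ValueError("flow rate must be >= 0")
        for _, r in self.segments:
            if r <= 0:
                raise ValueError("tube radius must be positive")

    def vmax(self, segment: int = 0) -> float:
        return poiseuille_vmax(self.flow_rate, self.segments[segment][1])


def make_tube_phantom(
    diameter: float = 0.87,
    flow_rate: float = 75.0,
    geometry: str = "straight",
    depth: float = 60.0,
    length: float = 40.0,
) -> FlowPhantom:
    """Flow phantom mimicking the in-vitro tube set-up.

    ``straight``: one horizontal tube along x at ``depth`` mm.  ``twisted``:
    two intertwined inclined tubes descending from 42 to 80 mm depth.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    radius = diameter / 2
    if geometry == "straight":
        xs = np.linspace(-length / 2, length / 2, 65)
        pts = np.column_stack([xs, np.zeros_like(xs), np.full_like(xs, depth)])
        return FlowPhantom([(Polyline(pts), radius)], flow_rate)
    if geometry == "twisted":
        xs = np.linspace(-length / 2, length / 2, 129)
        zs = np.linspace(42.0, 80.0, xs.size)
        phase = 2 * np.pi * (xs - xs[0]) / 18.0
        segs = []
        for off in (0.0, np.pi):
            y = 2.0 * np.cos(phase + off)
            dz = 2.0 * np.sin(phase + off)
            pts = np.column_stack([xs, y, zs + dz])
            segs.append((Polyline(pts), radius))
        return FlowPhantom(segs, flow_rate)
    raise ValueError(f"unknown geometry {geometry!r}")


@dataclass
class VesselTree:
    """Binary branching tree obeying a radius power law at bifurcations:
    r_parent^x = r_child1^x + r_child2^x, flow split proportional to r^x."""

    nodes: np.ndarray  # (n, 3) mm
    edges: list[tuple[int, int, float, float]]  # (parent, child, radius mm, flow mL/h)
    branching_exponent: float

    def segment_radii_flows(self) -> tuple[np.ndarray, np.ndarray]:
        r = np.array([e[2] for e in self.edges])
        q = np.array([e[3] for e in self.edges])
        return r, q

    def children_of(self, node: int) -> list[int]:
        return [i for i, e in enumerate(self.edges) if e[0] == node]


def make_vessel_tree(
    generations: int,
    root_radius: float = 0.6,
    branching_exponent: float = 3.0,
    seed: int = 0,
    root_flow: float = 30.0,
    length_per_radius: float = 12.0,
    root_position: np.ndarray | None = None,
) -> VesselTree:
    """Synthetic Murray-law tree (ground truth for branching-exponent fits).

    Child radii are drawn with an asymmetry fraction a ~ U(0.35, 0.65) and
    set to r_parent * a^(1/x) and r_parent * (1-a)^(1/x), which satisfies
    the power-law identity exactly; flows split in the same proportions.
    Segment length is ``length_per_radius`` times the segment radius.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if branching_exponent <= 0:
        raise ValueError("branching exponent must be positive")
    rng = np.random.default_rng(seed)
    x = branching_exponent
    start = np.array([0.0, 0.0, 40.0]) if root_position is None else np.asarray(root_position, float)
    nodes = [start]
    edges: list[tuple[int, int, float, float]] = []

    def grow(parent_idx: int, direction: np.ndarray, radius: float, flow: float, gen: int) -> None:
        end = nodes[parent_idx] + direction * length_per_radius * radius
        nodes.append(end)
        child_idx = len(nodes) - 1
        edges.append((parent_idx, child_idx, radius, flow))
        if gen >= generations:
            return
        a = rng.uniform(0.35, 0.65)
        r1, r2 = radius * a ** (1 / x), radius * (1 - a) ** (1 / x)
        q1, q2 = flow * a, flow * (1 - a)
        # split in a random plane containing the parent direction
        ref = rng.normal(size=3)
        n = np.cross(direction, ref)
        n /= np.linalg.norm(n) + 1e-30
        for r_c, q_c, sign in ((r1, q1, 1.0), (r2, q2, -1.0)):
            ang = np.deg2rad(rng.uniform(20.0, 45.0)) * sign
            d = direction * np.cos(ang) + np.cross(n, direction) * np.sin(ang)
            d /= np.linalg.norm(d)
            grow(child_idx, d, r_c, q_c, gen + 1)

    grow(0, np.array([0.0, 0.0, 1.0]), root_radius, root_flow, 1)
    return VesselTree(np.asarray(nodes), edges, x)


@dataclass
class MBPopulation:
    """Per-frame microbubble positions with identities and ground truth.

    Flat records: entry k is bubble ``ids[k]`` at ``positions[k]`` during
    frame ``frame_indices[k]``; ``velocities`` is the ground-truth advection
    velocity (mm/s) at that instant.
    """

    frame_times: np.ndarray  # (n_frames,) s
    frame_indices: np.ndarray  # (k,) int
    ids: np.ndarray  # (k,) int
    positions: np.ndarray  # (k, 3) mm
    velocities: np.ndarray  # (k, 3) mm/s
    echogenicity: dict[int, float] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    def at_frame(self, f: int) -> tuple[np.ndarray, np.ndarray]:
        m = self.frame_indices == f
        return self.ids[m], self.positions[m]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.positions.min(axis=0), self.positions.max(axis=0)


def _flux_weighted_radius_fraction(rng: np.random.Generator) -> float:
    """Fractional radius of an arriving bubble, weighted by local flux.

    With a parabolic profile the flux through an annulus is proportional to
    (1 - u) du for u = (rho/R)^2, giving u = 1 - sqrt(1 - U) by inversion;
    no bubbles arrive exactly at the no-slip wall.
    """
    return float(np.sqrt(1.0 - np.sqrt(1.0 - rng.uniform())))


def _advect_tube(
    phantom: FlowPhantom, concentration: float, frame_times: np.ndarray, rng: np.random.Generator
) -> MBPopulation:
    recs_f, recs_id, recs_p, recs_v = [], [], [], []
    echo: dict[int, float] = {}
    next_id = 0
    per_seg = concentration / max(len(phantom.segments), 1)
    # live bubbles per segment: (id, s0, t0, rho, phi, speed)
    live: list[list] = [[] for _ in phantom.segments]
    t_start = float(frame_times[0]) if len(frame_times) else 0.0
    # steady-state seeding: the expected in-tube count is the arrival rate
    # times the flux-weighted mean transit time L / (vmax/2)
    dt_frame = float(np.median(np.diff(frame_times))) if len(frame_times) > 1 else 0.0
    for si, (line, radius) in enumerate(phantom.segments):
        vmax = phantom.vmax(si)
        if vmax <= 0 or dt_frame <= 0:
            continue
        n_seed = rng.poisson(per_seg * line.length / (vmax / 2) / dt_frame)
        for _ in range(n_seed):
            frac = _flux_weighted_radius_fraction(rng)
            speed = vmax * (1 - frac**2)
            live[si].append(
                [next_id, rng.uniform(0, line.length), t_start, radius * frac,
                 rng.uniform(0, 2 * np.pi), speed]
            )
            echo[next_id] = rng.uniform(0.5, 1.0)
            next_id += 1
    for fi, t in enumerate(np.asarray(frame_times, dtype=float)):
        for si, (line, radius) in enumerate(phantom.segments):
            vmax = phantom.vmax(si)
            n_new = rng.poisson(per_seg) if fi > 0 else 0
            for _ in range(n_new):
                frac = _flux_weighted_radius_fraction(rng)
                speed = vmax * (1 - frac**2)
                live[si].append(
                    [next_id, 0.0, t, radius * frac, rng.uniform(0, 2 * np.pi), speed]
                )
                echo[next_id] = rng.uniform(0.5, 1.0)
                next_id += 1
            keep = []
            for b in live[si]:
                bid, s0, t0, rho, phi, speed = b
                s = s0 + speed * (t - t0)
                if s > line.length:
                    continue
                keep.append(b)
                pos, tang, n1, n2 = line.frame_at(np.array([s]))
                p = pos[0] + rho * (np.cos(phi) * n1[0] + np.sin(phi) * n2[0])
                recs_f.append(fi)
                recs_id.append(bid)
                recs_p.append(p)
                recs_v.append(speed * tang[0])
            live[si] = keep
    return MBPopulation(
        np.asarray(frame_times, dtype=float),
        np.asarray(recs_f, dtype=int),
        np.asarray(recs_id, dtype=int),
        np.asarray(recs_p, dtype=float).reshape(-1, 3),
        np.asarray(recs_v, dtype=float).reshape(-1, 3),
        echo,
    )


def _advect_tree(
    tree: VesselTree, concentration: float, frame_times: np.ndarray, rng: np.random.Generator
) -> MBPopulation:
    # pre-build per-edge polylines and speeds; bubbles pick a root-to-leaf
    # path with probability proportional to flow and keep their fractional
    # radial position across segments.
    edge_lines = []
    for p, c, r, q in tree.edges:
        edge_lines.append(Polyline(np.vstack([tree.nodes[p], tree.nodes[c]])))
    children = {}
    for ei, (p, c, r, q) in enumerate(tree.edges):
        children.setdefault(p, []).append(ei)
    root_edges = children.get(0, [])
    recs_f, recs_id, recs_p, recs_v = [], [], [], []
    echo: dict[int, float] = {}
    next_id = 0
    live: list[list] = []  # [id, path(list of edge idx), frac_radius, t0, phi]
    for fi, t in enumerate(np.asarray(frame_times, dtype=float)):
        for _ in range(rng.poisson(concentration)):
            path = []
            q_tot = sum(tree.edges[e][3] for e in root_edges)
            cur = root_edges[rng.choice(len(root_edges), p=[tree.edges[e][3] / q_tot for e in root_edges])] if root_edges else None
            while cur is not None:
                path.append(cur)
                nxt = children.get(tree.edges[cur][1], [])
                if not nxt:
                    break
                w = np.array([tree.edges[e][3] for e in nxt])
                cur = nxt[rng.choice(len(nxt), p=w / w.sum())]
            live.append([next_id, path, _flux_weighted_radius_fraction(rng), t, rng.uniform(0, 2 * np.pi)])
            echo[next_id] = rng.uniform(0.5, 1.0)
            next_id += 1
        keep = []
        for b in live:
            bid, path, frac, t0, phi = b
            # integrate travel time along the path
            tau = t - t0
            placed = False
            for ei in path:
                _, _, r, q = tree.edges[ei]
                line = edge_lines[ei]
                speed = poiseuille_vmax(q, r) * (1 - frac**2)
                if speed <= 0:
                    break
                t_seg = line.length / speed
                if tau <= t_seg:
                    s = speed * tau
                    pos, tang, n1, n2 = line.frame_at(np.array([s]))
                    d = frac * r
                    p = pos[0] + d * (np.cos(phi) * n1[0] + np.sin(phi) * n2[0])
                    recs_f.append(fi)
                    recs_id.append(bid)
                    recs_p.append(p)
                    recs_v.append(speed * tang[0])
                    placed = True
                    break
                tau -= t_seg
            if placed:
                keep.append(b)
        live = keep
    return MBPopulation(
        np.asarray(frame_times, dtype=float),
        np.asarray(recs_f, dtype=int),
        np.asarray(recs_id, dtype=int),
        np.asarray(recs_p, dtype=float).reshape(-1, 3),
        np.asarray(recs_v, dtype=float).reshape(-1, 3),
        echo,
    )


def advect_microbubbles(
    phantom: FlowPhantom | VesselTree,
    concentration: float,
    frame_times: np.ndarray,
    seed: int = 0,
) -> MBPopulation:
    """Advect Poisson-arriving microbubbles along phantom streamlines.

    ``concentration`` is the mean number of bubbles entering per frame.
    Bubbles keep their fractional radial position (no-slip parabolic speed)
    and never leave the lumen.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size > 1 and np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame times must be strictly increasing")
    rng = np.random.default_rng(seed)
    if isinstance(phantom, FlowPhantom):
        return _advect_tube(phantom, concentration, frame_times, rng)
    return _advect_tree(phantom, concentration, frame_times, rng)


def population_window(population: MBPopulation, f0: int, f1: int) -> MBPopulation:
    """Sub-population restricted to frames [f0, f1), reindexed from zero."""
    m = (population.frame_indices >= f0) & (population.frame_indices < f1)
    return MBPopulation(
        population.frame_times[f0:f1],
        population.frame_indices[m] - f0,
        population.ids[m],
        population.positions[m],
        population.velocities[m],
        population.echogenicity,
    )


def block_frame_times(seq: SequenceSpec, n_blocks: int) -> np.ndarray:
    """Volume timestamps for ``n_blocks`` acquisition blocks.

    Within a block, volumes tick at the volume rate; successive blocks are
    separated by the storage gap ``seq.block_period``.
    """
    dt = 1.0 / seq.volume_rate
    times = []
    t0 = 0.0
    for _ in range(n_blocks):
        times.append(t0 + np.arange(seq.volumes_per_block) * dt)
        t0 = times[-1][-1] + dt + seq.block_period
    return np.concatenate(times)


@dataclass
class RFBlock:
    """One acquisition block of raw receive data.

    ``samples[time, element, transmit_event]`` with transmit events ordered
    volume-major (event = volume_in_block * n_tx + tx).
    """

    samples: np.ndarray
    fs: float  # Hz
    t0: float  # record start (s) relative to each transmit
    prf: float
    block_index: int
    transmit_sources: np.ndarray  # element index per transmit event
    n_transmits_per_volume: int
    frame_times: np.ndarray  # (volumes,) s

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        n_ev = self.samples.shape[2]
        if n_ev != len(self.transmit_sources):
            raise ValueError("transmit_sources length must match event axis")
        if n_ev % self.n_transmits_per_volume:
            raise ValueError("event axis not divisible by transmits per volume")

    @property
    def n_volumes(self) -> int:
        return self.samples.shape[2] // self.n_transmits_per_volume


def simulate_rf(
    layout: ArrayLayout,
    seq: SequenceSpec,
    population: MBPopulation,
    noise_snr_dB: float | None = None,
    seed: int = 0,
    c: float = 1540.0,
    max_depth: float | None = None,
    pattern: ElementPattern | None = None,
    transmit_indices: np.ndarray | None = None,
    record_start: float = 0.0,
) -> list[RFBlock]:
    """Simulate diverging-wave RF blocks from a microbubble population.

    Each bubble echoes once per transmit event with delay (source->bubble +
    bubble->receiver)/c plus the lens apex delay on both paths, amplitude
    given by the element far-field pattern (narrowband at f0), obliquity and
    1/r spreading on both paths.  Samples are complex analytic (IQ) values
    at ``seq.samples_per_wavelength`` times f0 — the bandpass-sampling
    equivalent of digitizing a 100%-bandwidth signal at two samples per
    wavelength; optional complex white noise is added at ``noise_snr_dB``
    relative to the peak echo amplitude.
    """
    rng = np.random.default_rng(seed)
    el = layout.element_spec
    f0 = el.center_frequency * 1e6
    fs = seq.sampling_frequency(el)
    c_mm = c * MM_PER_S
    pulse, T = hann_pulse(seq.pulse_cycles, f0)
    if pattern is None:
        # f0 plus two close side frequencies for group-delay estimation
        pattern = element_pattern(
            el,
            layout.lens,
            cycles=seq.pulse_cycles,
            freqs_hz=np.array([0.96 * f0, f0, 1.04 * f0]),
        )
    tx_idx = np.asarray(
        transmit_indices
        if transmit_indices is not None
        else (seq.transmit_element_indices or range(seq.n_transmits_per_volume)),
        dtype=int,
    )
    n_tx = len(tx_idx)
    apex = lens_apex_delay(layout.lens) if layout.lens is not None else 0.0

    if max_depth is None:
        if population.positions.size:
            max_depth = float(population.positions[:, 2].max()) + 10.0
        else:
            max_depth = 60.0
    diag = np.linalg.norm(layout.aperture) / 2
    t_max = 2 * np.sqrt(max_depth**2 + diag**2) / c_mm + 2 * T + 2 * abs(apex)
    t0_rec = max(0.0, float(record_start))
    n_t = int(np.ceil((t_max - t0_rec) * fs)) + 1
    if n_t < 8:
        raise ValueError("record window too short for the stated depth")
    n_win = int(np.ceil(T * fs)) + 2

    n_frames = population.n_frames
    vpb = seq.volumes_per_block
    n_blocks = int(np.ceil(n_frames / vpb))
    centers = layout.element_centers
    blocks: list[RFBlock] = []
    dropped = 0
    for b in range(n_blocks):
        frames = range(b * vpb, min((b + 1) * vpb, n_frames))
        nf = len(frames)
        rf = np.zeros((n_t, layout.n_elements, nf * n_tx), dtype=np.complex64)
        for j, fi in enumerate(frames):
            ids, pos = population.at_frame(fi)
            if len(ids) == 0:
                continue
            inside = pos[:, 2] > 0
            dropped += int(np.count_nonzero(~inside))
            pos = pos[inside]
            ids = ids[inside]
            if len(ids) == 0:
                continue
            d = pos[:, None, :] - centers[None, :, :]  # (nb, ne, 3)
            r = np.linalg.norm(d, axis=2)
            r = np.maximum(r, 1e-3)
            u = d[:, :, 0] / r
            v = d[:, :, 1] / r
            w = np.clip(d[:, :, 2] / r, 0.0, None)
            n_pf = pattern.freqs_hz.size
            i_f0 = n_pf // 2
            g0 = pattern.gain(i_f0, u.ravel(), v.ravel()).reshape(r.shape)
            g = g0 * w / r
            delay = r / c_mm + apex
            if n_pf >= 3:
                # lens group delay: the echo envelope lags the geometric
                # arrival by -d(arg G)/d(omega) at steep angles
                g_lo = pattern.gain(0, u.ravel(), v.ravel()).reshape(r.shape)
                g_hi = pattern.gain(n_pf - 1, u.ravel(), v.ravel()).reshape(r.shape)
                dphi = np.angle(g_hi * np.conj(g_lo))
                dw = 2 * np.pi * (pattern.freqs_hz[-1] - pattern.freqs_hz[0])
                gd = np.clip(-dphi / dw, -2e-6, 2e-6)
                delay = delay + gd
                # keep the carrier phase anchored to G(f0) while the
                # envelope moves by the group delay
                g = g * np.exp(2j * np.pi * f0 * gd)
            echog = np.array([population.echogenicity.get(i, 1.0) for i in ids])
            for k, s_el in enumerate(tx_idx):
                ev = j * n_tx + k
                amp = (echog[:, None] * g[:, s_el][:, None] * g)  # (nb, ne) complex
                # time reference at the pulse envelope peak: the echo
                # envelope culminates exactly at the two-way transit time
                tau = delay[:, [s_el]] + delay - T / 2  # (nb, ne)
                i0 = np.floor((tau - t0_rec) * fs).astype(int)
                offs = np.arange(n_win)
                idx = i0[:, :, None] + offs[None, None, :]
                tt = idx / fs + t0_rec - tau[:, :, None]
                contrib = (amp[:, :, None] * pulse(tt)).astype(np.complex64)
                valid = (idx >= 0) & (idx < n_t)
                e_idx = np.broadcast_to(
                    np.arange(layout.n_elements)[None, :, None], idx.shape
                )
                np.add.at(
                    rf[:, :, ev], (idx[valid], e_idx[valid]), contrib[valid]
                )
        if noise_snr_dB is not None:
            peak = float(np.max(np.abs(rf))) or 1.0
            sigma = np.float32(peak * 10 ** (-noise_snr_dB / 20) / np.sqrt(2))
            rf.real += rng.standard_normal(rf.shape, dtype=np.float32) * sigma
            rf.imag += rng.standard_normal(rf.shape, dtype=np.float32) * sigma
        blocks.append(
            RFBlock(
                samples=rf,
                fs=fs,
                t0=t0_rec,
                prf=seq.prf,
                block_index=b,
                transmit_sources=np.tile(tx_idx, nf),
                n_transmits_per_volume=n_tx,
                frame_times=population.frame_times[b * vpb : b * vpb + nf],
            )
        )
    return blocks


def apply_rigid_motion(
    population: MBPopulation, transforms: list[RigidTransform], volumes_per_block: int
) -> MBPopulation:
    """Apply one rigid transform per acquisition block to bubble positions.

    Frame ``f`` belongs to block ``f // volumes_per_block``; ground-truth
    transforms should be retained by the caller for recovery tests.
    """
    pos = population.positions.copy()
    vel = population.velocities.copy()
    block_of = population.frame_indices // volumes_per_block
    for k, tr in enumerate(transforms):
        m = block_of == k
        if np.any(m):
            pos[m] = tr.apply(pos[m])
            vel[m] = vel[m] @ tr.rotation_matrix().T
    return MBPopulation(
        population.frame_times,
        population.frame_indices.copy(),
        population.ids.copy(),
        pos,
        vel,
        dict(population.echogenicity),
    )


@dataclass
class PhysioTrace:
    """Synthetic ECG + respiration with R-peaks and low-motion gating windows."""

    fs: float  # Hz
    ecg: np.ndarray
    respiration: np.ndarray
    r_peak_times: np.ndarray  # s, strictly increasing
    low_resp_windows: list[tuple[float, float]]  # non-overlapping (start, end) s

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.ecg)) / self.fs

    def trigger_times(self) -> np.ndarray:
        """R-peaks falling inside the low-respiration windows."""
        out = []
        for t in self.r_peak_times:
            if any(a <= t <= b for a, b in self.low_resp_windows):
                out.append(t)
        return np.asarray(out)

    def rr_interval_of(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Previous R-peak time and RR interval for each query time; NaN outside."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        i = np.searchsorted(self.r_peak_times, t, side="right") - 1
        prev = np.where(i >= 0, self.r_peak_times[np.clip(i, 0, None)], np.nan)
        nxt = np.where(
            i + 1 < len(self.r_peak_times),
            self.r_peak_times[np.clip(i + 1, 0, len(self.r_peak_times) - 1)],
            np.nan,
        )
        return prev, nxt - prev


def generate_physio(
    heart_rate: float,
    resp_rate: float,
    duration: float,
    seed: int = 0,
    fs: float = 500.0,
    resp_quantile: float = 0.3,
    rr_jitter: float = 0.02,
) -> PhysioTrace:
    """Synthetic ECG (jittered R-peaks) and sinusoidal respiration.

    Low-respiration windows are the intervals where |respiration| stays
    below the ``resp_quantile`` quantile of its magnitude, emulating
    acquisition triggers placed between two respiratory phases.
    """
    if heart_rate <= 0 or resp_rate <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    rr = 60.0 / heart_rate
    peaks = []
    t = rr * rng.uniform(0.2, 0.8)
    while t < duration:
        peaks.append(t)
        t += rr * (1 + rr_jitter * rng.normal())
    r_peaks = np.asarray(peaks)
    tvec = np.arange(int(duration * fs)) / fs
    ecg = np.zeros_like(tvec)
    for tp in r_peaks:
        ecg += np.exp(-0.5 * ((tvec - tp) / 0.012) ** 2)
    resp = np.sin(2 * np.pi * resp_rate / 60.0 * tvec)
    thr = np.quantile(np.abs(resp), min(resp_quantile, 1.0))
    low = np.abs(resp) <= thr if resp_quantile < 1.0 else np.ones_like(resp, bool)
    windows: list[tuple[float, float]] = []
    in_win = False
    for i, flag in enumerate(low):
        if flag and not in_win:
            start = tvec[i]
            in_win = True
        elif not flag and in_win:
            windows.append((start, tvec[i - 1]))
            in_win = False
    if in_win:
        windows.append((start, tvec[-1]))
    return PhysioTrace(fs, ecg, resp, r_peaks, windows)
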