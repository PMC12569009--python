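"""File formats, pipeline configuration and the end-to-end demo pipeline.

Formats: volumes as NIfTI (see :mod:`lensulm.grids`), RF blocks as HDF5
with named datasets plus a JSON metadata sidecar, tracks and localizations
as CSV, manifests and reports as JSON.  The pipeline composes simulate ->
beamform -> clutter filter -> localize -> track -> (motion correct) ->
quantify on a synthetic tube phantom and is fully deterministic under a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from . import arrays, beamform, phantoms, quantify, ulm
from .grids import ScalarVolume, VolumeGrid, write_nifti

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "save_rfblock",
    "load_rfblock",
    "population_to_dataframe",
    "skeleton_to_dataframe",
    "save_transform",
    "load_transform",
    "tracks_to_dataframe",
    "save_tracks_csv",
    "load_tracks_csv",
    "run_pipeline",
]

_FLOAT_FMT = "%.9g"  # fixed CSV float precision


def save_rfblock(block: phantoms.RFBlock, path: str) -> None:
    """Write an RF block as HDF5 (datasets rf, transmit_sources, frame_times;
    scalar attributes) plus a ``<path>.json`` metadata sidecar."""
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=block.samples, chunks=True)
        f.create_dataset("transmit_sources", data=block.transmit_sources)
        f.create_dataset("frame_times", data=block.frame_times)
        f.attrs["fs"] = block.fs
        f.attrs["t0"] = block.t0
        f.attrs["prf"] = block.prf
        f.attrs["block_index"] = block.block_index
        f.attrs["n_transmits_per_volume"] = block.n_transmits_per_volume
    meta = {
        "fs_hz": block.fs,
        "t0_s": block.t0,
        "prf_hz": block.prf,
        "block_index": block.block_index,
        "n_transmits_per_volume": block.n_transmits_per_volume,
        "shape_time_element_transmit": list(block.samples.shape),
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_rfblock(path: str) -> phantoms.RFBlock:
    with h5py.File(path, "r") as f:
        return phantoms.RFBlock(
            samples=f["rf"][()],
            fs=float(f.attrs["fs"]),
            t0=float(f.attrs["t0"]),
            prf=float(f.attrs["prf"]),
            block_index=int(f.attrs["block_index"]),
            transmit_sources=f["transmit_sources"][()],
            n_transmits_per_volume=int(f.attrs["n_transmits_per_volume"]),
            frame_times=f["frame_times"][()],
        )


def population_to_dataframe(population: phantoms.MBPopulation) -> pd.DataFrame:
    """Ground-truth bubble records as (id, frame, x, y, z, vx, vy, vz)."""
    return pd.DataFrame(
        {
            "id": population.ids,
            "frame": population.frame_indices,
            "x": population.positions[:, 0],
            "y": population.positions[:, 1],
            "z": population.positions[:, 2],
            "vx": population.velocities[:, 0],
            "vy": population.velocities[:, 1],
            "vz": population.velocities[:, 2],
        }
    )


def skeleton_to_dataframe(skeleton) -> pd.DataFrame:
    """Skeleton point table: position, radius (mm) and branch label."""
    return pd.DataFrame(
        {
            "x": skeleton.points[:, 0],
            "y": skeleton.points[:, 1],
            "z": skeleton.points[:, 2],
            "radius_mm": skeleton.radius,
            "branch": skeleton.segment_labels,
        }
    )


def save_transform(transform, path: str) -> None:
    """Plain-text rigid-transform parameter file: intrinsic z-y-x Euler
    angles in degrees, then translation and rotation centre in mm."""
    rot = np.degrees(transform.rotation)
    with open(path, "w") as fh:
        fh.write("# rigid transform: rotation_zyx_deg, translation_mm, center_mm\n")
        fh.write("rotation_zyx_deg: " + " ".join(f"{v:.9g}" for v in rot) + "\n")
        fh.write(
            "translation_mm: " + " ".join(f"{v:.9g}" for v in transform.translation) + "\n"
        )
        fh.write("center_mm: " + " ".join(f"{v:.9g}" for v in transform.center) + "\n")


def load_transform(path: str):
    from .motion import RigidTransform

    vals = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or ":" not in line:
                continue
            key, rest = line.split(":", 1)
            vals[key.strip()] = tuple(float(v) for v in rest.split())
    return RigidTransform(
        rotation=tuple(np.radians(vals["rotation_zyx_deg"])),
        translation=vals["translation_mm"],
        center=vals["center_mm"],
    )


def tracks_to_dataframe(tracks: list[ulm.MicrobubbleTrack]) -> pd.DataFrame:
    """Flatten tracks to rows (id, frame, x, y, z, vx, vy, vz); the velocity
    columns carry the step velocity leading into each localization (NaN on
    track starts)."""
    rows = []
    for tr in tracks:
        for i, loc in enumerate(tr.localizations):
            v = tr.velocities[i - 1] if i > 0 else (np.nan, np.nan, np.nan)
            rows.append(
                {
                    "id": tr.track_id,
                    "frame": loc.frame_index,
                    "x": loc.position[0],
                    "y": loc.position[1],
                    "z": loc.position[2],
                    "vx": v[0],
                    "vy": v[1],
                    "vz": v[2],
                }
            )
    return pd.DataFrame(rows, columns=["id", "frame", "x", "y", "z", "vx", "vy", "vz"])


def save_tracks_csv(tracks: list[ulm.MicrobubbleTrack], path: str) -> None:
    tracks_to_dataframe(tracks).to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_tracks_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class PipelineConfig:
    """All pipeline parameters with the documented acquisition profile as
    defaults (1 MHz lensed 14 x 18 array, 16-source diverging waves at PRF
    5 kHz, 256-volume blocks).  Unknown config keys are rejected."""

    seed: int = 0
    # array
    rows: int = 18
    cols: int = 14
    pitch: float = 5.48
    element_width: float = 4.5
    use_lens: bool = True
    # sequence
    prf: float = 5000.0
    n_transmits: int = 16
    pulse_cycles: int = 2
    samples_per_wavelength: int = 2
    volumes_per_block: int = 256
    n_blocks: int = 2
    block_gap_s: float = 0.3
    # phantom
    tube_diameter_mm: float = 0.87
    flow_rate_mlh: float = 75.0
    tube_depth_mm: float = 60.0
    tube_length_mm: float = 44.0
    inlet_buffer_mm: float = 8.0  # tube length upstream of the imaging box
    bubbles_per_frame: float | None = None  # explicit arrival-rate override
    bubble_concentration_mm3: float = 0.15  # bubbles per mm^3 of injectate
    noise_snr_db: float | None = 30.0
    # beamforming
    grid_spacing_mm: float = 0.77  # along the tube (x)
    cross_spacing_mm: float = 0.385  # across the lumen (y, z)
    cross_extent_mm: float = 2.2  # half-extent of the grid around the axis
    grid_margin_mm: float = 3.0
    map_spacing_mm: float = 0.075  # super-resolved ULM map voxel
    clutter_rank_cut: int = 0
    # localization / tracking
    noise_multiple: float = 4.0
    rel_max_db: float | None = -12.0
    correlation_threshold: float = 0.6
    psf_fwhm_mm: tuple[float, float, float] = (1.5, 1.5, 0.9)
    max_link_distance_mm: float | None = None
    max_gap_frames: int = 1
    min_track_length: int = 3
    motion_correction: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "psf_fwhm_mm" in data:
            data = dict(data)
            data["psf_fwhm_mm"] = tuple(data["psf_fwhm_mm"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["psf_fwhm_mm"] = list(d["psf_fwhm_mm"])
        return d


@dataclass
class RunManifest:
    config: dict
    package_version: str
    stage_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    output_hashes: dict = field(default_factory=dict)

    def digest(self) -> str:
        payload = json.dumps(
            {
                "config": self.config,
                "counts": self.stage_counts,
                "hashes": self.output_hashes,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "package_version": self.package_version,
                    "stage_counts": self.stage_counts,
                    "warnings": self.warnings,
                    "output_hashes": self.output_hashes,
                    "digest": self.digest(),
                },
                fh,
                indent=2,
            )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | None = None):
    """Run the full synthetic tube pipeline.

    Returns ``(manifest, results)`` where ``results`` holds the ULM maps,
    tracks, fitted Poiseuille profile and recovered flow rate.  With
    ``out_dir`` set, maps (NIfTI), tracks (CSV) and the manifest (JSON) are
    written there.
    """
    from . import __version__
    from .grids import VolumeGrid

    element = arrays.ElementSpec(
        width_lateral=config.element_width, width_elevational=config.element_width
    )
    lens = arrays.LensSpec() if config.use_lens else None
    layout = arrays.build_multilens_array(config.rows, config.cols, config.pitch, element, lens)
    n_sub = max(int(round(np.sqrt(config.n_transmits))), 1)
    seq = arrays.SequenceSpec(
        prf=config.prf,
        n_transmits_per_volume=config.n_transmits,
        transmit_element_indices=arrays.central_transmit_indices(
            config.rows, config.cols, n_sub
        )[: config.n_transmits],
        pulse_cycles=config.pulse_cycles,
        samples_per_wavelength=config.samples_per_wavelength,
        volumes_per_block=config.volumes_per_block,
        block_period=config.block_gap_s,
    )
    phantom = phantoms.make_tube_phantom(
        config.tube_diameter_mm,
        config.flow_rate_mlh,
        "straight",
        depth=config.tube_depth_mm,
        length=config.tube_length_mm,
    )
    frame_times = phantoms.block_frame_times(seq, config.n_blocks)
    if config.bubbles_per_frame is not None:
        arrivals = config.bubbles_per_frame
    else:
        # constant dilution: arrival rate is concentration times flow
        q_mm3s = phantoms.flow_mlh_to_mm3s(config.flow_rate_mlh)
        arrivals = config.bubble_concentration_mm3 * q_mm3s / seq.volume_rate
    population = phantoms.advect_microbubbles(
        phantom, arrivals, frame_times, seed=config.seed
    )
    chunk_frames = 24  # RF synthesis granularity, bounds peak memory

    def iter_chunks(b: int):
        base = b * config.volumes_per_block
        for c0 in range(0, config.volumes_per_block, chunk_frames):
            f0 = base + c0
            f1 = min(base + config.volumes_per_block, f0 + chunk_frames)
            sub = phantoms.population_window(population, f0, f1)
            # depth-gated record: echoes from the imaged depth band only
            t_rec = max(
                0.0, 2 * (config.tube_depth_mm - config.cross_extent_mm - 4.0) / 1.54e6
            )
            blk = phantoms.simulate_rf(
                layout,
                seq,
                sub,
                noise_snr_dB=config.noise_snr_db,
                seed=config.seed + 1 + 7919 * b + c0,
                max_depth=config.tube_depth_mm + 10.0,
                record_start=t_rec,
            )[0]
            yield f0, blk

    # beamforming grid: a box around the tube, excluding the inlet
    # development zone where freshly injected bubbles have not yet
    # separated along their streamlines; cross-sectional voxels are finer
    # than the lumen so sub-voxel offsets stay well inside one voxel
    m = config.grid_margin_mm
    sp = config.grid_spacing_mm
    csp = config.cross_spacing_mm
    ce = config.cross_extent_mm
    lo = np.array(
        [
            -config.tube_length_mm / 2 + config.inlet_buffer_mm,
            -ce,
            config.tube_depth_mm - ce,
        ]
    )
    hi = np.array([config.tube_length_mm / 2 + m, ce, config.tube_depth_mm + ce])
    spacing = (sp, csp, csp)
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing[i])) + 1 for i in range(3))
    grid = VolumeGrid(tuple(lo), spacing, shape)

    sigma_vox = np.asarray(
        [ulm.fwhm_to_sigma(f) / s for f, s in zip(config.psf_fwhm_mm, spacing)]
    )
    if config.max_link_distance_mm is None:
        # expected per-frame travel plus headroom for localization jitter
        # (~3 sigma at the lambda/10 precision scale)
        max_link = 1.2 * phantom.vmax() / seq.volume_rate + 0.3 * arrays.FIELD_WAVELENGTH_MM
    else:
        max_link = config.max_link_distance_mm

    counts = {"blocks": config.n_blocks, "frames": int(population.n_frames)}
    warnings: list[str] = []
    all_tracks: list[ulm.MicrobubbleTrack] = []
    pds = []
    n_cand = 0
    for b in range(config.n_blocks):
        locs_per_frame = []
        pd_sum = np.zeros(grid.shape)
        frame0 = b * config.volumes_per_block
        for f0, block in iter_chunks(b):
            series = beamform.das_beamform(block, layout, grid)
            if config.clutter_rank_cut > 0:
                series = beamform.svd_clutter_filter(series, config.clutter_rank_cut)
            pd_sum += beamform.power_doppler(series).values
            for f in range(series.n_frames):
                env = series.envelope(f)
                locs = ulm.localize_volume(
                    env,
                    f0 + f,
                    sigma_vox,
                    noise_multiple=config.noise_multiple,
                    correlation_threshold=config.correlation_threshold,
                    rel_max_db=config.rel_max_db,
                )
                n_cand += len(locs)
                locs_per_frame.append(locs)
        tracks = ulm.link_tracks(
            locs_per_frame,
            max_link,
            frame_times,
            max_gap_frames=config.max_gap_frames,
            min_track_length=config.min_track_length,
            block_index=b,
        )
        for t in tracks:
            t.track_id += len(all_tracks)
        pds.append(ScalarVolume(grid, pd_sum, "a.u."))
        all_tracks.extend(tracks)
    counts["localizations"] = n_cand
    counts["tracks"] = len(all_tracks)

    if config.motion_correction and len(pds) >= 2:
        from .motion import interblock_correct

        per_block = [
            [t for t in all_tracks if t.block_index == b] for b in range(config.n_blocks)
        ]
        corrected, reg = interblock_correct(pds, per_block)
        all_tracks = [t for blk in corrected for t in blk]
        counts["registered_blocks"] = sum(1 for r in reg if r.converged)

    # super-resolved ULM maps on a fine grid inside the imaging box
    msp = config.map_spacing_mm
    map_lo = np.array([lo[0], -3 * config.tube_diameter_mm, config.tube_depth_mm - 3 * config.tube_diameter_mm])
    map_hi = np.array([hi[0], 3 * config.tube_diameter_mm, config.tube_depth_mm + 3 * config.tube_diameter_mm])
    map_shape = tuple(int(np.ceil((map_hi[i] - map_lo[i]) / msp)) + 1 for i in range(3))
    map_grid = VolumeGrid(tuple(map_lo), (msp, msp, msp), map_shape)
    maps = ulm.tracks_to_maps(all_tracks, map_grid)

    # vessel radius from the skeletonized density (the structural route),
    # then the Poiseuille amplitude from the tracks (the velocity route)
    line, radius = phantom.segments[0]
    skel = quantify.skeletonize_radii(maps.density, binarize_threshold=1)
    counts["skeleton_points"] = int(skel.n_points)
    mid = line.frame_at(np.array([line.length / 2]))[0][0]
    mid[0] = (map_lo[0] + map_hi[0]) / 2  # centre of the imaged span
    profile = quantify.extract_velocity_profile(
        all_tracks,
        axis_point=mid,
        axis_direction=np.array([1.0, 0.0, 0.0]),
        normal_direction=np.array([0.0, 0.0, 1.0]),
        slab_thickness=(map_hi[0] - map_lo[0]),
        max_offset=1.5 * radius,
    )
    flow = quantify.segment_flow_rate(profile) if profile.fit_ok else float("nan")
    if not profile.fit_ok:
        warnings.append("Poiseuille fit not attempted or failed (too few bins)")
    results = {
        "maps": maps,
        "tracks": all_tracks,
        "profile": profile,
        "flow_rate_mlh": flow,
        "power_dopplers": pds,
        "population": population,
    }

    manifest = RunManifest(config.to_dict(), __version__, counts, warnings)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "density.nii.gz": maps.density,
            "speed.nii.gz": maps.speed,
            "direction.nii.gz": maps.axial_direction,
        }
        for name, vol in paths.items():
            write_nifti(vol, os.path.join(out_dir, name))
        save_tracks_csv(all_tracks, os.path.join(out_dir, "tracks.csv"))
        report = {"flow_rate_mlh": flow, "n_tracks": len(all_tracks)}
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
        for name in list(paths) + ["tracks.csv", "report.json"]:
            manifest.output_hashes[name] = _sha256(os.path.join(out_dir, name))
        manifest.save(os.path.join(out_dir, "manifest.json"))
    return manifest, results
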