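"""Multi-lens transducer array geometry, compound-lens physics and sequence timing.

The array modelled here is a large-aperture 1 MHz matrix of 252 elements
(14 x 18, 5.48 mm pitch, 104 x 82 mm^2 aperture) whose 4.5 x 4.5 mm^2
(~3 lambda) elements each carry a compound diverging lens: an epoxy
plano-convex cap (fast medium, c1 = 2570 m/s) topped by a silicone
plano-concave layer (slow medium, c2 = 1015 m/s).  Refraction at the two
interfaces widens the angular beam of the large element, trading the
half-wavelength pitch of conventional dense matrices for sensitivity and
aperture at a fraction of the channel count.

Units: mm for lengths, MHz for frequencies, m/s for speeds of sound,
seconds for times.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ElementSpec",
    "LensSpec",
    "ArrayLayout",
    "SequenceSpec",
    "InvalidGeometryError",
    "TotalInternalReflectionError",
    "SOUND_SPEED_TISSUE",
    "TILING_WAVELENGTH_MM",
    "FIELD_WAVELENGTH_MM",
    "build_multilens_array",
    "build_comparison_arrays",
    "elements_for_halfwavelength_tiling",
    "snell_refract",
    "lens_thickness_profile",
    "lens_delay_profile",
    "lens_apex_delay",
    "volume_rate",
    "central_transmit_indices",
    "multilens_252",
    "default_sequence",
]

#: Speed of sound in soft tissue / water-like media (m/s).
SOUND_SPEED_TISSUE = 1540.0
#: Nominal wavelength (mm) used for element-count and pitch arithmetic.
TILING_WAVELENGTH_MM = 1.5
#: Wavelength (mm) at 1 MHz in tissue used by the field engine (c / f0).
FIELD_WAVELENGTH_MM = 1.54


class InvalidGeometryError(ValueError):
    """Raised for non-physical array or lens geometry."""


class TotalInternalReflectionError(ValueError):
    """Raised when Snell's law has no real refracted angle."""


@dataclass(frozen=True)
class ElementSpec:
    width_lateral: float = 4.5  # mm
    width_elevational: float = 4.5  # mm
    center_frequency: float = 1.0  # MHz
    bandwidth_fraction: float = 0.67

    def __post_init__(self) -> None:
        if self.width_lateral <= 0 or self.width_elevational <= 0:
            raise InvalidGeometryError("element widths must be positive")
        if self.center_frequency <= 0:
            raise InvalidGeometryError("center frequency must be positive")
        if not 0 < self.bandwidth_fraction < 2:
            raise InvalidGeometryError("bandwidth fraction must be in (0, 2)")

    @property
    def wavelength_mm(self) -> float:
        """Wavelength in the propagation medium (mm)."""
        return SOUND_SPEED_TISSUE / (self.center_frequency * 1e6) * 1e3


@dataclass(frozen=True)
class LensSpec:
    """Compound diverging lens: plano-convex fast cap + plano-concave slow top.

    The convex epoxy cap (speed ``c_convex``) has apex thickness
    ``convex_max_thickness`` and spherical radius ``radius_of_curvature``;
    the silicone layer fills from the cap surface up to a flat top plane
    ``concave_max_thickness`` above the apex (speed ``c_concave``).
    """

    radius_of_curvature: float = 3.2  # mm
    convex_max_thickness: float = 3.2  # mm
    concave_max_thickness: float = 0.375  # mm
    c_convex: float = 2570.0  # m/s
    c_concave: float = 1015.0  # m/s
    c_medium: float = SOUND_SPEED_TISSUE  # m/s
    impedance_convex: float = 3.0  # MRayl
    impedance_concave: float = 1.1  # MRayl
    impedance_medium: float = 1.54  # MRayl

    def __post_init__(self) -> None:
        if min(self.c_convex, self.c_concave, self.c_medium) <= 0:
            raise InvalidGeometryError("lens speeds of sound must be positive")
        if self.convex_max_thickness < 0 or self.concave_max_thickness < 0:
            raise InvalidGeometryError("lens thicknesses must be >= 0")
        if self.radius_of_curvature <= 0:
            raise InvalidGeometryError("radius of curvature must be positive")

    @property
    def stack_height(self) -> float:
        """Total lens stack height above the transducer face (mm)."""
        return self.convex_max_thickness + self.concave_max_thickness

    def transmission_amplitude(self) -> float:
        """Normal-incidence pressure transmission through the two interfaces."""
        t12 = 2 * self.impedance_concave / (self.impedance_convex + self.impedance_concave)
        t23 = 2 * self.impedance_medium / (self.impedance_concave + self.impedance_medium)
        return t12 * t23


@dataclass(frozen=True)
class ArrayLayout:
    element_centers: np.ndarray  # (n, 3) mm, probe plane z = 0
    element_spec: ElementSpec
    lens: LensSpec | None
    pitch_lateral: float
    pitch_elevational: float
    aperture: tuple[float, float]  # (width, height) mm, outermost element edges

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.element_centers, dtype=float))
        object.__setattr__(self, "element_centers", centers)
        if centers.shape[1] != 3:
            raise InvalidGeometryError("element centers must be (n, 3)")
        half_w = self.aperture[0] / 2 + 1e-9
        half_h = self.aperture[1] / 2 + 1e-9
        if np.any(np.abs(centers[:, 0]) > half_w) or np.any(np.abs(centers[:, 1]) > half_h):
            raise InvalidGeometryError("element centers outside stated aperture")

    @property
    def n_elements(self) -> int:
        return self.element_centers.shape[0]

    @property
    def wavelength(self) -> float:
        return self.element_spec.wavelength_mm


@dataclass(frozen=True)
class SequenceSpec:
    prf: float = 5000.0  # Hz
    n_transmits_per_volume: int = 16
    transmit_element_indices: tuple[int, ...] = ()
    pulse_cycles: int = 2
    samples_per_wavelength: int = 2
    volumes_per_block: int = 256
    block_period: float = 0.3  # s between block starts (storage gap)

    def __post_init__(self) -> None:
        if self.prf <= 0:
            raise ValueError("prf must be positive")
        if self.n_transmits_per_volume < 1:
            raise ValueError("need at least one transmit per volume")
        if self.transmit_element_indices and (
            len(self.transmit_element_indices) != self.n_transmits_per_volume
        ):
            raise ValueError("transmit index count must match transmits per volume")

    @property
    def volume_rate(self) -> float:
        return self.prf / self.n_transmits_per_volume

    @property
    def block_duration(self) -> float:
        return self.volumes_per_block / self.volume_rate

    def sampling_frequency(self, element: ElementSpec) -> float:
        """RF sampling rate (Hz): samples-per-wavelength times f0."""
        return self.samples_per_wavelength * element.center_frequency * 1e6


def build_multilens_array(
    rows: int,
    cols: int,
    pitch: float,
    element: ElementSpec | None = None,
    lens: LensSpec | None = None,
) -> ArrayLayout:
    """Centered regular grid of ``rows x cols`` elements at ``pitch`` mm.

    ``rows`` counts elements along x (lateral), ``cols`` along y.  The
    aperture is reported as the span of the outermost element edges.
    """
    element = element or ElementSpec()
    if rows < 1 or cols < 1:
        raise InvalidGeometryError("rows and cols must be >= 1")
    if pitch <= 0:
        raise InvalidGeometryError("pitch must be positive")
    x = (np.arange(rows) - (rows - 1) / 2) * pitch
    y = (np.arange(cols) - (cols - 1) / 2) * pitch
    xx, yy = np.meshgrid(x, y, indexing="ij")
    centers = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(rows * cols)])
    aperture = (
        (rows - 1) * pitch + element.width_lateral,
        (cols - 1) * pitch + element.width_elevational,
    )
    return ArrayLayout(centers, element, lens, pitch, pitch, aperture)


def elements_for_halfwavelength_tiling(
    aperture_w: float, aperture_h: float, wavelength: float
) -> int:
    """Element count needed to tile an aperture at half-wavelength size/pitch."""
    if min(aperture_w, aperture_h, wavelength) <= 0:
        raise InvalidGeometryError("aperture and wavelength must be positive")
    half = wavelength / 2
    return int(np.floor(aperture_w / half)) * int(np.floor(aperture_h / half))


def snell_refract(theta_incident: float, c_in: float, c_out: float) -> float:
    """Refracted angle (rad) across an interface; faster exit medium bends away.

    Raises :class:`TotalInternalReflectionError` when ``sin(theta) * c_out/c_in``
    exceeds 1 (no silent clipping).
    """
    if not 0 <= theta_incident < np.pi / 2:
        raise ValueError("incident angle must be in [0, pi/2)")
    s = np.sin(theta_incident) * c_out / c_in
    if s > 1.0:
        raise TotalInternalReflectionError(
            f"total internal reflection: sin(theta_t) = {s:.4f} > 1"
        )
    return float(np.arcsin(s))


def lens_thickness_profile(lens: LensSpec, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convex-cap and concave-layer thicknesses (mm) at radius ``rho`` from the apex axis.

    The convex cap is a spherical cap of radius R and apex thickness t1:
    t1(rho) = sqrt(R^2 - rho^2) - (R - t1max), clipped at zero.  The
    silicone layer fills from the cap surface up to the flat top plane at
    ``stack_height``.
    """
    rho = np.asarray(rho, dtype=float)
    R = lens.radius_of_curvature
    sag = np.sqrt(np.clip(R**2 - np.minimum(rho, R) ** 2, 0.0, None))
    t_convex = np.clip(sag - (R - lens.convex_max_thickness), 0.0, None)
    t_concave = lens.stack_height - t_convex
    return t_convex, t_concave


def lens_delay_profile(
    lens: LensSpec, element: ElementSpec, sample_points: np.ndarray
) -> np.ndarray:
    """One-way traversal-time offsets (s) relative to the element centre.

    Thin-phase-screen model: each (x, y) point on the element face crosses
    the local convex/concave thicknesses along the surface normal at the
    layer speeds of sound.  Positive values lag the centre, so the screen
    advances the central rays of the fast convex cap and curves the
    wavefront outward (a diverging lens).
    """
    pts = np.atleast_2d(np.asarray(sample_points, dtype=float))
    half_w = element.width_lateral / 2
    half_h = element.width_elevational / 2
    if np.any(np.abs(pts[:, 0]) > half_w + 1e-9) or np.any(np.abs(pts[:, 1]) > half_h + 1e-9):
        raise InvalidGeometryError("sample points outside the element footprint")
    rho = np.hypot(pts[:, 0], pts[:, 1])
    t1, t2 = lens_thickness_profile(lens, rho)
    # mm / (m/s) -> ms; convert to s with 1e-3
    tau = (t1 / lens.c_convex + t2 / lens.c_concave) * 1e-3
    t1c, t2c = lens_thickness_profile(lens, np.array([0.0]))
    tau0 = float(t1c[0] / lens.c_convex + t2c[0] / lens.c_concave) * 1e-3
    return tau - tau0


def lens_apex_delay(lens: LensSpec) -> float:
    """Extra one-way transit time (s) through the lens stack on the element axis,
    relative to the same thickness of propagation medium."""
    t1, t2 = lens_thickness_profile(lens, np.array([0.0]))
    through = (t1[0] / lens.c_convex + t2[0] / lens.c_concave) * 1e-3
    medium = lens.stack_height / lens.c_medium * 1e-3
    return float(through - medium)


def lens_virtual_source(
    lens: LensSpec, element: ElementSpec, n_samples: int = 33
) -> tuple[float, float]:
    """Virtual-source model of the compound lens.

    The diverging lens makes the element radiate (and receive) like a point
    source a distance f behind its face: the phase-screen delay profile is
    close to (sqrt(rho^2 + f^2) - f)/c_medium, fitted by least squares over
    the full element face.  Returns ``(f_mm, delay_offset_s)`` where the
    effective one-way transit time from a field point P to the element is
    |P - V|/c + delay_offset with V = center - (0, 0, f); the offset
    contains the apex delay, the virtual-source standoff and the lens
    carrier insertion phase at f0 (so beamformed peaks stay axially
    unbiased).
    """
    x = np.linspace(-element.width_lateral / 2, element.width_lateral / 2, n_samples)
    y = np.linspace(-element.width_elevational / 2, element.width_elevational / 2, n_samples)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    rho = np.hypot(pts[:, 0], pts[:, 1])
    tau = lens_delay_profile(lens, element, pts)  # relative to centre, s
    c_mm_us = lens.c_medium * 1e-3  # mm/us
    tau_us = tau * 1e6

    def resid(f: float) -> float:
        model = (np.sqrt(rho**2 + f**2) - f) / c_mm_us
        return float(np.sum((model - tau_us) ** 2))

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(resid, bounds=(0.1, 100.0), method="bounded")
    f = float(res.x)
    # on-axis insertion delay of the screen: group delay at f0, so that
    # beamforming samples each channel at its envelope peak (any constant
    # carrier phase offset is common to all channels and drops out of the
    # envelope magnitude)
    f0 = element.center_frequency * 1e6
    f_lo, f_hi = 0.96 * f0, 1.04 * f0
    g_lo = np.sum(np.exp(-2j * np.pi * f_lo * tau))
    g_hi = np.sum(np.exp(-2j * np.pi * f_hi * tau))
    t_ins = -float(np.angle(g_hi * np.conj(g_lo))) / (2 * np.pi * (f_hi - f_lo))
    offset = lens_apex_delay(lens) - f / lens.c_medium * 1e-3 + t_ins
    return f, offset


def volume_rate(seq: SequenceSpec) -> float:
    """Volumetric frame rate (Hz) = PRF / transmits per volume."""
    return seq.volume_rate


def central_transmit_indices(rows: int, cols: int, n_sub: int = 4) -> tuple[int, ...]:
    """Element indices of a centred ``n_sub x n_sub`` transmit sub-grid.

    Element indexing follows :func:`build_multilens_array` (row-major,
    x fastest over rows).
    """
    r0 = (rows - n_sub) // 2
    c0 = (cols - n_sub) // 2
    idx = [(r0 + i) * cols + (c0 + j) for i in range(n_sub) for j in range(n_sub)]
    return tuple(idx)


def build_comparison_arrays(
    reference: ArrayLayout, seed: int = 7, min_separation: float | None = None
) -> tuple[ArrayLayout, ArrayLayout]:
    """Dense and sparse lambda/2-element comparison arrays.

    Both carry the reference element count.  The dense array packs them in
    a compact grid at lambda/2 pitch (aperture ~14 x 11 mm^2 for the 252
    element reference); the sparse array scatters them uniformly over the
    reference aperture with minimum-separation rejection sampling
    (deterministic for a given ``seed``).
    """
    lam = reference.wavelength
    small = replace(
        reference.element_spec, width_lateral=lam / 2, width_elevational=lam / 2
    )
    n = reference.n_elements
    cols = int(np.floor(np.sqrt(n * reference.aperture[1] / reference.aperture[0])))
    cols = max(cols, 1)
    rows = int(np.ceil(n / cols))
    dense_full = build_multilens_array(rows, cols, lam / 2, small, lens=None)
    dense = ArrayLayout(
        dense_full.element_centers[:n],
        small,
        None,
        lam / 2,
        lam / 2,
        dense_full.aperture,
    )

    rng = np.random.default_rng(seed)
    sep = min_separation if min_separation is not None else lam
    half_w = (reference.aperture[0] - lam / 2) / 2
    half_h = (reference.aperture[1] - lam / 2) / 2
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        cand = np.array([rng.uniform(-half_w, half_w), rng.uniform(-half_h, half_h), 0.0])
        attempts += 1
        if attempts > 100000:
            raise InvalidGeometryError("sparse placement failed; relax min separation")
        if placed:
            d = np.linalg.norm(np.asarray(placed)[:, :2] - cand[:2], axis=1)
            if np.min(d) < sep:
                continue
        placed.append(cand)
    sparse = ArrayLayout(
        np.asarray(placed), small, None, float("nan"), float("nan"), reference.aperture
    )
    return dense, sparse


def multilens_252() -> ArrayLayout:
    """The default large-aperture profile: 252 lensed elements (14 x 18),
    5.48 mm pitch, 104 x 82 mm^2 aperture at 1 MHz."""
    layout = build_multilens_array(18, 14, 5.48, ElementSpec(), LensSpec())
    return layout


def default_sequence(rows: int = 18, cols: int = 14) -> SequenceSpec:
    """16-source diverging-wave ultrafast sequence: PRF 5 kHz, 312.5 Hz volume
    rate, 2-cycle pulses, 2 samples per wavelength, 256-volume blocks."""
    return SequenceSpec(
        transmit_element_indices=central_transmit_indices(rows, cols, 4)
    )
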