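"""Synthetic 8-channel transceiver-coil phantom simulator.

Generates paired training data emulating a multi-subject 7T head library:
parametric ellipsoidal head phantoms inside an 8-element transceiver loop
array, producing channel-wise complex transmit (B1+) field maps as ground
truth and CP+-mode receive-weighted localizer images as network input, in
transversal, sagittal and coronal slice orientations.

The field model is analytic — a loop-field distance falloff with a central
brightening term for the magnitude, and an azimuthal phase plus a linear
"wave" phase accrual with distance mimicking RF wavelength effects at 7T.
It is deliberately not a full-wave electromagnetic solution: the goal is a
controllable, seeded generator that poses the same learning problem
(receive profiles resembling transmit profiles, orientation-dependent
patterns, complex noise), not Maxwell fidelity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import ComplexSliceStack, SimulatedPair, ORIENTATIONS
from .model import CP_WEIGHTS, cp_combined


# ---------------------------------------------------------------------------
# Coil array and phantom geometry
# ---------------------------------------------------------------------------


@dataclass
class CoilArrayModel:
    """8-element loop array on a cylinder around the head.

    azimuths: element angles (rad); gains: per-element magnitude scaling;
    radius: cylinder radius (m); loop_radius: element current-loop radius (m);
    wave_phase: linear phase accrual with distance (rad/m), mimicking the
    short RF wavelength in tissue at 7T.
    """

    n_channels: int
    azimuths: np.ndarray
    gains: np.ndarray
    radius: float = 0.14
    loop_radius: float = 0.08
    wave_phase: float = 20.0
    falloff_exponent: float = 1.2
    central_brightening: float = 0.25
    brightening_width: float = 0.06
    z_center: float = 0.0

    def __post_init__(self):
        if self.radius <= 0 or self.radius > 1.0:
            raise ValueError(f"non-physical coil radius {self.radius} m")

    @property
    def positions(self):
        """Element centers, shape (n_channels, 3)."""
        return np.stack(
            [
                self.radius * np.cos(self.azimuths),
                self.radius * np.sin(self.azimuths),
                np.full_like(self.azimuths, self.z_center),
            ],
            axis=1,
        )


def make_coil_array(
    n_channels: int = 8,
    radius: float = 0.14,
    seed: int = 0,
    jitter: bool = True,
) -> CoilArrayModel:
    """Equally spaced loop array with optional seeded per-element
    perturbations (gain +/-10%, small azimuth jitter) mimicking
    inter-session variation."""
    if n_channels < 2:
        raise ValueError(f"need at least 2 channels, got {n_channels}")
    base = 2 * np.pi * np.arange(n_channels) / n_channels
    rng = np.random.default_rng(seed)
    if jitter:
        azim = base + rng.uniform(-np.deg2rad(2), np.deg2rad(2), n_channels)
        gains = 1.0 + rng.uniform(-0.1, 0.1, n_channels)
    else:
        azim, gains = base, np.ones(n_channels)
    return CoilArrayModel(
        n_channels=n_channels, azimuths=azim, gains=gains, radius=radius
    )


@dataclass
class PhantomSubject:
    """Ellipsoidal head phantom with a smooth proton-density field."""

    semi_axes: np.ndarray  # (3,) meters
    center: np.ndarray  # (3,) meters
    pd_coeffs: np.ndarray  # low-order harmonic coefficients, shape (6,)
    seed: int = 0

    def inside(self, xyz):
        u = (xyz - self.center) / self.semi_axes
        return (u ** 2).sum(axis=-1) <= 1.0

    def proton_density(self, xyz):
        """Smooth nonnegative proton density, zero outside the phantom."""
        mask = self.inside(xyz)
        u = (xyz - self.center) / self.semi_axes
        c = self.pd_coeffs
        pd = (
            1.0
            + 0.15 * c[0] * np.sin(np.pi * u[..., 0])
            + 0.15 * c[1] * np.cos(np.pi * u[..., 1])
            + 0.15 * c[2] * np.sin(np.pi * u[..., 2])
            + 0.1 * c[3] * u[..., 0] * u[..., 1]
            + 0.1 * c[4] * (u ** 2).sum(axis=-1)
            + 0.1 * c[5]
        )
        return np.clip(pd, 0.1, None) * mask


def make_phantom_subject(seed: int) -> PhantomSubject:
    """Seeded random head geometry: ellipsoid semi-axes around
    (7.5, 9, 8) cm varied by +/-10%, small center offset, random smooth
    proton-density coefficients."""
    rng = np.random.default_rng(seed)
    semi = np.array([0.075, 0.09, 0.08]) * (1 + rng.uniform(-0.1, 0.1, 3))
    center = rng.uniform(-0.008, 0.008, 3)
    return PhantomSubject(
        semi_axes=semi,
        center=center,
        pd_coeffs=rng.uniform(-1, 1, 6),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Slice geometry
# ---------------------------------------------------------------------------


def slice_coordinates(orientation, positions, shape, spacing):
    """World coordinates (n, H, W, 3) of the voxel centers of a slice stack.

    transversal: rows span anterior-posterior (y), columns left-right (x);
    sagittal: rows span foot-head (z), columns anterior-posterior (y);
    coronal: rows span foot-head (z), columns left-right (x).
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}")
    h, w = shape
    rows = (np.arange(h) - (h - 1) / 2) * spacing
    cols = (np.arange(w) - (w - 1) / 2) * spacing
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = np.zeros((len(positions), h, w, 3))
    for i, p in enumerate(positions):
        if orientation == "transversal":
            out[i, ..., 0], out[i, ..., 1], out[i, ..., 2] = cc, rr, p
        elif orientation == "sagittal":
            out[i, ..., 0], out[i, ..., 1], out[i, ..., 2] = p, cc, rr
        else:  # coronal
            out[i, ..., 0], out[i, ..., 1], out[i, ..., 2] = cc, p, rr
    return out


def default_slice_positions(subject: PhantomSubject, orientation, n_slices):
    """Evenly spaced slice positions covering 90% of the phantom extent
    along the slice-normal axis."""
    axis = {"transversal": 2, "sagittal": 0, "coronal": 1}[orientation]
    half = 0.9 * subject.semi_axes[axis]
    c = subject.center[axis]
    return np.linspace(c - half, c + half, n_slices)


# ---------------------------------------------------------------------------
# Field simulation
# ---------------------------------------------------------------------------


def _channel_fields(xyz, coil: CoilArrayModel, mirror: bool = False):
    """Complex per-channel fields at coordinates xyz (..., 3) -> (..., n_ch).

    mirror=True evaluates the receive-field rule: azimuth-mirrored pattern
    with conjugated wave phase (the transceive "B1- resembles B1+" rule).
    """
    pts = xyz.copy()
    if mirror:
        pts[..., 1] = -pts[..., 1]
    az = np.arctan2(pts[..., 1], pts[..., 0])
    rho_c = np.linalg.norm(pts - np.array([0.0, 0.0, 0.0]), axis=-1)
    fields = np.empty(pts.shape[:-1] + (coil.n_channels,), dtype=np.complex64)
    wave = -coil.wave_phase if mirror else coil.wave_phase
    d0 = coil.loop_radius
    bright = coil.central_brightening * np.exp(
        -(rho_c ** 2) / (2 * coil.brightening_width ** 2)
    )
    for c in range(coil.n_channels):
        d = np.linalg.norm(pts - coil.positions[c], axis=-1)
        mag = coil.gains[c] * ((d0 / (d0 + d)) ** coil.falloff_exponent + bright)
        phase = (coil.azimuths[c] - az) + wave * d
        fields[..., c] = mag * np.exp(1j * phase)
    return fields


def simulate_b1_fields(
    subject: PhantomSubject,
    coil: CoilArrayModel,
    orientation: str,
    slice_positions,
    shape=(64, 48),
    spacing=0.004,
) -> ComplexSliceStack:
    """Ground-truth channel-wise transmit fields on a slice stack.

    Returns a (n, H, W, 8) complex stack with the phantom tissue mask; the
    fields themselves are smooth and defined on the whole grid.
    """
    slice_positions = np.atleast_1d(np.asarray(slice_positions, dtype=float))
    xyz = slice_coordinates(orientation, slice_positions, shape, spacing)
    mask = subject.inside(xyz)
    if not mask.any():
        warnings.warn("slice positions do not intersect the phantom; empty stack")
    b1 = _channel_fields(xyz, coil, mirror=False)
    return ComplexSliceStack(
        b1,
        subject=f"s{subject.seed}",
        orientation=orientation,
        mask=mask,
        positions=slice_positions,
        spacing=spacing,
    )


def simulate_receive_fields(
    subject, coil, orientation, slice_positions, shape=(64, 48), spacing=0.004
) -> ComplexSliceStack:
    """Receive (B1-) fields: mirrored-azimuth copies of the transmit fields
    with conjugated wave phase (the transceive-coil rule)."""
    slice_positions = np.atleast_1d(np.asarray(slice_positions, dtype=float))
    xyz = slice_coordinates(orientation, slice_positions, shape, spacing)
    mask = subject.inside(xyz)
    bm = _channel_fields(xyz, coil, mirror=True)
    return ComplexSliceStack(
        bm,
        subject=f"s{subject.seed}",
        orientation=orientation,
        mask=mask,
        positions=slice_positions,
        spacing=spacing,
    )


def simulate_localizer(
    subject: PhantomSubject,
    coil: CoilArrayModel,
    b1: ComplexSliceStack,
    mode_weights=None,
    snr: float = 50.0,
    seed: int = 0,
    nominal_fa_deg: float = 25.0,
) -> ComplexSliceStack:
    """CP+-mode localizer images given ground-truth transmit fields.

    Per receive channel j:
        signal_j = proton_density * sin(FA_nom * |sum_k w_k B1+_k| / ref) * B1-_j
    plus complex Gaussian noise scaled to the requested image SNR (mean
    in-mask signal magnitude / per-component noise standard deviation; pass
    ``snr=np.inf`` to disable). The 9th channel is the root-sum-of-squares
    magnitude of the (noisy) receive channels, stored as a purely real
    image. The reference scaling maps the subject's mean in-mask combined
    field to the nominal flip angle.
    """
    if snr <= 0:
        raise ValueError(f"snr must be positive, got {snr}")
    if b1.positions is None or b1.spacing is None:
        raise ValueError("B1 stack lacks slice geometry (positions/spacing)")
    if mode_weights is None:
        mode_weights = CP_WEIGHTS[: b1.n_channels]
    mode_weights = np.asarray(mode_weights, dtype=np.complex64)
    xyz = slice_coordinates(
        b1.orientation, np.atleast_1d(b1.positions), b1.data.shape[1:3], b1.spacing
    )
    mask = subject.inside(xyz)
    brx = _channel_fields(xyz, coil, mirror=True)
    combined = np.tensordot(b1.data, mode_weights, axes=([-1], [0]))
    pd = subject.proton_density(xyz)
    ref = np.abs(combined)[mask].mean() if mask.any() else 1.0
    fa = np.deg2rad(nominal_fa_deg) * np.abs(combined) / max(ref, 1e-12)
    signal = (pd * np.sin(fa))[..., None] * brx
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sig_level = np.abs(signal)[mask].mean() if mask.any() else 1.0
        sigma = sig_level / snr
        signal = signal + sigma * (
            rng.standard_normal(signal.shape) + 1j * rng.standard_normal(signal.shape)
        )
    rss = np.sqrt((np.abs(signal) ** 2).sum(axis=-1))
    loc = np.concatenate(
        [signal.astype(np.complex64), rss[..., None].astype(np.complex64)], axis=-1
    )
    return ComplexSliceStack(
        loc,
        subject=b1.subject,
        orientation=b1.orientation,
        mask=mask,
        positions=b1.positions,
        spacing=b1.spacing,
    )


def generate_library(
    n_subjects: int = 15,
    orientations=ORIENTATIONS,
    slices_per_orientation: int = 12,
    snr: float = 50.0,
    seed: int = 0,
    shape=(64, 48),
    spacing: float = 0.004,
    nominal_fa_deg: float = 25.0,
    coil_jitter: bool = True,
):
    """Generate a multi-subject paired library.

    Returns {subject_id: {orientation: SimulatedPair}}. Every subject has
    every orientation; the actual number of slices varies mildly with head
    size around `slices_per_orientation`. All randomness is funneled
    through one seeded generator.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    for o in orientations:
        if o not in ORIENTATIONS:
            raise ValueError(f"invalid orientation label {o!r}")
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(3 * n_subjects + 1)
    library = {}
    for i in range(n_subjects):
        subj_seed = int(child[3 * i] % (2 ** 31))
        coil_seed = int(child[3 * i + 1] % (2 ** 31))
        noise_seed = int(child[3 * i + 2] % (2 ** 31))
        subject = make_phantom_subject(subj_seed)
        coil = make_coil_array(seed=coil_seed, jitter=coil_jitter)
        sid = f"subject{i:02d}"
        library[sid] = {}
        for k, orient in enumerate(orientations):
            axis = {"transversal": 2, "sagittal": 0, "coronal": 1}[orient]
            rel = subject.semi_axes[axis] / np.array([0.075, 0.09, 0.08])[axis]
            n_slices = max(3, int(round(slices_per_orientation * rel)))
            positions = default_slice_positions(subject, orient, n_slices)
            pair = simulate_pair(
                subject,
                coil,
                orient,
                positions,
                shape=shape,
                spacing=spacing,
                snr=snr,
                seed=noise_seed + k,
                nominal_fa_deg=nominal_fa_deg,
            )
            pair.localizer.subject = sid
            pair.b1.subject = sid
            library[sid][orient] = pair
    return library


def simulate_pair(
    subject,
    coil,
    orientation,
    slice_positions,
    shape=(64, 48),
    spacing=0.004,
    snr=50.0,
    seed=0,
    nominal_fa_deg=25.0,
    mode_weights=None,
) -> SimulatedPair:
    """Simulate one (localizer, ground-truth B1+) pair for a slice stack."""
    b1 = simulate_b1_fields(subject, coil, orientation, slice_positions, shape, spacing)
    loc = simulate_localizer(
        subject,
        coil,
        b1,
        mode_weights=mode_weights,
        snr=snr,
        seed=seed,
        nominal_fa_deg=nominal_fa_deg,
    )
    meta = {
        "orientation": orientation,
        "positions": np.atleast_1d(np.asarray(slice_positions, float)).tolist(),
        "spacing": float(spacing),
        "snr": None if not np.isfinite(snr) else float(snr),
        "seed": int(seed),
        "nominal_fa_deg": float(nominal_fa_deg),
    }
    return SimulatedPair(localizer=loc, b1=b1, meta=meta)
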