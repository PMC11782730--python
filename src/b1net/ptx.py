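"""Parallel-transmit pulse design on channel-wise B1+ maps.

Downstream consumers of the estimated maps: CP+/shim channel combination,
static phase-only RF shimming with a coefficient-of-variation cost and an
efficiency constraint, kt-point pulse design (greedy k-space location
selection + magnitude-least-squares variable exchange with Tikhonov
regularization), the small-tip-angle (STA) forward model, and a hard-pulse
Bloch simulator for flip-angle maps.

Units: B1+ maps are in normalized units (the per-subject normalization of
the training pipeline); ``B1_SCALE_T`` converts one normalized unit to
tesla so that gamma * tau * B1 is an angle in radians. RF weights are
dimensionless multipliers of the channel fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import minimize

GAMMA = 267.522e6  # rad / (s T), proton gyromagnetic ratio
B1_SCALE_T = 1e-6  # tesla per normalized B1 unit

from .model import CP_WEIGHTS


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class ShimSetting:
    """Static per-channel complex weights."""

    weights: np.ndarray
    constraint: str = "phase_only"  # or "unconstrained"
    achieved_cv: float = None
    achieved_efficiency: float = None
    feasible: bool = True

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.complex128)
        if self.constraint == "phase_only" and not np.allclose(
            np.abs(self.weights), 1.0, atol=1e-6
        ):
            raise ValueError("phase_only shim requires unit-magnitude weights")


def cp_shim(n_channels: int = 8) -> ShimSetting:
    """CP+ mode: channel k driven with phase -2 pi k / n."""
    return ShimSetting(weights=CP_WEIGHTS[:n_channels].astype(np.complex128))


@dataclass
class KtPointPulse:
    """kt-point pulse: a train of hard subpulses at excitation-k-space
    locations reached by gradient blips."""

    k_locations: np.ndarray  # (n_points, 3) rad/m
    rf_weights: np.ndarray  # (n_points, n_channels) complex
    subpulse_duration: float = 100e-6  # s
    blip_duration: float = 50e-6  # s
    target_fa_deg: float = 10.0
    predicted_cv: float = None

    def __post_init__(self):
        self.k_locations = np.atleast_2d(np.asarray(self.k_locations, dtype=float))
        self.rf_weights = np.atleast_2d(np.asarray(self.rf_weights, dtype=np.complex128))
        if not np.isfinite(self.rf_weights).all():
            raise ValueError("non-finite RF weights")
        if self.subpulse_duration <= 0 or self.blip_duration <= 0:
            raise ValueError("durations must be positive")

    @property
    def n_points(self):
        return self.k_locations.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "k_locations_rad_per_m": self.k_locations.tolist(),
                "rf_weights_re": self.rf_weights.real.tolist(),
                "rf_weights_im": self.rf_weights.imag.tolist(),
                "subpulse_duration_s": self.subpulse_duration,
                "blip_duration_s": self.blip_duration,
                "target_fa_deg": self.target_fa_deg,
                "predicted_cv": self.predicted_cv,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "KtPointPulse":
        d = json.loads(text)
        return cls(
            k_locations=np.array(d["k_locations_rad_per_m"]),
            rf_weights=np.array(d["rf_weights_re"]) + 1j * np.array(d["rf_weights_im"]),
            subpulse_duration=d["subpulse_duration_s"],
            blip_duration=d["blip_duration_s"],
            target_fa_deg=d["target_fa_deg"],
            predicted_cv=d.get("predicted_cv"),
        )


@dataclass
class FAMap:
    """Flip-angle map (degrees) with excitation phase (radians)."""

    fa_deg: np.ndarray
    phase_rad: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        if (np.asarray(self.fa_deg) < -1e-9).any():
            raise ValueError("flip angles must be nonnegative")


# ---------------------------------------------------------------------------
# Channel combination + statistics
# ---------------------------------------------------------------------------


def combine_channels(b1, shim) -> np.ndarray:
    """Voxelwise sum_k b_k B1+_k of an (..., n_channels) complex array.

    The magnitude of the result is the MOS map, its angle the POS map.
    """
    b1 = np.asarray(b1)
    w = shim.weights if isinstance(shim, ShimSetting) else np.asarray(shim)
    if b1.shape[-1] != len(w):
        raise ValueError(
            f"channel mismatch: maps have {b1.shape[-1]} channels, shim has {len(w)}"
        )
    return np.tensordot(b1, w, axes=([-1], [0]))


def coefficient_of_variation(fa, mask=None) -> float:
    """Population std / mean over the masked voxels."""
    x = fa.fa_deg if isinstance(fa, FAMap) else np.asarray(fa)
    if mask is None:
        mask = np.ones(x.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    v = x[mask]
    mean = v.mean()
    if mean == 0:
        raise ValueError("zero-mean flip angle: CV undefined")
    return float(v.std() / mean)


def shim_efficiency(b1, weights, mask) -> float:
    """mean(|sum_k b_k B1k|) / mean(sum_k |B1k|) over the mask."""
    mos = np.abs(combine_channels(b1, weights))
    full = np.abs(np.asarray(b1)).sum(axis=-1)
    return float(mos[mask].mean() / full[mask].mean())


# ---------------------------------------------------------------------------
# Static phase-only shimming
# ---------------------------------------------------------------------------


def design_phase_shim(
    b1,
    mask,
    efficiency_target: float = 0.6,
    seed: int = 0,
    n_starts: int = 8,
    efficiency_scope: str = "center_slice",
    tol: float = 0.01,
) -> ShimSetting:
    """Phase-only shim minimizing the CV of the combined magnitude subject
    to a fixed efficiency.

    The cost is the coefficient of variation of |sum_k e^{i phi_k} B1k|
    over the mask; the constraint fixes mean(MOS)/mean(sum|B1k|) at
    ``efficiency_target`` (relative tolerance ``tol``), evaluated on the
    center slice by default (``efficiency_scope="volume"`` uses all masked
    voxels). Multi-start local optimization (SLSQP), the CP+ phases always
    among the start points; deterministic for a fixed seed. If no start
    satisfies the constraint the best attempt is returned with
    ``feasible=False``.
    """
    b1 = np.asarray(b1)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if not 0 < efficiency_target <= 1:
        raise ValueError("efficiency target must be in (0, 1]")
    nc = b1.shape[-1]
    vox = b1[mask]  # (Nvox, nc)
    if efficiency_scope == "center_slice" and b1.ndim == 4 and b1.shape[0] > 1:
        c = b1.shape[0] // 2
        evox = b1[c][mask[c]]
    elif efficiency_scope in ("center_slice", "volume"):
        evox = vox
    else:
        raise ValueError(f"unknown efficiency scope {efficiency_scope!r}")
    efull = np.abs(evox).sum(axis=-1).mean()

    if nc == 1:
        w = np.ones(1, dtype=np.complex128)
        mos = np.abs(vox[:, 0])
        return ShimSetting(
            weights=w,
            achieved_cv=float(mos.std() / mos.mean()),
            achieved_efficiency=1.0,
            feasible=abs(1.0 - efficiency_target) <= tol * efficiency_target,
        )

    def mos_of(phi):
        w = np.exp(1j * np.concatenate([[0.0], phi]))
        return np.abs(vox @ w), w

    def cv_of(phi):
        mos, _ = mos_of(phi)
        return mos.std() / mos.mean()

    def eff_of(phi):
        w = np.exp(1j * np.concatenate([[0.0], phi]))
        return np.abs(evox @ w).mean() / efull

    rng = np.random.default_rng(seed)
    cp_phi = np.angle(CP_WEIGHTS[:nc].astype(np.complex128) / CP_WEIGHTS[0])[1:]
    starts = [cp_phi] + [rng.uniform(-np.pi, np.pi, nc - 1) for _ in range(n_starts - 1)]

    best = None
    for x0 in starts:
        lo = efficiency_target * (1 - tol)
        hi = efficiency_target * (1 + tol)
        res = minimize(
            cv_of,
            np.asarray(x0, dtype=np.float64),
            method="SLSQP",
            constraints=[
                {"type": "ineq", "fun": lambda p: eff_of(p) - lo},
                {"type": "ineq", "fun": lambda p: hi - eff_of(p)},
            ],
            options={"maxiter": 200, "ftol": 1e-10},
        )
        eff = eff_of(res.x)
        ok = lo - 1e-6 <= eff <= hi + 1e-6
        key = (not ok, res.fun)
        if best is None or key < best[0]:
            best = (key, res.x, ok)
    _, phi, ok = best
    mos, w = mos_of(phi)
    return ShimSetting(
        weights=w,
        achieved_cv=float(mos.std() / mos.mean()),
        achieved_efficiency=float(eff_of(phi)),
        feasible=bool(ok),
    )


# ---------------------------------------------------------------------------
# kt-point design
# ---------------------------------------------------------------------------


def _system_matrix(b1_vox, pos_vox, k_locations, tau):
    """STA system matrix (Nvox, n_points * n_channels):
    A[r, (n, c)] = gamma tau B1c(r) e^{i r . k_n} (radians per unit weight)."""
    phase = np.exp(1j * (pos_vox @ np.asarray(k_locations).T))  # (N, n_points)
    scale = GAMMA * tau * B1_SCALE_T
    return scale * (phase[:, :, None] * b1_vox[:, None, :]).reshape(
        len(b1_vox), -1
    )


def solve_mls(A, target, reg=1e-6, n_iter=30, phase_init=None):
    """Magnitude-least-squares via variable exchange.

    Minimizes || |A w| - target ||^2 + reg ||w||^2 by alternating a
    Tikhonov-regularized complex least-squares solve with a phase update
    phi = angle(A w). Returns (w, cost).
    """
    n = A.shape[1]
    AtA = A.conj().T @ A + reg * np.eye(n)
    phase = np.ones(len(A), dtype=np.complex128) if phase_init is None else phase_init
    w = None
    for _ in range(n_iter):
        rhs = A.conj().T @ (target * phase)
        w = np.linalg.solve(AtA, rhs)
        pred = A @ w
        mag = np.abs(pred)
        phase = np.where(mag > 0, pred / np.maximum(mag, 1e-30), 1.0)
    cost = float(((np.abs(A @ w) - target) ** 2).sum() + reg * (np.abs(w) ** 2).sum())
    return w, cost


def candidate_k_grid(k_max: float = 30.0) -> np.ndarray:
    """Symmetric low-frequency 3x3x3 candidate grid (rad/m), k=0 included."""
    axis = np.array([-k_max, 0.0, k_max])
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
    order = np.argsort(np.linalg.norm(grid, axis=1), kind="stable")
    return grid[order]


def design_ktpoints(
    b1,
    mask,
    positions,
    n_points: int = 4,
    target_fa_deg: float = 10.0,
    reg: float = 1e-6,
    seed: int = 0,
    subpulse_duration: float = 100e-6,
    blip_duration: float = 50e-6,
    k_max: float = 30.0,
    n_iter: int = 30,
) -> KtPointPulse:
    """Greedy kt-point design on a multi-slice B1+ volume.

    k-space locations are selected greedily from a symmetric 3x3x3
    low-frequency candidate grid (k=0 first by construction); for every
    candidate set the RF weights are found by magnitude-least-squares
    variable exchange with Tikhonov regularization, initialized with the
    CP+ phase pattern. Returns the pulse with its predicted-FA CV.
    """
    b1 = np.asarray(b1)
    mask = np.asarray(mask, dtype=bool)
    positions = np.asarray(positions, dtype=float)
    if not mask.any():
        raise ValueError("empty mask")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    b1_vox = b1[mask]
    pos_vox = positions[mask]
    nc = b1.shape[-1]
    target = np.full(len(b1_vox), np.deg2rad(target_fa_deg))
    cp_phase = None
    # CP+-combined phase as the variable-exchange initialization
    cp = b1_vox @ CP_WEIGHTS[:nc]
    cp_phase = np.where(np.abs(cp) > 0, cp / np.maximum(np.abs(cp), 1e-30), 1.0)

    candidates = candidate_k_grid(k_max)
    chosen: list = []
    best_w = None
    for _ in range(n_points):
        best = None
        for cand in candidates:
            if any(np.allclose(cand, c) for c in chosen):
                continue
            ks = np.array(chosen + [cand])
            A = _system_matrix(b1_vox, pos_vox, ks, subpulse_duration)
            w, cost = solve_mls(A, target, reg=reg, n_iter=n_iter, phase_init=cp_phase)
            if best is None or cost < best[0] - 1e-15:
                best = (cost, cand, w)
        chosen.append(best[1])
        best_w = best[2]
    ks = np.array(chosen)
    weights = best_w.reshape(len(ks), nc)
    pulse = KtPointPulse(
        k_locations=ks,
        rf_weights=weights,
        subpulse_duration=subpulse_duration,
        blip_duration=blip_duration,
        target_fa_deg=target_fa_deg,
    )
    theta = sta_forward(pulse, b1, positions)
    fa = np.abs(theta)
    pulse.predicted_cv = float(fa[mask].std() / fa[mask].mean())
    return pulse


def rf_power(pulse: KtPointPulse) -> float:
    """Total RF power surrogate: sum |w|^2 * subpulse duration."""
    return float((np.abs(pulse.rf_weights) ** 2).sum() * pulse.subpulse_duration)


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------


def sta_forward(pulse: KtPointPulse, b1, positions) -> np.ndarray:
    """Small-tip-angle excitation profile (complex radians):

        theta(r) = gamma tau sum_n sum_c w_nc B1c(r) e^{i r . k_n}

    FA in degrees is |theta| * 180 / pi; the excitation phase is its angle.
    """
    b1 = np.asarray(b1)
    positions = np.asarray(positions, dtype=float)
    if positions.shape[:-1] != b1.shape[:-1] or positions.shape[-1] != 3:
        raise ValueError(
            f"positions {positions.shape} do not match B1 grid {b1.shape}"
        )
    if b1.shape[-1] != pulse.rf_weights.shape[1]:
        raise ValueError("channel count mismatch between pulse and B1 maps")
    scale = GAMMA * pulse.subpulse_duration * B1_SCALE_T
    theta = np.zeros(b1.shape[:-1], dtype=np.complex128)
    for n in range(pulse.n_points):
        bn = b1 @ pulse.rf_weights[n]
        theta += bn * np.exp(1j * (positions @ pulse.k_locations[n]))
    return scale * theta


def bloch_simulate_fa(pulse: KtPointPulse, b1, positions) -> FAMap:
    """Hard-pulse Bloch simulation of the kt-point pulse (relaxation
    neglected).

    Each subpulse rotates the magnetization about the instantaneous
    transverse effective field (the combined complex B1 of that subpulse);
    the gradient blips that realize the k-space steps enter as the
    position-dependent phase r . k_n of each subpulse's rotation axis,
    which is the hard-pulse equivalent of the interleaved z-precession.
    The flip angle is arccos(Mz) of the final magnetization.
    """
    b1 = np.asarray(b1)
    positions = np.asarray(positions, dtype=float)
    if positions.shape[:-1] != b1.shape[:-1] or positions.shape[-1] != 3:
        raise ValueError(
            f"positions {positions.shape} do not match B1 grid {b1.shape}"
        )
    shp = b1.shape[:-1]
    mx = np.zeros(shp)
    my = np.zeros(shp)
    mz = np.ones(shp)
    scale = GAMMA * pulse.subpulse_duration * B1_SCALE_T
    for n in range(pulse.n_points):
        bn = b1 @ pulse.rf_weights[n]
        alpha = scale * np.abs(bn)
        psi = np.angle(bn) + positions @ pulse.k_locations[n]
        ax, ay = np.cos(psi), np.sin(psi)
        ca, sa = np.cos(alpha), np.sin(alpha)
        # Rodrigues rotation about the unit transverse axis (ax, ay, 0)
        dot = ax * mx + ay * my
        nmx = ca * mx + sa * (ay * mz) + (1 - ca) * dot * ax
        nmy = ca * my + sa * (-ax * mz) + (1 - ca) * dot * ay
        nmz = ca * mz + sa * (ax * my - ay * mx)
        mx, my, mz = nmx, nmy, nmz
    fa = np.rad2deg(np.arccos(np.clip(mz, -1.0, 1.0)))
    phase = np.arctan2(my, mx)
    return FAMap(fa_deg=fa, phase_rad=phase)
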