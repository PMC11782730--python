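"""Desk-scale reproduction study: the end-to-end experiment harness.

Runs the whole calibration chain on the synthetic library at the scaled
profile (64 x 48 grid at 4 mm, base 8 features, short Adam schedule with a
proportionally larger starting step): subject-wise cross-validation fold,
orientation-specific and all-orientation model training, held-out map
quality, the orientation-transfer comparison, and the downstream pulse
design comparison (CP+ mode vs. kt-points designed on ground-truth and on
predicted maps, Bloch-evaluated on the ground truth).

Problem sizes (15 subjects, 6 slices per orientation, 64 x 48 grid,
30 / 6 training epochs) are the package's desk-scale study conditions;
the full-size profile (128 x 96, base 16, 1000 epochs) is available through
the same interfaces.
"""

from __future__ import annotations

import numpy as np

from .metrics import magnitude_rel_error, phase_abs_diff, ssim
from .model import (
    CP_WEIGHTS,
    ComplexB1Mapper,
    collect_slices,
    make_subject_folds,
    normalize_dataset,
)
from .phantom import generate_library, slice_coordinates
from .ptx import (
    KtPointPulse,
    bloch_simulate_fa,
    coefficient_of_variation,
    design_ktpoints,
    design_phase_shim,
    sta_forward,
)

SCALED_SHAPE = (64, 48)
SCALED_SPACING = 0.004
SLICES_PER_ORIENTATION = 6
N_SUBJECTS = 15
SNR = 50.0
EPOCHS_SINGLE = 30  # single-orientation model (~72 training slices)
EPOCHS_ALL = 6  # all-orientation model (~216 training slices)
LR0_SCALED = 5e-4
LR_DECAY_SCALED = 0.04  # compresses the full schedule's total decay


def build_study_library(seed: int):
    """Seeded 15-subject library at the scaled profile, normalized."""
    lib = generate_library(
        n_subjects=N_SUBJECTS,
        slices_per_orientation=SLICES_PER_ORIENTATION,
        snr=SNR,
        seed=seed,
        shape=SCALED_SHAPE,
        spacing=SCALED_SPACING,
    )
    lib, scales = normalize_dataset(lib)
    return lib, scales


def scaled_mapper(seed: int, epochs: int) -> ComplexB1Mapper:
    return ComplexB1Mapper(
        height=SCALED_SHAPE[0],
        width=SCALED_SHAPE[1],
        base_features=8,
        lr0=LR0_SCALED,
        lr_decay=LR_DECAY_SCALED,
        epochs=epochs,
        seed=seed,
    )


def train_fold_models(lib, seed: int, epochs_single=EPOCHS_SINGLE, epochs_all=EPOCHS_ALL):
    """Fold 0 of the subject-wise 5-fold split: train the transversal-only
    and the all-orientation model on the same 12 training subjects."""
    split = make_subject_folds(sorted(lib), 5, seed=seed)
    train_ids, test_ids = split.folds[0]
    Xtr, Ytr, _, _ = collect_slices(lib, train_ids, ["transversal"])
    est_tra = scaled_mapper(seed, epochs_single).fit(Xtr, Ytr)
    Xall, Yall, _, _ = collect_slices(lib, train_ids)
    est_all = scaled_mapper(seed, epochs_all).fit(Xall, Yall)
    return {
        "split": split,
        "train_ids": train_ids,
        "test_ids": test_ids,
        "est_tra": est_tra,
        "est_all": est_all,
    }


def heldout_map_quality(est, lib, subject_ids, orientation="transversal"):
    """Per-slice map quality of a model on held-out subjects."""
    X, Y, M, _ = collect_slices(lib, subject_ids, [orientation])
    pred = est.predict(X)
    return {
        "complex_ssim": float(
            np.mean([ssim(pred[i], Y[i], "complex") for i in range(len(pred))])
        ),
        "rel_error_pct": float(
            np.mean(
                [
                    magnitude_rel_error(pred[i], Y[i], M[i][..., None])
                    for i in range(len(pred))
                ]
            )
        ),
        "phase_error_deg": float(
            np.mean(
                [phase_abs_diff(pred[i], Y[i], M[i][..., None]) for i in range(len(pred))]
            )
        ),
        "n_slices": int(len(pred)),
    }


def orientation_transfer(models, lib):
    """Complex SSIM of the transversal-trained and all-orientation models on
    held-out transversal and coronal slices, with the transfer gaps."""
    out = {}
    for tag in ("est_tra", "est_all"):
        est = models[tag]
        for orient in ("transversal", "coronal"):
            q = heldout_map_quality(est, lib, models["test_ids"], orient)
            out[f"{tag[4:]}_{orient}_ssim"] = q["complex_ssim"]
    out["gap_tra_model"] = out["tra_transversal_ssim"] - out["tra_coronal_ssim"]
    out["gap_all_model"] = out["all_transversal_ssim"] - out["all_coronal_ssim"]
    return out


def _stack_positions(pair):
    return slice_coordinates(
        pair.b1.orientation,
        np.atleast_1d(pair.b1.positions),
        pair.b1.data.shape[1:3],
        pair.b1.spacing,
    )


def cp_mode_pulse(b1, mask, pos, target_fa_deg=10.0) -> KtPointPulse:
    """Single k=0 pulse driving the CP+ mode, scaled to the target mean FA."""
    pulse = KtPointPulse(
        k_locations=np.zeros((1, 3)),
        rf_weights=CP_WEIGHTS[None, :].astype(np.complex128),
        target_fa_deg=target_fa_deg,
    )
    theta = sta_forward(pulse, b1, pos)
    pulse.rf_weights = pulse.rf_weights * (
        np.deg2rad(target_fa_deg) / np.abs(theta)[mask].mean()
    )
    return pulse


def pulse_design_comparison(models, lib, n_points=4, target_fa_deg=10.0):
    """Per held-out subject: Bloch-evaluated flip-angle CV (on ground truth)
    for the CP+ mode, kt-points designed on ground truth, and kt-points
    designed on the predicted maps."""
    est = models["est_tra"]
    rows = []
    for sid in models["test_ids"]:
        pair = lib[sid]["transversal"]
        b1, mask = pair.b1.data.astype(np.complex128), pair.b1.mask
        pos = _stack_positions(pair)
        pred = est.predict(pair.localizer.data).astype(np.complex128)

        cp = cp_mode_pulse(b1, mask, pos, target_fa_deg)
        cv_cp = coefficient_of_variation(bloch_simulate_fa(cp, b1, pos), mask)

        p_gt = design_ktpoints(b1, mask, pos, n_points=n_points, target_fa_deg=target_fa_deg)
        cv_gt = coefficient_of_variation(bloch_simulate_fa(p_gt, b1, pos), mask)

        p_pr = design_ktpoints(pred, mask, pos, n_points=n_points, target_fa_deg=target_fa_deg)
        cv_pr = coefficient_of_variation(bloch_simulate_fa(p_pr, b1, pos), mask)

        rows.append(
            {
                "subject": sid,
                "cv_cp": cv_cp,
                "cv_kt_gt": cv_gt,
                "cv_kt_pred": cv_pr,
                "reduction_gt_vs_cp": 1.0 - cv_gt / cv_cp,
            }
        )
    return rows


def shim_study(lib, subject_ids, efficiency_target=0.6, seed=0):
    """Per held-out transversal slice: phase-only shim at the efficiency
    target vs. the CP+ mode."""
    rows = []
    for sid in subject_ids:
        pair = lib[sid]["transversal"]
        for i in range(pair.b1.n_slices):
            b1 = pair.b1.data[i : i + 1].astype(np.complex128)
            mask = pair.b1.mask[i : i + 1]
            shim = design_phase_shim(
                b1, mask, efficiency_target=efficiency_target, seed=seed
            )
            mos_cp = np.abs((b1 @ CP_WEIGHTS)[mask])
            rows.append(
                {
                    "subject": sid,
                    "slice": i,
                    "cv_shim": shim.achieved_cv,
                    "cv_cp": float(mos_cp.std() / mos_cp.mean()),
                    "efficiency": shim.achieved_efficiency,
                    "feasible": shim.feasible,
                }
            )
    return rows


def small_tip_consistency(lib, subject_id, target_fa_deg=5.0):
    """Max per-voxel relative deviation between Bloch and STA flip angles
    for a designed pulse at a small target flip angle."""
    pair = lib[subject_id]["transversal"]
    b1, mask = pair.b1.data.astype(np.complex128), pair.b1.mask
    pos = _stack_positions(pair)
    pulse = design_ktpoints(b1, mask, pos, n_points=4, target_fa_deg=target_fa_deg)
    sta_fa = np.rad2deg(np.abs(sta_forward(pulse, b1, pos)))
    bloch_fa = bloch_simulate_fa(pulse, b1, pos).fa_deg
    rel = np.abs(bloch_fa - sta_fa)[mask] / np.maximum(sta_fa[mask], 1e-9)
    return float(rel.max())


def run_study(seed: int):
    """The full desk-scale study; returns a flat result dictionary."""
    lib, _ = build_study_library(seed)
    models = train_fold_models(lib, seed)
    heldout = heldout_map_quality(models["est_tra"], lib, models["test_ids"])
    orient = orientation_transfer(models, lib)
    pulses = pulse_design_comparison(models, lib)
    shims = shim_study(lib, models["test_ids"], seed=seed)
    smalltip = small_tip_consistency(lib, models["test_ids"][0])
    return {
        "library": lib,
        "models": models,
        "heldout": heldout,
        "orientation": orient,
        "pulses": pulses,
        "shims": shims,
        "smalltip_max_rel_dev": smalltip,
    }
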