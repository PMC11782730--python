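"""Dataset, configuration and artifact I/O.

The paired-library HDF5 layout is::

    /                          attrs: schema_version, seed, config_json
    /subjects/<id>/<orientation>/
        localizer_re, localizer_im   float32 (n, H, W, 9)
        b1_re, b1_im                 float32 (n, H, W, 8)
        mask                         uint8   (n, H, W)
        attrs: orientation, positions, spacing, snr, seed, nominal_fa_deg

Complex arrays are always stored as paired real arrays. Configurations are
YAML mappings with blocks for the simulator, network, training, metrics and
pulse design; every artifact written by the command-line layer embeds the
seed and a hash of the generating configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .containers import ComplexSliceStack, SimulatedPair

SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "simulator": {
        "n_subjects": 15,
        "orientations": ["transversal", "sagittal", "coronal"],
        "slices_per_orientation": 6,
        "snr": 50.0,
        "shape": [64, 48],
        "spacing": 0.004,
        "nominal_fa_deg": 25.0,
    },
    "network": {
        "height": 64,
        "width": 48,
        "base_features": 8,
        "n_stages": 4,
        "dropout_rate": 0.1,
        "variant": "complex",
    },
    "train": {
        "lr0": 5e-4,
        "lr_decay": 0.04,
        "epochs": 30,
        "batch_size": 1,
        "lambda_l2": 1.0,
        "orientations": ["transversal"],
    },
    "pulse_design": {
        "n_points": 4,
        "target_fa_deg": 10.0,
        "reg": 1e-6,
        "efficiency_target": 0.6,
    },
    "crossval": {"k": 5},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def save_config(cfg: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Library HDF5
# ---------------------------------------------------------------------------


def write_library(library, path, config=None, seed=None):
    """Write a {subject: {orientation: SimulatedPair}} library to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if seed is not None:
            f.attrs["seed"] = int(seed)
        if config is not None:
            f.attrs["config_json"] = json.dumps(config, sort_keys=True, default=str)
            f.attrs["config_hash"] = config_hash(config)
        subs = f.create_group("subjects")
        for sid, pairs in library.items():
            gs = subs.create_group(sid)
            for orient, pair in pairs.items():
                g = gs.create_group(orient)
                loc, b1 = pair.localizer.data, pair.b1.data
                g.create_dataset("localizer_re", data=loc.real.astype(np.float32))
                g.create_dataset("localizer_im", data=loc.imag.astype(np.float32))
                g.create_dataset("b1_re", data=b1.real.astype(np.float32))
                g.create_dataset("b1_im", data=b1.imag.astype(np.float32))
                g.create_dataset("mask", data=pair.b1.mask.astype(np.uint8))
                g.attrs["orientation"] = orient
                for key, val in pair.meta.items():
                    if val is not None:
                        g.attrs[key] = val


def read_library(path):
    """Read a paired library written by :func:`write_library`.

    Raises a clear schema error for foreign or truncated files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"{path} is not a readable HDF5 file: {exc}") from None
    with f:
        version = f.attrs.get("schema_version")
        if version is None or "subjects" not in f:
            raise ValueError(
                f"{path} is not a paired-library file (missing schema_version "
                "or /subjects group)"
            )
        if str(version) != SCHEMA_VERSION:
            raise ValueError(
                f"schema version mismatch: file has {version!r}, "
                f"reader supports {SCHEMA_VERSION!r}"
            )
        library = {}
        for sid, gs in f["subjects"].items():
            library[sid] = {}
            for orient, g in gs.items():
                required = ("localizer_re", "localizer_im", "b1_re", "b1_im", "mask")
                missing = [k for k in required if k not in g]
                if missing:
                    raise ValueError(
                        f"group /subjects/{sid}/{orient} is missing datasets {missing}"
                    )
                loc = g["localizer_re"][()] + 1j * g["localizer_im"][()]
                b1 = g["b1_re"][()] + 1j * g["b1_im"][()]
                mask = g["mask"][()].astype(bool)
                meta = {k: _attr(v) for k, v in g.attrs.items()}
                pos = meta.get("positions")
                positions = np.asarray(pos) if pos is not None else None
                spacing = meta.get("spacing")
                library[sid][orient] = SimulatedPair(
                    localizer=ComplexSliceStack(
                        loc, subject=sid, orientation=orient, mask=mask,
                        positions=positions, spacing=spacing,
                    ),
                    b1=ComplexSliceStack(
                        b1, subject=sid, orientation=orient, mask=mask,
                        positions=positions, spacing=spacing,
                    ),
                    meta=meta,
                )
        return library


def _attr(v):
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, np.generic):
        return v.item()
    return v


# ---------------------------------------------------------------------------
# Other artifacts
# ---------------------------------------------------------------------------


def write_predictions(preds, path, config=None, seed=None):
    """preds: {subject: {orientation: complex array (n, H, W, 8)}}."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if seed is not None:
            f.attrs["seed"] = int(seed)
        if config is not None:
            f.attrs["config_hash"] = config_hash(config)
        subs = f.create_group("subjects")
        for sid, by_orient in preds.items():
            gs = subs.create_group(sid)
            for orient, arr in by_orient.items():
                g = gs.create_group(orient)
                g.create_dataset("pred_re", data=np.asarray(arr).real.astype(np.float32))
                g.create_dataset("pred_im", data=np.asarray(arr).imag.astype(np.float32))


def read_predictions(path):
    with h5py.File(path, "r") as f:
        if "subjects" not in f:
            raise ValueError(f"{path} is not a predictions file")
        out = {}
        for sid, gs in f["subjects"].items():
            out[sid] = {}
            for orient, g in gs.items():
                out[sid][orient] = (g["pred_re"][()] + 1j * g["pred_im"][()]).astype(
                    np.complex64
                )
        return out


def export_fa_nifti(fa_map, path, spacing=0.004):
    """Export a flip-angle map (n, H, W) as NIfTI (degrees)."""
    import nibabel as nib

    data = np.asarray(fa_map.fa_deg if hasattr(fa_map, "fa_deg") else fa_map)
    vol = np.moveaxis(data, 0, -1).astype(np.float32)  # (H, W, n_slices)
    affine = np.diag([spacing * 1e3, spacing * 1e3, spacing * 1e3, 1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))
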