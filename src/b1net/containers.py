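"""In-memory data containers shared across the pipeline.

The common currency is a stack of complex 2D slices with an orientation
label and a subject id. A localizer stack carries 9 channels (8 receive
channels + the root-sum-of-squares magnitude as a purely real 9th channel);
a B1+ stack carries 8 transmit channels in normalized units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ORIENTATIONS = ("transversal", "sagittal", "coronal")


@dataclass
class ComplexSliceStack:
    """Stack of complex-valued 2D multi-channel slices.

    data: complex array (n_slices, H, W, C); mask: bool (n_slices, H, W).
    """

    data: np.ndarray
    subject: str
    orientation: str
    mask: np.ndarray = None
    positions: np.ndarray = None  # slice positions along the normal (m)
    spacing: float = None  # in-plane voxel spacing (m)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.complex64)
        if self.data.ndim != 4:
            raise ValueError(
                f"expected (n_slices, H, W, C) data, got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite entries in slice stack")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"unknown orientation {self.orientation!r}; expected one of {ORIENTATIONS}"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_slices(self):
        return self.data.shape[0]

    @property
    def n_channels(self):
        return self.data.shape[-1]


@dataclass
class SimulatedPair:
    """Paired localizer input and ground-truth B1+ maps for one subject and
    one slice orientation, on a shared grid."""

    localizer: ComplexSliceStack  # (n, H, W, 9)
    b1: ComplexSliceStack  # (n, H, W, 8)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.localizer.data.shape[:3] != self.b1.data.shape[:3]:
            raise ValueError("localizer and B1 stacks must share the grid")
        if self.localizer.orientation != self.b1.orientation:
            raise ValueError("localizer and B1 stacks must share the orientation")


# A library is a nested mapping {subject_id: {orientation: SimulatedPair}}.
Library = dict
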