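"""Voxel-wise majority-vote fusion of co-registered binary predictions.

A 2.5D segmentation pipeline trains one network per viewing plane
(axial, sagittal, coronal) and fuses the three co-registered prediction
volumes into one: a voxel is foreground iff strictly more than half the
inputs mark it foreground.  With an even number of inputs an exact tie
is resolved by an explicit rule (background by default — conservative
contours).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .masks import BinaryMask, as_mask

__all__ = ["PlanarPredictionSet", "majority_vote"]


@dataclass
class PlanarPredictionSet:
    """Co-registered binary predictions of the same object, one per plane."""

    predictions: List[BinaryMask]
    plane_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if not self.predictions:
            raise ValueError("need at least one prediction")
        self.predictions = [as_mask(p) for p in self.predictions]
        ref = self.predictions[0]
        for i, p in enumerate(self.predictions[1:], start=1):
            if p.shape != ref.shape:
                raise ValueError(
                    f"prediction {i} shape {p.shape} != prediction 0 shape {ref.shape}"
                )
        if self.plane_labels is not None and len(self.plane_labels) != len(self.predictions):
            raise ValueError("plane_labels length must match predictions")

    def __len__(self) -> int:
        return len(self.predictions)


def majority_vote(predictions, ties: str = "background") -> BinaryMask:
    """Fuse predictions voxel-wise: output 1 iff > half the inputs are 1.

    Parameters
    ----------
    predictions : PlanarPredictionSet or sequence of masks/arrays
        All predictions must share one grid shape.
    ties : {"background", "foreground"}
        Resolution for exact half-votes; only reachable with an even
        number of inputs.  Default "background" keeps fused contours
        conservative.
    """
    if ties not in ("background", "foreground"):
        raise ValueError(f"ties must be 'background' or 'foreground', got {ties!r}")
    if not isinstance(predictions, PlanarPredictionSet):
        predictions = PlanarPredictionSet(list(predictions))
    masks = predictions.predictions
    n = len(masks)
    votes = np.zeros(masks[0].shape, dtype=np.int32)
    for m in masks:
        votes += m.grid
    fused = votes * 2 > n
    if ties == "foreground" and n % 2 == 0:
        fused |= votes * 2 == n
    return BinaryMask(
        fused.astype(np.uint8),
        spacing=masks[0].spacing,
        connectivity=masks[0].connectivity,
    )
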