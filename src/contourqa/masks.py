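"""Per-slice segmentation quality metrics on binary mask pairs.

Five metrics are computed between a ground-truth and a predicted binary
mask: the Sørensen–Dice coefficient, the 95th-percentile Hausdorff
distance (HD95), precision, sensitivity and pixel-wise accuracy.

Conventions (fixed here and recorded in every output file):

* The default HD95 is the *directed* distance: for each surface point of
  the prediction, the Euclidean distance to the nearest surface point of
  the ground truth, then the 95th percentile of that multiset.
  ``symmetric=True`` returns the maximum of the two directed percentiles.
* Percentiles interpolate linearly between order statistics at rank
  ``p/100 * (n - 1)`` (the "type-7" convention).
* Surface points are foreground voxels with at least one background
  neighbour under 4-connectivity (2D) / 6-connectivity (3D); the outside
  of the grid counts as background.
* Empty-mask conventions: both masks empty -> Dice 1.0 and HD95 0.0;
  exactly one empty -> Dice 0.0 and HD95 ``nan``.  Undefined ratios
  (e.g. precision with an empty prediction) are ``nan``, never silently 0.
* Coordinates are 0-based array indices; distances are in voxels unless
  ``use_spacing`` scales each axis by the voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "BinaryMask",
    "MaskPair",
    "MetricRecord",
    "METRIC_NAMES",
    "dice",
    "confusion_rates",
    "surface_points",
    "hd95",
    "compute_record",
]

#: Canonical metric order used throughout the package (tables, reader models).
METRIC_NAMES = ("dice", "hd95", "precision", "sensitivity", "pixel_accuracy")


def _default_connectivity(ndim: int) -> int:
    return 8 if ndim == 2 else 26


@dataclass
class BinaryMask:
    """A 2D or 3D binary mask with optional physical voxel spacing.

    Parameters
    ----------
    grid : ndarray of {0, 1}
        The mask itself.  Any integer/bool dtype is accepted; values must
        be exactly 0 or 1.
    spacing : tuple of float, optional
        Physical size per axis; defaults to 1 voxel per axis.
    connectivity : int, optional
        Declared foreground connectivity: 4 or 8 in 2D, 6 or 26 in 3D.
        Defaults to 8 (2D) / 26 (3D).
    """

    grid: np.ndarray
    spacing: Optional[Sequence[float]] = None
    connectivity: Optional[int] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.grid)
        if arr.ndim not in (2, 3):
            raise ValueError(f"mask must be 2D or 3D, got {arr.ndim}D")
        bad = np.setdiff1d(np.unique(arr), [0, 1])
        if bad.size:
            raise ValueError(f"mask contains non-binary values: {sorted(bad.tolist())}")
        self.grid = arr.astype(np.uint8)
        if self.spacing is None:
            self.spacing = (1.0,) * arr.ndim
        else:
            self.spacing = tuple(float(s) for s in self.spacing)
            if len(self.spacing) != arr.ndim:
                raise ValueError("spacing length must match mask dimensionality")
            if any(s <= 0 for s in self.spacing):
                raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.connectivity is None:
            self.connectivity = _default_connectivity(arr.ndim)
        valid = {2: (4, 8), 3: (6, 26)}[arr.ndim]
        if self.connectivity not in valid:
            raise ValueError(f"connectivity must be one of {valid} for {arr.ndim}D")

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    @property
    def ndim(self) -> int:
        return self.grid.ndim

    def is_empty(self) -> bool:
        return not bool(self.grid.any())

    def area(self) -> int:
        """Foreground voxel count."""
        return int(self.grid.sum())


def as_mask(obj, spacing=None) -> BinaryMask:
    """Coerce an array or BinaryMask to a BinaryMask."""
    if isinstance(obj, BinaryMask):
        return obj
    return BinaryMask(np.asarray(obj), spacing=spacing)


@dataclass
class MaskPair:
    """A ground-truth / prediction mask pair on the same grid."""

    truth: BinaryMask
    pred: BinaryMask
    slice_id: str = ""

    def __post_init__(self) -> None:
        self.truth = as_mask(self.truth)
        self.pred = as_mask(self.pred)
        if self.truth.shape != self.pred.shape:
            raise ValueError(
                f"truth shape {self.truth.shape} != pred shape {self.pred.shape}"
            )
        if self.truth.spacing != self.pred.spacing:
            raise ValueError(
                f"truth spacing {self.truth.spacing} != pred spacing {self.pred.spacing}"
            )


@dataclass
class MetricRecord:
    """The five per-slice metric values plus validity flags.

    Undefined values are ``nan``: HD95 when exactly one mask is empty,
    precision when the prediction is empty, sensitivity when the truth is
    empty.  Flags record *why* a value is undefined.
    """

    slice_id: str = ""
    dice: float = np.nan
    hd95: float = np.nan
    precision: float = np.nan
    sensitivity: float = np.nan
    pixel_accuracy: float = np.nan
    empty_truth: bool = False
    empty_pred: bool = False

    def values(self) -> np.ndarray:
        """Metric vector in canonical :data:`METRIC_NAMES` order."""
        return np.array(
            [self.dice, self.hd95, self.precision, self.sensitivity, self.pixel_accuracy],
            dtype=float,
        )


def _check_pair(pair: MaskPair) -> MaskPair:
    if not isinstance(pair, MaskPair):
        raise TypeError("expected a MaskPair")
    return pair


def dice(pair: MaskPair) -> float:
    """Sørensen–Dice coefficient 2|A∩B| / (|A| + |B|).

    Symmetric in (truth, pred).  Both masks empty -> 1.0 (perfect
    agreement on an empty slice); exactly one empty -> 0.0.
    """
    _check_pair(pair)
    a, b = pair.truth.grid, pair.pred.grid
    sa, sb = int(a.sum()), int(b.sum())
    if sa == 0 and sb == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (sa + sb)


def confusion_rates(pair: MaskPair) -> tuple:
    """(precision, sensitivity, pixel_accuracy) from the voxel confusion counts.

    precision = TP/(TP+FP), sensitivity = TP/(TP+FN),
    pixel_accuracy = (TP+TN)/total.  Empty denominators yield ``nan``.
    """
    _check_pair(pair)
    t = pair.truth.grid.astype(bool)
    p = pair.pred.grid.astype(bool)
    tp = int(np.logical_and(t, p).sum())
    fp = int(np.logical_and(~t, p).sum())
    fn = int(np.logical_and(t, ~p).sum())
    tn = t.size - tp - fp - fn
    precision = tp / (tp + fp) if tp + fp > 0 else np.nan
    sensitivity = tp / (tp + fn) if tp + fn > 0 else np.nan
    accuracy = (tp + tn) / t.size
    return precision, sensitivity, accuracy


def surface_points(mask: BinaryMask) -> np.ndarray:
    """Coordinates (N, ndim) of foreground voxels on the object surface.

    A surface voxel is a foreground voxel with >= 1 background neighbour
    under 4-connectivity (2D) / 6-connectivity (3D).  Voxels touching the
    grid edge count the outside as background.
    """
    mask = as_mask(mask)
    if mask.is_empty():
        raise ValueError("surface_points undefined for an empty mask")
    grid = mask.grid.astype(bool)
    # cross-shaped structuring element = face connectivity
    structure = ndimage.generate_binary_structure(grid.ndim, 1)
    interior = ndimage.binary_erosion(grid, structure=structure, border_value=0)
    return np.argwhere(grid & ~interior)


def hd95(
    pair: MaskPair,
    percentile: float = 95.0,
    symmetric: bool = False,
    use_spacing: bool = False,
) -> float:
    """Percentile Hausdorff distance between mask surfaces.

    Default is the directed prediction->truth distance: for each surface
    point of the prediction, the Euclidean distance to the nearest surface
    point of the truth; the ``percentile``-th percentile of that multiset
    is returned (linear interpolation between order statistics).
    ``symmetric=True`` returns the max of the two directed percentiles.

    Distances are in voxels unless ``use_spacing`` is set, in which case
    coordinates are scaled by the per-axis spacing first.

    Both masks empty -> 0.0; exactly one empty -> ``nan``.
    """
    _check_pair(pair)
    if not 0.0 < percentile <= 100.0:
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    te, pe = pair.truth.is_empty(), pair.pred.is_empty()
    if te and pe:
        return 0.0
    if te or pe:
        return np.nan
    scale = np.asarray(pair.truth.spacing) if use_spacing else None

    def directed(src: BinaryMask, dst: BinaryMask) -> float:
        sp = surface_points(src).astype(float)
        dp = surface_points(dst).astype(float)
        if scale is not None:
            sp = sp * scale
            dp = dp * scale
        dists, _ = cKDTree(dp).query(sp)
        return float(np.percentile(dists, percentile))

    d_pt = directed(pair.pred, pair.truth)
    if not symmetric:
        return d_pt
    return max(d_pt, directed(pair.truth, pair.pred))


def compute_record(
    pair: MaskPair,
    percentile: float = 95.0,
    symmetric: bool = False,
    use_spacing: bool = False,
) -> MetricRecord:
    """Assemble all five metrics and validity flags for one mask pair."""
    _check_pair(pair)
    p, s, acc = confusion_rates(pair)
    return MetricRecord(
        slice_id=pair.slice_id,
        dice=dice(pair),
        hd95=hd95(pair, percentile=percentile, symmetric=symmetric, use_spacing=use_spacing),
        precision=p,
        sensitivity=s,
        pixel_accuracy=acc,
        empty_truth=pair.truth.is_empty(),
        empty_pred=pair.pred.is_empty(),
    )
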