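"""Synthetic segmentation study: masks, degraded predictions, virtual readers.

This module generates the full synthetic counterpart of a contour
acceptance study: smooth heart-like binary masks, predictions degraded
with controllable severity, three per-plane prediction volumes for
majority-vote fusion, a class-imbalanced slice population including
empty-ground-truth slices, and a panel of virtual readers producing
ordinal A/B/C/D answers driven by latent segmentation quality with
reader-specific noise.

Masks are star-convex radial blobs (base radius plus a low-order
sinusoidal boundary perturbation), not anatomical shapes: sufficient to
exercise every metric without external data.  All generation is a pure
function of the seed; sub-generators derive their streams from the
master seed combined with a stable per-component integer tag, so fixing
the seed fixes every artifact bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .agreement import HIGHER_IS_BETTER
from .consensus import AnswerPanel, ConsensusLabel, consensus
from .fusion import PlanarPredictionSet, majority_vote
from .masks import METRIC_NAMES, BinaryMask, MaskPair, MetricRecord, compute_record

__all__ = [
    "VALID_MODES",
    "SyntheticStudyConfig",
    "ReaderModel",
    "SyntheticStudy",
    "generate_mask",
    "degrade",
    "generate_plane_predictions",
    "simulate_readers",
    "threshold_reader_model",
    "generate_study",
    "parse_severity_distribution",
]

VALID_MODES = (
    "boundary_jitter",
    "translation",
    "false_positive_blob",
    "dropout",
    "rough_edges",
)

# per-component tags for seed derivation (stable, never reordered)
_TAG_MASK = 11
_TAG_DEGRADE = 12
_TAG_PLANES = 13
_TAG_READERS = 14
_TAG_STUDY = 15


def _rng(seed: int, tag: int) -> np.random.Generator:
    if seed < 0:
        raise ValueError(f"seed must be non-negative, got {seed}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(tag)]))


def parse_severity_distribution(spec: str) -> tuple:
    """Parse 'uniform:0,1', 'beta:1.5,3' or 'constant:0.4' into a dist tuple."""
    name, _, rest = spec.partition(":")
    params = tuple(float(x) for x in rest.split(",")) if rest else ()
    dist = (name, *params)
    _draw_severity(dist, np.random.default_rng(0), 1)  # validates
    return dist


def _draw_severity(dist, rng: np.random.Generator, size: int) -> np.ndarray:
    name = dist[0]
    if name == "uniform":
        lo, hi = dist[1:] if len(dist) > 1 else (0.0, 1.0)
        s = rng.uniform(lo, hi, size)
    elif name == "beta":
        a, b = dist[1:]
        s = rng.beta(a, b, size)
    elif name == "constant":
        s = np.full(size, float(dist[1]))
    else:
        raise ValueError(f"unknown severity distribution {name!r}; "
                         "expected uniform, beta or constant")
    return np.clip(s, 0.0, 1.0)


@dataclass
class SyntheticStudyConfig:
    """Study-level knobs: population size, grid, imbalance, degradation.

    Defaults emulate a reader study of 101 slices with a class imbalance
    in which 20% of included slices carry no organ, three prediction
    planes fused by majority vote, and a severity distribution skewed
    toward mildly degraded predictions (most contours clinically usable).
    """

    n_slices: int = 101
    grid_shape: Tuple[int, ...] = (64, 64)
    empty_fraction: float = 0.2
    severity_distribution: tuple = ("beta", 1.5, 3.0)
    degradation_modes: Tuple[str, ...] = ("boundary_jitter", "translation", "rough_edges")
    n_planes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if not 0.0 <= self.empty_fraction < 1.0:
            raise ValueError("empty_fraction must be in [0, 1)")
        self.grid_shape = tuple(int(d) for d in self.grid_shape)
        for i, d in enumerate(self.grid_shape):
            if d < 8:
                raise ValueError(f"grid dimension {i} is {d}; every dimension must be >= 8")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        bad = set(self.degradation_modes) - set(VALID_MODES)
        if bad:
            raise ValueError(f"unknown degradation modes {sorted(bad)}; valid: {VALID_MODES}")
        if isinstance(self.severity_distribution, str):
            self.severity_distribution = parse_severity_distribution(self.severity_distribution)


@dataclass
class ReaderModel:
    """Latent-quality model for a panel of virtual readers.

    Each reader's latent score for a slice is q = Σ w·metric + noise,
    with the metric vector in canonical order (dice, hd95, precision,
    sensitivity, pixel_accuracy), z-scored across the study by default
    so the weights are comparable between metrics.  Three strictly
    increasing cutpoints τ_A < τ_B < τ_C partition the latent axis into
    answers A (q < τ_A), B, C and D (q >= τ_C); a score exactly at a
    cutpoint falls in the higher (better) category.  With noise sd 0 all
    readers answer identically.

    Default weights load mostly on Dice (negatively on HD95); default
    cutpoints were placed so a typical study yields an answer mix with D
    most frequent and A rarest, the shape seen in reader panels that
    accept roughly three quarters of presented contours.
    """

    quality_weights: Tuple[float, ...] = (1.0, -0.6, 0.3, 0.3, 0.2)
    category_cutpoints: Tuple[float, float, float] = (-2.4, -1.1, 0.0)
    reader_noise_sd: float = 0.35
    n_readers: int = 3
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        c = tuple(float(x) for x in self.category_cutpoints)
        if len(c) != 3 or not (c[0] < c[1] < c[2]):
            raise ValueError(f"cutpoints must be three strictly increasing values, got {c}")
        self.category_cutpoints = c
        if self.reader_noise_sd < 0:
            raise ValueError("reader_noise_sd must be >= 0")
        if self.n_readers < 1:
            raise ValueError("n_readers must be >= 1")
        self.quality_weights = tuple(float(w) for w in self.quality_weights)


def generate_mask(grid_shape: Sequence[int], shape_seed: int) -> BinaryMask:
    """A single connected, smooth, star-convex blob on the given grid.

    The boundary is a radial function: base radius plus a low-order
    sinusoidal perturbation.  The blob stays strictly inside the grid
    and occupies between 2% and 60% of it.  Deterministic given the seed.
    """
    shape = tuple(int(d) for d in grid_shape)
    if len(shape) not in (2, 3):
        raise ValueError(f"grid must be 2D or 3D, got {len(shape)}D")
    for i, d in enumerate(shape):
        if d < 8:
            raise ValueError(f"grid dimension {i} is {d}; every dimension must be >= 8")
    rng = _rng(shape_seed, _TAG_MASK)
    ndim = len(shape)
    min_dim = min(shape)
    center = np.array([(d - 1) / 2.0 + rng.uniform(-0.04, 0.04) * d for d in shape])
    r0 = rng.uniform(0.18, 0.30) * min_dim
    amp = rng.uniform(0.02, 0.10, size=2)
    phase = rng.uniform(0.0, 2 * np.pi, size=2)
    # keep the maximal radius strictly inside the grid with a margin
    limit = min(min(center[i], shape[i] - 1 - center[i]) for i in range(ndim)) - 1.2
    r0 = min(r0, limit / (1.0 + amp.sum()))
    idx = np.indices(shape, dtype=float)
    off = [idx[i] - center[i] for i in range(ndim)]
    rad = np.sqrt(sum(o**2 for o in off))
    if ndim == 2:
        theta = np.arctan2(off[1], off[0])
        f = 1.0 + amp[0] * np.sin(2 * theta + phase[0]) + amp[1] * np.sin(3 * theta + phase[1])
    else:
        ratio = np.divide(off[0], rad, out=np.zeros_like(rad), where=rad > 0)
        polar = np.arccos(np.clip(ratio, -1.0, 1.0))
        azim = np.arctan2(off[2], off[1])
        f = (
            1.0
            + amp[0] * np.sin(polar) * np.sin(2 * azim + phase[0])
            + amp[1] * np.cos(2 * polar + phase[1])
        )
    grid = (rad <= r0 * f).astype(np.uint8)
    return BinaryMask(grid)


def _int_shift(grid: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Integer translation with zero fill."""
    out = np.zeros_like(grid)
    src = []
    dst = []
    for o, d in zip(offsets, grid.shape):
        o = int(o)
        if abs(o) >= d:
            return out
        if o >= 0:
            src.append(slice(0, d - o))
            dst.append(slice(o, d))
        else:
            src.append(slice(-o, d))
            dst.append(slice(0, d + o))
    out[tuple(dst)] = grid[tuple(src)]
    return out


def _ball(shape, center, radius) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    rad = np.sqrt(sum((idx[i] - center[i]) ** 2 for i in range(len(shape))))
    return rad <= radius


def degrade(
    mask: BinaryMask,
    severity: float,
    modes: Sequence[str] = ("boundary_jitter", "translation"),
    seed: int = 0,
    max_shift: float = 5.0,
) -> BinaryMask:
    """Perturb a mask into a synthetic prediction of controllable quality.

    Each enabled mode's magnitude scales with ``severity`` in [0, 1];
    severity 0 returns the input unchanged.  Modes (applied in a fixed
    canonical order regardless of the order given):

    * ``translation`` — rigid shift of up to ``max_shift`` voxels,
    * ``boundary_jitter`` — smooth correlated displacement of the contour
      (spatially filtered noise added to the signed distance),
    * ``rough_edges`` — independent single-voxel flips along the contour,
    * ``dropout`` — a ball-shaped region of the object removed,
    * ``false_positive_blob`` — a spurious component added in background.
    """
    mask = mask if isinstance(mask, BinaryMask) else BinaryMask(np.asarray(mask))
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")
    bad = set(modes) - set(VALID_MODES)
    if bad:
        raise ValueError(f"unknown degradation modes {sorted(bad)}; valid: {VALID_MODES}")
    if severity == 0.0:
        return BinaryMask(mask.grid.copy(), spacing=mask.spacing, connectivity=mask.connectivity)
    rng = _rng(seed, _TAG_DEGRADE)
    grid = mask.grid.astype(bool)
    ndim = grid.ndim
    enabled = [m for m in VALID_MODES if m in set(modes)]
    for mode in enabled:
        nonempty = grid.any()
        if mode == "boundary_jitter" and nonempty and not grid.all():
            signed = ndimage.distance_transform_edt(grid) - ndimage.distance_transform_edt(~grid)
            noise = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=2.0)
            noise /= max(float(noise.std()), 1e-12)
            grid = (signed + severity * 2.5 * noise) > 0
        elif mode == "translation" and nonempty:
            u = rng.standard_normal(ndim)
            norm = float(np.linalg.norm(u))
            u = u / norm if norm > 0 else np.eye(ndim)[0]
            off = np.rint(severity * max_shift * u).astype(int)
            while np.linalg.norm(off) > max_shift:  # rounding can overshoot the budget
                i = int(np.argmax(np.abs(off)))
                off[i] -= int(np.sign(off[i]))
            grid = _int_shift(grid, off)
        elif mode == "false_positive_blob":
            far_bg = ~ndimage.binary_dilation(grid, iterations=3) if nonempty else ~grid
            cand = np.argwhere(far_bg)
            if cand.size:
                c = cand[rng.integers(len(cand))]
                grid = grid | _ball(grid.shape, c, 0.5 + 2.5 * severity)
        elif mode == "dropout" and nonempty:
            fg = np.argwhere(grid)
            c = fg[rng.integers(len(fg))]
            area = float(grid.sum())
            r_eq = (area / np.pi) ** 0.5 if ndim == 2 else (3 * area / (4 * np.pi)) ** (1 / 3)
            grid = grid & ~_ball(grid.shape, c, severity * 0.6 * r_eq)
        elif mode == "rough_edges" and nonempty:
            full = ndimage.generate_binary_structure(ndim, ndim)
            inner = grid & ~ndimage.binary_erosion(grid, structure=full, border_value=0)
            outer = ndimage.binary_dilation(grid, structure=full) & ~grid
            band = inner | outer
            flips = band & (rng.random(grid.shape) < 0.4 * severity)
            grid = grid ^ flips
    return BinaryMask(grid.astype(np.uint8), spacing=mask.spacing, connectivity=mask.connectivity)


def generate_plane_predictions(
    mask: BinaryMask,
    severity: float,
    n_planes: int = 3,
    seed: int = 0,
    modes: Sequence[str] = ("boundary_jitter", "translation"),
    max_shift: float = 5.0,
) -> PlanarPredictionSet:
    """n_planes independently degraded predictions of the same mask.

    Emulates one model per viewing plane: each plane's errors are drawn
    from an independent stream derived from the master seed.
    """
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    child = _rng(seed, _TAG_PLANES).integers(2**31, size=n_planes)
    preds = [
        degrade(mask, severity, modes=modes, seed=int(child[i]), max_shift=max_shift)
        for i in range(n_planes)
    ]
    labels = ("axial", "sagittal", "coronal") if n_planes == 3 else tuple(
        f"plane_{i}" for i in range(n_planes)
    )
    return PlanarPredictionSet(preds, labels)


def simulate_readers(records: Sequence[MetricRecord], model: ReaderModel) -> List[AnswerPanel]:
    """Ordinal A/B/C/D answers for every slice and reader.

    Latent quality per slice is the weighted sum of the (optionally
    z-scored) metric vector; each reader adds independent Gaussian noise
    and the cutpoints map the noisy score to a letter.  Undefined metric
    values are imputed with the study-worst observed value of that
    metric before standardization (a missing distance reads as a bad
    contour, not an average one).
    """
    if not records:
        raise ValueError("no records")
    M = np.array([r.values() for r in records], dtype=float)
    w = np.asarray(model.quality_weights, dtype=float)
    if w.size != M.shape[1]:
        raise ValueError(
            f"quality_weights has length {w.size}, expected {M.shape[1]} "
            f"(one per metric in {METRIC_NAMES})"
        )
    for j, name in enumerate(METRIC_NAMES):
        col = M[:, j]
        bad = np.isnan(col)
        if bad.all():
            col[:] = 0.0
        elif bad.any():
            col[bad] = np.nanmax(col) if not HIGHER_IS_BETTER[name] else np.nanmin(col)
    if model.standardize:
        mu = M.mean(axis=0)
        sd = M.std(axis=0)
        sd[sd == 0] = 1.0
        M = (M - mu) / sd
    q = M @ w
    cuts = np.asarray(model.category_cutpoints)
    rng = _rng(model.seed, _TAG_READERS)
    if model.reader_noise_sd > 0:
        noise = rng.normal(0.0, model.reader_noise_sd, size=(len(records), model.n_readers))
    else:
        noise = np.zeros((len(records), model.n_readers))
    letters = "ABCD"
    panels = []
    for i, rec in enumerate(records):
        # score exactly at a cutpoint goes to the higher (better) category
        idx = np.searchsorted(cuts, q[i] + noise[i], side="right")
        panels.append(AnswerPanel(rec.slice_id, tuple(letters[k] for k in idx)))
    return panels


def threshold_reader_model(
    metric: str = "dice",
    threshold: float = 0.85,
    n_readers: int = 3,
    noise_sd: float = 0.0,
    spread: float = 0.1,
    seed: int = 0,
) -> ReaderModel:
    """A reader model whose accept boundary is a hard threshold on one raw metric.

    With ``noise_sd = 0`` the panel accepts a slice iff the metric is at
    or beyond ``threshold`` (in the metric's better direction) — the
    generative ground truth for threshold-recovery experiments.  Accept
    means an answer of C or D, so the hard threshold sits at the B/C
    cutpoint; ``spread`` spaces the other two cutpoints around it.
    """
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}; valid: {METRIC_NAMES}")
    j = METRIC_NAMES.index(metric)
    higher = HIGHER_IS_BETTER[metric]
    w = [0.0] * len(METRIC_NAMES)
    w[j] = 1.0 if higher else -1.0
    tau_b = threshold if higher else -threshold
    cuts = (tau_b - spread, tau_b, tau_b + spread)
    return ReaderModel(
        quality_weights=tuple(w),
        category_cutpoints=cuts,
        reader_noise_sd=noise_sd,
        n_readers=n_readers,
        standardize=False,
        seed=seed,
    )


@dataclass
class SyntheticStudy:
    """All artifacts of one simulated study, aligned per slice."""

    config: SyntheticStudyConfig
    reader_model: ReaderModel
    truths: List[BinaryMask]
    plane_predictions: List[PlanarPredictionSet]
    fused: List[BinaryMask]
    records: List[MetricRecord]
    panels: List[AnswerPanel]
    labels: List[ConsensusLabel]
    table: pd.DataFrame

    @property
    def n_slices(self) -> int:
        return len(self.records)


def generate_study(
    config: SyntheticStudyConfig,
    reader_model: Optional[ReaderModel] = None,
) -> SyntheticStudy:
    """End-to-end synthetic study: truth, planes, fusion, metrics, readers.

    Exactly ``round(empty_fraction * n_slices)`` slices get an empty
    ground truth (exact count, not Bernoulli draws); they are flagged in
    the table, never silently dropped.  Metrics are computed between the
    truth and the majority-vote fusion of the per-plane predictions.
    """
    if reader_model is None:
        reader_model = ReaderModel(seed=config.seed)
    n = config.n_slices
    rng = _rng(config.seed, _TAG_STUDY)
    n_empty = int(round(config.empty_fraction * n))
    empty_idx = set(rng.permutation(n)[:n_empty].tolist())
    severities = _draw_severity(config.severity_distribution, rng, n)
    mask_seeds = rng.integers(2**31, size=n)
    degrade_seeds = rng.integers(2**31, size=n)

    truths, plane_sets, fused_masks, records = [], [], [], []
    for i in range(n):
        sid = f"s{i:04d}"
        if i in empty_idx:
            truth = BinaryMask(np.zeros(config.grid_shape, dtype=np.uint8))
        else:
            truth = generate_mask(config.grid_shape, int(mask_seeds[i]))
        planes = generate_plane_predictions(
            truth,
            float(severities[i]),
            n_planes=config.n_planes,
            seed=int(degrade_seeds[i]),
            modes=config.degradation_modes,
        )
        fused = majority_vote(planes) if config.n_planes % 2 == 1 else majority_vote(
            planes, ties="background"
        )
        rec = compute_record(MaskPair(truth, fused, sid))
        truths.append(truth)
        plane_sets.append(planes)
        fused_masks.append(fused)
        records.append(rec)

    panels = simulate_readers(records, reader_model)
    labels = [consensus(p) for p in panels]

    rows = []
    for i, (rec, panel, lab) in enumerate(zip(records, panels, labels)):
        row = {
            "slice_id": rec.slice_id,
            "severity": float(severities[i]),
            "empty_truth": rec.empty_truth,
            "empty_pred": rec.empty_pred,
            "dice": rec.dice,
            "hd95": rec.hd95,
            "precision": rec.precision,
            "sensitivity": rec.sensitivity,
            "pixel_accuracy": rec.pixel_accuracy,
        }
        for r, a in enumerate(panel.answers, start=1):
            row[f"reader_{r}"] = a
        row["consensus_answer"] = lab.consensus_answer
        row["accepted"] = lab.accepted
        rows.append(row)
    table = pd.DataFrame(rows)
    return SyntheticStudy(
        config, reader_model, truths, plane_sets, fused_masks, records, panels, labels, table
    )
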