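"""File formats: NIfTI / PNG masks, CSV tables, JSON sidecars.

Naming conventions (documented, relied on by :func:`load_mask_pairs`):

* volume layout: a directory containing ``truth.nii``/``truth.nii.gz``
  and ``pred.nii``/``pred.nii.gz`` — one 3D mask pair.
* slice_directory layout: files ``<slice_id>_truth.<ext>`` paired with
  ``<slice_id>_pred.<ext>`` (ext: nii, nii.gz or png) — one 2D pair per
  slice, sorted by slice id.

Tables are RFC-4180 CSV with a header row: ``answers.csv`` has columns
(slice_id, reader_id, answer), ``metrics.csv`` the per-slice metric
record, ``consensus.csv`` (slice_id, accepted, consensus_answer).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional, Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .consensus import AnswerPanel, ConsensusLabel
from .masks import BinaryMask, MaskPair, MetricRecord

__all__ = [
    "save_mask",
    "load_mask",
    "load_mask_pairs",
    "records_to_frame",
    "frame_to_records",
    "write_metrics_csv",
    "read_metrics_csv",
    "write_answers_csv",
    "read_answers_csv",
    "write_consensus_csv",
    "read_consensus_csv",
    "save_study",
]

_METRIC_COLUMNS = [
    "slice_id",
    "dice",
    "hd95",
    "precision",
    "sensitivity",
    "pixel_accuracy",
    "empty_truth",
    "empty_pred",
]


def save_mask(mask: BinaryMask, path) -> Path:
    """Write a mask as NIfTI (.nii/.nii.gz, spacing in the affine) or PNG (2D)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        ndim = mask.ndim
        affine = np.eye(4)
        for i in range(ndim):
            affine[i, i] = mask.spacing[i]
        nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), affine), str(path))
    elif name.endswith(".png"):
        if mask.ndim != 2:
            raise ValueError("PNG output supports 2D masks only")
        iio.imwrite(path, (mask.grid * 255).astype(np.uint8))
    else:
        raise ValueError(f"unsupported mask format: {path.name} (use .nii, .nii.gz or .png)")
    return path


def load_mask(path) -> BinaryMask:
    """Read a mask, validating that its values are binary."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        arr = np.squeeze(data)
        if arr.ndim not in (2, 3):
            raise ValueError(f"{path.name}: expected a 2D or 3D mask, got shape {data.shape}")
        spacing = spacing[: arr.ndim] if len(spacing) >= arr.ndim else None
    elif name.endswith(".png"):
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:  # collapse identical color channels
            arr = arr[..., 0]
        spacing = None
    else:
        raise ValueError(f"unsupported mask format: {path.name}")
    vals = set(np.unique(arr).tolist())
    if vals <= {0, 255} and 255 in vals:
        arr = (arr > 0).astype(np.uint8)
    else:
        bad = sorted(v for v in vals if v not in (0, 1))
        if bad:
            raise ValueError(f"{path.name}: mask contains non-binary values: {bad}")
    return BinaryMask(arr.astype(np.uint8), spacing=spacing)


_MASK_EXTS = (".nii.gz", ".nii", ".png")


def _find_with_ext(directory: Path, stem: str) -> Optional[Path]:
    for ext in _MASK_EXTS:
        p = directory / f"{stem}{ext}"
        if p.exists():
            return p
    return None


def load_mask_pairs(path, layout: str = "slice_directory") -> List[MaskPair]:
    """Discover and load truth/pred mask pairs from a directory.

    ``volume`` layout expects ``truth`` and ``pred`` NIfTI volumes;
    ``slice_directory`` expects per-slice ``<id>_truth`` / ``<id>_pred``
    files.  A truth file without its prediction (or vice versa) is an
    error naming the slice.
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"not a directory: {root}")
    if layout == "volume":
        truth_p = _find_with_ext(root, "truth")
        pred_p = _find_with_ext(root, "pred")
        if truth_p is None:
            raise FileNotFoundError(f"{root}: no truth volume (truth.nii/.nii.gz)")
        if pred_p is None:
            raise FileNotFoundError(f"{root}: no pred volume (pred.nii/.nii.gz)")
        return [MaskPair(load_mask(truth_p), load_mask(pred_p), slice_id=root.name)]
    if layout != "slice_directory":
        raise ValueError(f"layout must be 'volume' or 'slice_directory', got {layout!r}")
    stems = {}
    for p in sorted(root.iterdir()):
        name = p.name
        for ext in _MASK_EXTS:
            if name.endswith(ext):
                stem = name[: -len(ext)]
                if stem.endswith("_truth"):
                    stems.setdefault(stem[: -len("_truth")], {})["truth"] = p
                elif stem.endswith("_pred"):
                    stems.setdefault(stem[: -len("_pred")], {})["pred"] = p
                break
    if not stems:
        raise FileNotFoundError(f"{root}: no *_truth/*_pred mask files found")
    pairs = []
    for sid in sorted(stems):
        found = stems[sid]
        if "truth" not in found:
            raise FileNotFoundError(f"slice {sid!r}: prediction present but truth missing")
        if "pred" not in found:
            raise FileNotFoundError(f"slice {sid!r}: truth present but prediction missing")
        pairs.append(MaskPair(load_mask(found["truth"]), load_mask(found["pred"]), slice_id=sid))
    return pairs


def records_to_frame(records: Sequence[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=_METRIC_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> List[MetricRecord]:
    return [
        MetricRecord(
            slice_id=str(row.slice_id),
            dice=float(row.dice),
            hd95=float(row.hd95),
            precision=float(row.precision),
            sensitivity=float(row.sensitivity),
            pixel_accuracy=float(row.pixel_accuracy),
            empty_truth=bool(row.empty_truth),
            empty_pred=bool(row.empty_pred),
        )
        for row in frame.itertuples(index=False)
    ]


def write_metrics_csv(records: Sequence[MetricRecord], path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path


def read_metrics_csv(path) -> List[MetricRecord]:
    return frame_to_records(pd.read_csv(path))


def write_answers_csv(panels: Sequence[AnswerPanel], path) -> Path:
    rows = [
        {"slice_id": p.slice_id, "reader_id": r, "answer": a}
        for p in panels
        for r, a in enumerate(p.answers, start=1)
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["slice_id", "reader_id", "answer"]).to_csv(path, index=False)
    return path


def read_answers_csv(path) -> List[AnswerPanel]:
    df = pd.read_csv(path, dtype={"slice_id": str})
    panels = []
    for sid, grp in df.groupby("slice_id", sort=True):
        grp = grp.sort_values("reader_id")
        panels.append(AnswerPanel(str(sid), tuple(grp["answer"])))
    return panels


def write_consensus_csv(labels: Sequence[ConsensusLabel], path) -> Path:
    rows = [
        {"slice_id": l.slice_id, "accepted": l.accepted, "consensus_answer": l.consensus_answer}
        for l in labels
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["slice_id", "accepted", "consensus_answer"]).to_csv(
        path, index=False
    )
    return path


def read_consensus_csv(path) -> List[ConsensusLabel]:
    df = pd.read_csv(path, dtype={"slice_id": str})
    return [
        ConsensusLabel(str(r.slice_id), bool(r.accepted), str(r.consensus_answer))
        for r in df.itertuples(index=False)
    ]


def save_study(study, out_dir, image_format: str = "nii.gz", save_planes: bool = False) -> Path:
    """Write a synthetic study to disk: masks, tables, config sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    masks_dir = out / "masks"
    masks_dir.mkdir(exist_ok=True)
    ext = image_format.lstrip(".")
    for truth, planes, fused, rec in zip(
        study.truths, study.plane_predictions, study.fused, study.records
    ):
        sid = rec.slice_id
        save_mask(truth, masks_dir / f"{sid}_truth.{ext}")
        save_mask(fused, masks_dir / f"{sid}_pred.{ext}")
        if save_planes:
            for label, pred in zip(planes.plane_labels, planes.predictions):
                save_mask(pred, masks_dir / f"{sid}_plane_{label}.{ext}")
    write_metrics_csv(study.records, out / "metrics.csv")
    write_answers_csv(study.panels, out / "answers.csv")
    write_consensus_csv(study.labels, out / "consensus.csv")
    study.table.to_csv(out / "study.csv", index=False)
    sidecar = {
        "config": asdict(study.config),
        "reader_model": asdict(study.reader_model),
        "seed": study.config.seed,
    }
    (out / "config.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True, default=str))
    return out
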