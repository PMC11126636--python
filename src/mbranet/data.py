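"""Label-table readers, split handling, and image preprocessing.

Two CSV dialects are supported.  The ChestX-ray14 dialect has an image
index column and a pipe-separated finding-labels column ("No Finding" or
an empty cell meaning no pathology).  The CheXpert dialect has one column
per class with entries 1 / 0 / -1 / blank; uncertain (-1) entries are
remapped according to a U-Ones or U-Zeros policy and blanks count as
negative.  Both readers produce the same record type so synthetic and
real inputs share one code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

#: the 14 pathology classes of the ChestX-ray14 label space
CHESTXRAY14_CLASSES = (
    "Atelectasis", "Cardiomegaly", "Effusion", "Infiltration", "Mass",
    "Nodule", "Pneumonia", "Pneumothorax", "Consolidation", "Edema",
    "Emphysema", "Fibrosis", "Pleural_Thickening", "Hernia",
)

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class SampleRecord:
    image_id: str
    image_path: str
    labels: np.ndarray          # binary vector, one entry per class
    patient_id: str | None = None


@dataclass
class LabelPolicy:
    """How CheXpert uncertain (-1) labels are resolved."""
    mode: str = "u_ones"

    def __post_init__(self):
        if self.mode not in ("u_ones", "u_zeros"):
            raise ValueError("label policy mode must be 'u_ones' or 'u_zeros'")

    @property
    def uncertain_value(self) -> float:
        return 1.0 if self.mode == "u_ones" else 0.0


def read_chestxray14_csv(path, class_names=CHESTXRAY14_CLASSES,
                         image_root=None) -> list[SampleRecord]:
    """Read a ChestX-ray14-dialect label table into sample records."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.empty and len(df.columns) == 0:
        return []
    required = {"Image Index", "Finding Labels"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in {path.name}: {sorted(missing)}")
    index = {name: i for i, name in enumerate(class_names)}
    root = Path(image_root) if image_root is not None else path.parent
    records = []
    unknown: set[str] = set()
    for _, row in df.iterrows():
        labels = np.zeros(len(class_names), dtype=np.float32)
        findings = row["Finding Labels"]
        if isinstance(findings, str) and findings.strip():
            for name in findings.split("|"):
                name = name.strip()
                if not name or name == "No Finding":
                    continue
                if name not in index:
                    unknown.add(name)
                    continue
                labels[index[name]] = 1.0
        patient = row.get("Patient ID")
        records.append(SampleRecord(
            image_id=row["Image Index"],
            image_path=str(root / row["Image Index"]),
            labels=labels,
            patient_id=None if pd.isna(patient) else str(patient)))
    if unknown:
        raise ValueError(f"unknown finding labels in {path.name}: {sorted(unknown)}")
    return records


def read_chexpert_csv(path, class_names, policy: LabelPolicy | None = None,
                      image_root=None, return_remap_count: bool = False):
    """Read a CheXpert-dialect label table (per-class 1/0/-1/blank columns)."""
    policy = policy or LabelPolicy()
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return ([], 0) if return_remap_count else []
    missing = [c for c in ("Path", *class_names) if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path.name}: {missing}")
    root = Path(image_root) if image_root is not None else path.parent
    records = []
    n_remapped = 0
    for _, row in df.iterrows():
        labels = np.zeros(len(class_names), dtype=np.float32)
        for i, name in enumerate(class_names):
            val = row[name]
            if pd.isna(val):
                continue                        # blank counts as negative
            if val not in (1, 0, -1, 1.0, 0.0, -1.0):
                raise ValueError(
                    f"invalid label value {val!r} for class {name!r}")
            if val == -1:
                labels[i] = policy.uncertain_value
                n_remapped += 1
            else:
                labels[i] = float(val)
        rel = str(row["Path"])
        records.append(SampleRecord(
            image_id=rel, image_path=str(root / rel), labels=labels,
            patient_id=_chexpert_patient(rel)))
    logger.info("remapped %d uncertain labels using %s", n_remapped, policy.mode)
    return (records, n_remapped) if return_remap_count else records


def _chexpert_patient(rel_path: str) -> str | None:
    for part in Path(rel_path).parts:
        if part.startswith("patient"):
            return part
    return None


def split_records(records, mode: str = "patient_grouped_ratio",
                  ratios=(0.7, 0.1, 0.2), seed: int = 0, official_lists=None):
    """Partition records into train/validation/test lists.

    ``patient_grouped_ratio`` shuffles patients (not images) and allocates
    whole patients by the given ratios so no patient straddles splits.
    ``official_lists`` partitions by three explicit image-id lists.
    """
    if mode == "official_lists":
        if official_lists is None or len(official_lists) != 3:
            raise ValueError("official_lists mode needs three id lists")
        sets = [set(ids) for ids in official_lists]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(
                        f"ids appear in two official lists: {sorted(overlap)[:5]}")
        by_id = {r.image_id: r for r in records}
        unknown = (sets[0] | sets[1] | sets[2]) - set(by_id)
        if unknown:
            raise ValueError(f"official lists contain unknown ids: {sorted(unknown)[:5]}")
        return tuple([by_id[i] for i in ids] for ids in official_lists)
    if mode != "patient_grouped_ratio":
        raise ValueError(f"unknown split mode {mode!r}")
    if abs(sum(ratios) - 1.0) > 1e-9 or len(ratios) != 3:
        raise ValueError("ratios must be three numbers summing to 1")
    groups: dict[str, list[SampleRecord]] = {}
    for r in records:
        key = r.patient_id if r.patient_id is not None else r.image_id
        groups.setdefault(key, []).append(r)
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    n = len(keys)
    n_train = int(n * ratios[0])
    n_val = int(n * ratios[1])
    parts = (keys[:n_train], keys[n_train:n_train + n_val], keys[n_train + n_val:])
    return tuple([r for k in part for r in groups[k]] for part in parts)


def preprocess(image, phase: str = "eval_deterministic", rng=None,
               resize_to: int = 256, crop_to: int = 224) -> np.ndarray:
    """Decode, resize, crop, flip (train only) and normalise an image.

    Phases: ``train`` = random crop + random horizontal flip;
    ``eval_paper`` = random crop (the published evaluation protocol);
    ``eval_deterministic`` = centre crop, the reproducible default.
    Returns a float32 array of shape (3, crop_to, crop_to) normalised with
    the standard ImageNet channel statistics.
    """
    if phase not in ("train", "eval_paper", "eval_deterministic"):
        raise ValueError(f"unknown phase {phase!r}")
    if phase in ("train", "eval_paper") and rng is None:
        rng = np.random.default_rng()
    if isinstance(image, (str, Path)):
        with Image.open(image) as img:
            image = img.convert("RGB").copy()
    elif isinstance(image, np.ndarray):
        arr = image
        if arr.dtype != np.uint8:
            arr = np.clip(arr * 255.0, 0, 255).astype(np.uint8)
        image = Image.fromarray(arr).convert("RGB")
    else:
        image = image.convert("RGB")
    image = image.resize((resize_to, resize_to), Image.BILINEAR)
    margin = resize_to - crop_to
    if phase == "eval_deterministic":
        top = left = margin // 2
    else:
        top = int(rng.integers(0, margin + 1))
        left = int(rng.integers(0, margin + 1))
    arr = np.asarray(image, dtype=np.float32)[top:top + crop_to,
                                              left:left + crop_to] / 255.0
    if phase == "train" and rng.random() < 0.5:
        arr = arr[:, ::-1]
    arr = (arr - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(arr.transpose(2, 0, 1))
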