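"""Dataset IO, 224x224 standardization, and the five-round cross-validation plan.

The split follows the 3.5 : 0.5 : 1 train/test/eval ratio (70% / 10% / 20%):
ids are shuffled once, dealt into ten shards, and round r (r = 0..4) takes
shard 2r as its test set and the two following shards (cyclically) as the
evaluation set, leaving seven shards for training. Test shards are therefore
pairwise disjoint across rounds. When labels are available the shards are
stratified by class (each shard receives an equal share of every class, within
one sample) because a 10% test shard of a small unbalanced dataset can
otherwise miss a class entirely.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

from .errors import FormatError, SizeError
from .synthetic_data import CLASS_NAMES, LabelledSample

__all__ = ["LabelledSample", "FoldPlan", "load_dataset", "standardize",
           "make_fold_plan"]

log = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    rounds: list   # 5 entries of (train_ids, test_ids, eval_ids)

    def to_json(self, **kwargs) -> str:
        payload = [{"train": list(tr), "test": list(te), "eval": list(ev)}
                   for tr, te, ev in self.rounds]
        return json.dumps(payload, sort_keys=True, **kwargs)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json(indent=1))

    @classmethod
    def load(cls, path) -> "FoldPlan":
        payload = json.loads(Path(path).read_text())
        return cls(rounds=[(r["train"], r["test"], r["eval"]) for r in payload])


def load_dataset(root) -> list[LabelledSample]:
    """Read the images/ masks/ labels.csv layout; ids sorted lexicographically."""
    root = Path(root)
    images_dir = root / "images"
    if not images_dir.is_dir():
        raise FormatError(f"no images/ directory under {root}")
    labels: dict[str, int] = {}
    labels_path = root / "labels.csv"
    if labels_path.exists():
        table = pd.read_csv(labels_path)
        for _, row in table.iterrows():
            name = str(row["class_name"])
            if name not in CLASS_NAMES:
                raise FormatError(
                    f"unknown class name {name!r} for id {row['id']!r} "
                    f"(expected one of {CLASS_NAMES})")
            labels[str(row["id"])] = CLASS_NAMES.index(name)
    samples = []
    for img_path in sorted(images_dir.glob("*.png")) + sorted(images_dir.glob("*.jpg")):
        sid = img_path.stem
        image = np.asarray(Image.open(img_path).convert("RGB"))
        mask = None
        mask_path = root / "masks" / f"{sid}.png"
        if mask_path.exists():
            mask = (np.asarray(Image.open(mask_path).convert("L")) > 127).astype(np.uint8)
            if mask.shape != image.shape[:2]:
                raise FormatError(
                    f"image/mask size mismatch for id {sid!r}: "
                    f"image {image.shape[:2]} vs mask {mask.shape}")
        else:
            log.warning("sample %s has no mask", sid)
        label = labels.get(sid)
        if label is None:
            log.warning("sample %s has no label", sid)
        samples.append(LabelledSample(id=sid, image=image, mask=mask, label=label))
    return samples


def standardize(sample: LabelledSample, size: int = 224) -> LabelledSample:
    """Resample to size x size; image bilinear in [0,1], mask nearest + rebinarized."""
    image = np.asarray(sample.image)
    if image.size == 0:
        raise ValueError(f"sample {sample.id!r} has an empty image")
    if image.dtype == np.uint8:
        image = image.astype(np.float32) / 255.0
    image = resize(image, (size, size), order=1, anti_aliasing=False,
                   preserve_range=True).astype(np.float32)
    image = np.clip(image, 0.0, 1.0)
    mask = sample.mask
    if mask is not None:
        mask = resize(mask.astype(np.float32), (size, size), order=0,
                      anti_aliasing=False, preserve_range=True)
        mask = (mask > 0.5).astype(np.uint8)
    return replace(sample, image=image, mask=mask)


def make_fold_plan(ids, seed: int, labels=None, stratify: bool = True) -> FoldPlan:
    """Five-round 70/10/20 plan with pairwise-disjoint test shards."""
    ids = list(ids)
    if len(ids) < 10:
        raise SizeError(f"need at least 10 ids for a 10-shard plan, got {len(ids)}")
    rng = np.random.default_rng(seed)
    if labels is not None and stratify:
        labels = list(labels)
        if len(labels) != len(ids):
            raise ValueError("labels and ids differ in length")
        ordered: list = []
        for cls in sorted(set(labels)):
            members = [i for i, lab in zip(ids, labels) if lab == cls]
            rng.shuffle(members)
            ordered.extend(members)
        shards: list[list] = [[] for _ in range(10)]
        for k, sid in enumerate(ordered):
            shards[k % 10].append(sid)
    else:
        shuffled = list(ids)
        rng.shuffle(shuffled)
        shards = [list(s) for s in np.array_split(np.array(shuffled, dtype=object), 10)]
    rounds = []
    for r in range(5):
        test_idx = 2 * r
        eval_idx = {(2 * r + 1) % 10, (2 * r + 2) % 10}
        test = list(shards[test_idx])
        ev = [sid for k in sorted(eval_idx) for sid in shards[k]]
        train = [sid for k in range(10) if k != test_idx and k not in eval_idx
                 for sid in shards[k]]
        rounds.append((train, test, ev))
    return FoldPlan(rounds=rounds)
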