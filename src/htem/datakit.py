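"""Dataset handling: image-folder I/O, the evaluation protocol's split /
augmentation / one-vs-rest / noise constructions, and a synthetic generator
of microorganism-like images.

The synthetic generator emulates the regime of a small balanced microscopy
collection — by default 21 classes of 40 images each (840 total) — where
classes are separable mostly by organism shape.  Six shape archetypes are
cycled (ellipsoid, rod, rayed star, spiral, flagellated blob, ring) with
per-class size ranges, texture frequencies and background intensities so
that any requested number of classes stays pairwise distinct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "Record", "LabelledDataset", "SplitSpec", "NoiseSpec", "SynthSpec",
    "load_image_folder", "split_dataset", "augment_geometric",
    "make_imbalanced_versions", "add_noise", "generate_synthetic_dataset",
    "preprocess", "preprocess_batch", "write_dataset",
]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}

ARCHETYPES = ("ellipsoid", "rod", "rayed_star", "spiral", "flagellated_blob", "ring")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Record:
    image: "np.ndarray | str | Path"        # uint8 HWC array or a file path
    label: int
    split: str = "none"
    uid: str = ""


@dataclass
class LabelledDataset:
    records: list[Record]
    class_names: list[str]

    def __post_init__(self):
        for r in self.records:
            if not 0 <= r.label < len(self.class_names):
                raise ValueError(f"record {r.uid!r} label {r.label} out of range")

    def __len__(self) -> int:
        return len(self.records)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    def get_image(self, i: int) -> np.ndarray:
        """Decoded uint8 RGB array of record ``i``."""
        img = self.records[i].image
        if isinstance(img, np.ndarray):
            arr = img
        else:
            try:
                with Image.open(img) as im:
                    arr = np.asarray(im.convert("RGB"))
            except Exception as exc:
                raise ValueError(f"cannot decode image file {img}") from exc
        if arr.ndim == 2:
            arr = np.repeat(arr[:, :, None], 3, axis=2)
        return arr

    def subset(self, split: str) -> "LabelledDataset":
        recs = [r for r in self.records if r.split == split]
        return LabelledDataset(recs, self.class_names)

    def class_counts(self) -> np.ndarray:
        counts = np.zeros(len(self.class_names), dtype=np.int64)
        for r in self.records:
            counts[r.label] += 1
        return counts

    def manifest_csv(self, seed_note: str = "") -> str:
        lines = [f"# seed: {seed_note}", "path,class,split"]
        for r in self.records:
            path = r.image if isinstance(r.image, (str, Path)) else r.uid
            lines.append(f"{path},{self.class_names[r.label]},{r.split}")
        return "\n".join(lines)


@dataclass
class SplitSpec:
    train_frac: float = 0.375
    val_frac: float = 0.25
    test_frac: float = 0.375
    seed: int = 0

    def __post_init__(self):
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(f < 0 for f in fracs):
            raise ValueError("split fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(fracs)}")


@dataclass
class NoiseSpec:
    kind: str = "salt_pepper"               # or "gaussian"
    amount: float = 0.05                    # salt-pepper pixel fraction
    sigma: float = 0.05                     # gaussian std on [0,1] scale
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("salt_pepper", "gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not 0.0 <= self.amount <= 1.0:
            raise ValueError(f"amount must be in [0,1], got {self.amount}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass
class SynthSpec:
    n_classes: int = 21
    per_class: int = 40
    image_size: int = 224
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.per_class < 1:
            raise ValueError("need at least 1 image per class")


# ---------------------------------------------------------------------------
# folder I/O
# ---------------------------------------------------------------------------

def load_image_folder(root) -> LabelledDataset:
    """Load a class-per-directory image tree.

    Classes are sorted lexicographically to fix indices; records are sorted
    by (class, filename) so ordering is deterministic.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    class_names, records = [], []
    for d in class_dirs:
        files = sorted(f for f in d.iterdir()
                       if f.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            warnings.warn(f"skipping empty class directory {d}", UserWarning)
            continue
        label = len(class_names)
        class_names.append(d.name)
        for f in files:
            try:
                with Image.open(f) as im:
                    im.verify()
            except Exception as exc:
                raise ValueError(f"undecodable image file: {f}") from exc
            records.append(Record(image=str(f), label=label, uid=f"{d.name}/{f.name}"))
    return LabelledDataset(records, class_names)


def write_dataset(ds: LabelledDataset, out_dir, seed_note: str = "") -> None:
    """Write a dataset as class-per-directory PNGs plus a manifest CSV."""
    out_dir = Path(out_dir)
    for i, r in enumerate(ds.records):
        cls_dir = out_dir / ds.class_names[r.label]
        cls_dir.mkdir(parents=True, exist_ok=True)
        name = (r.uid or f"img_{i:05d}").replace("/", "_") + ".png"
        Image.fromarray(ds.get_image(i)).save(cls_dir / name)
    (out_dir / "manifest.csv").write_text(ds.manifest_csv(seed_note))


# ---------------------------------------------------------------------------
# protocol constructions
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, fracs: list[float]) -> list[int]:
    ideal = [n * f for f in fracs]
    base = [int(np.floor(x)) for x in ideal]
    short = n - sum(base)
    order = sorted(range(len(fracs)), key=lambda i: (-(ideal[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def split_dataset(ds: LabelledDataset, spec: SplitSpec) -> LabelledDataset:
    """Stratified train/val/test assignment with largest-remainder rounding."""
    rng = np.random.default_rng(spec.seed)
    fracs = [spec.train_frac, spec.val_frac, spec.test_frac]
    names = ["train", "val", "test"]
    n_splits = sum(1 for f in fracs if f > 0)
    out = [replace(r) for r in ds.records]
    for label in range(len(ds.class_names)):
        idx = [i for i, r in enumerate(ds.records) if r.label == label]
        if len(idx) < n_splits:
            raise ValueError(f"class {ds.class_names[label]!r} has {len(idx)} "
                             f"records, fewer than {n_splits} splits")
        counts = _largest_remainder(len(idx), fracs)
        perm = rng.permutation(len(idx))
        pos = 0
        for split_name, cnt in zip(names, counts):
            for j in perm[pos:pos + cnt]:
                out[idx[j]].split = split_name
            pos += cnt
    return LabelledDataset(out, ds.class_names)


_TRANSFORMS = (
    ("rot90", lambda a: np.rot90(a, 1)),
    ("rot180", lambda a: np.rot90(a, 2)),
    ("rot270", lambda a: np.rot90(a, 3)),
    ("flipud", np.flipud),
    ("fliplr", np.fliplr),
)


def augment_geometric(ds: LabelledDataset) -> LabelledDataset:
    """Original plus five geometric copies per image (6x the input size).

    The transforms are rotations by 90/180/270 degrees and up-down /
    left-right mirrors; labels and split tags are preserved.
    """
    if not ds.records:
        raise ValueError("cannot augment an empty dataset")
    out: list[Record] = []
    for i, r in enumerate(ds.records):
        img = ds.get_image(i)
        out.append(Record(image=img, label=r.label, split=r.split, uid=r.uid))
        for name, fn in _TRANSFORMS:
            out.append(Record(image=np.ascontiguousarray(fn(img)), label=r.label,
                              split=r.split, uid=f"{r.uid}:{name}"))
    return LabelledDataset(out, ds.class_names)


def make_imbalanced_versions(ds: LabelledDataset) -> list[LabelledDataset]:
    """One binary dataset per class: class i relabelled positive (1), rest 0."""
    if len(ds.class_names) < 2:
        raise ValueError("need at least 2 classes")
    versions = []
    for pos in range(len(ds.class_names)):
        recs = [Record(image=r.image, label=int(r.label == pos),
                       split=r.split, uid=r.uid) for r in ds.records]
        versions.append(LabelledDataset(
            recs, ["negative", f"positive:{ds.class_names[pos]}"]))
    return versions


def add_noise(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Corrupt a float image on [0,1] scale; deterministic per seed.

    salt_pepper: exactly round(amount * H * W) pixel locations forced to
    0 or 1 (all channels, equal probability).  gaussian: additive
    N(0, sigma^2) per channel, clipped to [0,1].
    """
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image intensities must be normalized to [0,1]")
    rng = np.random.default_rng(spec.seed)
    out = image.copy()
    if spec.kind == "salt_pepper":
        h, w = image.shape[:2]
        n_hit = int(round(spec.amount * h * w))
        flat = rng.choice(h * w, size=n_hit, replace=False)
        values = rng.integers(0, 2, size=n_hit).astype(np.float64)
        rr, cc = np.unravel_index(flat, (h, w))
        if image.ndim == 3:
            out[rr, cc, :] = values[:, None]
        else:
            out[rr, cc] = values
    else:
        out = np.clip(out + rng.normal(0.0, spec.sigma, size=image.shape), 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# synthetic microorganism-like image generator
# ---------------------------------------------------------------------------

def _class_params(label: int) -> dict:
    """Deterministic per-class rendering parameters."""
    archetype = ARCHETYPES[label % len(ARCHETYPES)]
    variant = label // len(ARCHETYPES)
    return {
        "archetype": archetype,
        "scale_range": (0.45 - 0.07 * variant, 0.65 - 0.07 * variant),
        "texture_freq": 6.0 + 4.0 * variant,
        "background": 0.25 + 0.12 * variant,
        "rays": 5 + 2 * variant,            # rayed star only
        "foreground": 0.85 - 0.1 * (variant % 2),
    }


def _stamp_disks(canvas: np.ndarray, xs, ys, radius: float, value: float,
                 grid_x: np.ndarray, grid_y: np.ndarray) -> None:
    for px, py in zip(xs, ys):
        mask = (grid_x - px) ** 2 + (grid_y - py) ** 2 <= radius ** 2
        canvas[mask] = value


def _render_organism(size: int, params: dict, rng: np.random.Generator) -> np.ndarray:
    """One grayscale [0,1] image of the class archetype with random pose."""
    lin = np.linspace(-1.0, 1.0, size)
    gx, gy = np.meshgrid(lin, lin)
    theta = rng.uniform(0, 2 * np.pi)
    cx, cy = rng.uniform(-0.15, 0.15, size=2)
    scale = rng.uniform(*params["scale_range"])
    # rotate + translate coordinates into the organism frame
    x = ((gx - cx) * np.cos(theta) + (gy - cy) * np.sin(theta)) / scale
    y = (-(gx - cx) * np.sin(theta) + (gy - cy) * np.cos(theta)) / scale
    r = np.sqrt(x ** 2 + y ** 2)
    phi = np.arctan2(y, x)

    arch = params["archetype"]
    if arch == "ellipsoid":
        mask = (x / 1.0) ** 2 + (y / 0.6) ** 2 <= 1.0
    elif arch == "rod":
        mask = (np.abs(x) <= 1.0) & (np.abs(y) <= 0.28)
        mask |= ((np.abs(x) - 1.0) ** 2 + y ** 2 <= 0.28 ** 2)   # capsule caps
    elif arch == "rayed_star":
        mask = r <= 0.55 * (1.0 + 0.45 * np.cos(params["rays"] * phi))
    elif arch == "ring":
        mask = (r >= 0.55) & (r <= 0.95)
    elif arch == "spiral":
        t = np.linspace(0, 4 * np.pi, 160)
        rr = 0.08 + 0.075 * t
        mask = np.zeros((size, size), dtype=bool)
        canvas = mask.astype(float)
        _stamp_disks(canvas, rr * np.cos(t), rr * np.sin(t), 0.09, 1.0, x, y)
        mask = canvas > 0.5
    else:  # flagellated blob
        mask = (x / 0.55) ** 2 + (y / 0.45) ** 2 <= 1.0
        t = np.linspace(0, 1, 120)
        tail_x = 0.5 + 1.1 * t
        tail_y = 0.22 * np.sin(9.0 * t)
        canvas = np.zeros((size, size))
        _stamp_disks(canvas, tail_x, tail_y, 0.06, 1.0, x, y)
        mask |= canvas > 0.5

    img = np.full((size, size), params["background"])
    img += rng.normal(0.0, 0.04, size=(size, size))              # background grain
    texture = 1.0 + 0.25 * np.sin(params["texture_freq"] * x) \
                  * np.sin(params["texture_freq"] * y)
    img[mask] = params["foreground"] * texture[mask]
    img += rng.normal(0.0, 0.02, size=(size, size))              # sensor noise
    return np.clip(img, 0.0, 1.0)


def generate_synthetic_dataset(spec: SynthSpec) -> LabelledDataset:
    """Render a balanced, fully seeded dataset of shape-discriminable classes."""
    rng = np.random.default_rng(spec.seed)
    records = []
    class_names = []
    for label in range(spec.n_classes):
        params = _class_params(label)
        name = f"class{label:02d}_{params['archetype']}"
        class_names.append(name)
        for j in range(spec.per_class):
            gray = _render_organism(spec.image_size, params, rng)
            img = (np.repeat(gray[:, :, None], 3, axis=2) * 255).round().astype(np.uint8)
            records.append(Record(image=img, label=label, uid=f"{name}/{j:04d}"))
    return LabelledDataset(records, class_names)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(image: np.ndarray, side: int = 224,
               standardize: bool = False) -> np.ndarray:
    """Resize the shorter side to ``side``, center-crop, scale to [0,1].

    Returns a float32 (side, side, 3) array.  ``side`` must be divisible
    by 32 (the network's total downsampling factor).
    """
    if side % 32 != 0:
        raise ValueError(f"side must be divisible by 32, got {side}")
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    h, w = arr.shape[:2]
    if (h, w) != (side, side):
        if h < w:
            new_h, new_w = side, max(side, int(round(w * side / h)))
        else:
            new_h, new_w = max(side, int(round(h * side / w))), side
        im = Image.fromarray(arr.astype(np.uint8))
        im = im.resize((new_w, new_h), Image.BILINEAR)
        arr = np.asarray(im)
        top = (new_h - side) // 2
        left = (new_w - side) // 2
        arr = arr[top:top + side, left:left + side]
    out = arr.astype(np.float32) / 255.0
    if standardize:
        out = (out - out.mean(axis=(0, 1))) / (out.std(axis=(0, 1)) + 1e-7)
    return out


def preprocess_batch(ds: LabelledDataset, side: int = 224,
                     noise: NoiseSpec | None = None,
                     standardize: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Stack a dataset into (B, side, side, 3) float32 plus int labels.

    Noise, when given, is applied on the [0,1] scale before resizing, with
    a per-record seed derived from the spec seed so runs are reproducible.
    """
    images, labels = [], []
    for i, r in enumerate(ds.records):
        img = ds.get_image(i)
        if noise is not None:
            f = img.astype(np.float64) / 255.0
            f = add_noise(f, replace(noise, seed=noise.seed + i))
            img = (f * 255).round().astype(np.uint8)
        images.append(preprocess(img, side, standardize))
        labels.append(r.label)
    return np.stack(images), np.array(labels, dtype=np.int64)
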