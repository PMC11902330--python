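"""Dataset I/O, offline augmentation and the synthetic scene generator.

Labels follow the YOLO text convention: one ``class cx cy w h`` line per
object, coordinates normalized to ``[0, 1]``.  Maturity classes are fixed
as ``0 = ripe`` (red), ``1 = semi-ripe`` (orange), ``2 = unripe`` (green).

The offline augmentation mirrors the acquisition protocol of the tomato
study this package models: minority-class images are expanded by +90/+180/
+270-degree rotations (x4), then the whole set — originals and rotations —
is flipped horizontally (x2).  Starting from 1249 images with 304 minority
images this yields 1216 minority-derived images and 4322 images overall,
which an 8:1:1 split partitions into 3457/432/433.

Because the original orchard photographs are not publicly deposited, a
synthetic scene generator stands in for them: textured foliage backgrounds,
elliptical fruit in class-specific color bands with hue jitter, overlapping
clusters, partial leaf/branch occluders and illumination jitter, with
pixel-accurate labels.  It makes no attempt at photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .boxes import Box

__all__ = [
    "CLASS_NAMES", "LabeledImage", "DatasetSplit", "SceneSpec",
    "read_yolo_labels", "write_yolo_labels", "rotate_augment", "flip_augment",
    "augment_dataset", "split_dataset", "generate_scenes", "render_scene",
    "save_dataset", "write_dataset_yaml",
]

CLASS_NAMES = ("ripe", "semi-ripe", "unripe")


@dataclass
class LabeledImage:
    """An image's identity, size and normalized ground-truth boxes."""

    image_id: str
    width: int
    height: int
    boxes: List[Box] = field(default_factory=list)

    def __post_init__(self):
        for b in self.boxes:
            _check_box(b, self.image_id)

    def pixel_boxes(self) -> List[Box]:
        """Boxes scaled from normalized to pixel units of this image."""
        return [Box(b.cx * self.width, b.cy * self.height,
                    b.w * self.width, b.h * self.height,
                    b.class_id, b.confidence) for b in self.boxes]

    def class_counts(self, num_classes: int = 3) -> np.ndarray:
        out = np.zeros(num_classes, dtype=int)
        for b in self.boxes:
            out[b.class_id] += 1
        return out


def _check_box(b: Box, ctx: str) -> None:
    for name, v in (("cx", b.cx), ("cy", b.cy), ("w", b.w), ("h", b.h)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{ctx}: normalized {name}={v} outside [0, 1]")
    if b.class_id is None or b.class_id < 0:
        raise ValueError(f"{ctx}: box missing a valid class id")


@dataclass
class DatasetSplit:
    """Disjoint train/val/test image-id lists."""

    train: List[str]
    val: List[str]
    test: List[str]
    ratios: Tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self):
        sets = [set(self.train), set(self.val), set(self.test)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("split groups overlap")


# ---------------------------------------------------------------------
# label files
# ---------------------------------------------------------------------

def read_yolo_labels(path, image_id: Optional[str] = None,
                     width: int = 0, height: int = 0) -> LabeledImage:
    """Parse a YOLO label file; malformed lines are rejected with their
    line number, out-of-range coordinates with file and line."""
    path = Path(path)
    boxes = []
    with open(path) as f:
        for ln, line in enumerate(f, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(
                    f"{path}:{ln}: expected 5 fields 'class cx cy w h', got {len(parts)}")
            try:
                cid = int(parts[0])
                cx, cy, w, h = (float(p) for p in parts[1:])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: unparseable field ({e})") from None
            if cid < 0:
                raise ValueError(f"{path}:{ln}: negative class id {cid}")
            for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
                if not (0.0 <= v <= 1.0):
                    raise ValueError(
                        f"{path}:{ln}: {name}={v} outside the normalized range [0, 1]")
            boxes.append(Box(cx, cy, w, h, class_id=cid))
    return LabeledImage(image_id or path.stem, width, height, boxes)


def write_yolo_labels(img: LabeledImage, path) -> None:
    """Write labels at 6 decimal places (lossless round-trip at that precision)."""
    lines = [f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
             for b in img.boxes]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------
# geometric augmentation
# ---------------------------------------------------------------------

def _rot_box(b: Box, angle: int) -> Box:
    if angle == 90:
        return Box(1.0 - b.cy, b.cx, b.h, b.w, b.class_id, b.confidence)
    if angle == 180:
        return Box(1.0 - b.cx, 1.0 - b.cy, b.w, b.h, b.class_id, b.confidence)
    if angle == 270:
        return Box(b.cy, 1.0 - b.cx, b.h, b.w, b.class_id, b.confidence)
    raise ValueError(f"rotation angle must be 90, 180 or 270, got {angle}")


def rotate_augment(img: LabeledImage, angle: int,
                   pixels: Optional[np.ndarray] = None):
    """Rotate clockwise by +90/+180/+270 degrees.

    Box coordinates transform exactly; a 90/270 rotation swaps the canvas
    width and height.  If ``pixels`` is given the image array is rotated
    too and ``(LabeledImage, ndarray)`` is returned.
    """
    if angle not in (90, 180, 270):
        raise ValueError(f"rotation angle must be 90, 180 or 270, got {angle}")
    boxes = [_rot_box(b, angle) for b in img.boxes]
    if angle in (90, 270):
        w, h = img.height, img.width
    else:
        w, h = img.width, img.height
    out = LabeledImage(f"{img.image_id}_rot{angle}", w, h, boxes)
    if pixels is None:
        return out
    k = {90: 3, 180: 2, 270: 1}[angle]  # np.rot90 turns counter-clockwise
    return out, np.ascontiguousarray(np.rot90(pixels, k))


def flip_augment(img: LabeledImage, pixels: Optional[np.ndarray] = None):
    """Horizontal mirror: ``cx -> 1 - cx``; an involution."""
    boxes = [Box(1.0 - b.cx, b.cy, b.w, b.h, b.class_id, b.confidence)
             for b in img.boxes]
    out = LabeledImage(f"{img.image_id}_flip", img.width, img.height, boxes)
    if pixels is None:
        return out
    return out, np.ascontiguousarray(pixels[:, ::-1])


def augment_dataset(images: Sequence[LabeledImage], minority_ids: Set[str]
                    ) -> List[LabeledImage]:
    """Offline expansion: minority images gain their three rotations, then
    the complete set is mirrored and appended.

    Output size is ``(N - M + 4M) * 2`` for ``N`` inputs of which ``M`` are
    minority.  Generated ids are deterministic (``<id>_rot90``,
    ``<id>_flip``, ...), and duplicate input ids are rejected.
    """
    ids = [im.image_id for im in images]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate image ids in input")
    unknown = set(minority_ids) - set(ids)
    if unknown:
        raise ValueError(f"minority ids not present in the dataset: {sorted(unknown)[:5]}")
    expanded: List[LabeledImage] = []
    for im in images:
        expanded.append(im)
        if im.image_id in minority_ids:
            for angle in (90, 180, 270):
                expanded.append(rotate_augment(im, angle))
    return expanded + [flip_augment(im) for im in expanded]


def split_dataset(images: Sequence[LabeledImage],
                  ratios: Tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0) -> DatasetSplit:
    """Deterministic seeded shuffle into train/val/test.

    Sizes are ``floor(r0*N)``, ``floor(r1*N)`` and the remainder — the
    rounding rule under which 4322 images give 3457/432/433 at 8:1:1.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    ids = [im.image_id for im in images]
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 images to split, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(ratios[0] * n)
    n_val = int(ratios[1] * n)
    shuffled = [ids[i] for i in order]
    return DatasetSplit(shuffled[:n_train],
                        shuffled[n_train:n_train + n_val],
                        shuffled[n_train + n_val:], ratios)


# ---------------------------------------------------------------------
# synthetic scenes
# ---------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Parameters of the synthetic orchard-scene generator.

    Defaults emulate the source imagery: three maturity classes mixed
    roughly 12:5:10, a handful of fruit per frame, frequent cluster overlap
    and partial occlusion, variable illumination, and small-to-medium
    object scales.
    """

    n_images: int = 100
    image_size: int = 640
    objects_per_image: Tuple[int, int] = (3, 8)
    class_mix: Tuple[float, float, float] = (12 / 27, 5 / 27, 10 / 27)
    overlap_prob: float = 0.3
    occlusion_prob: float = 0.3
    illumination_jitter: float = 0.3
    rng_seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-6:
            raise ValueError("class_mix proportions must sum to 1")
        for name in ("overlap_prob", "occlusion_prob", "illumination_jitter"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_images < 1 or self.image_size < 32:
            raise ValueError("need n_images >= 1 and image_size >= 32")


# class color bands (RGB, pre-jitter): red / orange / green
_CLASS_RGB = np.array([[200, 35, 30], [235, 140, 35], [120, 170, 60]], float)
_LEAF_RGB = np.array([45, 90, 40], float)


def _background(rng: np.random.Generator, s: int) -> np.ndarray:
    """Foliage-like texture: bilinearly upsampled coarse noise in dark greens."""
    coarse = rng.random((s // 16 + 2, s // 16 + 2, 3))
    yy = np.linspace(0, coarse.shape[0] - 1.001, s)
    xx = np.linspace(0, coarse.shape[1] - 1.001, s)
    y0, x0 = yy.astype(int), xx.astype(int)
    fy, fx = (yy - y0)[:, None, None], (xx - x0)[None, :, None]
    up = (coarse[y0][:, x0] * (1 - fy) * (1 - fx)
          + coarse[y0 + 1][:, x0] * fy * (1 - fx)
          + coarse[y0][:, x0 + 1] * (1 - fy) * fx
          + coarse[y0 + 1][:, x0 + 1] * fy * fx)
    base = np.array([35, 60, 30], float) + up * np.array([30, 50, 30], float)
    return base


def _ellipse_mask(s: int, cx: float, cy: float, rx: float, ry: float,
                  angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0:s, 0:s]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def render_scene(spec: SceneSpec, rng: np.random.Generator
                 ) -> Tuple[np.ndarray, List[Box]]:
    """Render one scene; returns (HxWx3 uint8 image, normalized boxes).

    Labels are pixel-accurate bounding boxes of each fruit's *unoccluded*
    silhouette clipped to the canvas.  Fruit whose silhouette falls fully
    outside the canvas are resampled rather than dropped, so every drawn
    object is labeled.  There are deliberately no unlabeled distant
    background fruit.
    """
    s = spec.image_size
    img = _background(rng, s)
    n_obj = int(rng.integers(spec.objects_per_image[0], spec.objects_per_image[1] + 1))
    classes = rng.choice(3, size=n_obj, p=np.asarray(spec.class_mix))
    boxes: List[Box] = []
    fruit_masks: List[np.ndarray] = []
    prev_center: Optional[Tuple[float, float]] = None
    for cid in classes:
        for _ in range(50):  # resample until the fruit is visible on canvas
            r = rng.uniform(0.035, 0.11) * s
            if prev_center is not None and rng.random() < spec.overlap_prob:
                # cluster next to the previous fruit -> overlapping pair
                cx = prev_center[0] + rng.uniform(-1.2, 1.2) * r
                cy = prev_center[1] + rng.uniform(-1.2, 1.2) * r
            else:
                cx, cy = rng.uniform(0, s), rng.uniform(0, s)
            rx, ry = r, r * rng.uniform(0.85, 1.0)
            mask = _ellipse_mask(s, cx, cy, rx, ry, rng.uniform(0, np.pi))
            if mask.any():
                break
        else:  # pragma: no cover - 50 draws on-canvas virtually always succeed
            continue
        prev_center = (cx, cy)
        color = _CLASS_RGB[cid] + rng.normal(0, 12, 3)  # hue jitter
        shade = 0.75 + 0.5 * ((np.mgrid[0:s, 0:s][1] - cx) / max(rx, 1)) * 0.1
        img[mask] = (color * np.clip(shade[mask], 0.6, 1.1)[:, None])
        fruit_masks.append(mask)
        ys, xs = np.nonzero(mask)
        boxes.append(Box(
            cx=float((xs.min() + xs.max() + 1) / 2) / s,
            cy=float((ys.min() + ys.max() + 1) / 2) / s,
            w=float(xs.max() - xs.min() + 1) / s,
            h=float(ys.max() - ys.min() + 1) / s,
            class_id=int(cid)))
    # partial leaf/branch occluders drawn over fruit edges
    for mask, b in zip(fruit_masks, boxes):
        if rng.random() < spec.occlusion_prob:
            r = max(b.w, b.h) * s / 2
            ang = rng.uniform(0, 2 * np.pi)
            ox = b.cx * s + np.cos(ang) * r
            oy = b.cy * s + np.sin(ang) * r
            leaf = _ellipse_mask(s, ox, oy, r * rng.uniform(0.5, 0.9),
                                 r * rng.uniform(0.25, 0.5), rng.uniform(0, np.pi))
            img[leaf] = _LEAF_RGB + rng.normal(0, 8, 3)
    gain = 1.0 + spec.illumination_jitter * rng.uniform(-1.0, 1.0)
    img = np.clip(img * gain, 0, 255).astype(np.uint8)
    return img, boxes


def generate_scenes(spec: SceneSpec, out_dir: Optional[Path] = None
                    ) -> List[Tuple[LabeledImage, np.ndarray]]:
    """Generate ``spec.n_images`` labeled scenes, reproducibly from
    ``spec.rng_seed``.  If ``out_dir`` is given, writes ``images/*.png``
    and ``labels/*.txt`` there as well."""
    rng = np.random.default_rng(spec.rng_seed)
    out = []
    for i in range(spec.n_images):
        img, boxes = render_scene(spec, rng)
        li = LabeledImage(f"scene_{i:05d}", spec.image_size, spec.image_size, boxes)
        out.append((li, img))
    if out_dir is not None:
        save_dataset(out, Path(out_dir))
    return out


def save_dataset(samples: Iterable[Tuple[LabeledImage, np.ndarray]],
                 out_dir: Path, split: str = "") -> None:
    """Write PNG images and YOLO label files in the usual layout
    (``images/[split]/*.png`` + ``labels/[split]/*.txt``)."""
    from PIL import Image

    out_dir = Path(out_dir)
    img_dir = out_dir / "images" / split if split else out_dir / "images"
    lbl_dir = out_dir / "labels" / split if split else out_dir / "labels"
    img_dir.mkdir(parents=True, exist_ok=True)
    lbl_dir.mkdir(parents=True, exist_ok=True)
    for li, arr in samples:
        Image.fromarray(arr).save(img_dir / f"{li.image_id}.png")
        write_yolo_labels(li, lbl_dir / f"{li.image_id}.txt")


def load_dataset_dir(root: Path, split: str = "") -> List[Tuple[LabeledImage, np.ndarray]]:
    """Load an ``images/[split]`` + ``labels/[split]`` directory pair."""
    from PIL import Image

    root = Path(root)
    img_dir = root / "images" / split if split else root / "images"
    lbl_dir = root / "labels" / split if split else root / "labels"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no image directory at {img_dir}")
    out = []
    for p in sorted(img_dir.iterdir()):
        if p.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        arr = np.asarray(Image.open(p).convert("RGB"))
        lp = lbl_dir / (p.stem + ".txt")
        li = (read_yolo_labels(lp, p.stem, arr.shape[1], arr.shape[0])
              if lp.exists() else LabeledImage(p.stem, arr.shape[1], arr.shape[0], []))
        out.append((li, arr))
    if not out:
        raise FileNotFoundError(f"no images found under {img_dir}")
    return out


def write_dataset_yaml(out_dir: Path, nc: int = 3,
                       names: Sequence[str] = CLASS_NAMES) -> Path:
    import yaml

    out_dir = Path(out_dir)
    p = out_dir / "dataset.yaml"
    with open(p, "w") as f:
        yaml.safe_dump({"path": str(out_dir), "train": "images/train",
                        "val": "images/val", "test": "images/test",
                        "nc": nc, "names": list(names)}, f, sort_keys=False)
    return p
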