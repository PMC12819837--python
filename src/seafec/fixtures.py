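"""Seeded synthetic agricultural-imagery fixtures.

Emulates the three visual regimes the operator targets, at desk scale
and with full determinism under a seed:

* classification — leaves bearing either dispersed near-circular
  lesion spots or elongated oriented strip lesions, optionally with
  blurred halos (the two canonical maize-lesion morphologies);
* segmentation — intertwined elongated crop and weed blades over soil,
  with per-pixel class masks (0 background, 1 crop, 2 weed) and a
  black/red/green pseudo-colour rendering;
* detection — sparse large or dense small lesion boxes with permitted
  overlap, half-open 0-based pixel coordinates.

Also implements the doubling augmentation policy (rotation, cropping,
scaling, blurring, noise addition; exactly one transformed copy per
image, so per-class counts double) and ratio-based per-class splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "SyntheticSample",
    "AugmentationPolicy",
    "gen_classification_fixture",
    "gen_segmentation_fixture",
    "gen_detection_fixture",
    "augment_double",
    "split_samples",
    "mask_to_pseudocolor",
    "pseudocolor_to_mask",
    "save_fixture",
    "samples_to_arrays",
    "CLS_CLASSES",
    "SEG_PALETTE",
]

CLS_CLASSES = ("spot", "strip")
# class id -> RGB pseudo-colour (background / crop / weed)
SEG_PALETTE = {0: (0, 0, 0), 1: (255, 0, 0), 2: (0, 255, 0)}

AUG_OPERATIONS = ("rotation", "cropping", "scaling", "blurring", "noise")


@dataclass
class SyntheticSample:
    image: np.ndarray                      # (H, W, 3) uint8
    label: int | None = None               # classification class id
    mask: np.ndarray | None = None         # (H, W) uint8 in {0, 1, 2}
    boxes: np.ndarray | None = None        # (N, 4) float, x_min y_min x_max y_max, half-open
    box_labels: np.ndarray | None = None   # (N,) int
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def class_key(self) -> int:
        """Class identity used for per-class bookkeeping (splits, doubling)."""
        return int(self.label) if self.label is not None else 0


@dataclass
class AugmentationPolicy:
    operations: tuple[str, ...] = AUG_OPERATIONS
    copies_per_image: int = 1
    rotation_angles: tuple[float, ...] = (90.0, 180.0, 270.0, 15.0, -15.0)
    crop_range: tuple[float, float] = (0.8, 1.0)
    scale_range: tuple[float, float] = (0.8, 1.2)
    blur_sigma: tuple[float, float] = (0.5, 1.5)
    noise_sigma: float = 8.0

    def __post_init__(self):
        self.operations = tuple(self.operations)
        if not self.operations:
            raise ValueError("at least one augmentation operation must be enabled")
        unknown = set(self.operations) - set(AUG_OPERATIONS)
        if unknown:
            raise ValueError(f"unknown augmentation operations: {sorted(unknown)}")
        if self.copies_per_image < 1:
            raise ValueError("copies_per_image must be >= 1")


def _rng_for(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, stream)])


def _grid(size: int):
    return np.meshgrid(np.arange(size), np.arange(size), indexing="ij")


def _soft_disc(size: int, cy, cx, r) -> np.ndarray:
    yy, xx = _grid(size)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _capsule(size: int, y0, x0, y1, x1, thickness) -> np.ndarray:
    """Pixels within ``thickness`` of the segment (y0,x0)-(y1,x1)."""
    yy, xx = _grid(size)
    dy, dx = y1 - y0, x1 - x0
    n2 = dy * dy + dx * dx
    t = np.clip(((yy - y0) * dy + (xx - x0) * dx) / max(n2, 1e-9), 0.0, 1.0)
    d2 = (yy - (y0 + t * dy)) ** 2 + (xx - (x0 + t * dx)) ** 2
    return d2 <= thickness * thickness


def _leaf_background(rng: np.random.Generator, size: int) -> np.ndarray:
    base = np.array([70, 128, 55], dtype=np.float32)
    img = np.tile(base, (size, size, 1))
    img += rng.normal(0, 6, (size, size, 3)).astype(np.float32)
    grad = np.linspace(-12, 12, size, dtype=np.float32)[:, None, None]
    return img + grad


# ----------------------------------------------------------------------
# classification
# ----------------------------------------------------------------------

def gen_classification_fixture(
    n_per_class: int,
    classes: tuple[str, ...] = CLS_CLASSES,
    image_size: int = 32,
    seed: int = 0,
    blur_halo: bool = False,
) -> list[SyntheticSample]:
    """Balanced spot-vs-strip lesion images, ``n_per_class`` per label.

    Spot images carry 3-6 dispersed near-circular blobs; strip images
    carry 2-4 elongated oriented streaks (which cover more pixels than
    the spots under the default shape parameters).  ``blur_halo``
    smooths lesion edges into the blurred-halo regime.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if image_size < 16:
        raise ValueError("image_size must be >= 16 for the lesion primitives")
    lesion_color = np.array([125, 92, 40], dtype=np.float32)
    samples = []
    for ci, cname in enumerate(classes):
        for i in range(n_per_class):
            rng = _rng_for(seed, 0, ci, i)
            img = _leaf_background(rng, image_size)
            lesion = np.zeros((image_size, image_size), dtype=bool)
            if cname == "strip" or (cname not in CLS_CLASSES and ci % 2 == 1):
                for _ in range(rng.integers(2, 5)):
                    theta = rng.uniform(0, np.pi)
                    length = rng.uniform(0.45, 0.85) * image_size
                    cy, cx = rng.uniform(0.2, 0.8, 2) * image_size
                    dy, dx = np.sin(theta) * length / 2, np.cos(theta) * length / 2
                    thick = rng.uniform(0.05, 0.08) * image_size
                    lesion |= _capsule(image_size, cy - dy, cx - dx, cy + dy, cx + dx, thick)
            else:
                for _ in range(rng.integers(3, 7)):
                    r = rng.uniform(0.04, 0.08) * image_size
                    cy, cx = rng.uniform(0.1, 0.9, 2) * image_size
                    lesion |= _soft_disc(image_size, cy, cx, r)
            alpha = lesion.astype(np.float32)
            if blur_halo:
                alpha = ndimage.gaussian_filter(alpha, sigma=image_size * 0.02 + 0.5)
                alpha = np.clip(alpha * 1.5, 0, 1)
            img = img * (1 - alpha[..., None]) + lesion_color * alpha[..., None]
            img += rng.normal(0, 2, img.shape)
            samples.append(
                SyntheticSample(
                    image=np.clip(img, 0, 255).astype(np.uint8),
                    label=ci,
                    seed=seed,
                    meta={"class_name": cname, "index": i,
                          "lesion_fraction": float(lesion.mean())},
                )
            )
    return samples


# ----------------------------------------------------------------------
# segmentation
# ----------------------------------------------------------------------

def _paint_blade(mask, img, rng, size, cls, color, length_frac, thick_frac):
    theta = rng.uniform(0, np.pi)
    length = rng.uniform(*length_frac) * size
    cy, cx = rng.uniform(0.1, 0.9, 2) * size
    dy, dx = np.sin(theta) * length / 2, np.cos(theta) * length / 2
    thick = rng.uniform(*thick_frac) * size
    blade = _capsule(size, cy - dy, cx - dx, cy + dy, cx + dx, thick)
    mask[blade] = cls
    shade = rng.uniform(0.85, 1.15)
    img[blade] = np.clip(np.array(color, dtype=np.float32) * shade, 0, 255)
    return blade


def gen_segmentation_fixture(
    n: int,
    image_size: int = 32,
    weed_fraction: float = 0.05,
    seed: int = 0,
) -> list[SyntheticSample]:
    """Crop/weed scenes with intertwined elongated blades.

    Weed blades are drawn over crop blades so the two classes share
    long, interleaved boundaries; the expected weed pixel share is
    calibrated to ``weed_fraction`` (within +/-50 percent on average).
    """
    if not (0.0 < weed_fraction < 0.5):
        raise ValueError("weed_fraction must lie in (0, 0.5)")
    samples = []
    # expected weed blade area fraction: length ~0.45, half-thickness ~0.016
    blade_frac = 0.45 * 2 * 0.016
    n_weeds = max(1, round(weed_fraction / blade_frac))
    for i in range(n):
        rng = _rng_for(seed, 1, i)
        soil = np.array([96, 72, 48], dtype=np.float32)
        img = np.tile(soil, (image_size, image_size, 1))
        img += rng.normal(0, 8, img.shape).astype(np.float32)
        mask = np.zeros((image_size, image_size), dtype=np.uint8)
        for _ in range(rng.integers(3, 6)):
            _paint_blade(mask, img, rng, image_size, 1, (60, 130, 50),
                         (0.5, 0.95), (0.04, 0.08))
        for _ in range(n_weeds):
            _paint_blade(mask, img, rng, image_size, 2, (110, 160, 60),
                         (0.35, 0.55), (0.012, 0.02))
        img += rng.normal(0, 3, img.shape)
        samples.append(
            SyntheticSample(
                image=np.clip(img, 0, 255).astype(np.uint8),
                mask=mask,
                seed=seed,
                meta={"index": i, "weed_share": float((mask == 2).mean())},
            )
        )
    return samples


def mask_to_pseudocolor(mask: np.ndarray) -> np.ndarray:
    """(H, W) class mask -> (H, W, 3) black/red/green rendering."""
    out = np.zeros((*mask.shape, 3), dtype=np.uint8)
    for cls, color in SEG_PALETTE.items():
        out[mask == cls] = color
    return out


def pseudocolor_to_mask(rgb: np.ndarray) -> np.ndarray:
    """Inverse of :func:`mask_to_pseudocolor` (exact for palette colours)."""
    mask = np.zeros(rgb.shape[:2], dtype=np.uint8)
    for cls, color in SEG_PALETTE.items():
        mask[(rgb == np.array(color, dtype=np.uint8)).all(axis=-1)] = cls
    return mask


# ----------------------------------------------------------------------
# detection
# ----------------------------------------------------------------------

def gen_detection_fixture(
    n: int,
    image_size: int = 48,
    density: str = "sparse",
    seed: int = 0,
    n_classes: int = 3,
) -> list[SyntheticSample]:
    """Lesion images with box annotations.

    ``dense`` places >= 10 small boxes per image with overlap allowed;
    ``sparse`` places 1-3 large boxes.  All boxes are 0-based half-open
    and lie inside the image.
    """
    if density not in ("sparse", "dense"):
        raise ValueError("density must be 'sparse' or 'dense'")
    lesion_color = np.array([130, 95, 45], dtype=np.float32)
    samples = []
    for i in range(n):
        rng = _rng_for(seed, 2, i)
        img = _leaf_background(rng, image_size)
        if density == "dense":
            count = int(rng.integers(10, 17))
            lo, hi = max(3, image_size // 16), max(5, image_size // 8)
        else:
            count = int(rng.integers(1, 4))
            lo, hi = image_size // 4, int(image_size * 0.55)
        boxes, labels = [], []
        for _ in range(count):
            for _attempt in range(50):
                w = int(rng.integers(lo, hi + 1))
                h = int(rng.integers(lo, hi + 1))
                if w < image_size and h < image_size:
                    break
            else:
                raise ValueError(f"cannot fit a {lo}-{hi} box into image size {image_size}")
            x0 = int(rng.integers(0, image_size - w + 1))
            y0 = int(rng.integers(0, image_size - h + 1))
            boxes.append((x0, y0, x0 + w, y0 + h))
            labels.append(int(rng.integers(0, n_classes)))
            cy, cx = y0 + h / 2, x0 + w / 2
            blob = _soft_disc(image_size, cy, cx, min(w, h) * 0.45)
            img[blob] = lesion_color + rng.normal(0, 4, 3)
        samples.append(
            SyntheticSample(
                image=np.clip(img, 0, 255).astype(np.uint8),
                boxes=np.asarray(boxes, dtype=np.float64),
                box_labels=np.asarray(labels, dtype=np.int64),
                seed=seed,
                meta={"index": i, "density": density},
            )
        )
    return samples


# ----------------------------------------------------------------------
# augmentation
# ----------------------------------------------------------------------

def _rotate_boxes(boxes, angle_deg, size):
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    ctr = (size - 1) / 2.0
    out = []
    for x0, y0, x1, y1 in boxes:
        xs = np.array([x0, x1, x0, x1]) - ctr
        ys = np.array([y0, y0, y1, y1]) - ctr
        # image rotation by +angle == coordinate rotation by -angle
        xr = c * xs + s * ys + ctr
        yr = -s * xs + c * ys + ctr
        out.append((max(xr.min(), 0), max(yr.min(), 0),
                    min(xr.max(), size), min(yr.max(), size)))
    return np.asarray(out, dtype=np.float64)


def _resize_image(img: np.ndarray, size: tuple[int, int], nearest=False) -> np.ndarray:
    pil = Image.fromarray(img)
    resample = Image.NEAREST if nearest else Image.BILINEAR
    return np.asarray(pil.resize((size[1], size[0]), resample))


def _apply_op(sample: SyntheticSample, op: str, policy: AugmentationPolicy,
              rng: np.random.Generator) -> SyntheticSample:
    img = sample.image
    mask, boxes = sample.mask, sample.boxes
    H, W = img.shape[:2]
    if op == "rotation":
        angle = float(rng.choice(policy.rotation_angles))
        if angle in (90.0, 180.0, 270.0):
            k = int(angle // 90)
            img = np.ascontiguousarray(np.rot90(img, k))
            if mask is not None:
                mask = np.ascontiguousarray(np.rot90(mask, k))
        else:
            img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
            if mask is not None:
                mask = ndimage.rotate(mask, angle, reshape=False, order=0, mode="nearest")
        if boxes is not None and len(boxes):
            boxes = _rotate_boxes(boxes, angle, H)
    elif op == "cropping":
        f = rng.uniform(*policy.crop_range)
        ch, cw = max(1, int(round(f * H))), max(1, int(round(f * W)))
        y0 = int(rng.integers(0, H - ch + 1))
        x0 = int(rng.integers(0, W - cw + 1))
        img = _resize_image(img[y0 : y0 + ch, x0 : x0 + cw], (H, W))
        if mask is not None:
            mask = _resize_image(mask[y0 : y0 + ch, x0 : x0 + cw], (H, W), nearest=True)
        if boxes is not None and len(boxes):
            b = boxes.copy()
            b[:, [0, 2]] = (b[:, [0, 2]] - x0) * (W / cw)
            b[:, [1, 3]] = (b[:, [1, 3]] - y0) * (H / ch)
            boxes = np.clip(b, 0, [W, H, W, H])
    elif op == "scaling":
        f = rng.uniform(*policy.scale_range)
        nh, nw = max(1, int(round(f * H))), max(1, int(round(f * W)))
        big = _resize_image(img, (nh, nw))
        bigm = _resize_image(mask, (nh, nw), nearest=True) if mask is not None else None
        if f >= 1.0:  # center crop back
            y0, x0 = (nh - H) // 2, (nw - W) // 2
            img = big[y0 : y0 + H, x0 : x0 + W]
            if bigm is not None:
                mask = bigm[y0 : y0 + H, x0 : x0 + W]
            off = (-x0, -y0)
        else:  # pad back
            y0, x0 = (H - nh) // 2, (W - nw) // 2
            img = np.zeros_like(sample.image)
            img[y0 : y0 + nh, x0 : x0 + nw] = big
            if bigm is not None:
                mask = np.zeros_like(sample.mask)
                mask[y0 : y0 + nh, x0 : x0 + nw] = bigm
            off = (x0, y0)
        if boxes is not None and len(boxes):
            b = boxes * f
            b[:, [0, 2]] += off[0]
            b[:, [1, 3]] += off[1]
            boxes = np.clip(b, 0, [W, H, W, H])
    elif op == "blurring":
        sigma = rng.uniform(*policy.blur_sigma)
        img = ndimage.gaussian_filter(img.astype(np.float32), sigma=(sigma, sigma, 0))
        img = np.clip(img, 0, 255).astype(np.uint8)
    elif op == "noise":
        noisy = img.astype(np.float32) + rng.normal(0, policy.noise_sigma, img.shape)
        img = np.clip(noisy, 0, 255).astype(np.uint8)
    else:  # pragma: no cover
        raise ValueError(f"unknown operation {op!r}")
    # drop boxes collapsed to zero extent by geometry
    box_labels = sample.box_labels
    if boxes is not None and len(boxes):
        keep = (boxes[:, 2] - boxes[:, 0] >= 1) & (boxes[:, 3] - boxes[:, 1] >= 1)
        boxes = boxes[keep]
        box_labels = box_labels[keep] if box_labels is not None else None
    return SyntheticSample(image=img, label=sample.label, mask=mask, boxes=boxes,
                           box_labels=box_labels, seed=sample.seed,
                           meta={**sample.meta, "augmented": op})


def augment_double(
    samples: list[SyntheticSample],
    policy: AugmentationPolicy | None = None,
    seed: int = 0,
) -> list[SyntheticSample]:
    """Originals plus exactly one transformed copy each.

    The operation for each copy is drawn from the policy's enabled set,
    so per-class counts double exactly: (511, 524, 562) -> (1022, 1048,
    1124) under the reference counts.
    """
    policy = policy if policy is not None else AugmentationPolicy()
    if policy.copies_per_image != 1:
        raise ValueError("the doubling policy requires copies_per_image = 1")
    out = list(samples)
    for j, s in enumerate(samples):
        rng = _rng_for(seed, 3, j)
        op = str(rng.choice(policy.operations))
        out.append(_apply_op(s, op, policy, rng))
    return out


# ----------------------------------------------------------------------
# splits and I/O
# ----------------------------------------------------------------------

def split_samples(
    samples: list[SyntheticSample],
    ratios: tuple[float, ...] = (0.7, 0.2, 0.1),
    seed: int = 0,
    names: tuple[str, ...] = ("train", "val", "test"),
) -> dict[str, list[SyntheticSample]]:
    """Disjoint per-class partition at the given ratios.

    Per class, split sizes are floored and the remainder goes to the
    first (training) split, so the splits partition the input exactly.
    """
    if len(ratios) != len(names):
        raise ValueError("ratios and names must align")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    by_class: dict[int, list[SyntheticSample]] = {}
    for s in samples:
        by_class.setdefault(s.class_key(), []).append(s)
    rng = np.random.default_rng(seed)
    out: dict[str, list[SyntheticSample]] = {n: [] for n in names}
    for cls in sorted(by_class):
        group = by_class[cls]
        order = rng.permutation(len(group))
        sizes = [int(np.floor(r * len(group))) for r in ratios]
        sizes[0] += len(group) - sum(sizes)
        pos = 0
        for name, sz in zip(names, sizes):
            out[name].extend(group[i] for i in order[pos : pos + sz])
            pos += sz
    return out


def samples_to_arrays(samples: list[SyntheticSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack classification samples into (N, H, W, 3) images and (N,) labels."""
    images = np.stack([s.image for s in samples])
    labels = np.array([s.label for s in samples], dtype=np.int64)
    return images, labels


def save_fixture(out_dir: str | Path, splits: dict[str, list[SyntheticSample]]):
    """Write images (PNG), pseudo-colour masks (paletted PNG) and a
    boxes/labels JSON per split."""
    out_dir = Path(out_dir)
    for split, samples in splits.items():
        d = out_dir / split
        d.mkdir(parents=True, exist_ok=True)
        records = []
        for i, s in enumerate(samples):
            name = f"{split}_{i:05d}.png"
            Image.fromarray(s.image).save(d / name)
            rec: dict = {"file": name}
            if s.label is not None:
                rec["label"] = int(s.label)
            if s.mask is not None:
                pal = Image.fromarray(s.mask, mode="P")
                palette = [0] * 768
                for cls, color in SEG_PALETTE.items():
                    palette[cls * 3 : cls * 3 + 3] = color
                pal.putpalette(palette)
                pal.save(d / f"{split}_{i:05d}_mask.png")
                rec["mask"] = f"{split}_{i:05d}_mask.png"
            if s.boxes is not None:
                rec["boxes"] = np.asarray(s.boxes, dtype=float).tolist()
                rec["labels"] = np.asarray(s.box_labels, dtype=int).tolist()
            records.append(rec)
        (d / "annotations.json").write_text(json.dumps(records, indent=1))
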