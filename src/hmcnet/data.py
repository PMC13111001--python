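"""Data pipeline: MIAS-format reading, ROI disc masks, preprocessing,
augmentation, patient-level k-fold splitting, and a synthetic phantom
generator.

The MIAS annotation dialect is one whitespace-delimited line per finding:

    mdb001 G CIRC B 535 425 197     (id, tissue, class, severity, x, y, radius)
    mdb003 D NORM                   (normal image: no severity, no ROI)

MIAS places the coordinate origin at the *bottom-left* corner, so mask
construction flips y to image rows.  MIAS ships no patient identifiers; the
322 films are consecutive left/right pairs of 161 patients, so records 2i-1
and 2i share patient i — that pairing is what makes patient-level
cross-validation possible.

The phantom generator emulates the three classes at desk scale: smooth
low-frequency background (normal), one bright near-circular blob with a
smooth boundary (benign), one irregular blob with radiating spicules
(malignant), each with its exact lesion-support mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .autodiff import bilinear_resize_array
from .errors import InputError

LABELS = ("normal", "benign", "malignant")
LABEL_INDEX = {name: i for i, name in enumerate(LABELS)}


# ---------------------------------------------------------------------------
# MIAS records
# ---------------------------------------------------------------------------

@dataclass
class MiasRecord:
    image_id: str
    background: str
    abnormality: str
    severity: str  # "benign" | "malignant" | "none"
    rois: tuple[tuple[tuple[int, int], int], ...] = ()  # ((x, y), radius), MIAS coords
    patient_id: int = -1
    label: str = "normal"
    image_path: Path | None = None

    @property
    def roi_center(self):
        return self.rois[0][0] if self.rois else None

    @property
    def roi_radius(self):
        return self.rois[0][1] if self.rois else None

    @property
    def label_index(self) -> int:
        return LABEL_INDEX[self.label]

    @property
    def image(self) -> np.ndarray:
        if self.image_path is None:
            raise InputError(f"record {self.image_id} has no image attached")
        return load_pgm(self.image_path)


_SEVERITY = {"B": "benign", "M": "malignant"}


def _parse_line(line: str, lineno: int):
    tokens = line.split()
    if len(tokens) == 3:
        image_id, bg, abn = tokens
        if abn != "NORM":
            raise InputError(
                f"line {lineno}: abnormality {abn!r} requires severity (and usually ROI) fields"
            )
        return image_id, bg, abn, "none", None
    if len(tokens) == 4:
        image_id, bg, abn, sev = tokens
        if abn == "NORM" or sev not in _SEVERITY:
            raise InputError(f"line {lineno}: malformed record {line!r}")
        return image_id, bg, abn, _SEVERITY[sev], None
    if len(tokens) == 7:
        image_id, bg, abn, sev, x, y, r = tokens
        if abn == "NORM" or sev not in _SEVERITY:
            raise InputError(f"line {lineno}: malformed record {line!r}")
        try:
            roi = ((int(x), int(y)), int(r))
        except ValueError:
            raise InputError(f"line {lineno}: non-integer ROI fields in {line!r}") from None
        return image_id, bg, abn, _SEVERITY[sev], roi
    raise InputError(f"line {lineno}: expected 3, 4 or 7 fields, got {len(tokens)}: {line!r}")


def parse_mias_info(text: str) -> list[MiasRecord]:
    """Parse the MIAS plain-text annotation file.

    Multi-abnormality images collapse to one record with label precedence
    malignant > benign and the union of ROI discs; patient ids are assigned
    by consecutive pairing (two films per patient).
    """
    order: list[str] = []
    records: dict[str, MiasRecord] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        image_id, bg, abn, severity, roi = _parse_line(line, lineno)
        label = severity if severity in ("benign", "malignant") else "normal"
        if image_id not in records:
            records[image_id] = MiasRecord(image_id, bg, abn, severity, label=label)
            order.append(image_id)
        rec = records[image_id]
        if LABEL_INDEX[label] > LABEL_INDEX[rec.label]:  # malignant > benign > normal
            rec.label = label
            rec.severity = severity
            rec.abnormality = abn
        if roi is not None:
            rec.rois = rec.rois + (roi,)
    result = [records[i] for i in order]
    for i, rec in enumerate(result):
        rec.patient_id = i // 2 + 1
    return result


def read_mias(image_dir, info_file) -> list[MiasRecord]:
    """Read the annotation file and attach the PGM image paths.

    Raises an error if a referenced image is absent from ``image_dir``.
    """
    info_file = Path(info_file)
    records = parse_mias_info(info_file.read_text())
    image_dir = Path(image_dir)
    for rec in records:
        path = image_dir / f"{rec.image_id}.pgm"
        if not path.exists():
            raise InputError(
                f"image {path} referenced by {info_file} not found (id mismatch?)"
            )
        rec.image_path = path
    return records


def load_pgm(path) -> np.ndarray:
    """Load an 8-bit PGM (binary or ASCII dialect) as float32 in [0, 1]."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float32)
    return arr / 255.0


def roi_mask(record: MiasRecord, image_size: int) -> np.ndarray:
    """Union of ROI discs as a boolean mask, y flipped from the MIAS
    bottom-left origin to image rows and clipped to bounds."""
    if not record.rois:
        raise InputError(f"record {record.image_id} carries no ROI")
    rows, cols = np.mgrid[0:image_size, 0:image_size]
    mask = np.zeros((image_size, image_size), dtype=bool)
    for (x, y), radius in record.rois:
        row_c = image_size - 1 - y
        mask |= (rows - row_c) ** 2 + (cols - x) ** 2 <= radius**2
    return mask


# ---------------------------------------------------------------------------
# preprocessing and augmentation
# ---------------------------------------------------------------------------

def preprocess(image: np.ndarray, size: int = 224) -> np.ndarray:
    """Grayscale [0,1] image -> (3, size, size) float32 in [-1, 1]:
    bilinear resize, replication onto three channels, then the fixed
    mean/variance 0.5 normalization (x - 0.5) / 0.5."""
    image = np.asarray(image, dtype=np.float32)
    if image.size == 0:
        raise InputError("empty image")
    if image.ndim != 2:
        raise InputError(f"expected a 2-D grayscale image, got shape {image.shape}")
    resized = bilinear_resize_array(image[None, None], (size, size))[0, 0]
    normalized = (resized - 0.5) / 0.5
    return np.repeat(normalized[None], 3, axis=0).astype(np.float32)


def augment(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stochastic training-time transform, fully determined by ``rng``:
    brightness and contrast factors in [0.8, 1.2], horizontal flip with
    probability 0.5, rotation uniform in [-15, +15] degrees (zero fill),
    applied in the order jitter -> flip -> rotate."""
    image = np.asarray(image, dtype=np.float32)
    brightness = rng.uniform(0.8, 1.2)
    contrast = rng.uniform(0.8, 1.2)
    flip = rng.random() < 0.5
    angle = rng.uniform(-15.0, 15.0)

    out = image * brightness
    out = (out - out.mean()) * contrast + out.mean()
    out = np.clip(out, 0.0, 1.0)
    if flip:
        out = out[:, ::-1]
    out = ndimage.rotate(out, angle, reshape=False, order=1, mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def expand_offline(samples, target_count: int, seed: int):
    """Offline augmentation regime: derive exactly ``target_count`` training
    images by cycling through the samples with fresh augmentation draws."""
    if target_count < 1:
        raise InputError("target_count must be >= 1")
    out = []
    for j in range(target_count):
        src = samples[j % len(samples)]
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, j]))
        out.append((augment(src.image, rng), src.label_index))
    return out


# ---------------------------------------------------------------------------
# patient-level k-fold
# ---------------------------------------------------------------------------

def patient_kfold(records, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition patients into k near-equal groups (sizes differ by at most
    one) and return per-fold (train_indices, test_indices) over records.
    Every image of a patient lands in exactly one test fold."""
    if k < 2:
        raise InputError("k must be >= 2")
    patients = np.array([r.patient_id if hasattr(r, "patient_id") else r for r in records])
    unique = np.unique(patients)
    if k > len(unique):
        raise InputError(f"k={k} exceeds the number of patients ({len(unique)})")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(unique)
    groups = np.array_split(shuffled, k)
    splits = []
    for g in groups:
        test_patients = set(g.tolist())
        test_idx = np.array([i for i, p in enumerate(patients) if p in test_patients], dtype=int)
        train_idx = np.array([i for i, p in enumerate(patients) if p not in test_patients], dtype=int)
        # leakage check: train and test patient sets must be disjoint
        assert not (set(patients[train_idx].tolist()) & set(patients[test_idx].tolist()))
        splits.append((train_idx, test_idx))
    all_test = np.concatenate([t for _, t in splits])
    assert len(all_test) == len(records) and len(np.unique(all_test)) == len(records)
    return splits


def splits_to_json(records, splits) -> dict:
    patients = [getattr(r, "patient_id", r) for r in records]
    return {
        f"fold_{i}": sorted({int(patients[j]) for j in test}) for i, (_, test) in enumerate(splits)
    }


# ---------------------------------------------------------------------------
# synthetic phantoms
# ---------------------------------------------------------------------------

@dataclass
class PhantomSample:
    image: np.ndarray  # (size, size) float32 in [0, 1]
    label: str
    mask: np.ndarray  # bool, same size; empty iff label == "normal"
    seed: int
    sample_id: str = ""
    patient_id: int | None = None

    @property
    def label_index(self) -> int:
        return LABEL_INDEX[self.label]


def _background(rng: np.random.Generator, size: int) -> np.ndarray:
    noise = rng.standard_normal((size, size))
    bg = ndimage.gaussian_filter(noise, sigma=size / 12.0)
    bg = (bg - bg.mean()) / (bg.std() + 1e-9)
    return 0.30 + 0.06 * bg


def _lesion_geometry(rng: np.random.Generator, size: int):
    cx = rng.uniform(0.35, 0.65) * size
    cy = rng.uniform(0.35, 0.65) * size
    r0 = rng.uniform(0.10, 0.16) * size
    return cx, cy, r0


def _radial_grid(size: int, cx: float, cy: float):
    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = rows - cy, cols - cx
    return np.hypot(dy, dx), np.arctan2(dy, dx)


def _benign_mask(rng, size):
    cx, cy, r0 = _lesion_geometry(rng, size)
    rho, theta = _radial_grid(size, cx, cy)
    # slow, low-order boundary undulations only: smooth, near-circular outline
    radius = r0 * (
        1.0
        + 0.06 * np.cos(2 * theta + rng.uniform(0, 2 * np.pi))
        + 0.04 * np.cos(3 * theta + rng.uniform(0, 2 * np.pi))
    )
    return rho <= radius, rho / r0


def _malignant_mask(rng, size):
    cx, cy, r0 = _lesion_geometry(rng, size)
    rho, theta = _radial_grid(size, cx, cy)
    radius = np.full_like(theta, r0 * rng.uniform(0.7, 0.85))
    for m in (3, 4, 5, 6):
        radius += r0 * rng.uniform(0.04, 0.12) * np.cos(m * theta + rng.uniform(0, 2 * np.pi))
    # radiating spicules: angular spikes extending well past the core, wide
    # enough to stay resolvable after rasterization at desk-scale sizes and
    # numerous enough that every malignant draw carries the signature
    n_spicules = rng.integers(8, 15)
    angles = rng.uniform(0, 2 * np.pi, n_spicules)
    widths = rng.uniform(0.08, 0.18, n_spicules)
    lengths = rng.uniform(1.0, 2.0, n_spicules) * r0
    for a, wdt, ln in zip(angles, widths, lengths):
        delta = np.angle(np.exp(1j * (theta - a)))
        radius = radius + ln * np.exp(-0.5 * (delta / wdt) ** 2)
    return rho <= radius, rho / r0


def generate_phantom(label: str, size: int, seed: int) -> PhantomSample:
    """One seeded phantom; identical (label, size, seed) is bit-reproducible."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    image = _background(rng, size)
    if label == "normal":
        mask = np.zeros((size, size), dtype=bool)
    else:
        maker = _benign_mask if label == "benign" else _malignant_mask
        mask, rho_norm = maker(rng, size)
        # brightness follows the lesion support (softened rim), so boundary
        # shape — the class cue — is visible in the image, not only the mask;
        # overlapping amplitude ranges keep intensity alone non-separating
        amplitude = rng.uniform(0.28, 0.42)
        profile = ndimage.gaussian_filter(mask.astype(np.float64), sigma=size / 64.0)
        peak = profile.max()
        if peak > 0:
            profile /= peak
        image = image + amplitude * profile
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return PhantomSample(image=image, label=label, mask=mask, seed=seed)


def generate_phantoms(
    n: int,
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    size: int = 224,
    seed: int = 0,
) -> list[PhantomSample]:
    """A seeded phantom set with deterministic class allocation.

    ``class_mix`` gives (normal, benign, malignant) proportions summing to 1;
    counts are the largest-remainder rounding of n * mix.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (3,) or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0, atol=1e-6):
        raise InputError("class_mix must be 3 non-negative proportions summing to 1")
    raw = mix * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[i] += 1
    samples = []
    idx = 0
    for label, count in zip(LABELS, counts):
        for _ in range(count):
            sub = int(np.random.SeedSequence([seed & 0x7FFFFFFF, idx]).generate_state(1)[0] % (2**31))
            s = generate_phantom(label, size, sub)
            s.sample_id = f"phantom{idx:05d}"
            s.patient_id = idx  # phantoms are independent: one per "patient"
            samples.append(s)
            idx += 1
    order = np.random.default_rng(seed).permutation(len(samples))
    return [samples[i] for i in order]


def write_phantom_set(samples, out_dir) -> Path:
    """PNG images + PNG masks + a CSV manifest (id, label, seed, mask_path)."""
    from PIL import Image
    import pandas as pd

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        img_path = out_dir / "images" / f"{s.sample_id}.png"
        Image.fromarray((s.image * 255).astype(np.uint8)).save(img_path)
        mask_path = ""
        if s.mask.any():
            mask_path = f"masks/{s.sample_id}.png"
            Image.fromarray((s.mask * 255).astype(np.uint8)).save(out_dir / mask_path)
        rows.append(
            {"id": s.sample_id, "label": s.label, "seed": s.seed,
             "image_path": f"images/{s.sample_id}.png", "mask_path": mask_path}
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_phantom_set(manifest_path) -> list[PhantomSample]:
    from PIL import Image
    import pandas as pd

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, keep_default_na=False)
    samples = []
    for i, row in df.iterrows():
        img = np.asarray(Image.open(base / row["image_path"]), dtype=np.float32) / 255.0
        if row["mask_path"]:
            mask = np.asarray(Image.open(base / row["mask_path"])) > 127
        else:
            mask = np.zeros(img.shape, dtype=bool)
        samples.append(
            PhantomSample(image=img, label=row["label"], mask=mask,
                          seed=int(row["seed"]), sample_id=row["id"], patient_id=i)
        )
    return samples
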