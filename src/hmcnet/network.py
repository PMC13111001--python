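"""The HMC network: a 50-layer bottleneck residual backbone with hierarchical
self-attention after stages 1 and 2 (HA1, HA2) and multi-scale cross-attention
fusing stages 2-3 and 3-4 (CA23, CA34), plus its ablation variants and the
Adam/cross-entropy training loop.

Stage layout at the default 224-pixel configuration:

    stem   7x7/2 conv + BN + ReLU + 3x3/2 maxpool   -> x0:   64 ch, 56x56
    layer1 3 bottlenecks                            -> x1:  256 ch, 56x56   (HA1)
    layer2 4 bottlenecks, stride 2                  -> x2:  512 ch, 28x28   (HA2)
    layer3 6 bottlenecks, stride 2                  -> x3: 1024 ch, 14x14   (CA23)
    layer4 3 bottlenecks, stride 2                  -> x4: 2048 ch,  7x7    (CA34)
    head   global average pool + fully connected    -> logits, 3 classes

All weights are trained from scratch (no pre-trained layers); every attention
gate gamma starts at exactly zero, so each variant's initial forward pass
equals the plain backbone. A width/size-reduced "tiny" preset (64-pixel input,
channels divided by 8) keeps CPU experiments in the minutes range.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .attention import DEFAULT_POSITIONS_CAP, AttentionBlock, ChannelMatchResample
from .autodiff import Tensor
from .errors import ConfigurationError, DimensionError, InputError, NumericError
from .nn import Adam, BatchNorm2d, Conv2d, Linear, Module

VARIANTS = ("hmc", "hierarchical_only", "multiscale_only", "baseline")
_VARIANT_ALIASES = {
    "hmc": "hmc",
    "hierarchical": "hierarchical_only",
    "hierarchical_only": "hierarchical_only",
    "multiscale": "multiscale_only",
    "multiscale_only": "multiscale_only",
    "baseline": "baseline",
}

CHECKPOINT_SCHEMA = 1


def canonical_variant(name: str) -> str:
    try:
        return _VARIANT_ALIASES[name]
    except KeyError:
        raise ConfigurationError(f"unknown variant {name!r}; choose from {VARIANTS}") from None


@dataclass(frozen=True)
class BackboneConfig:
    """Structural hyperparameters of the backbone."""

    stage_channels: tuple[int, ...] = (64, 256, 512, 1024, 2048)
    input_size: int = 224
    num_classes: int = 3
    width_divisor: int = 1
    blocks: tuple[int, ...] = (3, 4, 6, 3)
    positions_cap: int = DEFAULT_POSITIONS_CAP

    def __post_init__(self):
        if len(self.stage_channels) != 5:
            raise ConfigurationError("stage_channels must have 5 entries")
        for c in self.effective_channels:
            if c % 8 != 0 or c < 8:
                raise ConfigurationError(
                    f"channel count {c} not divisible by 8 after width reduction"
                )

    @property
    def effective_channels(self) -> tuple[int, ...]:
        return tuple(c // self.width_divisor for c in self.stage_channels)

    @classmethod
    def tiny(cls, **overrides) -> "BackboneConfig":
        """CPU-scale preset: 64-pixel input, all stage widths divided by 8."""
        kw = dict(input_size=64, width_divisor=8)
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            "stage_channels": list(self.stage_channels),
            "input_size": self.input_size,
            "num_classes": self.num_classes,
            "width_divisor": self.width_divisor,
            "blocks": list(self.blocks),
            "positions_cap": self.positions_cap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        return cls(
            stage_channels=tuple(d["stage_channels"]),
            input_size=int(d["input_size"]),
            num_classes=int(d["num_classes"]),
            width_divisor=int(d["width_divisor"]),
            blocks=tuple(d["blocks"]),
            positions_cap=int(d.get("positions_cap", DEFAULT_POSITIONS_CAP)),
        )


@dataclass
class TrainConfig:
    """Optimization hyperparameters (Adam, cross-entropy)."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    val_fraction: float = 0.1
    augment: bool = True

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ConfigurationError("learning rate must be >= 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch size must be >= 1")


class Bottleneck(Module):
    """Standard 1x1 -> 3x3 -> 1x1 residual bottleneck (expansion 4)."""

    def __init__(self, in_ch, out_ch, stride, rng):
        super().__init__()
        planes = out_ch // 4
        self.conv1 = Conv2d(in_ch, planes, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(planes)
        self.conv2 = Conv2d(planes, planes, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(planes)
        self.conv3 = Conv2d(planes, out_ch, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        out = ad.relu(self.bn1(self.conv1(x)))
        out = ad.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        shortcut = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return ad.relu(ad.add(out, shortcut))


class Stage(Module):
    def __init__(self, in_ch, out_ch, n_blocks, stride, rng):
        super().__init__()
        blocks = [Bottleneck(in_ch, out_ch, stride, rng)]
        for _ in range(n_blocks - 1):
            blocks.append(Bottleneck(out_ch, out_ch, 1, rng))
        self.blocks = blocks

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class HMCNet(Module):
    """The full model; which attention modules exist depends on ``variant``."""

    def __init__(self, variant: str, config: BackboneConfig, seed: int = 0):
        super().__init__()
        variant = canonical_variant(variant)
        rng = np.random.default_rng(seed)
        ch = config.effective_channels
        self.variant = variant
        self.config = config
        self.seed = seed

        self.conv1 = Conv2d(3, ch[0], 7, stride=2, padding=3, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(ch[0])
        self.layer1 = Stage(ch[0], ch[1], config.blocks[0], 1, rng)
        self.layer2 = Stage(ch[1], ch[2], config.blocks[1], 2, rng)
        self.layer3 = Stage(ch[2], ch[3], config.blocks[2], 2, rng)
        self.layer4 = Stage(ch[3], ch[4], config.blocks[3], 2, rng)
        self.fc = Linear(ch[4], config.num_classes, rng=rng)

        cap = config.positions_cap
        if variant in ("hmc", "hierarchical_only"):
            self.ha1 = AttentionBlock(ch[1], rng=rng, positions_cap=cap)
            self.ha2 = AttentionBlock(ch[2], rng=rng, positions_cap=cap)
        if variant in ("hmc", "multiscale_only"):
            self.match23 = ChannelMatchResample(ch[2], ch[3], rng=rng)
            self.ca23 = AttentionBlock(ch[3], rng=rng, positions_cap=cap)
            self.match34 = ChannelMatchResample(ch[3], ch[4], rng=rng)
            self.ca34 = AttentionBlock(ch[4], rng=rng, positions_cap=cap)

    # -- forward -------------------------------------------------------------
    def _check_input(self, batch: np.ndarray | Tensor) -> Tensor:
        x = batch if isinstance(batch, Tensor) else Tensor(batch)
        if x.data.ndim != 4 or x.data.shape[1] != 3:
            raise DimensionError(
                f"expected input (B, 3, {self.config.input_size}, {self.config.input_size}), "
                f"got {x.data.shape} at the stem"
            )
        return x

    def forward_stages(self, batch) -> dict[str, Tensor]:
        """Run the stage graph x0 -> x4' and return every intermediate."""
        x = self._check_input(batch)
        out: dict[str, Tensor] = {}
        x0 = ad.maxpool2d(ad.relu(self.bn1(self.conv1(x))), 3, 2, 1)
        out["x0"] = x0
        x1 = self.layer1(x0)
        out["x1"] = x1
        x1p = self.ha1(x1, x1) if hasattr(self, "ha1") else x1
        out["x1p"] = x1p
        x2 = self.layer2(x1p)
        out["x2"] = x2
        x2p = self.ha2(x2, x2) if hasattr(self, "ha2") else x2
        out["x2p"] = x2p
        x3 = self.layer3(x2p)
        out["x3"] = x3
        if hasattr(self, "ca23"):
            x2pp = self.match23(x2p, x3.data.shape[2:])
            out["x2pp"] = x2pp
            x3p = self.ca23(x3, x2pp)
        else:
            x3p = x3
        out["x3p"] = x3p
        x4 = self.layer4(x3p)
        out["x4"] = x4
        if hasattr(self, "ca34"):
            x3pp = self.match34(x3p, x4.data.shape[2:])
            out["x3pp"] = x3pp
            x4p = self.ca34(x4, x3pp)
        else:
            x4p = x4
        out["x4p"] = x4p
        out["logits"] = self.fc(ad.global_avg_pool(x4p))
        return out

    def forward(self, batch) -> Tensor:
        return self.forward_stages(batch)["logits"]


def build_model(variant: str, config: BackboneConfig | None = None, seed: int = 0) -> HMCNet:
    """Construct a seeded model; all gamma gates start at zero."""
    return HMCNet(variant, config or BackboneConfig(), seed=seed)


def softmax_rows(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def predict_proba(model: HMCNet, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Class probabilities (softmax of logits) for preprocessed images."""
    model.eval()
    probs = []
    with ad.no_grad():
        for i in range(0, len(images), batch_size):
            logits = model(images[i : i + batch_size]).data
            probs.append(softmax_rows(logits))
    return np.concatenate(probs, axis=0)


def predict_labels(model: HMCNet, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
    return predict_proba(model, images, batch_size).argmax(axis=1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _derive_seed(seed: int, *salt) -> int:
    """Stable sub-seed below 2**31 derived from a base seed and salt tokens."""
    text = ":".join(str(s) for s in (seed, *salt))
    return zlib.crc32(text.encode()) % (2**31)


def train(
    model: HMCNet,
    dataset,
    tcfg: TrainConfig | None = None,
    preprocess_fn=None,
    augment_fn=None,
) -> dict[str, list[float]]:
    """Train in place; returns the per-epoch history.

    ``dataset`` is a sequence of samples with ``image`` (2-D grayscale in
    [0, 1]), integer ``label`` in {0, 1, 2}, and optionally ``patient_id``.
    Augmentation (when enabled) is applied to training samples only, freshly
    per epoch; a patient-wise validation split (``val_fraction`` of training
    patients) is held out and never augmented.
    """
    from .data import augment as default_augment
    from .data import preprocess as default_preprocess

    tcfg = tcfg or TrainConfig()
    if len(dataset) == 0:
        raise InputError("training dataset is empty")
    labels = np.array([int(s.label_index if hasattr(s, "label_index") else s.label) for s in dataset])
    if labels.min() < 0 or labels.max() >= model.config.num_classes:
        raise InputError(f"labels must lie in [0, {model.config.num_classes})")
    preprocess_fn = preprocess_fn or (
        lambda img: default_preprocess(img, size=model.config.input_size)
    )
    augment_fn = augment_fn or default_augment

    patients = np.array(
        [getattr(s, "patient_id", None) if getattr(s, "patient_id", None) is not None else i
         for i, s in enumerate(dataset)]
    )
    rng = np.random.default_rng(_derive_seed(tcfg.seed, "train"))
    unique_patients = np.unique(patients)
    n_val_patients = int(round(tcfg.val_fraction * len(unique_patients)))
    val_patients = set(
        rng.choice(unique_patients, size=n_val_patients, replace=False).tolist()
        if n_val_patients
        else []
    )
    val_idx = np.array([i for i, p in enumerate(patients) if p in val_patients], dtype=int)
    train_idx = np.array([i for i, p in enumerate(patients) if p not in val_patients], dtype=int)
    if len(train_idx) == 0:
        raise InputError("validation split left no training samples")

    val_images = (
        np.stack([preprocess_fn(dataset[i].image) for i in val_idx]) if len(val_idx) else None
    )
    val_labels = labels[val_idx]

    opt = Adam(model.parameters(), lr=tcfg.learning_rate, betas=tcfg.betas, eps=tcfg.eps)
    history: dict[str, list[float]] = {
        "epoch": [], "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
    }
    for epoch in range(tcfg.epochs):
        model.train()
        order = train_idx.copy()
        rng.shuffle(order)
        epoch_loss, epoch_correct, epoch_n = 0.0, 0, 0
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            imgs = []
            for i in idx:
                img = dataset[i].image
                if tcfg.augment:
                    img = augment_fn(
                        img,
                        np.random.default_rng(_derive_seed(tcfg.seed, "aug", epoch, int(i))),
                    )
                imgs.append(preprocess_fn(img))
            batch = np.stack(imgs)
            y = labels[idx]
            logits = model(batch)
            loss = ad.cross_entropy(logits, y)
            if not np.isfinite(loss.data):
                raise NumericError(f"non-finite training loss at epoch {epoch}")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            epoch_correct += int((logits.data.argmax(axis=1) == y).sum())
            epoch_n += len(idx)

        history["epoch"].append(epoch)
        history["train_loss"].append(epoch_loss / epoch_n)
        history["train_acc"].append(epoch_correct / epoch_n)
        if val_images is not None and len(val_images):
            model.eval()
            with ad.no_grad():
                vl, vc = 0.0, 0
                for start in range(0, len(val_images), tcfg.batch_size):
                    vb = val_images[start : start + tcfg.batch_size]
                    vy = val_labels[start : start + tcfg.batch_size]
                    vlogits = model(vb)
                    vl += float(ad.cross_entropy(vlogits, vy).data) * len(vy)
                    vc += int((vlogits.data.argmax(axis=1) == vy).sum())
            history["val_loss"].append(vl / len(val_images))
            history["val_acc"].append(vc / len(val_images))
        else:
            history["val_loss"].append(float("nan"))
            history["val_acc"].append(float("nan"))
    model.eval()
    return history


def history_to_csv(history: dict[str, list[float]], path):
    import pandas as pd

    pd.DataFrame(history).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: HMCNet, path):
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "variant": model.variant,
        "config": model.config.to_dict(),
        "seed": model.seed,
    }
    arrays = {k.replace(".", "/"): v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> HMCNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise InputError(f"unsupported checkpoint schema {meta.get('schema')}")
        model = HMCNet(meta["variant"], BackboneConfig.from_dict(meta["config"]), meta["seed"])
        state = {k.replace("/", "."): data[k] for k in data.files if k != "__meta__"}
    model.load_state_dict(state)
    model.eval()
    return model
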