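"""Class-activation-map explainers and localization scoring.

Three CAM variants are hooked on the final attention-refined stage (x4', the
post-cross-attention stage-4 output, 2048 channels at 7x7 in the default
configuration), so attention refinement is visible in the heatmaps:

* Grad-CAM — channel weights are the spatial means of the gradients of the
  class score w.r.t. the target feature maps;
* Grad-CAM++ — per-pixel weights from the closed-form expression in powers
  of first derivatives, alpha_ij = G^2 / (2 G^2 + sum(A) G^3);
* Score-CAM — gradient-free: each channel's min-max-normalized, upsampled
  map masks the input, and the masked image's class confidence weights the
  channel.

Every heatmap is bilinearly resized to input resolution and min-max
normalized into [0, 1]; a constant pre-normalization map (max == min, where
the normalization is undefined) yields an all-zero heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, bilinear_resize_array
from .errors import ConfigurationError, InputError
from .network import HMCNet

TARGET_LAYER = "x4p"


@dataclass
class Heatmap:
    values: np.ndarray  # (H, W) in [0, 1]
    class_index: int
    method: str  # "gradcam" | "gradcampp" | "scorecam"


@dataclass
class CamIntermediates:
    A: np.ndarray  # target-layer feature maps (C, h, w)
    y_c: float  # class score the explanation is taken w.r.t.
    G: np.ndarray | None = None  # dy_c/dA, same shape as A (gradient methods)
    channel_weights: np.ndarray | None = None  # alpha_k / w_k / s_c^k per channel
    alpha_ij: np.ndarray | None = None  # Grad-CAM++ pixel weights
    masks: np.ndarray | None = None  # Score-CAM upsampled channel masks M_k


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); a constant input maps to all zeros."""
    lo, hi = float(x.min()), float(x.max())
    if hi - lo == 0.0:
        return np.zeros_like(x, dtype=np.float32)
    return ((x - lo) / (hi - lo)).astype(np.float32)


def normalize_resize(cam: np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to ``out_size`` then min-max normalization."""
    cam = np.asarray(cam, dtype=np.float32)
    resized = bilinear_resize_array(cam[None, None], out_size)[0, 0]
    return minmax_normalize(resized)


def _prepare(model: HMCNet, image: np.ndarray, class_index: int):
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3:
        image = image[None]
    if image.ndim != 4 or image.shape[0] != 1:
        raise InputError(f"expected one (3, H, W) image, got shape {image.shape}")
    if not 0 <= class_index < model.config.num_classes:
        raise InputError(
            f"class_index {class_index} outside [0, {model.config.num_classes})"
        )
    return image


def _class_score_backward(model, image, class_index, target, use_probabilities):
    """Forward with gradient capture; backward from the class score.
    Returns (A data, G, y_c)."""
    model.eval()
    stages = model.forward_stages(image)
    if target not in stages:
        raise ConfigurationError(
            f"target layer {target!r} not present; available: {sorted(stages)}"
        )
    feats = stages[target]
    if not feats.requires_grad:
        raise ConfigurationError(f"gradient capture unavailable at layer {target!r}")
    head = stages["logits"]
    if use_probabilities:
        head = ad.softmax_lastdim(head)
    seed = np.zeros_like(head.data)
    seed[0, class_index] = 1.0
    model.zero_grad()
    head.backward(seed)
    if feats.grad is None:
        raise ConfigurationError(f"no gradient reached layer {target!r}")
    return feats.data[0], feats.grad[0], float(head.data[0, class_index])


def grad_cam(
    model: HMCNet,
    image: np.ndarray,
    class_index: int,
    target: str = TARGET_LAYER,
    use_probabilities: bool = False,
    return_intermediates: bool = False,
):
    """Gradient-weighted CAM: alpha_k = spatial mean of dy_c/dA_k,
    heatmap = normalized resize of ReLU(sum_k alpha_k A_k)."""
    image = _prepare(model, image, class_index)
    A, G, y_c = _class_score_backward(model, image, class_index, target, use_probabilities)
    alpha = G.mean(axis=(1, 2))
    cam = np.maximum((alpha[:, None, None] * A).sum(axis=0), 0.0)
    values = normalize_resize(cam, image.shape[2:])
    hm = Heatmap(values, class_index, "gradcam")
    if return_intermediates:
        return hm, CamIntermediates(A=A, y_c=y_c, G=G, channel_weights=alpha)
    return hm


def gradcampp_pixel_weights(A: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Closed-form Grad-CAM++ pixel weights in powers of first derivatives:
    alpha_ij = G_ij^2 / (2 G_ij^2 + sum_{i'j'} A_{i'j'} * G_ij^3);
    pixels with a zero denominator get alpha_ij = 0."""
    g2 = G**2
    g3 = G**3
    sum_a = A.sum(axis=(1, 2), keepdims=True)
    denom = 2.0 * g2 + sum_a * g3
    alpha = np.where(denom != 0.0, g2 / np.where(denom == 0.0, 1.0, denom), 0.0)
    return alpha


def grad_cam_pp(
    model: HMCNet,
    image: np.ndarray,
    class_index: int,
    target: str = TARGET_LAYER,
    use_probabilities: bool = False,
    literal_eq24: bool = False,
    return_intermediates: bool = False,
):
    """Grad-CAM++ with higher-order weighting.

    Channel weight w_k = sum_ij alpha_ij * ReLU(G_ij) by default; with
    ``literal_eq24`` the ReLU(G) factor is dropped and the pixel weights are
    summed directly (the simplified aggregation some formulations print).
    """
    image = _prepare(model, image, class_index)
    A, G, y_c = _class_score_backward(model, image, class_index, target, use_probabilities)
    alpha = gradcampp_pixel_weights(A, G)
    if literal_eq24:
        w = alpha.sum(axis=(1, 2))
    else:
        w = (alpha * np.maximum(G, 0.0)).sum(axis=(1, 2))
    cam = np.maximum((w[:, None, None] * A).sum(axis=0), 0.0)
    values = normalize_resize(cam, image.shape[2:])
    hm = Heatmap(values, class_index, "gradcampp")
    if return_intermediates:
        return hm, CamIntermediates(A=A, y_c=y_c, G=G, channel_weights=w, alpha_ij=alpha)
    return hm


def score_cam(
    model: HMCNet,
    image: np.ndarray,
    class_index: int,
    target: str = TARGET_LAYER,
    use_probabilities: bool = True,
    chunk_size: int = 32,
    return_intermediates: bool = False,
):
    """Score-weighted CAM (gradient-free).

    Per channel k: M_k = min-max-normalized A_k upsampled to input size
    (constant channels give M_k = 0); the masked image image * M_k is passed
    through the model and its class-c confidence s_c^k weights the channel.
    Channel passes are batched in ``chunk_size`` chunks; the result is
    independent of the chunk size.
    """
    image = _prepare(model, image, class_index)
    model.eval()
    with ad.no_grad():
        stages = model.forward_stages(image)
        A = stages[target].data[0]
        size = image.shape[2:]
        masks = np.stack([minmax_normalize(bilinear_resize_array(a[None, None], size)[0, 0])
                          for a in A])
        scores = np.empty(len(masks), dtype=np.float64)
        for start in range(0, len(masks), chunk_size):
            chunk = masks[start : start + chunk_size]
            batch = image * chunk[:, None, :, :]
            logits = model(batch).data
            if use_probabilities:
                e = np.exp(logits - logits.max(axis=1, keepdims=True))
                out = e / e.sum(axis=1, keepdims=True)
            else:
                out = logits
            scores[start : start + len(chunk)] = out[:, class_index]
        y_c = float(stages["logits"].data[0, class_index])
    cam = np.maximum((scores[:, None, None] * A).sum(axis=0), 0.0)
    values = normalize_resize(cam, size)
    hm = Heatmap(values, class_index, "scorecam")
    if return_intermediates:
        return hm, CamIntermediates(A=A, y_c=y_c, channel_weights=scores, masks=masks)
    return hm


CAM_METHODS = {"gradcam": grad_cam, "gradcampp": grad_cam_pp, "scorecam": score_cam}


def explain(model: HMCNet, image: np.ndarray, class_index: int, method: str, **kw) -> Heatmap:
    try:
        fn = CAM_METHODS[method]
    except KeyError:
        raise InputError(f"unknown CAM method {method!r}; choose from {sorted(CAM_METHODS)}") from None
    return fn(model, image, class_index, **kw)


# ---------------------------------------------------------------------------
# localization scoring
# ---------------------------------------------------------------------------

def _nearest_resize_mask(mask: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    H, W = mask.shape
    Ho, Wo = out_hw
    rows = np.clip(((np.arange(Ho) + 0.5) * H / Ho).astype(int), 0, H - 1)
    cols = np.clip(((np.arange(Wo) + 0.5) * W / Wo).astype(int), 0, W - 1)
    return mask[np.ix_(rows, cols)]


def localization_iou(heatmap, roi_mask: np.ndarray, threshold: float = 0.5) -> float:
    """IoU between the thresholded heatmap and a ground-truth mask.

    The mask is resampled to the heatmap resolution by nearest neighbor; the
    heatmap is binarized at ``values >= threshold``.  An empty union scores 0.
    """
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    if not 0.0 < threshold < 1.0:
        raise InputError(f"threshold must lie in (0, 1), got {threshold}")
    mask = np.asarray(roi_mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise InputError(f"mask is not binary (values {uniq[:5]}...)")
        mask = mask.astype(bool)
    if mask.shape != values.shape:
        mask = _nearest_resize_mask(mask, values.shape)
    pred = values >= threshold
    union = np.logical_or(pred, mask).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(pred, mask).sum() / union)


def mean_iou(heatmaps, masks, threshold: float = 0.5) -> float:
    """Arithmetic mean of per-sample IoUs."""
    ious = [localization_iou(h, m, threshold) for h, m in zip(heatmaps, masks)]
    if not ious:
        raise InputError("empty evaluation set")
    return float(np.mean(ious))


def iou_report(rows, path) -> None:
    """Write (sample id, method, threshold, IoU) rows as CSV."""
    import pandas as pd

    pd.DataFrame(rows, columns=["sample_id", "method", "threshold", "iou"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def save_heatmap_png(heatmap: Heatmap, image: np.ndarray | None, out_prefix, alpha: float = 0.4):
    """8-bit grayscale heatmap PNG plus an RGB jet-colormap overlay PNG."""
    from PIL import Image as PILImage
    from matplotlib import cm

    out_prefix = Path(out_prefix)
    gray = (np.clip(heatmap.values, 0, 1) * 255).astype(np.uint8)
    PILImage.fromarray(gray).save(out_prefix.with_suffix(".png"))
    if image is not None:
        img = np.asarray(image, dtype=np.float32)
        if img.ndim == 3:  # (3, H, W) normalized network input -> grayscale [0,1]
            img = (img[0] * 0.5) + 0.5
        base = np.repeat(np.clip(img, 0, 1)[..., None], 3, axis=2)
        jet = cm.jet(np.clip(heatmap.values, 0, 1))[..., :3]
        overlay = (1 - alpha) * base + alpha * jet
        PILImage.fromarray((overlay * 255).astype(np.uint8)).save(
            out_prefix.with_name(out_prefix.stem + "_overlay.png")
        )
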