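"""Image feature extraction: CNN backbone features and the GLCM texture set.

Two feature families feed the classifiers:

* Deep features — the flattened activation at the final
  global-average-pooling layer of a registered CNN backbone (ResNet-101,
  DenseNet-201, NASNet-Large).  Feature length is fixed by the
  architecture: 2048, 1920 and 4032 respectively.
* Texture features — the classical 14 Haralick statistics of the
  gray-level co-occurrence matrix (GLCM), averaged over four offset
  directions, used by the SVM baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from ._backbones import NumpyCNN, build_backbone_net
from .frp import FeatureVector

__all__ = [
    "BackboneSpec",
    "BACKBONES",
    "get_backbone",
    "BackboneUnavailableError",
    "preprocess_image",
    "extract_cnn_features",
    "GLCMConfig",
    "GLCMFeatures",
    "extract_glcm_features",
    "to_grayscale",
]

# canonical ImageNet channel statistics used at backbone training time
_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
_IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


class BackboneUnavailableError(RuntimeError):
    """Raised when a registered backbone has no runnable architecture."""


@dataclass(frozen=True)
class BackboneSpec:
    """Registry entry for one pretrained-CNN backbone.

    ``extraction_layer_role`` is the role the read-out layer plays —
    the final global average pooling before the fully-connected head —
    which is what fixes ``expected_feature_length``; ``layer_alias`` is the
    layer's conventional name in published model zoos.
    """

    name: str
    input_size: tuple[int, int, int]
    expected_feature_length: int
    layer_alias: str
    extraction_layer_role: str = "final global-average-pooling before the fully-connected layer"
    available: bool = True


BACKBONES: dict[str, BackboneSpec] = {
    "resnet101": BackboneSpec("resnet101", (224, 224, 3), 2048, "pool5"),
    "densenet201": BackboneSpec("densenet201", (224, 224, 3), 1920, "avg_pool"),
    "nasnetlarge": BackboneSpec(
        "nasnetlarge", (331, 331, 3), 4032, "global_average_pooling2d_2",
        available=False,
    ),
}


def get_backbone(name: str) -> BackboneSpec:
    key = name.lower().replace("-", "").replace("_", "")
    if key not in BACKBONES:
        raise KeyError(f"unknown backbone {name!r}; registered: {sorted(BACKBONES)}")
    return BACKBONES[key]


def _load_rgb(image) -> np.ndarray:
    """Accept a path, PIL image, or (H,W[,3]) array; return (H,W,3) float in [0,1]."""
    if isinstance(image, (str, Path)):
        image = Image.open(image)
    if isinstance(image, Image.Image):
        if image.mode not in ("RGB", "L"):
            try:
                image = image.convert("RGB")
            except ValueError as exc:  # pragma: no cover - exotic modes
                raise ValueError(f"cannot convert image mode {image.mode!r} to RGB") from exc
        arr = np.asarray(image, dtype=np.float32)
        if arr.ndim == 2:
            arr = np.repeat(arr[:, :, None], 3, axis=2)
        return arr / 255.0
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an RGB or grayscale image, got shape {arr.shape}")
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def preprocess_image(image, backbone: BackboneSpec) -> np.ndarray:
    """Resize to the backbone input size and apply channel normalisation.

    Bilinear resize; grayscale inputs are replicated across the three
    channels first.  Returns a (3, H, W) float32 tensor-like array.
    Deterministic — the pipeline uses no augmentation anywhere.
    """
    arr = _load_rgb(image)
    h, w, _ = backbone.input_size
    img = Image.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="RGB")
    if img.size != (w, h):
        img = img.resize((w, h), resample=Image.BILINEAR)
    out = np.asarray(img, dtype=np.float32) / 255.0
    out = (out - _IMAGENET_MEAN) / _IMAGENET_STD
    return np.ascontiguousarray(out.transpose(2, 0, 1))


_NET_CACHE: dict[tuple[str, int], NumpyCNN] = {}


def _get_net(spec: BackboneSpec, weight_seed: int) -> NumpyCNN:
    if not spec.available:
        runnable = sorted(k for k, v in BACKBONES.items() if v.available)
        raise BackboneUnavailableError(
            f"backbone {spec.name!r} is registered (input {spec.input_size}, "
            f"GAP layer {spec.layer_alias!r}, feature length "
            f"{spec.expected_feature_length}) but its architecture is not "
            f"implemented here; runnable backbones: {runnable}"
        )
    key = (spec.name, weight_seed)
    if key not in _NET_CACHE:
        _NET_CACHE[key] = build_backbone_net(spec.name, seed=weight_seed)
    return _NET_CACHE[key]


def extract_cnn_features(image, backbone: BackboneSpec | str,
                         weight_seed: int = 0,
                         image_id: str = "") -> FeatureVector:
    """Flattened global-average-pooling activation for one image.

    The backbone is instantiated with seeded random weights (architecture
    fixes the feature length regardless of weight values); the weight seed
    is part of the extraction contract so repeated runs agree bitwise.
    """
    spec = get_backbone(backbone) if isinstance(backbone, str) else backbone
    net = _get_net(spec, weight_seed)
    x = preprocess_image(image, spec)
    feats = net.forward(x)
    if feats.size != spec.expected_feature_length:
        raise RuntimeError(
            f"backbone {spec.name} produced {feats.size} features, "
            f"expected {spec.expected_feature_length}"
        )
    return FeatureVector(values=feats, source_image_id=image_id, backbone=spec.name)


# ---------------------------------------------------------------------------
# GLCM / Haralick texture baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLCMConfig:
    """Co-occurrence settings: gray levels, pixel offsets, symmetry."""

    levels: int = 8
    distances: tuple[int, ...] = (1,)
    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    symmetric: bool = True


@dataclass
class GLCMFeatures:
    """The 14 Haralick statistics of one grayscale image."""

    values: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != 14:
            raise ValueError(f"expected 14 features, got {self.values.size}")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite texture feature")


def to_grayscale(image) -> np.ndarray:
    """ITU-R 601 luminance in [0,1] from an RGB or grayscale input."""
    arr = _load_rgb(image)
    return arr @ np.array([0.299, 0.587, 0.114], dtype=np.float32)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def haralick_features(P: np.ndarray) -> np.ndarray:
    """The 14 Haralick statistics of one normalised GLCM.

    ``P`` is a (levels, levels) joint probability matrix (sums to 1).
    Entropies use the natural logarithm.  Degenerate denominators
    (constant images) yield 0 for the affected correlation-type features
    rather than NaN.
    """
    L = P.shape[0]
    i = np.arange(L, dtype=float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((i - mu_y) ** 2) @ py))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    # p_{x+y}(k), k = 0..2L-2 and p_{x-y}(k), k = 0..L-1
    p_sum = np.bincount((ii + jj).astype(int).ravel(), weights=P.ravel(), minlength=2 * L - 1)
    p_diff = np.bincount(np.abs(ii - jj).astype(int).ravel(), weights=P.ravel(), minlength=L)
    k_sum = np.arange(2 * L - 1, dtype=float)
    k_diff = np.arange(L, dtype=float)

    f1 = float((P ** 2).sum())                                  # angular 2nd moment
    f2 = float((k_diff ** 2) @ p_diff)                          # contrast
    if sd_x * sd_y > 0:
        f3 = float(((ii * jj * P).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        f3 = 0.0                                                # correlation
    mu = float((ii * P).sum())
    f4 = float((((ii - mu) ** 2) * P).sum())                    # sum of squares: variance
    f5 = float((P / (1.0 + (ii - jj) ** 2)).sum())              # inverse difference moment
    f6 = float(k_sum @ p_sum)                                   # sum average
    f7 = float(((k_sum - f6) ** 2) @ p_sum)                     # sum variance
    f8 = _entropy(p_sum)                                        # sum entropy
    f9 = _entropy(P.ravel())                                    # entropy
    mu_d = float(k_diff @ p_diff)
    f10 = float(((k_diff - mu_d) ** 2) @ p_diff)                # difference variance
    f11 = _entropy(p_diff)                                      # difference entropy

    pxpy = np.outer(px, py)
    mask = pxpy > 0
    hxy = f9
    hxy1 = float(-(P[mask] * np.log(pxpy[mask])).sum())
    hxy2 = float(-(pxpy[mask] * np.log(pxpy[mask])).sum())
    hx, hy = _entropy(px), _entropy(py)
    denom = max(hx, hy)
    f12 = float((hxy - hxy1) / denom) if denom > 0 else 0.0     # info. corr. 1
    f13 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))  # info. corr. 2

    # maximal correlation coefficient: sqrt of 2nd-largest eigenvalue of Q
    nz = (px > 0) & (py > 0)
    if nz.sum() >= 2:
        Psub = P[np.ix_(nz, nz)]
        # Q_ij = sum_k P_ik P_jk / (px_i py_k)
        Q = np.einsum("ik,jk->ij", Psub / px[nz][:, None], Psub / py[nz][None, :])
        ev = np.sort(np.real(np.linalg.eigvals(Q)))
        f14 = float(np.sqrt(max(0.0, ev[-2])))
    else:
        f14 = 0.0
    return np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13, f14])


def glcm_matrix(gray: np.ndarray, config: GLCMConfig, distance: int,
                angle_deg: float, normed: bool = True) -> np.ndarray:
    """Quantised co-occurrence matrix for one (distance, angle) offset."""
    from skimage.feature import graycomatrix

    if min(gray.shape) <= distance:
        raise ValueError(
            f"image of shape {gray.shape} is smaller than offset distance {distance}"
        )
    q = np.clip((gray * config.levels).astype(int), 0, config.levels - 1).astype(np.uint8)
    M = graycomatrix(
        q, distances=[distance], angles=[np.deg2rad(angle_deg)],
        levels=config.levels, symmetric=config.symmetric, normed=False,
    )[:, :, 0, 0].astype(float)
    if normed:
        total = M.sum()
        if total == 0:
            raise ValueError("no valid pixel pairs for the requested offset")
        M = M / total
    return M


def extract_glcm_features(image, config: GLCMConfig = GLCMConfig(),
                          image_id: str = "") -> GLCMFeatures:
    """14 Haralick features averaged over the configured offsets."""
    gray = image if (isinstance(image, np.ndarray) and image.ndim == 2) else to_grayscale(image)
    gray = np.asarray(gray, dtype=float)
    feats = []
    for dist in config.distances:
        for ang in config.angles_deg:
            P = glcm_matrix(gray, config, dist, ang)
            feats.append(haralick_features(P))
    return GLCMFeatures(values=np.mean(feats, axis=0), image_id=image_id)
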