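"""Fuzzy recurrence plots (FRPs) of deep-feature vectors.

A fuzzy recurrence plot is a square grayscale matrix of fuzzy similarity
grades between the states of a reconstructed phase space.  The pipeline
implemented here turns one flattened deep-feature vector ``g`` of length N
into an M x M FRP in three steps:

1. *Compression*: FCM with ``c = n`` clusters over the N scalar feature
   values yields a short sequence ``x`` of the n cluster centers (n << N).
2. *Embedding*: Takens time-delay embedding of ``x`` with dimension ``d``
   and delay ``tau`` gives M = n - (d-1)*tau state vectors.
3. *FRP construction*: FCM with ``frp_c`` clusters over the states yields a
   membership matrix; similarity between states i and j is the max-min
   composition of their memberships through the cluster centers
   (fuzzy-relation transitivity), with unit diagonal (reflexivity) and
   symmetry.

With the pipeline defaults (n=13, d=1, tau=1, frp_c=3, m=2) any feature
vector maps to a 13 x 13 matrix with entries in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .fcm import FCMConfig, fcm_fit

__all__ = [
    "FeatureVector",
    "CompressedSequence",
    "EmbeddingConfig",
    "PhaseSpace",
    "FRPMatrix",
    "compress_sequence",
    "embed",
    "build_frp",
    "frp_from_memberships",
    "feature_to_frp",
    "image_to_frp",
]


@dataclass
class FeatureVector:
    """Flattened deep features of one image."""

    values: np.ndarray
    source_image_id: str = ""
    backbone: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError("feature vector must have at least one value")
        if not np.isfinite(self.values).all():
            raise ValueError("feature vector contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class CompressedSequence:
    """Short sequence of FCM cluster centers representing a feature vector."""

    values: np.ndarray
    n: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.n = self.values.size


@dataclass(frozen=True)
class EmbeddingConfig:
    """Takens embedding parameters: dimension ``d`` and delay ``tau``."""

    d: int = 1
    tau: int = 1

    def __post_init__(self) -> None:
        if int(self.d) != self.d or self.d < 1:
            raise ValueError(f"embedding dimension d must be an integer >= 1, got {self.d!r}")
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError(f"time delay tau must be an integer >= 1, got {self.tau!r}")


@dataclass
class PhaseSpace:
    """Embedded states s_i = (x_i, x_{i+tau}, ..., x_{i+(d-1)tau})."""

    vectors: np.ndarray  # (M, d)
    d: int
    tau: int

    @property
    def M(self) -> int:
        return self.vectors.shape[0]


@dataclass
class FRPMatrix:
    """M x M fuzzy recurrence plot: symmetric, unit diagonal, values in [0,1]."""

    values: np.ndarray
    frp_c: int = 3
    frp_m: float = 2.0
    source_image_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"FRP must be square, got shape {self.values.shape}")

    @property
    def M(self) -> int:
        return self.values.shape[0]

    def to_png(self, path: str | Path) -> None:
        """8-bit grayscale export (value = round(255*F)); lossy, for viewing."""
        img = np.round(255.0 * np.clip(self.values, 0.0, 1.0)).astype(np.uint8)
        Image.fromarray(img, mode="L").save(Path(path))

    def save(self, path: str | Path) -> None:
        """Lossless CSV serialization (full double precision)."""
        np.savetxt(Path(path), self.values, delimiter=",", fmt="%.17g")

    @classmethod
    def load(cls, path: str | Path, **kwargs) -> "FRPMatrix":
        return cls(values=np.loadtxt(Path(path), delimiter=",", ndmin=2), **kwargs)


def compress_sequence(
    g,
    n: int,
    fcm_config: FCMConfig | None = None,
    order: str = "sorted",
) -> CompressedSequence:
    """Compress a feature vector into the sequence of its n FCM cluster centers.

    The N scalar feature values are clustered as 1-D points with c = n.
    The pipeline-default FCM settings (m=2, delta=1e-5, Q=100) apply unless a
    config is given (its ``c`` is overridden by ``n``).

    Parameters
    ----------
    order : {"sorted", "first-claim"}
        "sorted" (default): centers ascending by value, which makes the
        representation invariant to cluster-label permutations.
        "first-claim": centers ordered by the index of the first feature
        value that claims them (argmax membership), i.e. roughly by where
        each center's mass first appears along ``g``.
    """
    vec = g if isinstance(g, FeatureVector) else FeatureVector(values=g)
    N = len(vec)
    if n > N:
        raise ValueError(f"cannot compress length {N} into n={n} > N clusters")
    if fcm_config is None:
        cfg = FCMConfig(c=n, m=2.0, delta=1e-5, max_iter=100, seed=0)
    else:
        cfg = FCMConfig(
            c=n, m=fcm_config.m, delta=fcm_config.delta,
            max_iter=fcm_config.max_iter, seed=fcm_config.seed,
        )
    part = fcm_fit(vec.values[:, None], cfg)
    centers = part.centers[:, 0]  # already sorted ascending by fcm_fit
    if order == "sorted":
        values = centers
    elif order == "first-claim":
        claims = part.memberships.argmax(axis=1)
        first_claim = np.array([
            np.argmax(claims == k) if (claims == k).any() else len(claims)
            for k in range(n)
        ])
        values = centers[np.argsort(first_claim, kind="stable")]
    else:
        raise ValueError(f"unknown order {order!r}")
    return CompressedSequence(values=values)


def embed(x, config: EmbeddingConfig = EmbeddingConfig()) -> PhaseSpace:
    """Takens time-delay embedding of a scalar sequence.

    Returns M = n - (d-1)*tau states of dimension d,
    s_i = (x_i, x_{i+tau}, ..., x_{i+(d-1)tau}).
    """
    seq = x.values if isinstance(x, CompressedSequence) else np.asarray(x, dtype=float).ravel()
    n = seq.size
    M = n - (config.d - 1) * config.tau
    if M < 2:
        raise ValueError(
            f"embedding leaves M={M} < 2 states (n={n}, d={config.d}, tau={config.tau})"
        )
    idx = np.arange(M)[:, None] + config.tau * np.arange(config.d)[None, :]
    return PhaseSpace(vectors=seq[idx], d=config.d, tau=config.tau)


def frp_from_memberships(memberships: np.ndarray) -> np.ndarray:
    """Max-min fuzzy-relation composition of a membership matrix.

    F(i,j) = max_k min(mu_ik, mu_jk) for i != j, F(i,i) = 1 (reflexivity).
    Symmetric by construction since min is commutative.
    """
    U = np.asarray(memberships, dtype=float)
    F = np.minimum(U[:, None, :], U[None, :, :]).max(axis=2)
    np.fill_diagonal(F, 1.0)
    return F


def build_frp(
    S: PhaseSpace,
    frp_c: int = 3,
    frp_m: float = 2.0,
    fcm_config: FCMConfig | None = None,
) -> FRPMatrix:
    """Build the FRP of a phase space by FCM + max-min composition."""
    if frp_c < 2:
        raise ValueError(f"frp_c must be >= 2, got {frp_c}")
    if S.M < frp_c:
        raise ValueError(f"M={S.M} states cannot support frp_c={frp_c} clusters")
    if fcm_config is None:
        cfg = FCMConfig(c=frp_c, m=frp_m, delta=1e-5, max_iter=100, seed=0)
    else:
        cfg = FCMConfig(
            c=frp_c, m=frp_m, delta=fcm_config.delta,
            max_iter=fcm_config.max_iter, seed=fcm_config.seed,
        )
    part = fcm_fit(S.vectors, cfg)
    return FRPMatrix(values=frp_from_memberships(part.memberships),
                     frp_c=frp_c, frp_m=frp_m)


@dataclass(frozen=True)
class FRPPipelineConfig:
    """Stage parameters for feature vector -> FRP."""

    n: int = 13
    frp_c: int = 3
    frp_m: float = 2.0
    d: int = 1
    tau: int = 1
    delta: float = 1e-5
    max_iter: int = 100
    seed: int = 0
    order: str = "sorted"


def feature_to_frp(g, config: FRPPipelineConfig = FRPPipelineConfig()) -> FRPMatrix:
    """Compression -> embedding -> FRP with the pipeline defaults."""
    fcm_cfg = FCMConfig(c=config.n, m=config.frp_m, delta=config.delta,
                        max_iter=config.max_iter, seed=config.seed)
    x = compress_sequence(g, config.n, fcm_config=fcm_cfg, order=config.order)
    S = embed(x, EmbeddingConfig(d=config.d, tau=config.tau))
    frp = build_frp(S, frp_c=config.frp_c, frp_m=config.frp_m, fcm_config=fcm_cfg)
    if isinstance(g, FeatureVector):
        frp.source_image_id = g.source_image_id
    return frp


def image_to_frp(image, backbone: str, config: FRPPipelineConfig = FRPPipelineConfig(),
                 weight_seed: int = 0) -> FRPMatrix:
    """Full image -> FRP path: CNN feature extraction then ``feature_to_frp``.

    Deterministic given ``config.seed`` and ``weight_seed`` (the backbone
    weight initialisation seed).
    """
    from .features import extract_cnn_features, get_backbone

    spec = get_backbone(backbone)
    g = extract_cnn_features(image, spec, weight_seed=weight_seed)
    return feature_to_frp(g, config)
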