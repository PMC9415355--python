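"""Per-image scoring models and training-time augmentation.

Images are resized to a square side (224 px by convention), randomly
augmented with rotation, axis flips and shear, and fed to a pluggable
per-image scoring model. A scorer maps one frame to an *unbounded* score
vector with one entry per taxon (no probability squashing); the per-image
prediction is the argmax.

The shear transform maps image coordinates (x = column, y = row, origin at
the image center) through::

    x' = x + lambda_x * y
    y' = lambda_y * x + y

where ``lambda_x`` and ``lambda_y`` are the vertical and horizontal
displacement factors; straight lines are preserved while angles change, and
areas scale by |1 - lambda_x * lambda_y|.

The reference scorer is a regularized multinomial linear model over a fixed
feature map — downsampled pixel intensities concatenated with blob shape
features — trained by deterministic full-batch gradient descent on the
cross-entropy loss. After every epoch the validation loss and accuracy are
logged; the returned weights are the snapshot from the epoch with minimum
validation loss, and training stops after a patience window without
improvement in either validation loss or validation accuracy. The problem is
convex, so zero initialization makes training fully deterministic. A heavier
convolutional model can be plugged in behind the same :class:`ScoringModel`
interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import AffineTransform, resize, rotate, warp

from .imaging import NoBlobFoundError, blob_features, detect_blob
from .synthetic import Frame

__all__ = [
    "ShearParams",
    "AugmentConfig",
    "TrainConfig",
    "ScoringModel",
    "ReferenceScorer",
    "FeatureExtractor",
    "resize_image",
    "shear_coords",
    "augment_image",
    "apply_augment",
    "predict_image",
]


@dataclass(frozen=True)
class ShearParams:
    """Shear displacement factors; invertible iff lambda_x * lambda_y != 1."""

    lambda_x: float = 0.0
    lambda_y: float = 0.0

    def __post_init__(self) -> None:
        if abs(1.0 - self.lambda_x * self.lambda_y) < 1e-12:
            raise ValueError("degenerate shear: determinant 1 - lx*ly is zero")


@dataclass(frozen=True)
class AugmentConfig:
    rotation_range: float = 180.0  # degrees, symmetric
    allow_horizontal_flip: bool = True
    allow_vertical_flip: bool = True
    shear_range: tuple[float, float] = (-0.2, 0.2)  # interval for lambda_x, lambda_y

    def __post_init__(self) -> None:
        if not (0 <= self.rotation_range <= 180):
            raise ValueError("rotation_range must lie in [0, 180] degrees")
        if self.shear_range[0] > self.shear_range[1]:
            raise ValueError("shear_range must be a non-empty interval")


def resize_image(frame: Frame, side: int = 224) -> Frame:
    """Scale a frame to ``side`` x ``side`` pixels (bilinear, range-clipped)."""
    if side < 1:
        raise ValueError("side must be >= 1")
    if frame.pixels.shape == (side, side):
        return Frame(frame.pixels.copy())
    out = resize(frame.pixels, (side, side), order=1, anti_aliasing=True)
    return Frame(np.clip(out, 0.0, 1.0))


def shear_coords(x: float, y: float, p: ShearParams) -> tuple[float, float]:
    """Apply the shear map: x' = x + lx*y, y' = ly*x + y."""
    return x + p.lambda_x * y, p.lambda_y * x + y


def _border_intensity(pixels: np.ndarray) -> float:
    edges = np.concatenate([pixels[0], pixels[-1], pixels[:, 0], pixels[:, -1]])
    return float(np.median(edges))


def apply_augment(
    frame: Frame,
    angle_deg: float = 0.0,
    flip_horizontal: bool = False,
    flip_vertical: bool = False,
    shear: ShearParams | None = None,
) -> Frame:
    """Deterministically apply rotation, flips, then shear, in that order.

    Output dimensions equal the input's; uncovered regions are padded with
    the border intensity (the backlit background for silhouette frames).
    Trivial parameters leave the image bit-identical.
    """
    pixels = frame.pixels
    cval = _border_intensity(pixels)
    if angle_deg % 360.0 != 0.0:
        pixels = rotate(pixels, angle_deg, resize=False, order=1,
                        mode="constant", cval=cval)
    if flip_horizontal:
        pixels = pixels[:, ::-1]
    if flip_vertical:
        pixels = pixels[::-1, :]
    if shear is not None and (shear.lambda_x != 0.0 or shear.lambda_y != 0.0):
        h, w = pixels.shape
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        center = AffineTransform(translation=(cx, cy))
        decenter = AffineTransform(translation=(-cx, -cy))
        mat = np.array(
            [[1.0, shear.lambda_x, 0.0], [shear.lambda_y, 1.0, 0.0], [0.0, 0.0, 1.0]]
        )
        fwd = decenter + AffineTransform(matrix=mat) + center
        pixels = warp(pixels, fwd.inverse, order=1, mode="constant", cval=cval)
    return Frame(np.clip(np.ascontiguousarray(pixels), 0.0, 1.0))


def augment_image(frame: Frame, cfg: AugmentConfig, draw_seed: int) -> Frame:
    """Randomly augment one frame; deterministic for a fixed draw seed."""
    rng = np.random.default_rng(draw_seed)
    angle = float(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
    flip_h = cfg.allow_horizontal_flip and bool(rng.random() < 0.5)
    flip_v = cfg.allow_vertical_flip and bool(rng.random() < 0.5)
    lx = float(rng.uniform(*cfg.shear_range))
    ly = float(rng.uniform(*cfg.shear_range))
    shear = ShearParams(lx, ly) if (lx, ly) != (0.0, 0.0) else None
    return apply_augment(frame, angle, flip_h, flip_v, shear)


def predict_image(scores: np.ndarray) -> int:
    """Argmax class of one score vector; ties break to the lowest index."""
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("score vector contains NaN")
    return int(np.argmax(scores))


class FeatureExtractor:
    """Fixed feature map: downsampled inverted pixels + blob shape features.

    Pixels are inverted (1 - intensity) so silhouette mass is positive, then
    averaged down to ``pixel_side`` x ``pixel_side``. Shape features come from
    Otsu blob detection on the frame: log(1+area), log(1+perimeter),
    log(1+max diameter), bbox aspect ratio, bbox fill fraction and the
    dimensionless compactness perimeter^2/area; frames with no detectable
    blob get zero shape features.
    """

    N_SHAPE = 6

    def __init__(self, pixel_side: int = 16):
        self.pixel_side = pixel_side

    @property
    def n_features(self) -> int:
        return self.pixel_side**2 + self.N_SHAPE

    def _pixel_block(self, pixels: np.ndarray) -> np.ndarray:
        ps = self.pixel_side
        h, w = pixels.shape
        inv = 1.0 - pixels
        if h % ps == 0 and w % ps == 0:  # exact block mean, fast path
            return inv.reshape(ps, h // ps, ps, w // ps).mean(axis=(1, 3))
        return resize(inv, (ps, ps), order=1, anti_aliasing=True)

    @staticmethod
    def _shape_features(feats) -> np.ndarray:
        r0, c0, r1, c1 = feats.bbox
        bbox_h, bbox_w = r1 - r0 + 1, c1 - c0 + 1
        return np.array(
            [
                np.log1p(feats.area),
                np.log1p(feats.perimeter),
                np.log1p(feats.max_diameter),
                bbox_h / bbox_w,
                feats.area / (bbox_h * bbox_w),
                feats.perimeter**2 / feats.area,
            ]
        )

    def __call__(self, frame: Frame) -> np.ndarray:
        small = self._pixel_block(frame.pixels)
        shape = np.zeros(self.N_SHAPE)
        try:
            shape = self._shape_features(blob_features(detect_blob(frame)))
        except NoBlobFoundError:
            pass
        return np.concatenate([small.ravel(), shape])

    def from_mask(self, frame: Frame, mask: np.ndarray) -> np.ndarray:
        """Feature vector when the blob mask is already known (skips re-detection)."""
        from .imaging import BlobMask

        small = self._pixel_block(frame.pixels)
        shape = self._shape_features(blob_features(BlobMask(mask)))
        return np.concatenate([small.ravel(), shape])


@dataclass
class TrainConfig:
    pixel_side: int = 16
    l2: float = 1e-3
    max_epochs: int = 200
    patience: int = 10
    momentum: float = 0.9
    n_augment: int = 0  # augmented copies per training image
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0


class ScoringModel:
    """Interface for per-image scorers: fit, then emit unbounded score vectors."""

    class_labels: list

    def fit(self, train_frames, train_labels, val_frames, val_labels):  # pragma: no cover
        raise NotImplementedError

    def score(self, frame: Frame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _softmax_loss_grad(W, b, X, y_onehot, l2):
    n = X.shape[0]
    z = X @ W.T + b
    z -= z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    loss = -np.log(np.clip(p[np.arange(n), y_onehot.argmax(1)], 1e-15, None)).mean()
    loss += 0.5 * l2 * float((W**2).sum())
    g = (p - y_onehot) / n
    return loss, g.T @ X + l2 * W, g.sum(axis=0)


def _log_loss_acc(W, b, X, y, l2):
    z = X @ W.T + b
    z -= z.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = float(-logp[np.arange(len(y)), y].mean()) + 0.5 * l2 * float((W**2).sum())
    acc = float((z.argmax(axis=1) == y).mean())
    return loss, acc


class ReferenceScorer(ScoringModel):
    """Regularized multinomial linear scorer over the fixed feature map."""

    def __init__(self, config: TrainConfig | None = None):
        self.config = config or TrainConfig()
        self.extractor = FeatureExtractor(self.config.pixel_side)
        self.class_labels: list = []
        self.W: np.ndarray | None = None
        self.b: np.ndarray | None = None
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None
        self.training_log: list[dict] = []
        self.best_epoch: int | None = None

    # -- feature plumbing -------------------------------------------------
    def featurize(self, frames: list[Frame]) -> np.ndarray:
        return np.array([self.extractor(f) for f in frames])

    def _encode_labels(self, labels) -> np.ndarray:
        index = {lab: i for i, lab in enumerate(self.class_labels)}
        return np.array([index[lab] for lab in labels], dtype=int)

    # -- training ---------------------------------------------------------
    def fit(self, train_frames, train_labels, val_frames, val_labels) -> "ReferenceScorer":
        if len(val_frames) == 0:
            raise ValueError("validation set must be non-empty")
        frames, labels = list(train_frames), list(train_labels)
        if self.config.n_augment > 0:
            rng = np.random.default_rng(self.config.seed)
            extra_frames, extra_labels = [], []
            for f, lab in zip(train_frames, train_labels):
                for _ in range(self.config.n_augment):
                    draw = int(rng.integers(2**31 - 1))
                    extra_frames.append(augment_image(f, self.config.augment, draw))
                    extra_labels.append(lab)
            frames += extra_frames
            labels += extra_labels
        self.class_labels = sorted(set(labels))
        if len(self.class_labels) < 2:
            raise ValueError("training labels must contain at least 2 classes")
        X = np.array([self.extractor(f) for f in frames])
        Xv = np.array([self.extractor(f) for f in val_frames])
        y = self._encode_labels(labels)
        yv = self._encode_labels(val_labels)
        return self.fit_matrix(X, y, Xv, yv, labels_already_set=True)

    def fit_matrix(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        class_labels: list | None = None,
        labels_already_set: bool = False,
    ) -> "ReferenceScorer":
        """Train on precomputed feature matrices (integer-encoded labels)."""
        if not labels_already_set:
            if class_labels is not None:
                self.class_labels = list(class_labels)
            else:
                self.class_labels = sorted(set(int(v) for v in y))
                y = np.searchsorted(self.class_labels, y)
                y_val = np.searchsorted(self.class_labels, y_val)
        if len(self.class_labels) < 2:
            raise ValueError("training labels must contain at least 2 classes")
        if len(X_val) == 0:
            raise ValueError("validation set must be non-empty")
        cfg = self.config
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 1e-12, sd, 1.0)
        Xs = (X - self._mu) / self._sd
        Xvs = (X_val - self._mu) / self._sd
        n, F = Xs.shape
        C = len(self.class_labels)
        onehot = np.zeros((n, C))
        onehot[np.arange(n), y] = 1.0

        # Lipschitz step size for softmax CE: 0.25 * ||X||_2^2 / n + l2
        v = np.ones(F) / np.sqrt(F)
        for _ in range(8):  # power iteration on X^T X
            v = Xs.T @ (Xs @ v)
            v /= np.linalg.norm(v) + 1e-30
        sigma2 = float(v @ (Xs.T @ (Xs @ v)))
        lr = 1.0 / (0.25 * sigma2 / n + cfg.l2)

        W = np.zeros((C, F))
        b = np.zeros(C)
        vel_W = np.zeros_like(W)
        vel_b = np.zeros_like(b)
        best = (np.inf, -1, None, None)  # (val loss, epoch, W, b)
        best_acc = -np.inf
        since_loss = since_acc = 0
        self.training_log = []
        for epoch in range(cfg.max_epochs):
            _, gW, gb = _softmax_loss_grad(W, b, Xs, onehot, cfg.l2)
            vel_W = cfg.momentum * vel_W - lr * gW
            vel_b = cfg.momentum * vel_b - lr * gb
            W = W + vel_W
            b = b + vel_b
            val_loss, val_acc = _log_loss_acc(W, b, Xvs, y_val, cfg.l2)
            self.training_log.append(
                {"epoch": epoch, "val_loss": val_loss, "val_accuracy": val_acc}
            )
            if val_loss < best[0] - 1e-12:
                best = (val_loss, epoch, W.copy(), b.copy())
                since_loss = 0
            else:
                since_loss += 1
            if val_acc > best_acc + 1e-12:
                best_acc = val_acc
                since_acc = 0
            else:
                since_acc += 1
            if since_loss >= cfg.patience and since_acc >= cfg.patience:
                break
        self.best_epoch = best[1]
        self.W, self.b = best[2], best[3]
        return self

    # -- scoring ----------------------------------------------------------
    def _check_fitted(self) -> None:
        if self.W is None:
            raise RuntimeError("model is not fitted")

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        Xs = (np.atleast_2d(X) - self._mu) / self._sd
        return Xs @ self.W.T + self.b

    def score(self, frame: Frame) -> np.ndarray:
        self._check_fitted()
        return self.score_matrix(self.extractor(frame)[None, :])[0]

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        self._check_fitted()
        meta = {
            "class_labels": list(self.class_labels),
            "pixel_side": self.config.pixel_side,
            "l2": self.config.l2,
            "best_epoch": self.best_epoch,
            "training_log": self.training_log,
        }
        np.savez(
            path,
            W=self.W,
            b=self.b,
            mu=self._mu,
            sd=self._sd,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceScorer":
        with np.load(path) as payload:
            meta = json.loads(bytes(payload["meta"]).decode())
            model = cls(TrainConfig(pixel_side=meta["pixel_side"], l2=meta["l2"]))
            model.class_labels = meta["class_labels"]
            model.training_log = meta["training_log"]
            model.best_epoch = meta["best_epoch"]
            model.W = payload["W"]
            model.b = payload["b"]
            model._mu = payload["mu"]
            model._sd = payload["sd"]
        return model
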