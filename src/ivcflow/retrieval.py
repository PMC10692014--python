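"""View retrieval and quality gating with open-set (OpenMax) rejection.

A small shared-encoder network consumes a downsampled frame and feeds two
heads: a K-class view head (subcostal IVC vs. decoy views) and a 2-class
quality head (good/bad).  Training minimises ``view loss + lambda * quality
loss`` with full-batch Adam, deterministically for a fixed seed.

Open-set recognition follows the OpenMax recipe: for each known class,
collect the activation vectors (pre-softmax view scores) of correctly
classified training samples, store their mean activation vector (MAV), and
fit a Weibull distribution to the tail of the largest distances from the
MAV.  At inference the top-ranked activations are discounted by the Weibull
tail probability of the sample's distance; the discounted mass becomes an
"unknown" pseudo-activation, so images far from every known class land in
an explicit unknown category instead of being forced into the closest one.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import weibull_min
from skimage.transform import resize

__all__ = [
    "TwoHeadModel",
    "OpenMaxCalibration",
    "ClipDecision",
    "train_two_head",
    "compute_mavs",
    "fit_weibull_tail",
    "calibrate_openmax",
    "openmax_scores",
    "classify_frame",
    "classify_clip",
]

INPUT_SIZE = (32, 32)
UNKNOWN = "unknown"


def frame_features(frame: np.ndarray, input_size=INPUT_SIZE) -> np.ndarray:
    small = resize(np.asarray(frame, dtype=float), input_size,
                   anti_aliasing=True, preserve_range=True)
    return small.ravel()


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclasses.dataclass
class TwoHeadModel:
    """Shared encoder + view head (K classes) + quality head (good/bad)."""

    W1: np.ndarray
    b1: np.ndarray
    Wv: np.ndarray
    bv: np.ndarray
    Wq: np.ndarray
    bq: np.ndarray
    view_classes: List[str]
    quality_classes: List[str]
    mu: np.ndarray  # feature standardisation from training data
    sd: np.ndarray
    input_size: Tuple[int, int] = INPUT_SIZE
    seed: int = 0
    final_loss: float = float("nan")

    def encode(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mu) / self.sd
        return np.tanh(Z @ self.W1 + self.b1)

    def activations(self, X: np.ndarray) -> np.ndarray:
        """Pre-softmax view scores (the OpenMax activation vectors)."""
        return self.encode(X) @ self.Wv + self.bv

    def quality_logits(self, X: np.ndarray) -> np.ndarray:
        return self.encode(X) @ self.Wq + self.bq

    def features(self, frames: Sequence[np.ndarray]) -> np.ndarray:
        return np.stack([frame_features(f, self.input_size) for f in frames])

    def save(self, path) -> None:
        np.savez(
            path, W1=self.W1, b1=self.b1, Wv=self.Wv, bv=self.bv,
            Wq=self.Wq, bq=self.bq, mu=self.mu, sd=self.sd,
            view_classes=np.array(self.view_classes),
            quality_classes=np.array(self.quality_classes),
            input_size=np.array(self.input_size), seed=self.seed,
            final_loss=self.final_loss,
        )

    @classmethod
    def load(cls, path) -> "TwoHeadModel":
        d = np.load(path, allow_pickle=False)
        return cls(
            W1=d["W1"], b1=d["b1"], Wv=d["Wv"], bv=d["bv"], Wq=d["Wq"],
            bq=d["bq"], view_classes=[str(s) for s in d["view_classes"]],
            quality_classes=[str(s) for s in d["quality_classes"]],
            mu=d["mu"], sd=d["sd"],
            input_size=tuple(int(x) for x in d["input_size"]),
            seed=int(d["seed"]), final_loss=float(d["final_loss"]),
        )


def train_two_head(corpus, config: Optional[dict] = None, seed: int = 0) -> TwoHeadModel:
    """Train the two-head classifier on the training split of a corpus.

    ``corpus`` is a :class:`~ivcflow.phantom.Corpus` (its training frames
    are used) or a ``(frames, view_labels, quality_labels)`` triple.  The
    run is deterministic: seeded initialisation, fixed data order,
    full-batch updates.
    """
    config = dict(config or {})
    lam = float(config.get("quality_weight", 1.0))
    n_epochs = int(config.get("epochs", 300))
    lr = float(config.get("lr", 3e-3))
    n_hidden = int(config.get("hidden", 64))

    if hasattr(corpus, "frames_and_labels"):
        frames, views, quals = corpus.subset("train").frames_and_labels()
    else:
        frames, views, quals = corpus
    view_classes = sorted(set(views))
    quality_classes = sorted(set(quals))  # ["bad", "good"]
    if len(view_classes) < 2:
        raise ValueError("training corpus must contain at least 2 view classes")
    if set(quality_classes) != {"bad", "good"}:
        raise ValueError(
            f"training corpus must contain both quality labels, got {quality_classes}"
        )

    X = np.stack([frame_features(f) for f in frames])
    yv = np.array([view_classes.index(v) for v in views])
    yq = np.array([quality_classes.index(q) for q in quals])
    mu = X.mean(axis=0)
    sd = X.std(axis=0) + 1e-8
    Z = (X - mu) / sd

    rng = np.random.default_rng(seed)
    n_in = Z.shape[1]
    K = len(view_classes)
    W1 = rng.normal(0, 1.0 / np.sqrt(n_in), (n_in, n_hidden))
    b1 = np.zeros(n_hidden)
    Wv = rng.normal(0, 1.0 / np.sqrt(n_hidden), (n_hidden, K))
    bv = np.zeros(K)
    Wq = rng.normal(0, 1.0 / np.sqrt(n_hidden), (n_hidden, 2))
    bq = np.zeros(2)
    params = [W1, b1, Wv, bv, Wq, bq]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    n = Z.shape[0]
    loss = float("nan")

    for epoch in range(1, n_epochs + 1):
        H = np.tanh(Z @ W1 + b1)
        Pv = _softmax(H @ Wv + bv)
        Pq = _softmax(H @ Wq + bq)
        loss_v = -np.mean(np.log(Pv[np.arange(n), yv] + 1e-12))
        loss_q = -np.mean(np.log(Pq[np.arange(n), yq] + 1e-12))
        loss = loss_v + lam * loss_q

        Gv = Pv.copy()
        Gv[np.arange(n), yv] -= 1
        Gv /= n
        Gq = Pq.copy()
        Gq[np.arange(n), yq] -= 1
        Gq *= lam / n
        dH = Gv @ Wv.T + Gq @ Wq.T
        dA1 = dH * (1 - H**2)
        grads = [Z.T @ dA1, dA1.sum(0), H.T @ Gv, Gv.sum(0), H.T @ Gq, Gq.sum(0)]
        for p, g, mi, vi in zip(params, grads, m, v):
            mi *= beta1
            mi += (1 - beta1) * g
            vi *= beta2
            vi += (1 - beta2) * g**2
            mhat = mi / (1 - beta1**epoch)
            vhat = vi / (1 - beta2**epoch)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    return TwoHeadModel(W1, b1, Wv, bv, Wq, bq, view_classes, quality_classes,
                        mu, sd, seed=seed, final_loss=float(loss))


# ---------------------------------------------------------------------------
# OpenMax calibration


@dataclasses.dataclass
class OpenMaxCalibration:
    """Per-class MAVs and Weibull tail models, plus decision knobs."""

    classes: List[str]
    mavs: np.ndarray  # (K, K) mean activation vectors
    weibulls: List[Tuple[float, float, float]]  # (shape, scale, shift) per class
    tail_size: int = 20
    alpha: int = 3
    unknown_threshold: float = 0.5

    def __post_init__(self) -> None:
        K = len(self.classes)
        if len(self.weibulls) != K or len(self.mavs) != K:
            raise ValueError("need one MAV and one Weibull triple per class")
        if self.tail_size < 2:
            raise ValueError("tail_size must be >= 2")
        if not (1 <= self.alpha <= K):
            raise ValueError("alpha must be in [1, K]")

    def wscore(self, k: int, distance: float) -> float:
        shape, scale, shift = self.weibulls[k]
        return float(weibull_min.cdf(max(distance - shift, 0.0), shape, scale=scale))

    def to_json(self, path) -> None:
        payload = {
            "classes": self.classes,
            "mavs": np.asarray(self.mavs).tolist(),
            "weibulls": [list(map(float, w)) for w in self.weibulls],
            "tail_size": self.tail_size,
            "alpha": self.alpha,
            "unknown_threshold": self.unknown_threshold,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "OpenMaxCalibration":
        d = json.loads(Path(path).read_text())
        return cls(
            classes=d["classes"], mavs=np.asarray(d["mavs"], dtype=float),
            weibulls=[tuple(w) for w in d["weibulls"]],
            tail_size=int(d["tail_size"]), alpha=int(d["alpha"]),
            unknown_threshold=float(d["unknown_threshold"]),
        )


def compute_mavs(model: TwoHeadModel, frames, views) -> Dict[str, np.ndarray]:
    """Mean activation vector per class over correctly classified samples."""
    X = model.features(frames)
    A = model.activations(X)
    pred = np.argmax(A, axis=1)
    mavs: Dict[str, np.ndarray] = {}
    for k, cls in enumerate(model.view_classes):
        idx = [i for i, vw in enumerate(views)
               if vw == cls and pred[i] == k]
        if not idx:
            raise ValueError(
                f"class {cls!r} has no correctly classified training samples"
            )
        mavs[cls] = A[idx].mean(axis=0)
    return mavs


def fit_weibull_tail(distances, tail_size: int, shift: float = 0.0):
    """ML Weibull fit to the ``tail_size`` largest distances (after shift).

    Returns ``(shape, scale, shift)``; the tail CDF evaluated at a distance
    d is ``weibull_min.cdf(max(d - shift, 0), shape, scale=scale)`` — zero
    at the shift point and nondecreasing in d.
    """
    d = np.sort(np.asarray(distances, dtype=float))
    if len(d) < tail_size:
        raise ValueError(f"need at least tail_size={tail_size} distances, got {len(d)}")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    tail = d[-tail_size:] - shift
    if np.ptp(tail) < 1e-12:
        raise ValueError("degenerate Weibull fit: tail distances are all equal")
    if np.any(tail <= 0):
        raise ValueError("shift must lie below every tail distance")
    shape, _, scale = weibull_min.fit(tail, floc=0.0)
    return float(shape), float(scale), float(shift)


def calibrate_openmax(
    model: TwoHeadModel, frames, views,
    tail_size: int = 20, alpha: Optional[int] = None,
    unknown_threshold: float = 0.5,
) -> OpenMaxCalibration:
    """Fit MAVs and per-class Weibull tails on (typically training) data."""
    K = len(model.view_classes)
    alpha = min(3, K) if alpha is None else alpha
    mavs_d = compute_mavs(model, frames, views)
    X = model.features(frames)
    A = model.activations(X)
    pred = np.argmax(A, axis=1)
    mavs = np.stack([mavs_d[c] for c in model.view_classes])
    weibulls = []
    for k, cls in enumerate(model.view_classes):
        idx = [i for i, vw in enumerate(views) if vw == cls and pred[i] == k]
        dist = np.linalg.norm(A[idx] - mavs[k], axis=1)
        eta = min(tail_size, max(2, len(dist)))
        weibulls.append(fit_weibull_tail(dist, eta))
    return OpenMaxCalibration(
        classes=list(model.view_classes), mavs=mavs, weibulls=weibulls,
        tail_size=tail_size, alpha=alpha, unknown_threshold=unknown_threshold,
    )


def openmax_scores(
    v: np.ndarray, calibration: OpenMaxCalibration, alpha: Optional[int] = None
) -> np.ndarray:
    """Revise an activation vector into K+1 class probabilities.

    The top-``alpha`` activations are discounted by
    ``w = WeibullCDF(dist to that class MAV) * rank_weight`` with rank
    weight ``(alpha - i)/alpha`` for rank ``i = 0..alpha-1``; the removed
    mass ``sum(v_k * w_k)`` becomes the unknown pseudo-activation and a
    softmax over the K+1 revised activations yields the output (unknown
    probability is the last entry).  ``alpha = 0`` disables revision and
    returns the closed-set softmax with unknown probability 0.
    """
    v = np.asarray(v, dtype=float)
    K = len(calibration.classes)
    if v.shape != (K,):
        raise ValueError(f"activation vector has shape {v.shape}, expected ({K},)")
    alpha = calibration.alpha if alpha is None else alpha
    if alpha == 0:
        return np.concatenate([_softmax(v), [0.0]])
    if not (1 <= alpha <= K):
        raise ValueError("alpha must be in [0, K]")
    ranks = np.argsort(v)[::-1]
    v_hat = v.copy()
    unknown_act = 0.0
    for i in range(alpha):
        k = int(ranks[i])
        dist = float(np.linalg.norm(v - calibration.mavs[k]))
        w = calibration.wscore(k, dist) * (alpha - i) / alpha
        v_hat[k] = v[k] * (1.0 - w)
        unknown_act += v[k] * w
    return _softmax(np.concatenate([v_hat, [unknown_act]]))


# ---------------------------------------------------------------------------
# frame / clip decisions


@dataclasses.dataclass
class ClipDecision:
    view_label: str  # a known view or "unknown"
    view_probs: np.ndarray  # length K+1, unknown last
    quality_label: str
    frame_view_probs: np.ndarray  # (n_sampled, K+1)
    frame_quality_labels: List[str]

    @property
    def analyzable(self) -> bool:
        return self.view_label == "ivc" and self.quality_label == "good"


def classify_frame(model: TwoHeadModel, calibration: OpenMaxCalibration,
                   frame: np.ndarray) -> np.ndarray:
    x = frame_features(frame, model.input_size)[None]
    return openmax_scores(model.activations(x)[0], calibration)


def classify_clip(
    model: TwoHeadModel, calibration: OpenMaxCalibration, clip,
    frame_stride: int = 1, aggregation: str = "mean",
) -> ClipDecision:
    """Aggregate per-frame OpenMax decisions into one clip decision.

    Default aggregation: mean view-probability vector over sampled frames,
    then unknown thresholding; quality by majority vote (ties are "bad").
    A clip shorter than the stride falls back to its first frame.
    """
    frames = clip.frames[::max(1, frame_stride)]
    if len(frames) == 0:
        frames = clip.frames[:1]
    X = model.features(frames)
    A = model.activations(X)
    fp = np.stack([openmax_scores(a, calibration) for a in A])
    if aggregation != "mean":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    probs = fp.mean(axis=0)
    Q = model.quality_logits(X)
    qlabels = [model.quality_classes[int(i)] for i in np.argmax(Q, axis=1)]
    n_good = sum(1 for q in qlabels if q == "good")
    quality = "good" if n_good > len(qlabels) / 2 else "bad"
    k_hat = int(np.argmax(probs))
    if k_hat == len(calibration.classes) or probs[-1] > calibration.unknown_threshold:
        view = UNKNOWN
    else:
        view = calibration.classes[k_hat]
    return ClipDecision(view, probs, quality, fp, qlabels)
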