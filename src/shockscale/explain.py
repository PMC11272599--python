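"""LIME-style local explanation of a single scalogram prediction.

The image is partitioned into contiguous superpixels (a regular grid — smooth
scalograms do not need a content-aware segmenter), ``n`` random on/off masks
over superpixels are drawn, masked-off regions are replaced by the whole-image
mean colour, and a ridge-regression surrogate of the target-class probability
is fit to the binary mask vectors with kernel weights
``exp(-d^2 / kernel_width^2)`` where ``d`` is the cosine distance of a mask to
the unperturbed all-ones mask.  The surrogate's coefficients rank superpixels
by their influence on the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge

from shockscale._layers import Sequential


@dataclass
class SuperpixelMap:
    """Per-pixel integer labels in [0, S); every superpixel is contiguous."""

    labels: np.ndarray
    n_superpixels: int

    def __post_init__(self) -> None:
        found = np.unique(self.labels)
        if len(found) != self.n_superpixels or found[0] != 0 or found[-1] != self.n_superpixels - 1:
            raise ValueError("labels must be contiguous integers 0..S-1")


@dataclass
class Explanation:
    """Per-superpixel surrogate weights for one (image, class) pair."""

    weights: np.ndarray
    target_class: int
    kernel_width: float
    n_perturbations: int
    seed: int

    def top_superpixels(self, k: int = 5) -> np.ndarray:
        """Indices of the k most positively influential superpixels."""
        return np.argsort(self.weights)[::-1][:k]


def segment_grid(image: np.ndarray, block: int) -> SuperpixelMap:
    """Regular-grid partition into ceil(H/block) x ceil(W/block) superpixels
    (edge blocks may be smaller)."""
    if block < 1:
        raise ValueError("block must be >= 1")
    h, w = image.shape[:2]
    rows = (np.arange(h) // block)[:, None]
    cols = (np.arange(w) // block)[None, :]
    n_cols = -(-w // block)
    labels = rows * n_cols + cols
    return SuperpixelMap(labels=labels.astype(np.int64), n_superpixels=int(labels.max()) + 1)


def explain(
    image: np.ndarray,
    model: Sequential,
    cls: int,
    spmap: SuperpixelMap | None = None,
    n: int = 1000,
    kernel_width: float = 0.25,
    seed: int = 0,
    block: int = 32,
    ridge_alpha: float = 1.0,
    batch_size: int = 64,
    predict_fn=None,
) -> Explanation:
    """Fit the local surrogate for class ``cls`` on ``image`` (H, W, 3 in [0, 1]).

    ``predict_fn(batch) -> (B, K) probabilities`` overrides the model's own
    softmax prediction (useful for testing against planted oracles).

    Raises
    ------
    ValueError
        If the perturbation design is degenerate (all masks identical);
        increase ``n``.
    """
    image = np.asarray(image, dtype=np.float32)
    if spmap is None:
        spmap = segment_grid(image, block)
    S = spmap.n_superpixels
    rng = np.random.default_rng(seed)
    masks = rng.integers(0, 2, size=(n, S)).astype(np.float64)
    if np.all(masks == masks[0]):
        raise ValueError("degenerate perturbation design (all masks identical); increase n")
    if predict_fn is None:
        predict_fn = lambda batch: model.predict_proba(batch, batch_size=batch_size)

    mean_color = image.reshape(-1, image.shape[2]).mean(axis=0)
    onehot = masks[:, spmap.labels]  # (n, H, W): 1 where superpixel kept
    responses = np.empty(n)
    for start in range(0, n, batch_size):
        sel = slice(start, min(start + batch_size, n))
        keep = onehot[sel][..., None]
        batch = keep * image[None] + (1.0 - keep) * mean_color
        responses[sel] = predict_fn(batch.astype(np.float32))[:, cls]

    ones = np.ones(S)
    norms = np.sqrt((masks**2).sum(axis=1) * S)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosine = np.where(norms > 0, masks @ ones / norms, 0.0)
    dist = 1.0 - cosine
    sample_weights = np.exp(-(dist**2) / kernel_width**2)

    ridge = Ridge(alpha=ridge_alpha)
    ridge.fit(masks, responses, sample_weight=sample_weights)
    return Explanation(
        weights=ridge.coef_.copy(),
        target_class=int(cls),
        kernel_width=kernel_width,
        n_perturbations=n,
        seed=seed,
    )


def overlay_mask(image: np.ndarray, spmap: SuperpixelMap, expl: Explanation, k: int = 5) -> np.ndarray:
    """Return a copy of ``image`` with the top-k superpixels highlighted."""
    top = set(expl.top_superpixels(k).tolist())
    out = np.asarray(image, dtype=np.float64).copy()
    member = np.isin(spmap.labels, list(top))
    out[~member] *= 0.35
    return out
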