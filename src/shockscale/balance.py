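"""From-scratch SMOTE oversampling of minority classes in the raw-signal domain.

New minority samples are linear interpolations ``x_i + u (x_z - x_i)`` between
a real fragment ``x_i`` and one of its k nearest same-class neighbours ``x_z``
(Euclidean distance on the raw sample vectors), with ``u`` uniform on [0, 1].
Base fragments are visited round-robin over the class so the synthetic mass is
spread evenly; neighbour choice and ``u`` come from a seeded stream.

Interpolation happens on the 1-D signals *before* the wavelet transform:
interpolating signals and then transforming always yields a valid scalogram,
whereas pixel-space interpolation can produce images no signal generates.
An image-domain variant is available for comparison via ``domain="image"`` on
arbitrary vectors through :func:`smote_vectors`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from shockscale.types import ECGFragment

logger = logging.getLogger(__name__)


@dataclass
class SmoteConfig:
    """k-NN interpolation settings; ``target_count`` is the per-class size after
    oversampling (classes already at or above it are passed through)."""

    k_neighbors: int = 5
    target_count: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target_count < 0:
            raise ValueError("target_count must be non-negative")


def _knn_indices(X: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbours of each row (self excluded),
    by brute-force Euclidean distance, ties broken by lower index."""
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, :k]


def smote_vectors(
    X: np.ndarray, n_new: int, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generate ``n_new`` interpolated rows from ``X``.

    Returns ``(S, base_idx, neigh_idx, u)`` with
    ``S[j] = X[base_idx[j]] + u[j] * (X[neigh_idx[j]] - X[base_idx[j]])``.
    """
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 samples to interpolate")
    k_eff = min(k, n - 1)
    if k_eff < k:
        logger.info("clipping k from %d to %d (class has %d members)", k, k_eff, n)
    nn = _knn_indices(X, k_eff)
    base = np.arange(n_new) % n
    neigh_pick = rng.integers(0, k_eff, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    neigh = nn[base, neigh_pick]
    S = X[base] + u[:, None] * (X[neigh] - X[base])
    return S, base, neigh, u


def smote_resample(fragments: list[ECGFragment], cfg: SmoteConfig) -> list[ECGFragment]:
    """Oversample every class up to ``cfg.target_count`` fragments.

    Real fragments are returned unchanged (in input order) followed by the
    synthetic ones, class-blocked; synthetic fragments carry
    ``synthetic=True`` and derived ids.

    Raises
    ------
    ValueError
        If a class that needs oversampling has fewer than 2 real members.
    """
    by_class: dict[str, list[ECGFragment]] = {}
    for f in fragments:
        if f.label is None:
            raise ValueError("all fragments must be labeled for SMOTE")
        by_class.setdefault(f.label, []).append(f)

    out = list(fragments)
    for ci, (cls, members) in enumerate(sorted(by_class.items())):
        need = cfg.target_count - len(members)
        if need <= 0:
            continue
        if len(members) < 2:
            raise ValueError(
                f"class {cls} has {len(members)} fragment(s); at least 2 are required "
                "to oversample (run with balancing off to keep the raw distribution)"
            )
        lengths = {len(m.samples) for m in members}
        if len(lengths) > 1:
            raise ValueError(f"class {cls} mixes fragment lengths {sorted(lengths)}")
        X = np.stack([m.samples for m in members])
        rng = np.random.default_rng([int(cfg.seed), ci])
        S, base, neigh, _ = smote_vectors(X, need, cfg.k_neighbors, rng)
        fs = members[0].fs
        for j in range(need):
            out.append(
                ECGFragment(
                    samples=S[j],
                    fs=fs,
                    label=cls,
                    id=f"{cls}-syn{j:05d}",
                    synthetic=True,
                )
            )
    return out


def class_counts(fragments: list[ECGFragment]) -> dict[str, tuple[int, int, int]]:
    """Per-class tallies ``label -> (real, synthetic, total)``."""
    counts: dict[str, list[int]] = {}
    for f in fragments:
        c = counts.setdefault(f.label, [0, 0])
        c[1 if f.synthetic else 0] += 1
    return {lab: (c[0], c[1], c[0] + c[1]) for lab, c in sorted(counts.items())}
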