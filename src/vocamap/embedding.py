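"""t-SNE repertoire map from a precomputed DTW distance matrix.

The all-to-all dissimilarity matrix is embedded into two dimensions with
t-distributed stochastic neighbor embedding.  The neighborhood-size
parameter is expressed as the *transition entropy* H (bits) of each point's
transition distribution; perplexity = 2^H, so the default H = 5 corresponds
to the usual perplexity 32.  t-SNE preserves local neighbor relations only:
the output axes are arbitrary (any rigid rotation/reflection is an
equivalent solution), and all downstream statistics — densities, entropy,
significance masks, step labels — are invariant to such transformations.

Initialization is a deterministic classical-MDS (Torgerson) projection of
the distance matrix, falling back to a seeded Gaussian when the Gram matrix
is degenerate, so that runs are reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .repertoire_distance import DistanceMatrix

__all__ = ["RepertoireMap", "embed"]


@dataclass
class RepertoireMap:
    """Per-contour 2-D coordinates in (arbitrary) map units."""

    coordinates: np.ndarray  # (n, 2)
    syllable_order: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("coordinates must be (n, 2)")
        if self.coordinates.shape[0] != len(self.syllable_order):
            raise ValueError("one coordinate pair per syllable required")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    @property
    def n(self) -> int:
        return self.coordinates.shape[0]

    def to_csv(self, path: str | Path) -> Path:
        df = pd.DataFrame(
            {
                "syllable_id": self.syllable_order,
                "x": self.coordinates[:, 0],
                "y": self.coordinates[:, 1],
            }
        )
        df.to_csv(path, index=False)
        return Path(path)

    @classmethod
    def from_csv(cls, path: str | Path, params: dict | None = None) -> "RepertoireMap":
        df = pd.read_csv(path)
        return cls(
            coordinates=df[["x", "y"]].to_numpy(dtype=float),
            syllable_order=[str(s) for s in df["syllable_id"]],
            params=params or {},
        )


def _cmds_init(sq: np.ndarray, seed: int) -> np.ndarray:
    """Classical multidimensional scaling of the distance matrix (2-D).

    Deterministic; used as the t-SNE initialization.  Falls back to a seeded
    Gaussian cloud when the double-centered Gram matrix has fewer than two
    positive eigenvalues.
    """
    n = sq.shape[0]
    d2 = sq**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:2]
    top = vals[order]
    if np.any(top <= 1e-12):
        rng = np.random.default_rng(seed)
        init = rng.normal(size=(n, 2))
    else:
        init = vecs[:, order] * np.sqrt(top)
    # sklearn convention: small-variance init stabilizes early optimization
    std = init.std()
    if std > 0:
        init = init / std * 1e-4
    return np.ascontiguousarray(init, dtype=np.float32)


def embed(
    d: DistanceMatrix,
    transition_entropy: float = 5.0,
    convergence_tol: float = 1e-4,
    seed: int = 0,
    max_iter: int = 1000,
    early_exaggeration: float = 12.0,
) -> RepertoireMap:
    """Embed a distance matrix into the 2-D repertoire map.

    ``transition_entropy`` is in bits; the Gaussian kernel bandwidth of each
    point is tuned so that its transition distribution has this entropy
    (perplexity = 2**transition_entropy).  For small collections the
    perplexity is capped at (n - 1) / 3.  Deterministic given ``seed``.
    """
    if transition_entropy <= 0:
        raise ValueError("transition_entropy must be > 0")
    sq = d.square()
    if not np.all(np.isfinite(sq)):
        raise ValueError("distance matrix contains non-finite values")
    if not np.allclose(sq, sq.T):
        raise ValueError("distance matrix must be symmetric")
    n = sq.shape[0]
    perplexity = float(min(2.0**transition_entropy, max((n - 1) / 3.0, 2.0)))
    init = _cmds_init(sq, seed)
    method = "barnes_hut" if n >= 300 else "exact"
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        perplexity=perplexity,
        init=init,
        random_state=seed,
        method=method,
        max_iter=max_iter,
        early_exaggeration=early_exaggeration,
        learning_rate="auto",
    )
    coords = tsne.fit_transform(sq)
    params = {
        "transition_entropy": transition_entropy,
        "perplexity": perplexity,
        "convergence_tol": convergence_tol,
        "seed": seed,
        "max_iter": max_iter,
        "early_exaggeration": early_exaggeration,
        "method": method,
        "kl_divergence": float(tsne.kl_divergence_),
    }
    return RepertoireMap(
        coordinates=np.asarray(coords, dtype=float),
        syllable_order=list(d.syllable_order),
        params=params,
    )
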