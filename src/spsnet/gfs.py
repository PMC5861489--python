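"""Gene Fuzzy Score (GFS): per-sample rank-quantile transform to [0, 1].

Within each sample, genes are ranked by raw expression. Genes in the upper
theta1 quantile score 1, genes below the theta2 quantile score 0, and genes
in between score by linear interpolation. The transform depends only on
within-sample ranks, so it is invariant to any strictly increasing
per-sample rescaling of the raw values (log transforms, scaling factors,
library-size normalisation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .containers import ExpressionMatrix

__all__ = ["FuzzyMatrix", "gfs_transform"]

DEFAULT_THETA1 = 0.05
DEFAULT_THETA2 = 0.15


@dataclass
class FuzzyMatrix:
    """Fuzzy scores F(g, p) in [0, 1], genes x samples."""

    genes: list[str]
    samples: list[str]
    scores: np.ndarray
    theta1: float
    theta2: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.genes), len(self.samples)):
            raise ValueError("scores shape does not match genes x samples")
        if self.scores.min() < 0.0 or self.scores.max() > 1.0:
            raise ValueError("fuzzy scores must lie in [0, 1]")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]

    def sample_index(self, sample: str) -> int:
        return self._sample_index[sample]


def gfs_transform(
    expr: ExpressionMatrix,
    theta1: float = DEFAULT_THETA1,
    theta2: float = DEFAULT_THETA2,
) -> FuzzyMatrix:
    """Apply the GFS transform to an expression matrix.

    For each sample, let ``q(g) = (rank_from_top(g) - 1) / (n_genes - 1)``
    with average (fractional) ranks for ties, so ``q = 0`` is the highest
    expressed gene. Then::

        F = 1                              if q <= theta1
        F = (theta2 - q) / (theta2 - theta1)   if theta1 < q <= theta2
        F = 0                              if q > theta2

    Parameters
    ----------
    expr
        Raw expression matrix (arbitrary monotone units).
    theta1, theta2
        Top-quantile fractions with ``0 < theta1 < theta2 < 1``. The default
        5% / 15% means the top 5% of a sample's genes score 1 and anything
        below the top 15% scores 0.

    Raises
    ------
    ValueError
        If the thetas are out of order/range, or if any sample is constant
        (ranks undefined).
    """
    if not (0.0 < theta1 < theta2 < 1.0):
        raise ValueError(f"require 0 < theta1 < theta2 < 1, got {theta1}, {theta2}")
    values = expr.values
    spans = values.max(axis=0) - values.min(axis=0)
    if np.any(spans == 0):
        bad = expr.samples[int(np.argmax(spans == 0))]
        raise ValueError(f"sample {bad!r} is constant; ranks are undefined")
    # rank 1 = highest expression; average ranks on ties keep the transform
    # independent of input row order
    ranks = rankdata(-values, axis=0, method="average")
    q = (ranks - 1.0) / (values.shape[0] - 1.0)
    scores = np.clip((theta2 - q) / (theta2 - theta1), 0.0, 1.0)
    return FuzzyMatrix(list(expr.genes), list(expr.samples), scores, theta1, theta2)
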