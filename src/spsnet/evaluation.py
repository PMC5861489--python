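"""Downstream quality metrics for subnetwork differential-expression results.

Scores of significant subnetworks form a samples x subnetworks feature
matrix; its PCA projection and silhouette coefficient quantify how well the
selected features separate known subpopulations (subtype, batch). Purity of
each subnetwork's representative-patient set diagnoses whether a
significant subnetwork marks one specific subpopulation, and the Jaccard
coefficient between significant sets from independent datasets measures
reproducibility.
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .scoring import DEFAULT_ALPHA_SIG, SubnetworkResult

__all__ = [
    "feature_matrix",
    "pca_silhouette",
    "representative_purity",
    "purity_enrichment_test",
    "jaccard_reproducibility",
]


def feature_matrix(
    results: list[SubnetworkResult],
    samples: list[str],
    alpha_sig: float = DEFAULT_ALPHA_SIG,
) -> pd.DataFrame:
    """Samples x significant-subnetworks matrix of SPS scores.

    Columns are restricted to subnetworks that passed the candidate filter
    and are significant at ``alpha_sig``; rows follow ``samples`` order.
    """
    sig = [r for r in results if r.passed_filter and r.p_value < alpha_sig]
    if not sig:
        raise ValueError("no significant subnetworks: empty feature matrix")
    data = {}
    for r in sig:
        missing = [s for s in samples if s not in r.sps_score]
        if missing:
            raise ValueError(f"subnetwork {r.subnetwork.id} lacks scores for {missing[:5]}")
        data[r.subnetwork.id] = [r.sps_score[s] for s in samples]
    return pd.DataFrame(data, index=samples)


def pca_silhouette(
    features: pd.DataFrame,
    labels: dict[str, str] | list[str],
    n_pcs: int = 3,
    *,
    pcs: list[int] | None = None,
    scale: bool = False,
) -> float:
    """Mean silhouette coefficient on a PCA projection of the feature matrix.

    Columns are mean-centred (optionally unit-scaled) and projected onto the
    first ``n_pcs`` principal components; the silhouette uses Euclidean
    distance in that projection. ``pcs`` selects an explicit 1-based list of
    components instead (e.g. ``[2, 3]`` to drop a batch-dominated PC1).

    Every label group needs at least 2 members.
    """
    if isinstance(labels, dict):
        y = np.array([labels[s] for s in features.index])
    else:
        y = np.asarray(labels)
        if len(y) != len(features):
            raise ValueError("labels length does not match samples")
    counts = Counter(y)
    if len(counts) < 2:
        raise ValueError("need at least 2 label groups")
    singletons = [k for k, c in counts.items() if c < 2]
    if singletons:
        raise ValueError(f"singleton label groups: {singletons}")
    X = features.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        X = X / sd
    if np.allclose(X, X[0]):
        warnings.warn("degenerate feature matrix: all samples identical", RuntimeWarning,
                      stacklevel=2)
    wanted = pcs if pcs is not None else list(range(1, n_pcs + 1))
    n_comp = min(max(wanted), min(X.shape))
    proj = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
    cols = [p - 1 for p in wanted if p <= n_comp]
    return float(silhouette_score(proj[:, cols], y, metric="euclidean"))


def representative_purity(
    representatives: tuple[str, ...] | list[str],
    subpop_labels: dict[str, str],
) -> tuple[float, str]:
    """Fraction of representative patients in the majority subpopulation.

    Returns ``(purity, majority_label)``; exact ties are broken by the
    lexicographically smallest label.
    """
    reps = list(representatives)
    if not reps:
        raise ValueError("empty representative set")
    missing = [p for p in reps if p not in subpop_labels]
    if missing:
        raise ValueError(f"representatives without labels: {missing[:5]}")
    counts = Counter(subpop_labels[p] for p in reps)
    best = max(sorted(counts), key=lambda k: counts[k])
    return counts[best] / len(reps), best


def purity_enrichment_test(
    purities: list[float],
    threshold: float = 0.75,
) -> tuple[float, float]:
    """Chi-squared test of high-purity enrichment among significant subnetworks.

    Splits purity values into high (> ``threshold``, strictly) and low
    (<= ``threshold``) and performs a 1-df chi-squared goodness-of-fit
    against a 50/50 null. Returns ``(chi2, p_value)``.
    """
    vals = np.asarray(purities, dtype=float)
    if vals.size == 0:
        raise ValueError("no purity values")
    n_high = int((vals > threshold).sum())
    n_low = int(vals.size - n_high)
    chi2, p = stats.chisquare([n_high, n_low])
    return float(chi2), float(p)


def jaccard_reproducibility(
    sig_a: set[str],
    sig_b: set[str],
) -> tuple[int, int, float]:
    """Jaccard agreement between two significant-subnetwork id sets.

    Returns ``(|A ∩ B|, |A ∪ B|, coefficient)``; the empty-vs-empty case is
    defined as 0 with a warning.
    """
    a, b = set(sig_a), set(sig_b)
    inter, union = len(a & b), len(a | b)
    if union == 0:
        warnings.warn("both significant sets empty: Jaccard defined as 0", RuntimeWarning,
                      stacklevel=2)
        return 0, 0, 0.0
    return inter, union, inter / union
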