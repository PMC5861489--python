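"""Synthetic reference datasets for tests, examples and benchmarks."""

from __future__ import annotations

import numpy as np

from .containers import PathwayCollection

__all__ = ["synthetic_pathway_collection", "PATHWAYAPI_N_PATHWAYS", "PATHWAYAPI_N_SUBNETWORKS"]

# scale of the human PathwayAPI database: 300 pathways yielding 5654
# ego subnetworks of >= 5 genes
PATHWAYAPI_N_PATHWAYS = 300
PATHWAYAPI_N_SUBNETWORKS = 5654


def synthetic_pathway_collection(
    n_pathways: int = PATHWAYAPI_N_PATHWAYS,
    n_subnetworks: int = PATHWAYAPI_N_SUBNETWORKS,
) -> PathwayCollection:
    """Synthetic pathway database at the scale of a curated human collection.

    This is a synthetic stand-in for a real pathway database: it is built so
    that ego-subnetwork generation with the default >= 5-gene filter yields
    exactly ``n_subnetworks`` candidates from ``n_pathways`` pathways,
    matching the published scale of the PathwayAPI human collection (300
    pathways, 5654 subnetworks).

    Each pathway is a ring of n genes where every gene is also connected to
    its second neighbours (so every ring gene has degree 4 and an ego
    network of exactly 5 genes), plus one pendant gene whose 2-gene ego is
    filtered out. The per-pathway ring sizes partition ``n_subnetworks``.
    """
    if n_subnetworks < 5 * n_pathways:
        raise ValueError("each pathway needs a ring of at least 5 genes")
    base, extra = divmod(n_subnetworks, n_pathways)
    pathways: dict[str, set[frozenset[str]]] = {}
    for i in range(n_pathways):
        n = base + 1 if i < extra else base
        name = f"SYNP{i + 1:03d}"
        genes = [f"{name}_G{j + 1:03d}" for j in range(n)]
        edges: set[frozenset[str]] = set()
        for j in range(n):
            edges.add(frozenset({genes[j], genes[(j + 1) % n]}))
            edges.add(frozenset({genes[j], genes[(j + 2) % n]}))
        # pendant gene: ego of size 2, always filtered at min_size 5
        edges.add(frozenset({genes[0], f"{name}_PENDANT"}))
        pathways[name] = edges
    return PathwayCollection(pathways)
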