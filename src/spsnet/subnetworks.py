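"""Candidate subnetwork generation from pathway graphs.

A candidate subnetwork is the ego network of one gene within one pathway:
the gene plus its immediate pathway neighbours. Candidates smaller than
``min_size`` genes (default 5) are discarded. Identical gene sets arising
from different (pathway, seed) pairs are deliberately kept as distinct
candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .containers import ExpressionMatrix, PathwayCollection

__all__ = ["Subnetwork", "generate_ego_subnetworks", "restrict_to_measured", "DEFAULT_MIN_SIZE"]

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 5


@dataclass(frozen=True)
class Subnetwork:
    """A named gene set rooted at a seed gene within one source pathway."""

    id: str
    pathway: str
    seed_gene: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.seed_gene not in self.genes:
            raise ValueError(f"seed gene {self.seed_gene!r} not in gene set of {self.id!r}")


def generate_ego_subnetworks(
    pathways: PathwayCollection,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[Subnetwork]:
    """Enumerate per-(pathway, gene) ego subnetworks, filtered by size.

    Every gene of every pathway seeds one candidate comprising the gene and
    its immediate neighbours in that pathway's edge list. Candidates with
    fewer than ``min_size`` genes are dropped. Output order is deterministic:
    pathway name, then seed gene, lexicographic.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    out: list[Subnetwork] = []
    for pathway in sorted(pathways.pathways):
        neighbours: dict[str, set[str]] = {}
        for edge in pathways.pathways[pathway]:
            a, b = sorted(edge)
            neighbours.setdefault(a, set()).add(b)
            neighbours.setdefault(b, set()).add(a)
        for seed in sorted(neighbours):
            genes = frozenset(neighbours[seed] | {seed})
            if len(genes) >= min_size:
                out.append(Subnetwork(f"{pathway}::{seed}", pathway, seed, genes))
    return out


def _canonical(gene: str) -> str:
    return gene.strip().casefold()


def restrict_to_measured(
    subnetworks: list[Subnetwork],
    expr: ExpressionMatrix,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[Subnetwork]:
    """Drop subnetwork genes absent from the expression matrix.

    Gene identifiers are matched exactly after whitespace trimming and case
    folding. Subnetworks falling below ``min_size`` measured genes are
    removed; per-subnetwork attrition is logged. The returned gene sets use
    the expression matrix's spelling of each identifier.
    """
    measured: dict[str, str] = {}
    for g in expr.genes:
        key = _canonical(g)
        if key in measured:
            logger.warning("gene id collision after case-fold: %r vs %r", measured[key], g)
            continue
        measured[key] = g
    kept: list[Subnetwork] = []
    n_dropped = 0
    for sub in subnetworks:
        mapped = {measured[_canonical(g)] for g in sub.genes if _canonical(g) in measured}
        lost = len(sub.genes) - len(mapped)
        if lost:
            logger.debug("subnetwork %s: dropped %d unmeasured genes", sub.id, lost)
        seed_key = _canonical(sub.seed_gene)
        if len(mapped) < min_size:
            n_dropped += 1
            continue
        seed = measured.get(seed_key, min(mapped))
        if seed not in mapped:
            seed = min(mapped)
        kept.append(Subnetwork(sub.id, sub.pathway, seed, frozenset(mapped)))
    if n_dropped:
        logger.info(
            "restrict_to_measured: dropped %d/%d subnetworks below %d measured genes",
            n_dropped, len(subnetworks), min_size,
        )
    return kept
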