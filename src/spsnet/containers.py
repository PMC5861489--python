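"""Core in-memory containers: expression matrix, phenotype assignment, pathways.

Expression values are arbitrary non-negative units (microarray intensities,
RNA-seq quantifications); every downstream statistic is rank-based within a
sample, so no between-sample normalisation is required or performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "PhenotypeAssignment", "PathwayCollection"]


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    dupes: list[str] = []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen.add(i)
    if dupes:
        raise ValueError(f"duplicate {kind} identifiers: {sorted(set(dupes))[:10]}")


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression matrix E(g, p).

    Parameters
    ----------
    genes
        Ordered gene identifiers (rows). Must be unique.
    samples
        Ordered sample identifiers (columns). Must be unique.
    values
        Numeric matrix of shape ``(len(genes), len(samples))``; every entry
        must be finite.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.genes) < 2 or len(self.samples) < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        _check_unique(self.genes, "gene")
        _check_unique(self.samples, "sample")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.genes[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]

    def sample_index(self, sample: str) -> int:
        return self._sample_index[sample]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_index(s) for s in samples]
        return ExpressionMatrix(list(self.genes), list(samples), self.values[:, idx])


@dataclass
class PhenotypeAssignment:
    """Assignment of samples to the control (C) and test (not-C) phenotypes."""

    control: frozenset[str]
    test: frozenset[str]

    def __post_init__(self) -> None:
        self.control = frozenset(map(str, self.control))
        self.test = frozenset(map(str, self.test))
        if not self.control or not self.test:
            raise ValueError("both phenotypes must be non-empty")
        overlap = self.control & self.test
        if overlap:
            raise ValueError(f"samples in both phenotypes: {sorted(overlap)[:10]}")

    def validate_against(self, expr: ExpressionMatrix) -> None:
        known = set(expr.samples)
        missing = (self.control | self.test) - known
        if missing:
            raise ValueError(f"phenotype samples absent from matrix: {sorted(missing)[:10]}")

    def ordered_control(self, expr: ExpressionMatrix) -> list[str]:
        return [s for s in expr.samples if s in self.control]

    def ordered_test(self, expr: ExpressionMatrix) -> list[str]:
        return [s for s in expr.samples if s in self.test]


@dataclass
class PathwayCollection:
    """Named biological pathways as undirected gene-gene edge lists.

    ``pathways`` maps pathway name -> set of frozenset({gene_a, gene_b})
    undirected edges. Self-loops are rejected at construction.
    """

    pathways: dict[str, set[frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ValueError("pathway collection is empty")
        for name, edges in self.pathways.items():
            if not edges:
                raise ValueError(f"pathway {name!r} has no edges")
            for e in edges:
                if len(e) != 2:
                    raise ValueError(f"self-loop or malformed edge in pathway {name!r}: {set(e)}")

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)

    def genes(self, pathway: str) -> set[str]:
        return {g for e in self.pathways[pathway] for g in e}

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for name in self.pathways:
            out |= self.genes(name)
        return out
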