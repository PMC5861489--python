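"""Readers and writers for expression matrices, pathway edge lists and results.

All formats are plain delimited text. Expression tables are genes x samples
with gene identifiers in the first column and sample identifiers in the
header row. Pathway files are edge lists grouped by pathway name; three
dialects cover the plausible layouts of curated pathway exports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PathwayCollection, PhenotypeAssignment

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_pathways",
    "write_pathways",
    "read_labels",
    "write_results",
    "write_manifest",
    "PATHWAY_DIALECTS",
]

logger = logging.getLogger(__name__)

PATHWAY_DIALECTS = ("generic-edgelist", "pathwayapi-txt", "kegg-txt")


def read_expression_matrix(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples expression table.

    The first row holds sample identifiers and the first column gene
    identifiers. Duplicate identifiers raise instead of being silently
    merged; malformed numeric cells are reported with their row and column.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    sample_ids = [h.strip() for h in header[1:]]
    if len(sample_ids) != len(set(sample_ids)):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample identifiers: {dupes[:10]}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns parsed (check delimiter)")
    genes = [str(g).strip() for g in df.index]
    samples = [str(s).strip() for s in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for j, s in enumerate(samples):
        for i in range(raw.shape[0]):
            try:
                # float() round-trips repr() output exactly
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: malformed numeric cell at gene {genes[i]!r}, "
                    f"sample {s!r}: {raw[i, j]!r}"
                ) from None
    return ExpressionMatrix(genes, samples, values)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path,
                            delimiter: str = "\t") -> None:
    """Write a matrix so that a read round-trip is lossless (repr precision)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(delimiter.join(["gene", *expr.samples]) + "\n")
        for i, g in enumerate(expr.genes):
            row = delimiter.join(repr(float(v)) for v in expr.values[i])
            fh.write(f"{g}{delimiter}{row}\n")


def _parse_edge_line(line: str, dialect: str) -> tuple[str, str, str] | None:
    parts = line.replace(",", "\t").split("\t") if "\t" in line or "," in line else line.split()
    parts = [p.strip() for p in parts if p.strip()]
    if len(parts) < 3:
        return None
    pathway, a, b = parts[0], parts[1], parts[2]
    if dialect == "kegg-txt":
        # KEGG gene tokens may carry an organism prefix like "rno:24153"
        a = a.split(":", 1)[-1]
        b = b.split(":", 1)[-1]
    return pathway, a, b


def read_pathways(path: str | Path, dialect: str = "generic-edgelist") -> PathwayCollection:
    """Parse a pathway edge-list file into a :class:`PathwayCollection`.

    All dialects expect one edge per line: pathway identifier, gene, gene
    (whitespace, tab or comma delimited; extra columns ignored). The
    ``kegg-txt`` dialect additionally strips organism prefixes from gene
    tokens. Header lines starting with ``#`` are skipped; self-loops are
    dropped with a logged count; undirected duplicate edges are merged.
    """
    if dialect not in PATHWAY_DIALECTS:
        raise ValueError(f"unknown pathway dialect {dialect!r}; choose from {PATHWAY_DIALECTS}")
    path = Path(path)
    pathways: dict[str, set[frozenset[str]]] = {}
    n_self_loops = 0
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rec = _parse_edge_line(line, dialect)
            if rec is None:
                continue
            pathway, a, b = rec
            if a == b:
                n_self_loops += 1
                continue
            pathways.setdefault(pathway, set()).add(frozenset({a, b}))
    if n_self_loops:
        logger.info("%s: dropped %d self-loop edges", path, n_self_loops)
    pathways = {k: v for k, v in pathways.items() if v}
    if not pathways:
        raise ValueError(f"{path}: no pathways parsed")
    return PathwayCollection(pathways)


def write_pathways(pathways: PathwayCollection, path: str | Path,
                   delimiter: str = "\t") -> None:
    """Write a collection as a generic edge list (deterministic order)."""
    path = Path(path)
    with path.open("w") as fh:
        for name in sorted(pathways.pathways):
            for edge in sorted(map(sorted, pathways.pathways[name])):
                fh.write(delimiter.join([name, *edge]) + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> label file (tab/comma/space delimited)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.replace(",", "\t").replace(" ", "\t").split("\t") if p]
        if len(parts) < 2:
            raise ValueError(f"labels file: malformed line {line!r}")
        out[parts[0]] = parts[1]
    if not out:
        raise ValueError("labels file is empty")
    return out


def phenotypes_from_labels(labels: dict[str, str], control: str,
                           test: str) -> PhenotypeAssignment:
    return PhenotypeAssignment(
        frozenset(s for s, l in labels.items() if l == control),
        frozenset(s for s, l in labels.items() if l == test),
    )


def write_results(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, *, params: dict, seed: int | None = None,
                   inputs: dict[str, str | Path] | None = None) -> None:
    """Write a JSON run manifest with parameters, seed and input checksums."""
    manifest: dict = {"params": params, "seed": seed, "inputs": {}}
    for name, p in (inputs or {}).items():
        digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        manifest["inputs"][name] = {"path": str(p), "sha256": digest}
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
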