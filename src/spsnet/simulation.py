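"""Simulation framework: synthetic cohorts, heterogeneity injection, and the
sensitivity/specificity and false-positive experiments.

The framework emulates the benchmark design used to characterise
subpopulation-sensitive subnetwork scoring:

* a homogeneous "normal" cohort is split into two pseudo-phenotypes N1
  (control) and N2 (test);
* N2 is further split into two hidden subtypes N21 and N22 holding an
  ``alpha`` / ``1 - alpha`` share of its samples;
* differential expression is induced by multiplying 10% of genes by a
  per-gene fold change drawn from {1.2, 1.5, 1.8, 2.0, 3.0} in N21, and an
  independent 10% subsample likewise in N22;
* ground-truth categories follow: G1 (DE in subtype 1), G2 (DE in subtype
  2), G12 (both), G0 (neither);
* benchmark subnetworks are built per category by hierarchically
  clustering the genes (correlation distance, average linkage), ordering
  them by dendrogram leaves so similar genes are adjacent, and chunking
  the ordered list into consecutive 7-gene sets (trailing remainder
  discarded). G0 contributes four times the number of genes used for G1's
  subnetworks, emulating pathway-database incompleteness.

The base cohort is synthetic (log-normal marginals, independent genes and
samples); the scoring method is rank-based within samples, so only the
shape of the within-sample rank distribution matters. Its dispersion
defaults are calibrated so the fold-change ladder straddles the GFS
top-quantile detection threshold: 1.2-fold rarely changes a gene's fuzzy
score while 3-fold almost always saturates it, which is what makes the
ladder informative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, optimal_leaf_ordering
from scipy.spatial.distance import pdist

from .containers import ExpressionMatrix, PhenotypeAssignment
from .scoring import run_spsnet
from .subnetworks import Subnetwork

__all__ = [
    "SimulatedCohort",
    "generate_base_cohort",
    "inject_heterogeneity",
    "build_simulated_subnetworks",
    "expected_subnetwork_counts",
    "run_sensitivity_experiment",
    "run_fp_experiment",
]

logger = logging.getLogger(__name__)

DEFAULT_R_SET = (1.2, 1.5, 1.8, 2.0, 3.0)
DEFAULT_DE_FRACTION = 0.10
DEFAULT_CHUNK_SIZE = 7
# log-scale dispersion of the homogeneous base cohort (see module docstring)
BASE_MEAN_LOG = 6.0
BASE_BETWEEN_GENE_SD = 0.25
BASE_WITHIN_GENE_SD = 0.12
# optimal leaf ordering is cubic; above this many genes plain leaf order is used
_OLO_MAX_GENES = 1500


@dataclass
class SimulatedCohort:
    """A synthetic cohort with injected subtype-specific differential expression."""

    expr: ExpressionMatrix
    n1: tuple[str, ...]
    n21: tuple[str, ...]
    n22: tuple[str, ...]
    alpha: float
    g1: frozenset[str]
    g2: frozenset[str]
    g12: frozenset[str]
    g0: frozenset[str]
    seed: int | None = None
    fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def n2(self) -> tuple[str, ...]:
        return self.n21 + self.n22

    def phenotypes(self) -> PhenotypeAssignment:
        """N1 as control, N2 as test."""
        return PhenotypeAssignment(frozenset(self.n1), frozenset(self.n2))

    def subtype_labels(self) -> dict[str, str]:
        out = {s: "N1" for s in self.n1}
        out.update({s: "N21" for s in self.n21})
        out.update({s: "N22" for s in self.n22})
        return out


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_base_cohort(
    n_genes: int,
    n_samples: int,
    seed=None,
    *,
    mean_log: float = BASE_MEAN_LOG,
    between_gene_sd: float = BASE_BETWEEN_GENE_SD,
    within_gene_sd: float = BASE_WITHIN_GENE_SD,
) -> ExpressionMatrix:
    """Homogeneous log-normal cohort with no differential structure.

    Each gene g has a latent log-level mu_g ~ N(mean_log, between_gene_sd^2);
    samples are i.i.d. around it with log-noise within_gene_sd. Identical
    seeds give identical matrices.
    """
    if n_genes < 2 or n_samples < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    rng = _rng(seed)
    mu = rng.normal(mean_log, between_gene_sd, n_genes)
    log_e = mu[:, None] + within_gene_sd * rng.standard_normal((n_genes, n_samples))
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    samples = [f"s{j + 1:04d}" for j in range(n_samples)]
    return ExpressionMatrix(genes, samples, np.exp(log_e))


def inject_heterogeneity(
    base: ExpressionMatrix,
    alpha: float,
    seed=None,
    *,
    de_fraction: float = DEFAULT_DE_FRACTION,
    r_set: tuple[float, ...] = DEFAULT_R_SET,
) -> SimulatedCohort:
    """Split a homogeneous cohort and inject subtype-specific fold changes.

    Samples are randomly split into equal halves N1 and N2 (an odd
    remainder goes to N1); N2 is split into subtypes N21 (round(alpha*|N2|)
    samples) and N22. Two independent subsamples of ``de_fraction`` of the
    genes are drawn; each selected gene's raw expression is multiplied by a
    per-gene factor drawn from ``r_set`` — the first subsample in the N21
    patients (ground truth G1), the second in N22 (G2). G12 is their
    intersection, G0 the untouched genes. Non-injected cells are preserved
    bit-exactly.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    rng = _rng(seed)
    samples = list(base.samples)
    order = rng.permutation(len(samples))
    half = len(samples) // 2
    n2 = [samples[i] for i in order[:half]]
    n1 = [samples[i] for i in order[half:]]
    n_21 = int(round(alpha * len(n2)))
    n_21 = min(max(n_21, 1), len(n2) - 1)
    n21, n22 = n2[:n_21], n2[n_21:]

    n_de = math.floor(de_fraction * base.n_genes)
    genes = np.array(base.genes)
    sub1 = rng.choice(base.n_genes, size=n_de, replace=False)
    sub2 = rng.choice(base.n_genes, size=n_de, replace=False)
    values = base.values.copy()
    fc: dict[str, dict[str, float]] = {"N21": {}, "N22": {}}
    for sub, cohort_samples, key in ((sub1, n21, "N21"), (sub2, n22, "N22")):
        cols = [base.sample_index(s) for s in cohort_samples]
        r = np.asarray(rng.choice(r_set, size=len(sub)), dtype=float)
        values[np.ix_(sub, cols)] *= r[:, None]
        fc[key] = dict(zip(genes[sub], r))

    g1 = frozenset(genes[sub1])
    g2 = frozenset(genes[sub2])
    g12 = g1 & g2
    g0 = frozenset(genes) - g1 - g2
    expr = ExpressionMatrix(list(base.genes), list(base.samples), values)
    return SimulatedCohort(
        expr=expr, n1=tuple(n1), n21=tuple(n21), n22=tuple(n22), alpha=alpha,
        g1=g1, g2=g2, g12=g12, g0=g0,
        seed=seed if isinstance(seed, int) else None, fold_changes=fc,
    )


def build_simulated_subnetworks(
    genes: set[str] | list[str],
    expr: ExpressionMatrix,
    size: int = DEFAULT_CHUNK_SIZE,
    *,
    samples: list[str] | None = None,
    label: str = "sim",
) -> list[Subnetwork]:
    """Cluster genes and chunk the leaf-ordered list into fixed-size sets.

    Genes are hierarchically clustered with correlation distance
    (1 - Pearson of log expression across ``samples``, default all samples)
    and average linkage; dendrogram leaf order places the most similar genes
    next to each other (with optimal leaf ordering up to 1500 genes). The
    ordered list is split into consecutive ``size``-gene subnetworks; a
    trailing remainder of fewer than ``size`` genes is discarded, so the
    count is floor(len(genes) / size).
    """
    gene_list = sorted(genes)
    if len(gene_list) < size:
        logger.warning("only %d genes for chunk size %d: no subnetworks", len(gene_list), size)
        return []
    cols = (
        np.arange(expr.n_samples)
        if samples is None
        else np.array([expr.sample_index(s) for s in samples])
    )
    rows = np.array([expr.gene_index(g) for g in gene_list])
    X = np.log(expr.values[np.ix_(rows, cols)] + 1e-12)
    dist = pdist(X, metric="correlation")
    Z = linkage(dist, method="average")
    if len(gene_list) <= _OLO_MAX_GENES:
        Z = optimal_leaf_ordering(Z, dist)
    ordered = [gene_list[i] for i in leaves_list(Z)]
    out = []
    for k in range(len(ordered) // size):
        chunk = ordered[k * size:(k + 1) * size]
        out.append(Subnetwork(f"{label}{k + 1:04d}", label, chunk[0], frozenset(chunk)))
    return out


def expected_subnetwork_counts(
    n_genes: int,
    de_fraction: float = DEFAULT_DE_FRACTION,
    size: int = DEFAULT_CHUNK_SIZE,
    g0_factor: int = 4,
) -> tuple[int, int]:
    """Benchmark subnetwork counts as a pure function of the gene universe.

    Returns ``(n_de_category, n_g0)`` where the DE categories (G1, G2) each
    yield floor(floor(de_fraction * n_genes) / size) subnetworks and G0
    yields ``g0_factor`` times as many (it is built from g0_factor times
    the number of genes actually chunked for G1).
    """
    n_de = math.floor(de_fraction * n_genes) // size
    return n_de, g0_factor * n_de


def _category_genes(cohort: SimulatedCohort, rng: np.random.Generator,
                    size: int, g0_factor: int) -> dict[str, list[str]]:
    g1 = sorted(cohort.g1)
    g2 = sorted(cohort.g2)
    g12 = sorted(cohort.g12)
    n_g1_chunked = (len(g1) // size) * size
    n_g0 = g0_factor * n_g1_chunked
    g0_pool = sorted(cohort.g0)
    n_g0 = min(n_g0, len(g0_pool))
    g0 = [g0_pool[i] for i in rng.choice(len(g0_pool), size=n_g0, replace=False)]
    return {"G1": g1, "G2": g2, "G12": g12, "G0": g0}


def run_sensitivity_experiment(
    n_genes: int = 13801,
    n_samples: int = 240,
    alpha: float = 0.5,
    iterations: int = 100,
    seed=None,
    *,
    methods: tuple[str, ...] = ("pfsnet", "spsnet"),
    r_set: tuple[float, ...] = DEFAULT_R_SET,
    de_fraction: float = DEFAULT_DE_FRACTION,
    size: int = DEFAULT_CHUNK_SIZE,
    g0_factor: int = 4,
    x: int = 10,
    alpha_sig: float = 0.05,
) -> pd.DataFrame:
    """Per-iteration fraction of benchmark subnetworks reported significant.

    Each iteration draws a fresh homogeneous cohort, injects heterogeneity
    at level ``alpha``, builds benchmark subnetworks for the ground-truth
    categories G1/G2/G12/G0, and runs each method with N1 as control and N2
    as test. The returned tidy frame has one row per (iteration, method,
    category) with the significant fraction; G1/G2/G12 rows measure
    sensitivity and G0 rows specificity (1 - fraction).
    """
    rng = _rng(seed)
    records = []
    for it in range(iterations):
        base = generate_base_cohort(n_genes, n_samples, rng)
        cohort = inject_heterogeneity(base, alpha, rng, de_fraction=de_fraction, r_set=r_set)
        cats = _category_genes(cohort, rng, size, g0_factor)
        subnets: list[Subnetwork] = []
        spans: dict[str, slice] = {}
        for cat, genes in cats.items():
            built = build_simulated_subnetworks(genes, cohort.expr, size, label=cat)
            spans[cat] = slice(len(subnets), len(subnets) + len(built))
            subnets.extend(built)
        phen = cohort.phenotypes()
        for method in methods:
            results = run_spsnet(cohort.expr, phen, subnets, mode=method, x=x,
                                 alpha_sig=alpha_sig)
            sig = np.array([r.passed_filter and r.p_value < alpha_sig for r in results])
            assert len(results) == len(subnets)
            for cat in cats:
                block = sig[spans[cat]]
                if block.size == 0:
                    continue
                records.append({
                    "iteration": it, "alpha": alpha, "method": method, "category": cat,
                    "n_subnetworks": int(block.size),
                    "n_significant": int(block.sum()),
                    "fraction_significant": float(block.mean()),
                })
    return pd.DataFrame(records)


def summarize_sensitivity(table: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of the significant fraction per method/category."""
    return (
        table.groupby(["alpha", "method", "category"])["fraction_significant"]
        .describe(percentiles=[0.25, 0.5, 0.75])
        .reset_index()
        .loc[:, ["alpha", "method", "category", "count", "25%", "50%", "75%"]]
        .rename(columns={"count": "iterations", "50%": "median"})
    )


def run_fp_experiment(
    n_genes: int = 13801,
    n_samples: int = 241,
    seed=None,
    *,
    n_null_subnetworks: int = 1000,
    sample_sizes: tuple[int, ...] = (240, 210, 180, 150, 120, 90, 60, 30),
    reps: int = 50,
    size: int = DEFAULT_CHUNK_SIZE,
    x: int = 10,
    alpha_sig: float = 0.05,
    mode: str = "spsnet",
) -> pd.DataFrame:
    """False-positive rates on null subnetworks from a homogeneous cohort.

    One homogeneous cohort is generated and ``n_null_subnetworks``
    clustering-ordered 7-gene subnetworks are built from its (entirely
    non-differentially-expressed) genes. For each subsample size, ``reps``
    random patient subsamples are drawn, each split in half into
    pseudo-phenotypes, and the scoring method is run; the false-positive
    rate of a repetition is the fraction of null subnetworks reported
    significant. Returns one row per (sample_size, rep).
    """
    rng = _rng(seed)
    need = n_null_subnetworks * size
    if n_genes < need:
        raise ValueError(f"need at least {need} genes for {n_null_subnetworks} null subnetworks")
    if max(sample_sizes) > n_samples:
        raise ValueError("largest subsample exceeds cohort size")
    base = generate_base_cohort(n_genes, n_samples, rng)
    pool = [base.genes[i] for i in rng.choice(n_genes, size=need, replace=False)]
    subnets = build_simulated_subnetworks(pool, base, size, label="null")
    assert len(subnets) == n_null_subnetworks
    records = []
    for n_sub in sample_sizes:
        for rep in range(reps):
            chosen = [base.samples[i] for i in rng.choice(n_samples, size=n_sub, replace=False)]
            half = n_sub // 2
            phen = PhenotypeAssignment(frozenset(chosen[:half]), frozenset(chosen[half:]))
            sub_expr = base.subset_samples(chosen)
            results = run_spsnet(sub_expr, phen, subnets, mode=mode, x=x, alpha_sig=alpha_sig)
            fp = float(np.mean([r.passed_filter and r.p_value < alpha_sig for r in results]))
            records.append({"sample_size": n_sub, "rep": rep, "n_subnetworks": len(results),
                            "fp_rate": fp})
    return pd.DataFrame(records)
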