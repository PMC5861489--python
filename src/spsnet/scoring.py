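"""SPSNet / PFSNet subnetwork scoring and significance testing.

For a subnetwork S and phenotype side X the method:

1. sums each patient's fuzzy votes over the genes of S (vote vector V);
2. picks the top-x patients of X by V as *representative patients* Q —
   a proxy for the subpopulation in which S is most active;
3. computes per-gene relevance factors beta(g, Q) = mean fuzzy score of g
   over Q;
4. scores every patient p on each side: SScore(p, S, X) = sum_g F(g, p) *
   beta(g, Q(S, X));
5. forms SPS_Score(p) = SScore(p, S, test) - SScore(p, S, control) and
   tests its mean against zero with a one-sample t-test (theoretical t
   null, two-sided).

A subnetwork is tested only if, on at least one side, at least
``min_genes`` genes have beta >= ``min_beta`` (defaults 5 and 0.5): its
genes must be highly expressed in at least half of the representative
patients of that side.

PFSNet is the homogeneous special case in which the representative set is
the entire phenotype; it is exposed as ``mode="pfsnet"`` and is bitwise
identical to ``mode="spsnet"`` whenever x >= the phenotype size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ExpressionMatrix, PhenotypeAssignment
from .gfs import DEFAULT_THETA1, DEFAULT_THETA2, FuzzyMatrix, gfs_transform
from .subnetworks import DEFAULT_MIN_SIZE, Subnetwork, restrict_to_measured

__all__ = [
    "RelevanceProfile",
    "SubnetworkResult",
    "relevance_factor",
    "vote_vector",
    "select_representatives",
    "sscore",
    "passes_candidate_filter",
    "test_subnetwork",
    "run_spsnet",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_X = 10
DEFAULT_MIN_GENES = 5
DEFAULT_MIN_BETA = 0.5
DEFAULT_ALPHA_SIG = 0.05


@dataclass
class RelevanceProfile:
    """Per-gene relevance factors beta(g, Q) for one side of one subnetwork."""

    subnetwork_id: str
    side: str  # "control" or "test"
    beta: dict[str, float]
    representatives: tuple[str, ...]


@dataclass
class SubnetworkResult:
    """Scores, test statistic and representative patients for one subnetwork."""

    subnetwork: Subnetwork
    sscore_control: dict[str, float]
    sscore_test: dict[str, float]
    sps_score: dict[str, float]
    t_statistic: float
    p_value: float
    direction: str  # "up-in-test" or "up-in-control"
    passed_filter: bool
    representatives_control: tuple[str, ...]
    representatives_test: tuple[str, ...]
    p_adjusted: float | None = None

    @property
    def significant(self) -> bool:
        return self.passed_filter and self.p_value < DEFAULT_ALPHA_SIG

    def is_significant(self, alpha: float = DEFAULT_ALPHA_SIG, adjusted: bool = False) -> bool:
        p = self.p_adjusted if adjusted and self.p_adjusted is not None else self.p_value
        return self.passed_filter and p < alpha


def relevance_factor(fuzzy: FuzzyMatrix, gene: str, patients: set[str] | list[str]) -> float:
    """beta(g, X): arithmetic mean of F(g, p) over the patients in X."""
    pats = list(patients)
    if not pats:
        raise ValueError("relevance factor over an empty patient set")
    gi = fuzzy.gene_index(gene)
    cols = [fuzzy.sample_index(p) for p in pats]
    return float(fuzzy.scores[gi, cols].mean())


def vote_vector(fuzzy: FuzzyMatrix, subnetwork: Subnetwork, patients: list[str]) -> np.ndarray:
    """V(S, X): per-patient sum of fuzzy scores over the subnetwork's genes."""
    rows = [fuzzy.gene_index(g) for g in sorted(subnetwork.genes)]
    cols = [fuzzy.sample_index(p) for p in patients]
    return fuzzy.scores[np.ix_(rows, cols)].sum(axis=0)


def select_representatives(votes: np.ndarray, patients: list[str], x: int) -> tuple[str, ...]:
    """Top-x patients by vote, ties broken by lexicographically smaller id.

    If ``x`` is at least the number of patients, all patients are returned
    (the PFSNet limit).
    """
    if x < 1:
        raise ValueError("x must be >= 1")
    votes = np.asarray(votes, dtype=float)
    if len(votes) != len(patients):
        raise ValueError("vote vector and patient list lengths differ")
    order = sorted(range(len(patients)), key=lambda i: (-votes[i], patients[i]))
    return tuple(patients[i] for i in order[:x])


def sscore(fuzzy: FuzzyMatrix, patient: str, subnetwork: Subnetwork,
           beta_map: dict[str, float]) -> float:
    """SScore(p, S, X) = sum over genes of F(g, p) * beta(g, Q(S, X))."""
    col = fuzzy.sample_index(patient)
    total = 0.0
    for g in subnetwork.genes:
        total += fuzzy.scores[fuzzy.gene_index(g), col] * beta_map[g]
    return total


def passes_candidate_filter(beta_map: dict[str, float],
                            min_genes: int = DEFAULT_MIN_GENES,
                            min_beta: float = DEFAULT_MIN_BETA) -> bool:
    """True iff at least ``min_genes`` genes have beta >= ``min_beta``."""
    return sum(1 for b in beta_map.values() if b >= min_beta) >= min_genes


def test_subnetwork(sps_scores: np.ndarray) -> tuple[float, float, str]:
    """One-sample two-sided t-test of the SPS score mean against zero.

    Returns ``(t_statistic, p_value, direction)`` with df = n - 1. A
    positive mean (test side scoring higher) gives direction "up-in-test".
    Degenerate zero-variance input is handled explicitly: all-zero scores
    are maximally null (p = 1); constant nonzero scores are maximally
    non-null (p = 0, with a warning).
    """
    scores = np.asarray(sps_scores, dtype=float)
    if scores.size < 3:
        raise ValueError("need at least 3 scores for the t-test")
    mean = scores.mean()
    direction = "up-in-test" if mean > 0 else "up-in-control"
    if np.ptp(scores) == 0.0:
        if mean == 0.0:
            return 0.0, 1.0, direction
        warnings.warn("zero-variance SPS scores with nonzero mean", RuntimeWarning,
                      stacklevel=2)
        return float(np.sign(mean)) * float("inf"), 0.0, direction
    t, p = stats.ttest_1samp(scores, 0.0)
    return float(t), float(p), direction


def _side_profile(F: np.ndarray, rows: np.ndarray, pats: list[str],
                  cols: np.ndarray, x: int, pfsnet: bool) -> tuple[np.ndarray, tuple[str, ...]]:
    """Representatives and per-gene beta vector for one side (vectorised)."""
    if pfsnet or x >= len(pats):
        q_cols = cols
        reps = tuple(pats)
    else:
        votes = F[np.ix_(rows, cols)].sum(axis=0)
        order = sorted(range(len(pats)), key=lambda i: (-votes[i], pats[i]))[:x]
        q_cols = cols[order]
        reps = tuple(pats[i] for i in order)
    beta = F[np.ix_(rows, q_cols)].mean(axis=1)
    return beta, reps


def run_spsnet(
    expr: ExpressionMatrix,
    phenotypes: PhenotypeAssignment,
    subnetworks: list[Subnetwork],
    *,
    theta1: float = DEFAULT_THETA1,
    theta2: float = DEFAULT_THETA2,
    x: int = DEFAULT_X,
    min_genes: int = DEFAULT_MIN_GENES,
    min_beta: float = DEFAULT_MIN_BETA,
    alpha_sig: float = DEFAULT_ALPHA_SIG,
    mode: str = "spsnet",
    test_population: str = "all",
    min_size: int = DEFAULT_MIN_SIZE,
    adjust: bool = False,
    fuzzy: FuzzyMatrix | None = None,
) -> list[SubnetworkResult]:
    """Run the full SPSNet (or PFSNet) pipeline.

    Parameters
    ----------
    expr, phenotypes, subnetworks
        Validated inputs; subnetworks are restricted to measured genes
        (re-applying ``min_size``) before scoring.
    x
        Number of representative patients per side (ignored in pfsnet
        mode). Clamped with a warning if a phenotype is smaller than x.
    mode
        "spsnet" (top-x representatives) or "pfsnet" (whole phenotype).
    test_population
        Which patients' SPS scores enter the t-test: "all" (default),
        "control" or "test".
    adjust
        Additionally compute Benjamini-Hochberg adjusted p-values across
        the tested (filter-passing) subnetworks.
    fuzzy
        Optional precomputed fuzzy matrix (must match ``expr``); computed
        from ``expr`` with ``theta1``/``theta2`` if absent.

    Returns
    -------
    list of SubnetworkResult, one per subnetwork surviving the measured-gene
    restriction, in input order. ``passed_filter`` records the beta-filter;
    callers should treat a subnetwork as significant only when it passed the
    filter and its p-value is below ``alpha_sig``.
    """
    if mode not in ("spsnet", "pfsnet"):
        raise ValueError(f"unknown mode {mode!r}")
    if test_population not in ("all", "control", "test"):
        raise ValueError(f"unknown test_population {test_population!r}")
    phenotypes.validate_against(expr)
    control = phenotypes.ordered_control(expr)
    test = phenotypes.ordered_test(expr)
    if len(control) < 3 or len(test) < 3:
        raise ValueError("each phenotype needs at least 3 samples")
    if mode == "spsnet" and x > min(len(control), len(test)):
        logger.warning("x=%d exceeds smallest phenotype (%d); clamping",
                       x, min(len(control), len(test)))

    if fuzzy is None:
        fuzzy = gfs_transform(expr, theta1, theta2)
    F = fuzzy.scores
    subnetworks = restrict_to_measured(subnetworks, expr, min_size=min_size)

    pop = {"all": control + test, "control": control, "test": test}[test_population]
    pop_cols = np.array([fuzzy.sample_index(p) for p in pop])
    c_cols = np.array([fuzzy.sample_index(p) for p in control])
    t_cols = np.array([fuzzy.sample_index(p) for p in test])
    pfsnet = mode == "pfsnet"

    results: list[SubnetworkResult] = []
    for sub in subnetworks:
        genes = sorted(sub.genes)
        rows = np.array([fuzzy.gene_index(g) for g in genes])
        beta_c, reps_c = _side_profile(F, rows, control, c_cols, x, pfsnet)
        beta_t, reps_t = _side_profile(F, rows, test, t_cols, x, pfsnet)
        passed = (
            int((beta_c >= min_beta).sum()) >= min_genes
            or int((beta_t >= min_beta).sum()) >= min_genes
        )
        Fp = F[np.ix_(rows, pop_cols)]
        ss_c = beta_c @ Fp
        ss_t = beta_t @ Fp
        sps = ss_t - ss_c
        t_stat, p_val, direction = test_subnetwork(sps)
        results.append(SubnetworkResult(
            subnetwork=sub,
            sscore_control=dict(zip(pop, ss_c)),
            sscore_test=dict(zip(pop, ss_t)),
            sps_score=dict(zip(pop, sps)),
            t_statistic=t_stat,
            p_value=p_val,
            direction=direction,
            passed_filter=passed,
            representatives_control=reps_c,
            representatives_test=reps_t,
        ))

    if adjust:
        tested = [r for r in results if r.passed_filter]
        if tested:
            adj = stats.false_discovery_control([r.p_value for r in tested], method="bh")
            for r, a in zip(tested, adj):
                r.p_adjusted = float(a)
    return results


def pfsnet_permutation_pvalues(
    expr: ExpressionMatrix,
    phenotypes: PhenotypeAssignment,
    subnetworks: list[Subnetwork],
    n_permutations: int = 200,
    seed=None,
    **params,
) -> dict[str, float]:
    """Class-label permutation null for whole-phenotype (PFSNet) scoring.

    Shuffles the control/test assignment ``n_permutations`` times, rescores,
    and returns per-subnetwork permutation p-values: the fraction of
    permutations whose |t| meets or exceeds the observed |t| (with the
    add-one correction). Only available for pfsnet mode: the top-x
    representative sets of the subpopulation-sensitive mode are too small to
    support enough distinct label permutations.
    """
    params.pop("mode", None)
    rng = np.random.default_rng(seed)
    observed = run_spsnet(expr, phenotypes, subnetworks, mode="pfsnet", **params)
    obs_t = {r.subnetwork.id: abs(r.t_statistic) for r in observed}
    exceed = {sid: 0 for sid in obs_t}
    pool = phenotypes.ordered_control(expr) + phenotypes.ordered_test(expr)
    n_control = len(phenotypes.control)
    for _ in range(n_permutations):
        perm = [pool[i] for i in rng.permutation(len(pool))]
        shuffled = PhenotypeAssignment(frozenset(perm[:n_control]),
                                       frozenset(perm[n_control:]))
        for r in run_spsnet(expr, shuffled, subnetworks, mode="pfsnet", **params):
            if abs(r.t_statistic) >= obs_t[r.subnetwork.id]:
                exceed[r.subnetwork.id] += 1
    return {sid: (1 + k) / (1 + n_permutations) for sid, k in exceed.items()}


def results_to_frame(results: list[SubnetworkResult],
                     alpha_sig: float = DEFAULT_ALPHA_SIG):
    """Tabulate results: one row per subnetwork, ready for TSV export."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "subnetwork_id": r.subnetwork.id,
            "pathway": r.subnetwork.pathway,
            "genes": ",".join(sorted(r.subnetwork.genes)),
            "direction": r.direction,
            "mean_sps_score": float(np.mean(list(r.sps_score.values()))),
            "t_statistic": r.t_statistic,
            "p_value": r.p_value,
            "p_adjusted": r.p_adjusted if r.p_adjusted is not None else np.nan,
            "passed_filter": r.passed_filter,
            "significant": r.passed_filter and r.p_value < alpha_sig,
            "representatives_control": ",".join(r.representatives_control),
            "representatives_test": ",".join(r.representatives_test),
        })
    return pd.DataFrame(rows)
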