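"""Independent brute-force reference implementation used as a test oracle.

Pure-Python double loops, sorting-based average ranks, and a closed-form
Student-t tail via ``scipy.special.stdtr``. Deliberately shares no code
with the package's vectorised implementation.
"""

from __future__ import annotations

import math

from scipy.special import stdtr


def ranks_from_top(values: list[float]) -> list[float]:
    """Average (fractional) ranks, rank 1 = largest value."""
    order = sorted(range(len(values)), key=lambda i: -values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + 1 + j + 1) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def gfs_ref(matrix: list[list[float]], theta1: float, theta2: float) -> list[list[float]]:
    """GFS transform of a genes x samples nested list."""
    n_genes = len(matrix)
    n_samples = len(matrix[0])
    out = [[0.0] * n_samples for _ in range(n_genes)]
    for p in range(n_samples):
        col = [matrix[g][p] for g in range(n_genes)]
        rk = ranks_from_top(col)
        for g in range(n_genes):
            q = (rk[g] - 1.0) / (n_genes - 1.0)
            if q <= theta1:
                f = 1.0
            elif q > theta2:
                f = 0.0
            else:
                f = (theta2 - q) / (theta2 - theta1)
            out[g][p] = f
    return out


def beta_ref(F: list[list[float]], gene: int, patients: list[int]) -> float:
    return sum(F[gene][p] for p in patients) / len(patients)


def vote_ref(F: list[list[float]], genes: list[int], patients: list[int]) -> list[float]:
    return [sum(F[g][p] for g in genes) for p in patients]


def representatives_ref(votes: list[float], patient_ids: list[str], x: int) -> list[str]:
    order = sorted(range(len(patient_ids)), key=lambda i: (-votes[i], patient_ids[i]))
    return [patient_ids[i] for i in order[:x]]


def sscore_ref(F: list[list[float]], genes: list[int], patient: int,
               beta: dict[int, float]) -> float:
    return sum(F[g][patient] * beta[g] for g in genes)


def t_test_ref(scores: list[float]) -> tuple[float, float]:
    """One-sample two-sided t-test against 0 via the closed-form t CDF."""
    n = len(scores)
    mean = sum(scores) / n
    var = sum((s - mean) ** 2 for s in scores) / (n - 1)
    t = mean / math.sqrt(var / n)
    p = 2.0 * (1.0 - stdtr(n - 1, abs(t)))
    return t, p


def pipeline_ref(matrix: list[list[float]], gene_ids: list[str], sample_ids: list[str],
                 control: list[str], test: list[str], genes: list[str],
                 theta1: float, theta2: float, x: int,
                 pfsnet: bool = False) -> dict:
    """Full scoring pipeline for one subnetwork; returns every intermediate."""
    F = gfs_ref(matrix, theta1, theta2)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    sidx = {s: i for i, s in enumerate(sample_ids)}
    rows = [gidx[g] for g in genes]
    out: dict = {"F": F}
    beta_by_side = {}
    for side, pats in (("control", control), ("test", test)):
        cols = [sidx[p] for p in pats]
        votes = vote_ref(F, rows, cols)
        reps = pats if pfsnet or x >= len(pats) else representatives_ref(votes, pats, x)
        rep_cols = [sidx[p] for p in reps]
        beta = {g: beta_ref(F, gidx[g], rep_cols) for g in genes}
        beta_by_side[side] = beta
        out[side] = {"votes": votes, "representatives": list(reps), "beta": beta}
    everyone = control + test
    sps = []
    for p in everyone:
        ss_c = sscore_ref(F, rows, sidx[p], {gidx[g]: b for g, b in beta_by_side["control"].items()})
        ss_t = sscore_ref(F, rows, sidx[p], {gidx[g]: b for g, b in beta_by_side["test"].items()})
        sps.append(ss_t - ss_c)
    out["sps"] = dict(zip(everyone, sps))
    out["t"], out["p"] = t_test_ref(sps)
    return out
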