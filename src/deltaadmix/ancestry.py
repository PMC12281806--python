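"""Supervised ancestry-proportion estimation with fixed panel frequencies.

With reference allele frequencies p_kj held fixed, an individual's ancestry
vector q (a point on the K-simplex) maximises the binomial admixture
log-likelihood

    l(q) = sum_j [ g_j log(sum_k q_k p_kj) + (c_j - g_j) log(sum_k q_k (1 - p_kj)) ]

where g_j is the counted-allele dosage and c_j the ploidy (2, or 1 for the
hemizygous male X). The maximiser is found by EM over latent per-allele
ancestry assignments; each update is

    q_k <- q_k / C * sum_j [ g_j p_kj / (q.p_j) + (c_j - g_j)(1-p_kj) / (q.(1-p_j)) ]

with C = sum_j c_j over non-missing SNPs. The likelihood is concave in q, so
EM from the uniform start converges to the global maximum and l(q) is
non-decreasing at every iteration. Missing genotypes contribute nothing.

The cohort-level entry point batches all individuals of one chromosome scope
into matrix operations; results are identical to per-individual runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import MISSING, X_CHROM, GenotypeMatrix, PanelFrequencies


@dataclass
class AncestryVector:
    """One individual's estimated ancestry proportions for one SNP scope."""

    individual_id: str
    q: np.ndarray
    scope: str
    loglik: float
    n_iter: int
    converged: bool
    labels: list[str]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if (self.q < -1e-12).any() or abs(self.q.sum() - 1.0) > 1e-8:
            raise ValueError("q must lie on the simplex")


def _em_batch(
    G: np.ndarray,
    C: np.ndarray,
    P: np.ndarray,
    tol: float,
    max_iter: int,
    return_trace: bool = False,
):
    """Vectorised EM for a batch of individuals sharing one SNP set.

    G: (n, m) dosages with MISSING sentinel; C: (n, m) ploidy; P: (m, K)
    panel frequencies, pre-clipped away from 0/1. Returns (Q, loglik, n_iter,
    converged[, trace]).
    """
    n, m = G.shape
    K = P.shape[1]
    obs = G != MISSING
    if not obs.any(axis=1).all():
        raise ValueError("at least one individual has no non-missing genotype")
    if ((P <= 0) | (P >= 1)).any():
        raise ValueError("panel frequencies must be strictly inside (0, 1); clip first")

    Gf = np.where(obs, G, 0).astype(float)
    Cf = np.where(obs, C, 0).astype(float)
    Hf = Cf - Gf  # non-counted allele count
    total = Cf.sum(axis=1, keepdims=True)  # per-individual allele observations

    Q = np.full((n, K), 1.0 / K)
    Pc = 1.0 - P
    trace = []
    # rows converge independently (the update is row-separable), so each row
    # is frozen the moment its own max |dq| drops below tol; a batched run is
    # then bit-identical to per-individual runs
    active = np.ones(n, dtype=bool)
    n_iter_row = np.zeros(n, dtype=int)
    for it in range(1, max_iter + 1):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Qa = Q[idx]
        A = Qa @ P.T  # (n_active, m) mixed counted-allele freq
        B = Qa @ Pc.T
        if return_trace:
            trace.append(_loglik(Gf, Hf, Q @ P.T, Q @ Pc.T, obs))
        R = np.where(obs[idx], Gf[idx] / A, 0.0)
        S = np.where(obs[idx], Hf[idx] / B, 0.0)
        Qnew = Qa * ((R @ P) + (S @ Pc)) / total[idx]
        delta_rows = np.abs(Qnew - Qa).max(axis=1)
        Q[idx] = Qnew
        n_iter_row[idx] = it
        active[idx[delta_rows < tol]] = False
    converged_row = ~active
    A = Q @ P.T
    B = Q @ Pc.T
    loglik = _loglik_rows(Gf, Hf, A, B, obs)
    if return_trace:
        trace.append(float(loglik.sum()))
        return Q, loglik, n_iter_row, converged_row, np.asarray(trace)
    return Q, loglik, n_iter_row, converged_row


def _loglik_rows(Gf, Hf, A, B, obs) -> np.ndarray:
    terms = np.where(obs, Gf * np.log(A) + Hf * np.log(B), 0.0)
    return terms.sum(axis=1)


def _loglik(Gf, Hf, A, B, obs) -> float:
    return float(_loglik_rows(Gf, Hf, A, B, obs).sum())


def estimate_q_supervised(
    genotypes: np.ndarray,
    ploidy: np.ndarray,
    panel: PanelFrequencies,
    tol: float = 1e-6,
    max_iter: int = 2000,
    individual_id: str = "ind",
    scope: str = "custom",
) -> AncestryVector:
    """EM ancestry estimate for a single individual over an aligned SNP set."""
    g = np.asarray(genotypes).reshape(1, -1)
    c = np.broadcast_to(np.asarray(ploidy), g.shape).reshape(1, -1)
    if g.shape[1] != panel.n_snp:
        raise ValueError("genotypes and panel must cover the same SNPs")
    if panel.K == 1:
        # degenerate simplex: the only admissible q
        obs = g[0] != MISSING
        if not obs.any():
            raise ValueError("all genotypes missing")
        p = np.clip(panel.freqs[:, 0], 1e-12, 1 - 1e-12)
        gl = float(
            (g[0][obs] * np.log(p[obs])
             + (c[0][obs] - g[0][obs]) * np.log(1 - p[obs])).sum()
        )
        return AncestryVector(individual_id, np.array([1.0]), scope, gl, 0, True,
                              list(panel.labels))
    Q, ll, n_iter, conv = _em_batch(g, c, panel.freqs, tol, max_iter)
    return AncestryVector(
        individual_id=individual_id,
        q=Q[0],
        scope=scope,
        loglik=float(ll[0]),
        n_iter=int(n_iter[0]),
        converged=bool(conv[0]),
        labels=list(panel.labels),
    )


def _scope_label(chrom: str) -> str:
    return "X" if chrom == X_CHROM else f"auto:{chrom}"


def estimate_cohort_q(
    geno: GenotypeMatrix,
    panel: PanelFrequencies,
    scope: str,
    snp_idx: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> list[AncestryVector]:
    """Supervised estimates for every individual on one chromosome scope.

    ``scope`` is a chromosome name ('chr7', 'X') or 'genomewide'. An explicit
    ``snp_idx`` (e.g. a matched downsampled subset) overrides the chromosome
    selection but keeps the scope label. Results are independent of individual
    order (the batch update is row-separable).
    """
    if snp_idx is None:
        if scope == "genomewide":
            snp_idx = np.arange(geno.n_snp)
        else:
            snp_idx = geno.chrom_snp_indices(scope)
    snp_idx = np.asarray(snp_idx)
    if snp_idx.size == 0:
        raise ValueError(f"scope '{scope}' selects no SNPs")

    # panel rows aligned by snp_id
    panel_pos = {s: i for i, s in enumerate(panel.snp_ids)}
    try:
        rows = np.array([panel_pos[s] for s in geno.snps["snp_id"].iloc[snp_idx]])
    except KeyError as e:
        raise ValueError(f"SNP {e} missing from the panel") from e
    sub_panel = panel.subset(rows).clipped()

    G = geno.genotypes[:, snp_idx]
    C = geno.ploidy()[:, snp_idx]
    Q, ll, n_iter, conv = _em_batch(G, C, sub_panel.freqs, tol, max_iter)
    label = "genomewide" if scope == "genomewide" else _scope_label(scope)
    ids = geno.individuals["individual_id"].tolist()
    return [
        AncestryVector(ids[i], Q[i], label, float(ll[i]), int(n_iter[i]),
                       bool(conv[i]), list(panel.labels))
        for i in range(geno.n_ind)
    ]


def average_autosomal_q(
    per_chromosome: list[list[AncestryVector]],
) -> list[AncestryVector]:
    """Unweighted mean over per-chromosome runs, per individual ('auto:mean').

    Inputs are one list of AncestryVectors per chromosome run, each covering
    the same individuals (any order); means are matched on individual_id and
    renormalised onto the simplex.
    """
    if not per_chromosome:
        raise ValueError("no chromosome runs supplied")
    by_id: dict[str, list[AncestryVector]] = {}
    for run in per_chromosome:
        for av in run:
            by_id.setdefault(av.individual_id, []).append(av)
    n_runs = len(per_chromosome)
    out = []
    for iid, vecs in by_id.items():
        if len(vecs) != n_runs:
            raise ValueError(f"individual {iid} missing from some runs")
        K = len(vecs[0].q)
        labels = vecs[0].labels
        for v in vecs:
            if len(v.q) != K or v.labels != labels:
                raise ValueError("mismatched K or ancestry labels across runs")
        q = np.mean([v.q for v in vecs], axis=0)
        q = q / q.sum()
        out.append(
            AncestryVector(
                individual_id=iid,
                q=q,
                scope="auto:mean",
                loglik=float(np.sum([v.loglik for v in vecs])),
                n_iter=max(v.n_iter for v in vecs),
                converged=all(v.converged for v in vecs),
                labels=list(labels),
            )
        )
    return out


def q_matrix(vectors: list[AncestryVector]) -> tuple[list[str], np.ndarray]:
    """Stack AncestryVectors into (ids, (n, K) array), preserving order."""
    ids = [v.individual_id for v in vectors]
    return ids, np.vstack([v.q for v in vectors])


def vectors_to_frame(vectors: list[AncestryVector]):
    """Tabular form: individual_id, scope, q_<label>..., loglik, converged."""
    import pandas as pd

    rows = []
    for v in vectors:
        row = {"individual_id": v.individual_id, "scope": v.scope}
        for lab, val in zip(v.labels, v.q):
            row[f"q_{lab}"] = val
        row["loglik"] = v.loglik
        row["n_iter"] = v.n_iter
        row["converged"] = v.converged
        rows.append(row)
    return pd.DataFrame(rows)
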