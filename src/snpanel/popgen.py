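"""Population-genetic analyses: p-distance, NJ tree, PCA, admixture EM.

The pairwise distance follows the fingerprinting convention for unordered
diploid genotypes at a biallelic locus: identical homozygotes score 0,
opposite homozygotes score 1, and any comparison involving a heterozygote
(including het vs het) scores 0.5.  The distance between two accessions is
the mean score over loci called in both; loci missing in either accession
are excluded and the averaging length L is the compared-locus count.

The admixture model treats each individual's two allele copies at locus l
as draws from a mixture over K ancestral populations with proportions q_i
and population alt-allele frequencies f_k; the binomial log-likelihood
sum_il [g log(pi) + (2 - g) log(1 - pi)], pi = sum_k q_ik f_kl, is maximised
by EM with closed-form M-steps.  Cross-validation over K masks a random
subset of genotypes, refits, and scores squared prediction error on the
masked entries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import DosageMatrix, GenotypeMatrix, MISSING


class UndefinedDistanceError(ValueError):
    """No loci are called in both accessions of a pair."""


class ParameterError(ValueError):
    """Invalid analysis parameter."""


class DegenerateInputError(ValueError):
    """Input carries no usable variation (e.g. constant dosage matrix)."""


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

def pair_distance(calls_i: np.ndarray, calls_j: np.ndarray) -> tuple[float, int]:
    """Mean per-locus genotype distance over pairwise-complete loci.

    ``calls_*`` are dosage-coded vectors over the same locus list.  Returns
    ``(distance, n_compared)``.
    """
    x = np.asarray(calls_i)
    y = np.asarray(calls_j)
    if x.shape != y.shape:
        raise ParameterError("call vectors must cover the same loci")
    ok = (x != MISSING) & (y != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise UndefinedDistanceError("no loci compared in both accessions")
    xi, yi = x[ok].astype(float), y[ok].astype(float)
    score = np.abs(xi - yi) / 2.0
    score[(xi == 1) | (yi == 1)] = 0.5  # any heterozygote involved scores 1/2
    return float(score.mean()), n


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair compared-locus counts."""

    accessions: list[str]
    values: np.ndarray          # N x N in [0, 1], zero diagonal
    n_compared: np.ndarray      # N x N integer counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accessions, columns=self.accessions)

    @property
    def min_overlap(self) -> int:
        n = len(self.accessions)
        if n < 2:
            return 0
        off = ~np.eye(n, dtype=bool)
        return int(self.n_compared[off].min())


def distance_matrix(gm: GenotypeMatrix) -> DistanceMatrix:
    """All-pairs p-distances for a genotype matrix."""
    if gm.n_accessions < 2:
        raise ParameterError("need at least 2 accessions")
    n = gm.n_accessions
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    counts[np.diag_indices(n)] = gm.n_loci
    for i in range(n):
        for j in range(i + 1, n):
            d, c = pair_distance(gm.dosage[i], gm.dosage[j])
            values[i, j] = values[j, i] = d
            counts[i, j] = counts[j, i] = c
    return DistanceMatrix(list(gm.accessions), values, counts)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an (unrooted, stored rooted) NJ tree."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def to_newick(self) -> str:
        return f"{self._newick_part()};"

    def _newick_part(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick_part() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.10g}"

    def path_length_matrix(self) -> pd.DataFrame:
        """Leaf-to-leaf patristic distances (for additivity checks)."""
        dist: dict[str, dict[str, float]] = {}

        def down_with_edges(node: TreeNode) -> dict[str, float]:
            if node.is_leaf():
                return {node.name: node.length}
            sub = [down_with_edges(c) for c in node.children]
            for a, b in itertools.combinations(range(len(sub)), 2):
                for la, da in sub[a].items():
                    for lb, db in sub[b].items():
                        dist.setdefault(la, {})[lb] = da + db
                        dist.setdefault(lb, {})[la] = da + db
            return {leaf: d + node.length for s in sub for leaf, d in s.items()}

        down_with_edges(self)
        names = sorted({leaf.name for leaf in self.leaves()})
        mat = pd.DataFrame(0.0, index=names, columns=names)
        for a in names:
            for b in names:
                if a != b:
                    mat.loc[a, b] = dist[a][b]
        return mat


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    The pair minimising the Q-criterion is joined at each step (ties broken
    by the lexicographically smallest node-name pair).  Negative branch
    lengths are clamped to zero with the deficit moved to the sister
    branch, preserving the path length between the joined nodes.
    """
    n = len(dm.accessions)
    if n < 3:
        raise ParameterError("neighbor joining needs at least 3 accessions")
    nodes: dict[str, TreeNode] = {a: TreeNode(name=a) for a in dm.accessions}
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(dm.accessions):
        for j, b in enumerate(dm.accessions):
            if i < j:
                d[(a, b)] = d[(b, a)] = float(dm.values[i, j])
    active = sorted(nodes)
    counter = 0
    while len(active) > 2:
        r = len(active)
        totals = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best: tuple[float, str, str] | None = None
        for a, b in itertools.combinations(active, 2):
            q = (r - 2) * d[(a, b)] - totals[a] - totals[b]
            key = (q, *sorted((a, b)))
            if best is None or key < best:
                best = key
        _, a, b = best  # type: ignore[misc]
        dij = d[(a, b)]
        la = dij / 2.0 + (totals[a] - totals[b]) / (2.0 * (r - 2))
        lb = dij - la
        if la < 0:
            la, lb = 0.0, dij
        elif lb < 0:
            la, lb = dij, 0.0
        counter += 1
        parent_name = f"__nj{counter}"
        na, nb = nodes[a], nodes[b]
        na.length, nb.length = la, lb
        parent = TreeNode(name=parent_name, children=[na, nb])
        nodes[parent_name] = parent
        for c in active:
            if c in (a, b):
                continue
            d[(parent_name, c)] = d[(c, parent_name)] = max(
                0.0, (d[(a, c)] + d[(b, c)] - dij) / 2.0
            )
        active = sorted(set(active) - {a, b} | {parent_name})
    # final join: attach one remaining node to the other with the full distance
    a, b = active
    root, other = (a, b) if not nodes[a].is_leaf() else (b, a)
    nodes[other].length = d[(a, b)]
    nodes[root].children.append(nodes[other])
    nodes[root].name = None
    nodes[root].length = 0.0
    return nodes[root]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    accessions: list[str]
    scores: np.ndarray                  # N x n_components
    explained_variance_pct: np.ndarray  # per returned component
    all_explained_pct: np.ndarray       # over every non-trivial component


def pca(dm: DosageMatrix, n_components: int = 2) -> PcaResult:
    """PCA of mean-imputed, column-centered dosages.

    Missing dosages are imputed with the locus mean before centering
    (configurable complete-case analysis is a matter of subsetting loci
    beforehand).  Explained percentages are eigenvalue shares of the sample
    covariance and sum to 100 over all components.
    """
    X = dm.values.copy()
    if X.shape[0] < 2:
        raise ParameterError("need at least 2 accessions")
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X -= X.mean(axis=0)
    if not np.any(X):
        raise DegenerateInputError("constant dosage matrix has no principal axes")
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2 / (X.shape[0] - 1)
    pct = 100.0 * eigvals / eigvals.sum()
    k = min(n_components, len(s))
    return PcaResult(
        accessions=list(dm.accessions),
        scores=u[:, :k] * s[:k],
        explained_variance_pct=pct[:k],
        all_explained_pct=pct,
    )


# ---------------------------------------------------------------------------
# Admixture EM
# ---------------------------------------------------------------------------

_EPS = 1e-6


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray                # N x K, rows sum to 1
    F: np.ndarray                # K x L in [eps, 1 - eps]
    loglik: float
    loglik_trace: list[float]
    cv_error: float | None = None


def _loglik(g: np.ndarray, obs: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    pi = np.clip(Q @ F, _EPS, 1 - _EPS)
    with np.errstate(invalid="ignore"):
        ll = g * np.log(pi) + (2.0 - g) * np.log1p(-pi)
    return float(np.nansum(np.where(obs, ll, 0.0)))


def admixture_fit(
    dm: DosageMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-5,
    n_restarts: int = 1,
) -> AdmixtureFit:
    """Fit the K-population admixture model by EM.

    E-step: expected alt/ref allele copies attributed to each population;
    M-step: closed-form updates of Q rows and F entries.  Parameters are
    clipped to [1e-6, 1 - 1e-6]; iteration stops when the log-likelihood
    improves by less than ``tol`` or at ``max_iter``.  ``n_restarts``
    independent initialisations (seeded from ``seed``) are run and the best
    log-likelihood kept.
    """
    G = dm.values
    N, L = G.shape
    if K < 1:
        raise ParameterError("K must be >= 1")
    if K > N:
        raise ParameterError(f"K={K} exceeds the number of accessions N={N}")
    obs = ~np.isnan(G)
    g = np.where(obs, G, 0.0)

    if K == 1:
        with np.errstate(invalid="ignore"):
            f = np.nansum(G, axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1))
        F = np.clip(f[None, :], _EPS, 1 - _EPS)
        Q = np.ones((N, 1))
        ll = _loglik(g, obs, Q, F)
        return AdmixtureFit(K=1, Q=Q, F=F, loglik=ll, loglik_trace=[ll])

    best: AdmixtureFit | None = None
    root = np.random.default_rng(seed)
    for restart in range(max(1, n_restarts)):
        rng = np.random.default_rng(root.integers(2**31 - 1))
        Q = rng.dirichlet(np.ones(K), size=N)
        F = np.clip(rng.uniform(0.05, 0.95, size=(K, L)), _EPS, 1 - _EPS)
        trace = [_loglik(g, obs, Q, F)]
        for _ in range(max_iter):
            pi = np.clip(Q @ F, _EPS, 1 - _EPS)
            # responsibilities: expected allele copies per population
            #   alt copies: g * q_k f_k / pi ; ref copies: (2-g) q_k (1-f_k)/(1-pi)
            A = np.empty((K, N, L))
            B = np.empty((K, N, L))
            for k in range(K):
                A[k] = np.where(obs, g * (Q[:, [k]] * F[[k], :]) / pi, 0.0)
                B[k] = np.where(obs, (2.0 - g) * (Q[:, [k]] * (1.0 - F[[k], :])) / (1.0 - pi), 0.0)
            AB = A + B
            denom = AB.sum(axis=0).sum(axis=1, keepdims=True)  # 2 * loci observed per i
            Q = AB.sum(axis=2).T / np.maximum(denom, _EPS)
            Q = np.clip(Q, _EPS, None)
            Q /= Q.sum(axis=1, keepdims=True)
            F = np.clip(A.sum(axis=1) / np.maximum(AB.sum(axis=1), _EPS), _EPS, 1 - _EPS)
            trace.append(_loglik(g, obs, Q, F))
            if trace[-1] - trace[-2] < tol:
                break
        fit = AdmixtureFit(K=K, Q=Q, F=F, loglik=trace[-1], loglik_trace=trace)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best  # type: ignore[return-value]


def align_q_to_truth(Q: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Permute columns of Q to best match a reference (label switching)."""
    K = Q.shape[1]
    best_perm = min(
        itertools.permutations(range(K)),
        key=lambda perm: np.abs(Q[:, list(perm)] - Q_true).mean(),
    )
    return Q[:, list(best_perm)]


def cv_error_over_k(
    dm: DosageMatrix,
    k_values: list[int],
    fold_masking_rate: float = 0.1,
    seed: int = 0,
    n_folds: int = 3,
    **fit_kwargs,
) -> dict[int, float]:
    """Masked-entry cross-validation error per K.

    For each fold, a random ``fold_masking_rate`` share of the non-missing
    genotype entries is hidden, the model is fit on the rest, and the error
    ``mean (g - 2 pi_hat)^2 / 2`` is scored on the hidden entries; folds are
    averaged.  The K with the lowest error is the supported cluster number.
    """
    if not 0.0 < fold_masking_rate < 0.5:
        raise ParameterError("fold_masking_rate must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(~np.isnan(dm.values))
    errors: dict[int, list[float]] = {k: [] for k in k_values}
    for fold in range(n_folds):
        mask = obs_idx[rng.random(len(obs_idx)) < fold_masking_rate]
        masked = dm.values.copy()
        masked[mask[:, 0], mask[:, 1]] = np.nan
        masked_dm = DosageMatrix(dm.accessions, dm.markers, masked)
        for k in k_values:
            fit = admixture_fit(masked_dm, k, seed=int(rng.integers(2**31 - 1)), **fit_kwargs)
            pi = np.clip(fit.Q @ fit.F, _EPS, 1 - _EPS)
            g_true = dm.values[mask[:, 0], mask[:, 1]]
            pred = 2.0 * pi[mask[:, 0], mask[:, 1]]
            errors[k].append(float(np.mean((g_true - pred) ** 2) / 2.0))
    return {k: float(np.mean(v)) for k, v in errors.items()}
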