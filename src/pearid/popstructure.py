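"""Population-structure analyses: distance AMOVA, PCoA and Evanno ΔK.

The two-level analysis of molecular variance follows the classical
distance-based decomposition.  With N accessions in G groups and squared
pairwise distances d2:

    SS_total  = (1/N) * sum_{i<j} d2_ij
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d2_ij
    SS_among  = SS_total - SS_within
    sigma2_w  = SS_within / (N - G)
    sigma2_a  = (SS_among / (G - 1) - sigma2_w) / n0,
                n0 = (N - sum_g n_g^2 / N) / (G - 1)
    Phi_ST    = sigma2_a / (sigma2_a + sigma2_w)

The permutation p-value shuffles accessions freely among groups (preserving
group sizes): p = (#{Phi_perm >= Phi_obs} + 1) / (n_perm + 1).

PCoA is the metric ordination of a distance matrix: Gower double-centering of
-d^2/2 followed by eigendecomposition; axes with negative eigenvalues are
reported but dropped from the coordinates, and axis percentages are taken
relative to the sum of positive eigenvalues.

Evanno's ΔK locates the strongest curvature of the clustering log-likelihood
L(K) over replicate runs: per replicate r, L'_r(K) = L_r(K) - L_r(K-1) and
|L''_r(K)| = |L'_r(K+1) - L'_r(K)|; ΔK = mean_r |L''_r(K)| / sd_r(L(K)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .identity import BandMatrix, SimilarityMatrix
from .model import ModelError, StructureRunTable

DistanceKind = Literal["one_minus_gs", "band_mismatch"]


def distance_matrix(
    source: SimilarityMatrix | BandMatrix, kind: DistanceKind = "band_mismatch"
) -> np.ndarray:
    """Squared pairwise distances for AMOVA.

    ``"one_minus_gs"`` takes 1 - GS from a similarity matrix;
    ``"band_mismatch"`` counts mismatching presence/absence columns over
    mutually scored columns (the squared Euclidean distance on binary bands).
    Pairs with no mutually scored column are NaN (flagged undefined).
    """
    if kind == "one_minus_gs":
        if not isinstance(source, SimilarityMatrix):
            raise ModelError("one_minus_gs needs a SimilarityMatrix")
        d2 = 1.0 - source.values
    elif kind == "band_mismatch":
        if not isinstance(source, BandMatrix):
            raise ModelError("band_mismatch needs a BandMatrix")
        p = source.presence.astype(np.int32) * source.valid
        q = (1 - source.presence.astype(np.int32)) * source.valid
        shared = source.valid.astype(np.int32) @ source.valid.astype(np.int32).T
        matches = p @ p.T + q @ q.T
        d2 = np.where(shared > 0, (shared - matches).astype(float), np.nan)
    else:
        raise ModelError(f"unknown distance kind {kind!r}")
    np.fill_diagonal(d2, 0.0)
    return d2


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ss_total: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    seed: int | None
    group_sizes: dict[str, int] = field(default_factory=dict)


def _ss_within(d2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def _phi(d2: np.ndarray, labels: np.ndarray, n: int, n_groups: int, n0: float,
         ss_total: float) -> tuple[float, float, float, float, float]:
    ss_within = _ss_within(d2, labels)
    ss_among = ss_total - ss_within
    sigma_w = ss_within / (n - n_groups)
    sigma_a = (ss_among / (n_groups - 1) - sigma_w) / n0
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom != 0 else float("nan")
    return phi, ss_within, ss_among, sigma_a, sigma_w


def amova(
    d2: np.ndarray,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AmovaResult:
    """Two-level distance-based AMOVA with a free permutation test.

    ``d2`` must be a symmetric matrix of squared distances with zero diagonal
    and no undefined (NaN) pairs; ``groups`` assigns each accession a group
    label.  Either ``seed`` or an explicit ``rng`` drives the permutations.
    """
    d2 = np.asarray(d2, dtype=float)
    n = d2.shape[0]
    if d2.shape != (n, n) or n != len(groups):
        raise ModelError("distance matrix and group labels have mismatched sizes")
    if np.isnan(d2).any():
        raise ModelError(
            "undefined pairwise distances; impute or drop the affected accessions"
        )
    if not np.allclose(d2, d2.T):
        raise ModelError("distance matrix must be symmetric")
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    n_groups = len(uniq)
    if n_groups < 2:
        raise ModelError("AMOVA needs >= 2 groups")
    if n < 3:
        raise ModelError("AMOVA needs >= 3 accessions")

    ss_total = d2.sum() / (2.0 * n)
    n0 = (n - float((counts**2).sum()) / n) / (n_groups - 1)
    phi_obs, ss_within, ss_among, sigma_a, sigma_w = _phi(
        d2, labels, n, n_groups, n0, ss_total
    )
    if sigma_a < 0:
        warnings.warn(
            "negative among-group variance component reported as computed",
            stacklevel=2,
        )
    denom = sigma_a + sigma_w
    pct_among = 100.0 * sigma_a / denom if denom != 0 else float("nan")
    pct_within = 100.0 * sigma_w / denom if denom != 0 else float("nan")

    if rng is None:
        rng = np.random.default_rng(seed)
    hits = 0
    valid_perms = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        phi_perm = _phi(d2, perm, n, n_groups, n0, ss_total)[0]
        if np.isnan(phi_perm):
            continue
        valid_perms += 1
        if phi_perm >= phi_obs - 1e-12:
            hits += 1
    p_value = (hits + 1) / (valid_perms + 1) if not np.isnan(phi_obs) else float("nan")

    return AmovaResult(
        df_among=n_groups - 1,
        df_within=n - n_groups,
        ss_among=ss_among,
        ss_within=ss_within,
        ss_total=ss_total,
        sigma2_among=sigma_a,
        sigma2_within=sigma_w,
        pct_among=pct_among,
        pct_within=pct_within,
        phi_st=phi_obs,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
        group_sizes={str(u): int(c) for u, c in zip(uniq, counts)},
    )


@dataclass
class PcoaResult:
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    coordinates: np.ndarray  # (n, k) for the k positive-eigenvalue axes
    pct_variance: np.ndarray  # per retained axis, relative to positive sum
    n_negative: int


def pcoa(d: np.ndarray, *, tol: float = 1e-10) -> PcoaResult:
    """Principal coordinate analysis via Gower double-centering.

    ``d`` is a symmetric zero-diagonal matrix of distances (not squared).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if np.isnan(d).any():
        raise ModelError("undefined distances in PCoA input")
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ModelError("PCoA needs a symmetric distance matrix")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    cutoff = tol * max(abs(eigval[0]), 1.0)
    positive = eigval > cutoff
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    pos_sum = eigval[positive].sum()
    pct = 100.0 * eigval[positive] / pos_sum if pos_sum > 0 else np.zeros(0)
    return PcoaResult(
        eigenvalues=eigval,
        coordinates=coords,
        pct_variance=pct,
        n_negative=int((eigval < -cutoff).sum()),
    )


@dataclass
class EvannoResult:
    ks: list[int]
    mean_lnp: np.ndarray
    sd_lnp: np.ndarray
    l_prime: np.ndarray  # mean over replicates of L'(K); NaN at the first K
    l_doubleprime_abs: np.ndarray  # mean over replicates of |L''(K)|; NaN at edges
    delta_k: np.ndarray  # NaN at edges and where sd = 0
    optimal_k: int
    local_maxima: list[int]

    def delta_k_of(self, k: int) -> float:
        return float(self.delta_k[self.ks.index(k)])


def evanno_delta_k(runs: StructureRunTable) -> EvannoResult:
    """Evanno ΔK over a replicate clustering-run table.

    Requires a contiguous K range with >= 2 replicates per K.  ΔK is defined
    only for interior K with positive replicate SD; local maxima of ΔK over
    the interior Ks are reported alongside the global optimum.
    """
    mat, ks = runs.lnp_matrix()  # (replicates, K)
    mean_lnp = mat.mean(axis=0)
    sd_lnp = mat.std(axis=0, ddof=1)
    n_k = len(ks)
    l_prime_rep = np.diff(mat, axis=1)  # L'_r(K) for ks[1:]
    l_pp_rep = np.abs(np.diff(l_prime_rep, axis=1))  # |L''_r(K)| for ks[1:-1]

    l_prime = np.full(n_k, np.nan)
    l_prime[1:] = l_prime_rep.mean(axis=0)
    l_pp = np.full(n_k, np.nan)
    l_pp[1:-1] = l_pp_rep.mean(axis=0)

    delta_k = np.full(n_k, np.nan)
    for j in range(1, n_k - 1):
        if sd_lnp[j] > 0:
            delta_k[j] = l_pp[j] / sd_lnp[j]
        else:
            warnings.warn(f"sd(L) = 0 at K={ks[j]}; ΔK undefined there", stacklevel=2)

    finite = np.where(np.isfinite(delta_k))[0]
    if finite.size == 0:
        raise ModelError("ΔK undefined everywhere (zero replicate variance?)")
    optimal = ks[int(finite[np.argmax(delta_k[finite])])]
    local_maxima = []
    for j in finite:
        left = delta_k[j - 1] if j - 1 >= 0 and np.isfinite(delta_k[j - 1]) else -np.inf
        right = delta_k[j + 1] if j + 1 < n_k and np.isfinite(delta_k[j + 1]) else -np.inf
        if delta_k[j] >= left and delta_k[j] >= right:
            local_maxima.append(ks[j])
    return EvannoResult(
        ks=ks,
        mean_lnp=mean_lnp,
        sd_lnp=sd_lnp,
        l_prime=l_prime,
        l_doubleprime_abs=l_pp,
        delta_k=delta_k,
        optimal_k=optimal,
        local_maxima=local_maxima,
    )
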