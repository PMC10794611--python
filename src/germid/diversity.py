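"""Population differentiation and multivariate diversity analyses.

One squared-Euclidean genotype distance kernel (pairwise-complete over
shared loci, rescaled for missingness) feeds AMOVA, PCoA and the
neighbor-joining tree; differentiation between labelled populations is
measured by the Weir–Cockerham theta estimator of F_ST with permutation
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "FstMatrix",
    "AmovaTable",
    "PcoaResult",
    "PhyloTree",
    "genetic_distance",
    "weir_cockerham_theta",
    "pairwise_fst",
    "amova",
    "pcoa",
    "nj_tree",
]


@dataclass
class DistanceMatrix:
    """Squared genetic distances between samples (or populations)."""

    sample_ids: list
    values: np.ndarray           # (n, n) symmetric, zero diagonal
    undefined: list = field(default_factory=list)  # pairs with no shared loci

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class FstMatrix:
    populations: list
    theta: np.ndarray       # pairwise Weir-Cockerham estimates
    p_values: np.ndarray    # permutation p-values, NaN on the diagonal
    n_permutations: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=self.populations, columns=self.populations)


@dataclass
class AmovaTable:
    table: pd.DataFrame          # rows: among/within/total
    per_population: pd.DataFrame  # within-population SS breakdown
    phi_st: float
    p_value: float
    n_permutations: int


@dataclass
class PcoaResult:
    eigenvalues: np.ndarray        # all eigenvalues, descending
    coordinates: np.ndarray        # (n, n_axes) for positive-eigenvalue axes
    percent_variance: np.ndarray   # per retained axis, over positive eigenvalues
    sample_ids: list


@dataclass
class PhyloTree:
    """Unrooted tree with non-negative branch lengths, Newick-serializable."""

    newick: str
    leaf_ids: list

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick + "\n")


def genetic_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Codominant squared-Euclidean genotype distance.

    ``d2[i, j] = sum over shared loci (g_i - g_j)^2``, rescaled by
    ``total_loci / shared_loci`` so samples with missing data are not
    artificially close.  Pairs sharing no locus are flagged undefined.
    """
    if gm.n_samples < 2:
        raise ValueError("need >=2 samples")
    obs = (~gm.missing).astype(np.float64)
    g = np.where(gm.missing, 0.0, gm.calls.astype(np.float64))
    g2 = g**2
    shared = obs @ obs.T
    # sum over shared loci of gi^2 + gj^2 - 2 gi gj, masked both ways
    raw = (g2 @ obs.T) + (obs @ g2.T) - 2.0 * (g @ g.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = raw * (gm.n_loci / shared)
    undefined = []
    if (shared == 0).any():
        i, j = np.nonzero(np.triu(shared == 0, k=1))
        undefined = [(gm.sample_ids[a], gm.sample_ids[b]) for a, b in zip(i, j)]
        d2[shared == 0] = 0.0
    d2 = np.maximum(d2, 0.0)
    np.fill_diagonal(d2, 0.0)
    d2 = 0.5 * (d2 + d2.T)
    return DistanceMatrix(list(gm.sample_ids), d2, undefined)


def _wc_components(calls, missing, labels):
    """Per-locus Weir-Cockerham variance components (a, b, c) summed arrays."""
    pops = pd.unique(labels)
    r = len(pops)
    L = calls.shape[1]
    n = np.zeros((r, L))      # called samples per pop per locus
    p = np.zeros((r, L))      # alt frequency
    h = np.zeros((r, L))      # observed het fraction
    for k, pop in enumerate(pops):
        rows = labels == pop
        obs = ~missing[rows]
        n[k] = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(missing[rows], 0, calls[rows]).sum(axis=0) / (2.0 * n[k])
            h[k] = ((calls[rows] == 1) & obs).sum(axis=0) / n[k]
    usable = (n >= 1).all(axis=0)
    n, p, h = n[:, usable], p[:, usable], h[:, usable]
    nbar = n.mean(axis=0)
    nsum = n.sum(axis=0)
    nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1)
    pbar = (n * p).sum(axis=0) / nsum
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / nsum
    pq = pbar * (1.0 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pq - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pq - s2 * (r - 1) / r - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
    c = hbar / 2.0
    good = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a[good], b[good], c[good]


def weir_cockerham_theta(gm: GenotypeMatrix, pops) -> float:
    """Multi-locus Weir-Cockerham theta (ratio of summed variance components)."""
    labels = np.asarray(list(pops))
    a, b, c = _wc_components(gm.calls, gm.missing, labels)
    denom = (a + b + c).sum()
    return float(a.sum() / denom) if denom != 0 else 0.0


def pairwise_fst(
    gm: GenotypeMatrix, pops, n_perm: int = 999, seed: int = 0
) -> FstMatrix:
    """Pairwise Weir-Cockerham theta with label-permutation significance.

    ``p = (#{permuted theta >= observed} + 1) / (n_perm + 1)``.
    """
    labels = np.asarray(list(pops))
    if len(labels) != gm.n_samples:
        raise ValueError("pops must label every sample")
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise ValueError("need >=2 populations")
    sizes = {p: int((labels == p).sum()) for p in names}
    small = [p for p, s in sizes.items() if s < 2]
    if small:
        raise ValueError(f"populations of size <2: {small}")
    rng = np.random.default_rng(seed)
    K = len(names)
    theta = np.zeros((K, K))
    pvals = np.full((K, K), np.nan)
    for i in range(K):
        for j in range(i + 1, K):
            rows = np.isin(labels, (names[i], names[j]))
            sub = gm.subset(samples=np.flatnonzero(rows))
            lab = labels[rows]
            obs = weir_cockerham_theta(sub, lab)
            theta[i, j] = theta[j, i] = obs
            if n_perm > 0:
                hits = 0
                for _ in range(n_perm):
                    hits += weir_cockerham_theta(sub, rng.permutation(lab)) >= obs
                p = (hits + 1) / (n_perm + 1)
                pvals[i, j] = pvals[j, i] = p
    return FstMatrix(names, theta, pvals, n_perm)


def _amova_ss(d2: np.ndarray, labels: np.ndarray):
    N = d2.shape[0]
    iu = np.triu_indices(N, k=1)
    ss_total = d2[iu].sum() / N
    ss_within = 0.0
    for pop in pd.unique(labels):
        rows = np.flatnonzero(labels == pop)
        if len(rows) > 1:
            block = d2[np.ix_(rows, rows)]
            ss_within += block[np.triu_indices(len(rows), k=1)].sum() / len(rows)
    return ss_total, ss_within, ss_total - ss_within


def amova(dm: DistanceMatrix, pops, n_perm: int = 999, seed: int = 0) -> AmovaTable:
    """Analysis of molecular variance on a squared-distance matrix.

    Partitions the total sum of squared distances into among- and
    within-population components; the among-population variance fraction
    (Phi_ST) is tested by permuting population labels.
    """
    labels = np.asarray(list(pops))
    if len(labels) != len(dm.sample_ids):
        raise ValueError("every sample must carry a population label")
    if dm.undefined:
        raise ValueError("distance matrix has undefined pairs")
    names = pd.unique(labels)
    K = len(names)
    if K < 2:
        raise ValueError("need >=2 populations")
    N = len(labels)
    nk = np.array([(labels == p).sum() for p in names], dtype=float)
    d2 = dm.values

    def decompose(lab):
        ss_t, ss_w, ss_a = _amova_ss(d2, lab)
        df_a, df_w = K - 1, N - K
        ms_a, ms_w = ss_a / df_a, ss_w / df_w
        sizes = np.array([(lab == p).sum() for p in pd.unique(lab)], dtype=float)
        n0 = (N - (sizes**2).sum() / N) / (K - 1)
        var_w = ms_w
        var_a = (ms_a - ms_w) / n0
        return ss_t, ss_w, ss_a, ms_a, ms_w, var_a, var_w

    ss_t, ss_w, ss_a, ms_a, ms_w, var_a, var_w = decompose(labels)
    var_a_f = max(var_a, 0.0)
    total_var = var_a_f + var_w
    phi = var_a_f / total_var if total_var > 0 else 0.0
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        *_, pa, pw = decompose(rng.permutation(labels))
        pa = max(pa, 0.0)
        pphi = pa / (pa + pw) if (pa + pw) > 0 else 0.0
        hits += pphi >= phi
    p_value = (hits + 1) / (n_perm + 1)

    pct_a = 100.0 * var_a_f / total_var if total_var > 0 else 0.0
    table = pd.DataFrame(
        {
            "df": [K - 1, N - K, N - 1],
            "SS": [ss_a, ss_w, ss_t],
            "MS": [ms_a, ms_w, np.nan],
            "est_var": [var_a_f, var_w, var_a_f + var_w],
            "percent": [pct_a, 100.0 - pct_a, 100.0],
        },
        index=["among_populations", "within_populations", "total"],
    )
    rows = []
    for pop, size in zip(names, nk):
        idx = np.flatnonzero(labels == pop)
        block = d2[np.ix_(idx, idx)]
        ss = block[np.triu_indices(len(idx), k=1)].sum() / size if size > 1 else 0.0
        df = size - 1
        rows.append({"population": pop, "n": int(size), "df": int(df),
                     "SS": ss, "MS": ss / df if df > 0 else np.nan})
    return AmovaTable(table, pd.DataFrame(rows), phi, p_value, n_perm)


def pcoa(dm: DistanceMatrix, n_axes: int = None) -> PcoaResult:
    """Principal coordinates analysis by Gower double-centering.

    Centers ``-d2 / 2``, eigendecomposes, and returns coordinates
    (eigenvectors scaled by sqrt eigenvalue) for positive-eigenvalue
    axes.  Negative eigenvalues are reported but excluded from the
    percent-variance denominator.
    """
    if dm.undefined:
        raise ValueError("distance matrix has undefined pairs")
    d2 = dm.values
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = 0.5 * (b + b.T)
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10 * max(abs(vals[0]), 1.0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    pct = 100.0 * vals[pos] / vals[pos].sum()
    if n_axes is not None:
        coords, pct = coords[:, :n_axes], pct[:n_axes]
    return PcoaResult(vals, coords, pct, list(dm.sample_ids))


def _min_leaf(node_leaves):
    return min(node_leaves)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree (Saitou-Nei agglomeration).

    Ties in the Q criterion are broken toward the lexicographically
    lowest leaf-id pair; negative branch lengths are clamped to zero
    with the deficit moved to the sister branch so path lengths are
    preserved.  Exact on additive distance matrices.
    """
    if dm.undefined:
        raise ValueError("distance matrix has undefined pairs")
    ids = list(dm.sample_ids)
    if len(ids) < 3:
        raise ValueError("need >=3 leaves")
    d = dm.values.astype(float).copy()
    # node bookkeeping: newick fragment and smallest contained leaf id
    nodes = [(str(s), str(s)) for s in ids]
    active = list(range(len(ids)))

    def clamp(li, lj):
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-9))
        cand = [(i, j) for i, j in cand if i < j]
        i, j = min(
            cand,
            key=lambda ij: tuple(
                sorted((nodes[active[ij[0]]][1], nodes[active[ij[1]]][1]))
            ),
        )
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        new_frag = f"({nodes[ai][0]}:{li:.10g},{nodes[aj][0]}:{lj:.10g})"
        new_min = min(nodes[ai][1], nodes[aj][1])
        # distances from the new node to the remaining actives
        dk = 0.5 * (sub[i, :] + sub[j, :] - dij)
        new_index = len(nodes)
        nodes.append((new_frag, new_min))
        d = np.pad(d, ((0, 1), (0, 1)))
        for pos, ak in enumerate(active):
            d[new_index, ak] = d[ak, new_index] = dk[pos]
        d[new_index, new_index] = 0.0
        active = [a for a in active if a not in (ai, aj)] + [new_index]

    a, b = active
    lab = d[a, b]
    half1, half2 = clamp(lab / 2.0, lab / 2.0)
    newick = f"({nodes[a][0]}:{half1:.10g},{nodes[b][0]}:{half2:.10g});"
    return PhyloTree(newick, [str(s) for s in ids])
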