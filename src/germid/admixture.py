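"""Model-based admixture clustering and supervised species assignment.

A Gibbs sampler for the classic admixture model: each of the two allele
copies of individual ``i`` at locus ``l`` originates from a latent
cluster ``z``; clusters carry independent allele frequencies ``P`` with
a flat Beta(1, 1) prior, and individuals carry ancestry proportions
``Q ~ Dirichlet(alpha)``.  The sweep alternates

    z  ~  Categorical( Q[i, k] * P[k, l]^a * (1 - P[k, l])^(1 - a) )
    P  ~  Beta(1 + alt copies, 1 + ref copies)          per cluster/locus
    Q  ~  Dirichlet(alpha + copy counts)                per individual

Reference individuals with fixed labels have every allele copy pinned
to their cluster (supervised mode), which turns the sampler into an
assignment test for query individuals.

Model selection across K uses the Evanno second-difference statistic on
the across-run distribution of mean data log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .genotype_io import GenotypeMatrix, PassportTable, concat_samples

__all__ = [
    "AdmixtureFit",
    "RunEnsemble",
    "AssignmentResult",
    "ClusterNode",
    "fit_admixture",
    "align_runs",
    "evanno_delta_k",
    "hierarchical_structure",
    "select_core_members",
    "simulate_reference",
    "assign_unknowns",
    "flag_mislabels",
    "HYBRID_LABEL",
]

HYBRID_LABEL = "inter-specific hybrid"


@dataclass
class AdmixtureFit:
    K: int
    sample_ids: list
    Q: np.ndarray              # (n, K) posterior-mean ancestry
    P: np.ndarray              # (K, L) posterior-mean alt frequencies
    loglik_trace: np.ndarray   # per recorded sweep
    mean_loglik: float
    var_loglik: float
    seed: int
    burnin: int
    reps: int

    def relabel(self, perm) -> "AdmixtureFit":
        perm = np.asarray(perm)
        return AdmixtureFit(
            self.K, self.sample_ids, self.Q[:, perm], self.P[perm],
            self.loglik_trace, self.mean_loglik, self.var_loglik,
            self.seed, self.burnin, self.reps,
        )


@dataclass
class RunEnsemble:
    """Replicate admixture runs across a range of K values."""

    runs: dict = field(default_factory=dict)   # K -> list[AdmixtureFit]
    alignments: dict = field(default_factory=dict)  # K -> list[perm per run]

    def add(self, fit: AdmixtureFit):
        self.runs.setdefault(fit.K, []).append(fit)

    @property
    def k_values(self) -> list:
        return sorted(self.runs)


@dataclass
class AssignmentResult:
    sample_ids: list
    species: list                     # cluster/species names, Q column order
    mean_q: np.ndarray                # (n_queries, K) mean over runs
    calls: pd.DataFrame               # per query: inferred label, top species
    q_call: float


@dataclass
class ClusterNode:
    """One node of a hierarchical structure analysis."""

    sample_ids: list
    depth: int
    k_chosen: int
    delta_k: pd.DataFrame = None
    assignments: dict = None          # sample -> child index (max-Q cluster)
    children: list = field(default_factory=list)

    @property
    def leaves(self) -> list:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves)
        return out


def _data_loglik(g, obs, Q, P):
    pi = Q @ P
    pi = np.clip(pi, 1e-12, 1.0 - 1e-12)
    lp = np.where(
        g == 0,
        2.0 * np.log1p(-pi),
        np.where(g == 1, np.log(2.0) + np.log(pi) + np.log1p(-pi), 2.0 * np.log(pi)),
    )
    return float(lp[obs].sum())


def fit_admixture(
    gm: GenotypeMatrix,
    K: int,
    burnin: int = 2000,
    reps: int = 5000,
    alpha: float = 1.0,
    seed: int = 0,
    fixed_labels=None,
) -> AdmixtureFit:
    """Run the admixture Gibbs sampler and return posterior means.

    ``fixed_labels`` is an optional per-sample array of cluster indices
    in ``0..K-1`` (or ``None``/``-1`` for free samples); labelled
    samples have their allele-copy origins pinned (supervised mode).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if burnin <= 0 or reps <= 0:
        raise ValueError("burnin and reps must be positive")
    n, L = gm.shape
    g = gm.calls.astype(np.int8)
    obs = ~gm.missing
    rng = np.random.default_rng(seed)

    if K == 1:
        Q = np.ones((n, 1))
        p, called = _posterior_freq_k1(g, obs)
        trace = np.full(reps, _data_loglik(g, obs, Q, p[None, :]))
        return AdmixtureFit(1, list(gm.sample_ids), Q, p[None, :], trace,
                            float(trace.mean()), 0.0, seed, burnin, reps)

    fixed = np.full(n, -1, dtype=np.int64)
    if fixed_labels is not None:
        for i, lab in enumerate(fixed_labels):
            if lab is None:
                continue
            lab = int(lab)
            if lab != -1 and not 0 <= lab < K:
                raise ValueError(f"fixed label {lab} outside 0..{K - 1}")
            fixed[i] = lab
    is_fixed = fixed >= 0

    # allele copies: copy 0 is alt iff code >= 1, copy 1 iff code == 2
    alt = np.stack([(g >= 1), (g == 2)])          # (2, n, L) bool
    obs2 = np.broadcast_to(obs, (2, n, L))
    z = rng.integers(0, K, size=(2, n, L))
    z[:, is_fixed, :] = fixed[is_fixed][None, :, None]

    Q = rng.dirichlet(np.full(K, alpha), size=n)
    P = rng.uniform(0.2, 0.8, size=(K, L))
    q_sum = np.zeros((n, K))
    p_sum = np.zeros((K, L))
    trace = np.empty(burnin + reps)
    free = ~is_fixed

    for sweep in range(burnin + reps):
        # --- sample z for free individuals ---
        for c in (0, 1):
            a = alt[c]
            lik = np.where(a[None, :, :], P[:, None, :], 1.0 - P[:, None, :])
            w = Q.T[:, :, None] * lik               # (K, n, L)
            cdf = np.cumsum(w, axis=0)
            u = rng.random((n, L)) * cdf[-1]
            znew = (u[None, :, :] > cdf).sum(axis=0)
            z[c][free] = znew[free]
        # --- update P ---
        alt_ct = np.zeros((K, L))
        tot_ct = np.zeros((K, L))
        for c in (0, 1):
            zc = np.where(obs, z[c], K)  # missing copies to a dump bin
            for k in range(K):
                sel = zc == k
                tot_ct[k] += sel.sum(axis=0)
                alt_ct[k] += (sel & alt[c]).sum(axis=0)
        P = rng.beta(1.0 + alt_ct, 1.0 + tot_ct - alt_ct)
        # --- update Q ---
        cnt = np.zeros((n, K))
        for c in (0, 1):
            zc = np.where(obs, z[c], K)
            for k in range(K):
                cnt[:, k] += (zc == k).sum(axis=1)
        gam = rng.gamma(alpha + cnt)
        Q = gam / gam.sum(axis=1, keepdims=True)
        trace[sweep] = _data_loglik(g, obs, Q, P)
        if sweep >= burnin:
            q_sum += Q
            p_sum += P

    Q_mean = q_sum / reps
    Q_mean /= Q_mean.sum(axis=1, keepdims=True)
    post = trace[burnin:]
    return AdmixtureFit(
        K, list(gm.sample_ids), Q_mean, p_sum / reps, trace,
        float(post.mean()), float(post.var(ddof=1)), seed, burnin, reps,
    )


def _posterior_freq_k1(g, obs):
    called = obs.sum(axis=0)
    alt = np.where(obs, g, 0).sum(axis=0)
    return (alt + 1.0) / (2.0 * called + 2.0), called


def _match_permutation(q_ref: np.ndarray, q_run: np.ndarray) -> np.ndarray:
    """Column permutation of ``q_run`` maximizing summed column agreement."""
    score = q_ref.T @ q_run   # (K, K) inner products
    row, col = linear_sum_assignment(-score)
    perm = np.empty(len(col), dtype=int)
    perm[row] = col
    return perm


def align_runs(ensemble: RunEnsemble) -> RunEnsemble:
    """Permute cluster labels of every run to match the first run at each K."""
    out = RunEnsemble()
    for K in ensemble.k_values:
        fits = ensemble.runs[K]
        ref = fits[0]
        perms = []
        for fit in fits:
            if fit.sample_ids != ref.sample_ids:
                raise ValueError("runs at one K must share the same samples")
            perm = (
                np.arange(K)
                if fit is ref or K == 1
                else _match_permutation(ref.Q, fit.Q)
            )
            perms.append(perm)
            out.add(fit.relabel(perm))
        out.alignments[K] = perms
    return out


def evanno_delta_k(ensemble: RunEnsemble) -> pd.DataFrame:
    """Evanno table: mean/sd of L(K) across runs, |L''(K)| and delta K.

    ``delta_k(K) = mean over runs |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K))``,
    defined for interior K only.  A zero sd is reported as infinite.
    """
    ks = ensemble.k_values
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >=3 consecutive K values")
    ll = {K: np.array([f.mean_loglik for f in ensemble.runs[K]]) for K in ks}
    counts = {K: len(v) for K, v in ll.items()}
    if min(counts.values()) < 2:
        raise ValueError("need >=2 runs per K")
    rows = []
    paired = len(set(counts.values())) == 1
    for K in ks:
        mean_l, sd_l = ll[K].mean(), ll[K].std(ddof=1)
        second = delta = np.nan
        if ks[0] < K < ks[-1]:
            if paired:
                diffs = np.abs(ll[K + 1] - 2.0 * ll[K] + ll[K - 1])
                second = diffs.mean()
            else:
                second = abs(ll[K + 1].mean() - 2.0 * mean_l + ll[K - 1].mean())
            delta = second / sd_l if sd_l > 0 else np.inf
        rows.append({"K": K, "mean_loglik": mean_l, "sd_loglik": sd_l,
                     "second_difference": second, "delta_k": delta})
    return pd.DataFrame(rows).set_index("K")


def _scan_k(gm, k_range, runs, burnin, reps, alpha, rng):
    ens = RunEnsemble()
    for K in k_range:
        for _ in range(runs):
            ens.add(
                fit_admixture(
                    gm, K, burnin=burnin, reps=reps, alpha=alpha,
                    seed=int(rng.integers(2**31 - 1)),
                )
            )
    return align_runs(ens)


def best_k(delta: pd.DataFrame) -> int:
    interior = delta["delta_k"].dropna()
    interior = interior[np.isfinite(interior)]
    if interior.empty:
        return 1
    return int(interior.idxmax())


def hierarchical_structure(
    gm: GenotypeMatrix,
    passport: PassportTable = None,
    max_depth: int = 2,
    runs: int = 3,
    k_range=range(1, 6),
    seed: int = 0,
    burnin: int = 300,
    reps: int = 700,
    alpha: float = 1.0,
    min_size: int = 10,
    delta_k_min: float = 5.0,
) -> ClusterNode:
    """Recursive admixture clustering, re-splitting each cluster.

    At each node the K scan is summarized by the Evanno table; the node
    splits at the delta-K-optimal K when that statistic clears
    ``delta_k_min`` (flat likelihood surfaces do not split).  Clusters
    smaller than ``min_size`` are leaves.  Samples go to their max-Q
    cluster of the run-averaged ancestry matrix.
    """
    rng = np.random.default_rng(seed)
    k_range = list(k_range)

    def analyze(sub: GenotypeMatrix, depth: int) -> ClusterNode:
        node = ClusterNode(list(sub.sample_ids), depth, 1)
        if depth >= max_depth or sub.n_samples < max(min_size, 2 * min(k_range)):
            return node
        ens = _scan_k(sub, k_range, runs, burnin, reps, alpha, rng)
        delta = evanno_delta_k(ens)
        node.delta_k = delta
        k_star = best_k(delta)
        peak = delta.loc[k_star, "delta_k"]
        if k_star < 2 or not (np.isinf(peak) or peak >= delta_k_min):
            return node
        # Evanno's statistic cannot test K=1: only split when the
        # structured model improves the likelihood by more than the
        # overfitting headroom of its extra parameters (AIC-style margin:
        # (K*-Kmin) blocks of per-locus frequencies plus ancestry dof)
        k_min = delta.index.min()
        baseline = delta.loc[k_min, "mean_loglik"]
        margin = 0.5 * (k_star - k_min) * (sub.n_loci + sub.n_samples)
        if delta.loc[k_star, "mean_loglik"] - baseline <= margin:
            return node
        node.k_chosen = k_star
        q_mean = np.mean([f.Q for f in ens.runs[k_star]], axis=0)
        hard = q_mean.argmax(axis=1)
        node.assignments = dict(zip(sub.sample_ids, hard))
        for k in range(k_star):
            members = np.flatnonzero(hard == k)
            if len(members) == 0:
                continue
            child_gm = sub.subset(samples=members)
            if len(members) >= min_size:
                node.children.append(analyze(child_gm, depth + 1))
            else:
                node.children.append(ClusterNode(list(child_gm.sample_ids), depth + 1, 1))
        return node

    return analyze(gm, 0)


def select_core_members(fit: AdmixtureFit, q_min: float = 0.80) -> dict:
    """Per-cluster ids of samples with ancestry strictly above ``q_min``.

    Samples exceeding the cutoff in no cluster are listed under the key
    ``"admixed"``.
    """
    if not 0.0 < q_min < 1.0:
        raise ValueError("q_min must be in (0, 1)")
    core = {k: [] for k in range(fit.K)}
    admixed = []
    for s, q in zip(fit.sample_ids, fit.Q):
        k = int(q.argmax())
        if q[k] > q_min:
            core[k].append(s)
        else:
            admixed.append(s)
    core["admixed"] = admixed
    return core


def simulate_reference(
    freqs_by_species: dict, n_per_species: int = 500, seed: int = 0
):
    """Expand species reference panels by Hardy-Weinberg simulation.

    ``freqs_by_species`` maps species name to a per-locus alt-frequency
    array (typically estimated from core members).  Returns a
    ``(GenotypeMatrix, labels)`` pair with ``n_per_species`` simulated
    genotypes per species.
    """
    if not freqs_by_species:
        raise ValueError("no species frequencies supplied")
    rng = np.random.default_rng(seed)
    blocks, labels, ids = [], [], []
    L = None
    for species, p in freqs_by_species.items():
        p = np.asarray(p, dtype=float)
        if np.isnan(p).any():
            raise ValueError(f"species {species!r} has undefined frequencies")
        L = len(p) if L is None else L
        if len(p) != L:
            raise ValueError("species frequency vectors differ in length")
        blocks.append(rng.binomial(2, p, size=(n_per_species, L)))
        labels.extend([species] * n_per_species)
        ids.extend(f"SIM_{species}_{i:04d}" for i in range(n_per_species))
    calls = np.vstack(blocks).astype(np.int8)
    gm = GenotypeMatrix(ids, [f"L{j:04d}" for j in range(L)], calls)
    return gm, labels


def assign_unknowns(
    reference: GenotypeMatrix,
    reference_labels,
    queries: GenotypeMatrix,
    runs: int = 10,
    burnin: int = 2000,
    reps: int = 5000,
    q_call: float = 0.80,
    alpha: float = 1.0,
    seed: int = 0,
) -> AssignmentResult:
    """Supervised species assignment of query genotypes.

    Reference individuals are pinned to their species cluster; K equals
    the number of reference species.  The mean query ancestry over
    ``runs`` independent chains is reported; a query is called as the
    species with mean Q above ``q_call``, otherwise as an inter-specific
    hybrid annotated with its two largest-ancestry species.
    """
    labels = list(reference_labels)
    if len(labels) != reference.n_samples:
        raise ValueError("reference_labels must cover the reference samples")
    if queries.locus_ids != reference.locus_ids:
        raise ValueError("query loci do not match reference loci")
    species = list(pd.unique(np.asarray(labels)))
    K = len(species)
    combined = concat_samples(reference, queries)
    fixed = [species.index(lab) for lab in labels] + [-1] * queries.n_samples
    rng = np.random.default_rng(seed)
    q_acc = np.zeros((queries.n_samples, K))
    for _ in range(runs):
        fit = fit_admixture(
            combined, K, burnin=burnin, reps=reps, alpha=alpha,
            seed=int(rng.integers(2**31 - 1)), fixed_labels=fixed,
        )
        q_acc += fit.Q[reference.n_samples :]
    mean_q = q_acc / runs
    rows = []
    for sid, q in zip(queries.sample_ids, mean_q):
        order = np.argsort(q)[::-1]
        top, second = order[0], order[1] if K > 1 else order[0]
        if q[top] > q_call:
            label = species[top]
        else:
            pair = sorted([species[top], species[second]])
            label = f"{HYBRID_LABEL} ({pair[0]} x {pair[1]})"
        rows.append(
            {
                "sample_id": sid,
                "inferred": label,
                "inferred_species": species[top] if q[top] > q_call else HYBRID_LABEL,
                "top_species": species[top],
                "top_q": float(q[top]),
                "second_species": species[second],
                "second_q": float(q[second]),
            }
        )
    calls = pd.DataFrame(rows).set_index("sample_id", drop=False)
    return AssignmentResult(list(queries.sample_ids), species, mean_q, calls, q_call)


AMBIGUOUS_RECORDS = {"unknown", "hybrid", "saccharum spp", "spp", "", "nan"}


def _is_concrete(species) -> bool:
    return str(species).strip().lower() not in AMBIGUOUS_RECORDS


def flag_mislabels(assignment: AssignmentResult, passport: PassportTable) -> pd.DataFrame:
    """Compare inferred species calls against recorded passport species.

    A *mislabel* is a concrete recorded species contradicted by a
    concrete inferred species.  Records of 'unknown' or 'hybrid' are
    clarifications rather than mislabels; a concrete record whose
    inferred call is 'inter-specific hybrid' is reported as ``admixed``
    (evidence of admixture, not of a wrong species record).
    """
    rows = []
    for sid in assignment.sample_ids:
        if sid not in passport.table.index:
            continue
        recorded = passport.species_of(sid)
        call = assignment.calls.loc[sid]
        inferred = str(call["inferred_species"])
        if not _is_concrete(recorded):
            status = "clarification"
        elif inferred == HYBRID_LABEL:
            status = "admixed"
        elif str(recorded) != inferred:
            status = "mislabel"
        else:
            status = "ok"
        rows.append(
            {
                "sample_id": sid,
                "recorded_species": recorded,
                "inferred_species": call["inferred_species"],
                "inferred": call["inferred"],
                "top_q": call["top_q"],
                "status": status,
            }
        )
    return pd.DataFrame(rows)
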