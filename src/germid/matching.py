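"""Multilocus matching: duplicate detection, error calibration, homonyms.

A genebank maintained as clonal material accumulates two symmetric
labelling faults.  *Synonymous* mislabeling (duplicates): distinct
accession codes carrying the same multilocus genotype.  *Homonymous*
mislabeling: one accession name carried by distinct genotypes.  Both are
decided from the pairwise allele-difference matrix, with the tolerance
for genotyping error calibrated on a replicated internal-control clone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PassportTable

__all__ = [
    "PairwiseDifference",
    "ErrorCalibration",
    "CloneGroup",
    "CloneGroupSet",
    "allele_difference_matrix",
    "calibrate_error",
    "find_clone_groups",
    "find_homonyms",
    "export_match_network",
    "duplicate_percentage",
]


@dataclass
class PairwiseDifference:
    """Pairwise allele-difference counts over shared (co-called) loci."""

    sample_ids: list
    diff: np.ndarray        # (n, n) int, symmetric, zero diagonal
    shared_loci: np.ndarray  # (n, n) int, loci non-missing in both
    mode: str = "allele"

    @property
    def undefined_pairs(self) -> list:
        """Pairs with zero shared loci, for which the difference is undefined."""
        i, j = np.nonzero(np.triu(self.shared_loci == 0, k=1))
        return [(self.sample_ids[a], self.sample_ids[b]) for a, b in zip(i, j)]

    def get(self, a: str, b: str) -> int:
        ia = self.sample_ids.index(a)
        ib = self.sample_ids.index(b)
        return int(self.diff[ia, ib])


@dataclass
class ErrorCalibration:
    """Genotyping error rate estimated from a clonal replicate set.

    The per-locus consensus is the modal non-missing code among the
    replicates; loci whose mode is tied are ambiguous and excluded from
    both the deviant and the called counts.  ``threshold`` is the
    largest pairwise allele difference observed inside the replicate
    set — the mismatch budget a true clone pair can exhaust through
    genotyping error alone.
    """

    n_replicates: int
    n_called: int
    n_deviant: int
    threshold: int
    ambiguous_loci: int = 0

    @property
    def error_rate(self) -> float:
        return self.n_deviant / self.n_called if self.n_called else 0.0

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "n_called": self.n_called,
            "n_deviant": self.n_deviant,
            "error_rate": self.error_rate,
            "threshold": self.threshold,
            "ambiguous_loci": self.ambiguous_loci,
        }


@dataclass
class CloneGroup:
    members: frozenset
    kind: str  # exact | near_identical | homonym
    name: str = None            # shared clone_name for homonym groups
    components: tuple = ()      # distinct-genotype partition (homonyms)
    max_diff: int = 0


@dataclass
class CloneGroupSet:
    groups: list
    kind: str
    threshold_used: int
    edges: list = field(default_factory=list)  # (a, b, diff) supporting pairs

    def __len__(self):
        return len(self.groups)

    @property
    def member_ids(self) -> set:
        out = set()
        for g in self.groups:
            out |= set(g.members)
        return out

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for k, g in enumerate(self.groups, start=1):
            rows.append(
                {
                    "group": k,
                    "kind": g.kind,
                    "name": g.name,
                    "n_members": len(g.members),
                    "members": ";".join(sorted(g.members)),
                    "max_diff": g.max_diff,
                }
            )
        return pd.DataFrame(rows)


def allele_difference_matrix(gm: GenotypeMatrix, mode: str = "allele") -> PairwiseDifference:
    """Pairwise genotype differences, excluding loci missing in either sample.

    ``mode="allele"`` sums ``|g_a - g_b|`` over shared loci (a hom-ref /
    hom-alt mismatch counts 2); ``mode="locus"`` counts mismatching loci.
    """
    if gm.n_samples < 2:
        raise ValueError("need >=2 samples for pairwise differences")
    if mode not in ("allele", "locus"):
        raise ValueError(f"unknown mode {mode!r}")
    obs = (~gm.missing).astype(np.float64)
    shared = (obs @ obs.T).astype(np.int64)
    # one-hot planes per genotype code; cross products count code pairs
    planes = [((gm.calls == c) & ~gm.missing).astype(np.float64) for c in (0, 1, 2)]
    cross = [[planes[a] @ planes[b].T for b in range(3)] for a in range(3)]
    if mode == "allele":
        diff = (
            cross[0][1] + cross[1][0] + cross[1][2] + cross[2][1]
            + 2.0 * (cross[0][2] + cross[2][0])
        )
    else:
        same = cross[0][0] + cross[1][1] + cross[2][2]
        diff = shared - same
    diff = np.rint(diff).astype(np.int64)
    np.fill_diagonal(diff, 0)
    return PairwiseDifference(list(gm.sample_ids), diff, shared, mode=mode)


def calibrate_error(gm: GenotypeMatrix, replicate_ids) -> ErrorCalibration:
    """Estimate the genotyping error rate from clonal replicate samples.

    Requires at least three replicates so the per-locus consensus is a
    genuine majority vote.
    """
    replicate_ids = list(replicate_ids)
    if len(replicate_ids) < 3:
        raise ValueError("error calibration needs >=3 clonal replicates")
    sub = gm.subset(samples=replicate_ids)
    counts = np.zeros((3, sub.n_loci), dtype=np.int64)
    for c in (0, 1, 2):
        counts[c] = ((sub.calls == c) & ~sub.missing).sum(axis=0)
    top = counts.max(axis=0)
    tied = (counts == top).sum(axis=0) > 1
    ambiguous = tied & (top > 0)
    consensus = counts.argmax(axis=0)
    deviant = (sub.calls != consensus[None, :]) & ~sub.missing
    usable = ~ambiguous
    n_called = int((~sub.missing)[:, usable].sum())
    n_deviant = int(deviant[:, usable].sum())
    pd_ = allele_difference_matrix(sub)
    threshold = int(pd_.diff.max()) if sub.n_samples > 1 else 0
    return ErrorCalibration(
        n_replicates=len(replicate_ids),
        n_called=n_called,
        n_deviant=n_deviant,
        threshold=threshold,
        ambiguous_loci=int(ambiguous.sum()),
    )


def _components(pd_: PairwiseDifference, ids, threshold: int):
    """Connected components of the <=threshold graph restricted to ``ids``."""
    idx = {s: i for i, s in enumerate(pd_.sample_ids)}
    g = nx.Graph()
    g.add_nodes_from(ids)
    edges = []
    for a_pos, a in enumerate(ids):
        for b in ids[a_pos + 1 :]:
            ia, ib = idx[a], idx[b]
            if pd_.shared_loci[ia, ib] == 0:
                continue  # undefined pair: no edge
            d = int(pd_.diff[ia, ib])
            if d <= threshold:
                g.add_edge(a, b)
                edges.append((a, b, d))
    return list(nx.connected_components(g)), edges


def find_clone_groups(pd_: PairwiseDifference, threshold: int = 0) -> CloneGroupSet:
    """Duplicate groups: connected components of the <=threshold graph.

    ``threshold=0`` yields exact-duplicate groups; the replicate-
    calibrated threshold yields putative (near-identical) duplicates.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kind = "exact" if threshold == 0 else "near_identical"
    comps, edges = _components(pd_, list(pd_.sample_ids), threshold)
    idx = {s: i for i, s in enumerate(pd_.sample_ids)}
    groups = []
    for comp in comps:
        if len(comp) < 2:
            continue
        members = sorted(comp)
        mx = max(
            int(pd_.diff[idx[a], idx[b]])
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        )
        groups.append(CloneGroup(frozenset(comp), kind, max_diff=mx))
    groups.sort(key=lambda g: sorted(g.members))
    return CloneGroupSet(groups, kind, threshold, edges)


def find_homonyms(
    pd_: PairwiseDifference, passport: PassportTable, threshold: int = 2
) -> CloneGroupSet:
    """Homonym groups: one clone name covering more than one genotype.

    A name shared by >=2 genotyped samples is flagged when at least one
    within-name pair differs by more than ``threshold``; the group
    records the partition of the name into distinct genotypes
    (components at <=threshold).
    """
    present = [s for s in pd_.sample_ids if s in passport.table.index]
    by_name = {}
    for s in present:
        by_name.setdefault(passport.name_of(s), []).append(s)
    idx = {s: i for i, s in enumerate(pd_.sample_ids)}
    groups, edges = [], []
    for name in sorted(by_name):
        ids = by_name[name]
        if len(ids) < 2:
            continue
        over = [
            (a, b, int(pd_.diff[idx[a], idx[b]]))
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
            if pd_.shared_loci[idx[a], idx[b]] > 0
            and pd_.diff[idx[a], idx[b]] > threshold
        ]
        if not over:
            continue
        comps, _ = _components(pd_, ids, threshold)
        mx = max(d for _, _, d in over)
        groups.append(
            CloneGroup(
                frozenset(ids),
                "homonym",
                name=name,
                components=tuple(frozenset(c) for c in comps),
                max_diff=mx,
            )
        )
        edges.extend(over)
    return CloneGroupSet(groups, "homonym", threshold, edges)


def export_match_network(
    groups: CloneGroupSet, path, passport: PassportTable = None
) -> nx.Graph:
    """Write the match network as GraphML plus an edge-list CSV.

    Nodes are clone codes (annotated with recorded species when a
    passport is given); edges carry the allele-difference count.
    Returns the graph for further use.
    """
    g = nx.Graph()
    for grp in groups.groups:
        for s in grp.members:
            g.add_node(s)
    for a, b, d in groups.edges:
        g.add_edge(a, b, diff=int(d))
    if passport is not None:
        for s in g.nodes:
            if s in passport.table.index:
                g.nodes[s]["species"] = str(passport.species_of(s))
    path = str(path)
    nx.write_graphml(g, path)
    csv_path = path.rsplit(".", 1)[0] + "_edges.csv"
    pd.DataFrame(
        [(a, b, g.edges[a, b]["diff"]) for a, b in g.edges],
        columns=["clone_a", "clone_b", "diff"],
    ).to_csv(csv_path, index=False)
    return g


def duplicate_percentage(groups, n_total: int) -> int:
    """Share of the collection sitting inside duplicate groups, as a
    nearest-integer percentage.  ``groups`` may be a :class:`CloneGroupSet`
    or a plain member count."""
    n_dup = groups if isinstance(groups, int) else len(groups.member_ids)
    return int(round(100.0 * n_dup / n_total))
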