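"""Greedy clustering of reference genomes into candidate organisms.

Several reference genomes often describe the same organism in a sample (the
well-sequenced E. coli problem). References are therefore clustered: each
cluster is one *candidate organism*, its members are the supporting
references, and the per-member GDV quantifies how well each reference
matches the candidate.

The clustering is greedy and two-stage. Each reference, in order of
descending read support, is compared against existing clusters: (i) if the
fraction of its core reads shared with a cluster reaches ``min_cr_overlap``
(default 20%), it joins the best such cluster; (ii) otherwise, if the
fraction of all its reads shared with a cluster reaches ``min_shared_reads``
(default 60%, higher because shared reads discriminate less than shared CR),
it joins the best such cluster; (iii) otherwise it founds a new cluster.
Cluster CR/read sets are unions over members. The candidate is named by the
lowest common ancestor (LCA) of its members in an optional taxonomy.

Abundance is reported per candidate as its depth over the summed depth of
all candidates (read counts are proportional to genome length times
abundance; depth already normalizes genome length out), with raw read counts
alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .alignment_io import AlignmentTable
from .core_reads import CoreReadSet
from .coverage import ReferenceProfile

__all__ = [
    "CandidateOrganism",
    "ClusterMember",
    "TaxonomyTable",
    "greedy_cluster",
    "lca",
    "estimate_abundances",
]

DEFAULT_MIN_CR_OVERLAP = 0.2
DEFAULT_MIN_SHARED_READS = 0.6
UNCLASSIFIED = "unclassified"


@dataclass
class ClusterMember:
    organism_id: str
    gdv: float
    depth: float
    n_reads: int
    n_unique_reads: int


@dataclass
class CandidateOrganism:
    cluster_id: str
    members: list[ClusterMember]
    n_reads: int
    n_cr: int
    depth: float
    lca_taxon: str = UNCLASSIFIED
    abundance: float = 0.0
    read_ids: set[str] = field(default_factory=set, repr=False)
    cr_ids: set[str] = field(default_factory=set, repr=False)


@dataclass
class TaxonomyTable:
    """Parent-pointer taxonomy with ranks and names.

    Loaded from a 4-column TSV (taxon_id, parent_id, rank, name). The root
    is its own parent (or has an empty parent field).
    """

    parent: dict[str, str]
    rank: dict[str, str] = field(default_factory=dict)
    name: dict[str, str] = field(default_factory=dict)
    root: str = ""

    def __post_init__(self) -> None:
        roots = [t for t, p in self.parent.items() if p == t or p == ""]
        if not self.root:
            if len(roots) != 1:
                raise ValueError(f"taxonomy must have exactly one root, found {roots}")
            self.root = roots[0]
        # validate: every path reaches the root without cycles
        for taxon in self.parent:
            seen = set()
            node = taxon
            while node != self.root:
                if node in seen:
                    raise ValueError(f"cycle in taxonomy at {node!r}")
                seen.add(node)
                node = self.parent.get(node, "")
                if node == "":
                    raise ValueError(f"taxon {taxon!r} does not reach the root")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTable":
        parent: dict[str, str] = {}
        rank: dict[str, str] = {}
        name: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"taxonomy line needs 4 columns: {line!r}")
                taxon, par, rk, nm = parts[:4]
                parent[taxon] = par or taxon
                rank[taxon] = rk
                name[taxon] = nm
        return cls(parent=parent, rank=rank, name=name)

    def ancestors(self, taxon: str) -> list[str]:
        """Path from ``taxon`` (inclusive) up to the root (inclusive)."""
        if taxon not in self.parent:
            raise KeyError(f"unknown taxon {taxon!r}")
        path = [taxon]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def depth_of(self, taxon: str) -> int:
        return len(self.ancestors(taxon)) - 1


def lca(members: set[str] | list[str], tax: TaxonomyTable) -> str:
    """Deepest taxon that is an ancestor-or-self of every member."""
    members = list(members)
    if not members:
        raise ValueError("empty member set")
    for m in members:
        if m not in tax.parent:
            raise KeyError(f"unknown taxon {m!r}")
    # lift all members to the same depth, then walk up in lockstep
    nodes = list(members)
    depths = [tax.depth_of(m) for m in nodes]
    d = min(depths)
    for i, node in enumerate(nodes):
        while depths[i] > d:
            node = tax.parent[node]
            depths[i] -= 1
        nodes[i] = node
    while len(set(nodes)) > 1:
        nodes = [tax.parent[n] for n in nodes]
    return nodes[0]


def _best_cluster(
    candidate_set: set[str],
    clusters: list[dict],
    key: str,
    threshold: float,
) -> int | None:
    """Index of the cluster with the highest overlap fraction >= threshold.

    Overlap is |candidate_set ∩ cluster set| / |candidate_set|; ties go to
    the earliest-created cluster.
    """
    if not candidate_set:
        return None
    best_idx, best_frac = None, -1.0
    for idx, cl in enumerate(clusters):
        frac = len(candidate_set & cl[key]) / len(candidate_set)
        if frac > best_frac:
            best_idx, best_frac = idx, frac
    if best_idx is not None and best_frac >= threshold:
        return best_idx
    return None


def greedy_cluster(
    profiles: dict[str, ReferenceProfile],
    cr: CoreReadSet,
    table: AlignmentTable,
    min_cr_overlap: float = DEFAULT_MIN_CR_OVERLAP,
    min_shared_reads: float = DEFAULT_MIN_SHARED_READS,
    taxonomy: TaxonomyTable | None = None,
    taxonomy_hint: bool = False,
) -> list[CandidateOrganism]:
    """Cluster references into candidate organisms.

    Processing order: descending total mapped reads, ties broken
    lexicographically by organism id — high-support references seed the
    clusters. With ``taxonomy_hint`` (and a taxonomy), ties are instead
    broken by taxon first so related references are compared early; results
    on well-separated inputs are order-independent.
    """
    read_sets = {org: table.reads_of(org) for org in profiles}

    def sort_key(org: str):
        if taxonomy_hint and taxonomy is not None and org in taxonomy.parent:
            return (-len(read_sets[org]), taxonomy.parent[org], org)
        return (-len(read_sets[org]), "", org)

    order = sorted(profiles, key=sort_key)

    clusters: list[dict] = []
    for org in order:
        org_cr = cr.cr_of(org)
        org_reads = read_sets[org]
        idx = _best_cluster(org_cr, clusters, "cr", min_cr_overlap)
        if idx is None:
            idx = _best_cluster(org_reads, clusters, "reads", min_shared_reads)
        if idx is None:
            clusters.append({"members": [org], "cr": set(org_cr), "reads": set(org_reads)})
        else:
            clusters[idx]["members"].append(org)
            clusters[idx]["cr"] |= org_cr
            clusters[idx]["reads"] |= org_reads

    candidates: list[CandidateOrganism] = []
    for i, cl in enumerate(clusters, 1):
        members = [
            ClusterMember(
                organism_id=org,
                gdv=profiles[org].gdv,
                depth=profiles[org].depth,
                n_reads=profiles[org].n_reads,
                n_unique_reads=profiles[org].n_unique_reads,
            )
            for org in cl["members"]
        ]
        # representative depth: read-count-weighted mean over members, which
        # agree by construction of the CR criterion
        w_tot = sum(m.n_reads for m in members)
        depth = (
            sum(m.depth * m.n_reads for m in members) / w_tot
            if w_tot
            else sum(m.depth for m in members) / len(members)
        )
        taxon = UNCLASSIFIED
        if taxonomy is not None:
            known = [m.organism_id for m in members if m.organism_id in taxonomy.parent]
            if known:
                taxon = lca(known, taxonomy)
                taxon = taxonomy.name.get(taxon, taxon)
        candidates.append(
            CandidateOrganism(
                cluster_id=f"C{i}",
                members=members,
                n_reads=len(cl["reads"]),
                n_cr=len(cl["cr"]),
                depth=float(depth),
                lca_taxon=taxon,
                read_ids=cl["reads"],
                cr_ids=cl["cr"],
            )
        )
    return estimate_abundances(candidates)


def estimate_abundances(candidates: list[CandidateOrganism]) -> list[CandidateOrganism]:
    """Fill relative abundances: depth_i / sum_j depth_j.

    Read counts scale with genome length times cell abundance; depth divides
    genome length back out, so depth ratios are organism-count ratios.
    """
    if not candidates:
        return candidates
    total = sum(c.depth for c in candidates)
    if total <= 0:
        warnings.warn("all candidate depths are zero; reporting uniform abundances")
        for c in candidates:
            c.abundance = 1.0 / len(candidates)
        return candidates
    for c in candidates:
        c.abundance = c.depth / total
    return candidates
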