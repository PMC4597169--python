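"""Module detection by fast greedy modularity optimisation and its null model.

Modules are communities of the weighted bipartite network found with the
Clauset-Newman-Moore agglomerative algorithm (via igraph), cutting the merge
dendrogram at maximum modularity.  Statistical support comes from a
weight-permutation null: the topology (nodes and edges) is held fixed and only
the positive/negative edge weights are shuffled, conserving their counts; the
real modularity is compared with the modularities of the shuffled replicates.
Modularity here is the general Newman-Girvan quantity

    Q = sum_c [ W_c / m  -  (d_c / 2m)^2 ]

where m is the total edge weight, W_c the weight inside community c and d_c
the total weighted degree of c's nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np

from hlanet.network import BipartiteNetwork, HLA_PREFIX, PEP_PREFIX


@dataclass
class ModulePartition:
    """Assignment of every network node to a module, with its modularity."""

    hla_modules: dict[str, int]
    peptide_modules: dict[str, int]
    modularity: float
    n_modules: int

    @property
    def assignment(self) -> dict[str, int]:
        """Single node -> module map (allele and peptide names merged)."""
        merged = dict(self.hla_modules)
        merged.update(self.peptide_modules)
        return merged

    def module_ids(self) -> list[int]:
        return sorted(set(self.hla_modules.values()) | set(self.peptide_modules.values()))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node\tside\tmodule_id\n")
            for h, m in self.hla_modules.items():
                fh.write(f"{h}\thla\t{m}\n")
            for p, m in self.peptide_modules.items():
                fh.write(f"{p}\tpeptide\t{m}\n")


@dataclass
class NullDistribution:
    """Modularities of weight-shuffled replicate networks vs the real value."""

    values: list[float]
    real_value: float
    empirical_p: float
    seeds: list[int]
    replicate_n_modules: list[int] = field(default_factory=list)

    def summary(self) -> dict:
        v = np.asarray(self.values)
        return {
            "real": self.real_value,
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "min": float(v.min()),
            "max": float(v.max()),
            "empirical_p": self.empirical_p,
            "replicates": len(self.values),
        }


# -- modularity on generic edge lists -------------------------------------


def modularity_from_edges(
    edges: Sequence[tuple[Hashable, Hashable, float]],
    assignment: Mapping[Hashable, int],
) -> float:
    """Newman-Girvan modularity of a partition of a weighted undirected graph.

    ``edges`` are (u, v, weight) triples; every endpoint must appear in
    ``assignment``.  Written from first principles so it can independently
    re-check partitions produced by any community algorithm.
    """
    m = 0.0
    within: dict[int, float] = {}
    deg: dict[int, float] = {}
    for u, v, w in edges:
        if u not in assignment or v not in assignment:
            missing = u if u not in assignment else v
            raise KeyError(f"node {missing!r} missing from assignment")
        m += w
        cu, cv = assignment[u], assignment[v]
        deg[cu] = deg.get(cu, 0.0) + w
        deg[cv] = deg.get(cv, 0.0) + w
        if cu == cv:
            within[cu] = within.get(cu, 0.0) + w
    if m == 0:
        raise ValueError("graph has no edges")
    q = 0.0
    for c, d in deg.items():
        q += within.get(c, 0.0) / m - (d / (2.0 * m)) ** 2
    return q


def modularity(
    network: BipartiteNetwork,
    assignment: Mapping[str, int],
    weighted: bool = True,
) -> float:
    """Modularity of a node->module assignment of the binding network."""
    edges = [
        (h, p, w if weighted else 1.0) for h, p, w in network.edges()
    ]
    return modularity_from_edges(edges, assignment)


# -- fast greedy (CNM) ----------------------------------------------------


def fast_greedy_from_edges(
    edges: Sequence[tuple[Hashable, Hashable, float]],
    weighted: bool = True,
) -> tuple[dict[Hashable, int], float]:
    """CNM fast-greedy community detection on a generic weighted edge list.

    Returns (node -> module id starting at 1, modularity of that cut).  The
    merge dendrogram is cut at its maximum-modularity level.
    """
    import igraph as ig

    if not edges:
        raise ValueError("empty graph")
    names: list = []
    index: dict = {}
    for u, v, _ in edges:
        for x in (u, v):
            if x not in index:
                index[x] = len(names)
                names.append(x)
    g = ig.Graph(n=len(names), edges=[(index[u], index[v]) for u, v, _ in edges])
    weights = [w for _, _, w in edges] if weighted else None
    dendro = g.community_fastgreedy(weights=weights)
    clustering = dendro.as_clustering()
    assignment = {names[i]: cid + 1 for i, cid in enumerate(clustering.membership)}
    q = modularity_from_edges(
        [(u, v, w if weighted else 1.0) for u, v, w in edges], assignment
    )
    return assignment, q


def fast_greedy_modules(network: BipartiteNetwork, weighted: bool = True) -> ModulePartition:
    """Detect binding modules in the network by fast greedy modularity optimisation.

    Weighted by default: the positive/negative weights (2/1) take part in the
    merge criterion, matching the weight-shuffling null-model design.
    """
    if network.n_edges == 0:
        raise ValueError("cannot detect modules in an empty network")
    edges = [
        (HLA_PREFIX + h, PEP_PREFIX + p, w) for h, p, w in network.edges()
    ]
    assignment, q = fast_greedy_from_edges(edges, weighted=weighted)
    hla_modules = {h: assignment[HLA_PREFIX + h] for h in network.hla_names
                   if HLA_PREFIX + h in assignment}
    pep_modules = {p: assignment[PEP_PREFIX + p] for p in network.peptide_names
                   if PEP_PREFIX + p in assignment}
    n_modules = len(set(hla_modules.values()) | set(pep_modules.values()))
    return ModulePartition(hla_modules, pep_modules, q, n_modules)


# -- weight-permutation null ----------------------------------------------


def shuffle_weights(network: BipartiteNetwork, seed: int) -> BipartiteNetwork:
    """Permute edge weights uniformly at random over the fixed edge set.

    Nodes and edges are untouched; the multiset of weights (and hence the
    counts of positives and negatives) is conserved exactly.
    """
    rng = np.random.default_rng(seed)
    ii, jj, ww = network.edge_arrays()
    shuffled = rng.permutation(ww)
    W = np.zeros_like(network.W)
    W[ii, jj] = shuffled
    return BipartiteNetwork(network.hla_names, network.peptide_names, W)


def rewire_null(network: BipartiteNetwork, seed: int) -> BipartiteNetwork:
    """Alternative null: redraw edges uniformly, keeping node counts and the
    numbers of positive and negative edges (topology NOT conserved)."""
    rng = np.random.default_rng(seed)
    n_edges = network.n_edges
    n_cells = network.n_hlas * network.n_peptides
    flat = rng.choice(n_cells, size=n_edges, replace=False)
    ww = rng.permutation(np.concatenate([
        np.full(network.n_positive, 2.0), np.full(network.n_negative, 1.0)
    ]))
    W = np.zeros_like(network.W)
    W.ravel()[flat] = ww
    return BipartiteNetwork(network.hla_names, network.peptide_names, W)


def permutation_null(
    network: BipartiteNetwork,
    replicates: int = 1000,
    base_seed: int = 0,
    weighted: bool = True,
    mode: str = "shuffle_weights",
    real_partition: ModulePartition | None = None,
) -> NullDistribution:
    """Compare the real modularity with weight-shuffled replicate networks.

    Replicate i is shuffled with seed ``base_seed + i`` and clustered with the
    same algorithm and parameters as the real network.  ``empirical_p`` uses
    the add-one estimator (1 + #{null >= real}) / (1 + replicates).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if mode not in ("shuffle_weights", "rewire"):
        raise ValueError(f"unknown null mode {mode!r}")
    nullgen = shuffle_weights if mode == "shuffle_weights" else rewire_null
    if real_partition is None:
        real_partition = fast_greedy_modules(network, weighted=weighted)
    real_q = real_partition.modularity
    seeds = [base_seed + i for i in range(replicates)]
    values: list[float] = []
    n_mods: list[int] = []
    for s in seeds:
        null_net = nullgen(network, seed=s)
        part = fast_greedy_modules(null_net, weighted=weighted)
        values.append(part.modularity)
        n_mods.append(part.n_modules)
    p = (1 + sum(v >= real_q for v in values)) / (1 + replicates)
    return NullDistribution(
        values=values,
        real_value=real_q,
        empirical_p=p,
        seeds=seeds,
        replicate_n_modules=n_mods,
    )
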