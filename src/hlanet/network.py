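"""Weighted bipartite HLA-peptide network.

Edges carry weight 2 (positive binding) or 1 (negative binding).  The network
is stored densely as an ``n_hla x n_peptide`` float matrix with 0 marking the
absence of an edge, which keeps neighbourhood queries, mean weights and the
Nebula similarity sums vectorisable; node order is fixed at construction so
that repeated runs are bit-reproducible.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from hlanet.records import BindingRecord

# Internal vertex-name prefixes keep the two sides of the bipartition in
# disjoint namespaces even for pathological inputs.
HLA_PREFIX = "H:"
PEP_PREFIX = "P:"


class UndefinedMeanError(ValueError):
    """A node has no incident edges left, so its mean weight is undefined."""


class BipartiteNetwork:
    """Weighted bipartite graph between HLA alleles and peptides."""

    def __init__(
        self,
        hla_names: Sequence[str],
        peptide_names: Sequence[str],
        weights: np.ndarray,
    ) -> None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(hla_names), len(peptide_names)):
            raise ValueError("weight matrix shape does not match node counts")
        present = weights[weights != 0]
        if present.size and not np.isin(present, (1.0, 2.0)).all():
            raise ValueError("edge weights must be 1 (negative) or 2 (positive)")
        if len(set(hla_names)) != len(hla_names) or len(set(peptide_names)) != len(peptide_names):
            raise ValueError("duplicate node names")
        self.hla_names: list[str] = list(hla_names)
        self.peptide_names: list[str] = list(peptide_names)
        self.W = weights
        self._hla_index = {h: i for i, h in enumerate(self.hla_names)}
        self._pep_index = {p: i for i, p in enumerate(self.peptide_names)}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[BindingRecord]) -> "BipartiteNetwork":
        records = list(records)
        seen = set()
        for r in records:
            key = (r.hla, r.peptide)
            if key in seen:
                raise ValueError(f"duplicate edge {key}; aggregate duplicates first")
            seen.add(key)
        hlas = sorted({r.hla for r in records})
        peps = sorted({r.peptide for r in records})
        W = np.zeros((len(hlas), len(peps)))
        hi = {h: i for i, h in enumerate(hlas)}
        pi = {p: i for i, p in enumerate(peps)}
        for r in records:
            W[hi[r.hla], pi[r.peptide]] = 2.0 if r.is_positive else 1.0
        return cls(hlas, peps, W)

    def copy(self) -> "BipartiteNetwork":
        return BipartiteNetwork(self.hla_names, self.peptide_names, self.W.copy())

    # -- basic queries -----------------------------------------------------

    @property
    def n_hlas(self) -> int:
        return len(self.hla_names)

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_names)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.W))

    @property
    def n_positive(self) -> int:
        return int((self.W == 2.0).sum())

    @property
    def n_negative(self) -> int:
        return int((self.W == 1.0).sum())

    def edges(self) -> list[tuple[str, str, float]]:
        """All edges as (hla, peptide, weight), in fixed node order."""
        ii, jj = np.nonzero(self.W)
        return [
            (self.hla_names[i], self.peptide_names[j], float(self.W[i, j]))
            for i, j in zip(ii, jj)
        ]

    def has_edge(self, hla: str, peptide: str) -> bool:
        return self.W[self._hla_index[hla], self._pep_index[peptide]] != 0

    def weight(self, hla: str, peptide: str) -> float:
        w = self.W[self._hla_index[hla], self._pep_index[peptide]]
        if w == 0:
            raise KeyError(f"no edge between {hla!r} and {peptide!r}")
        return float(w)

    def hla_index(self, hla: str) -> int:
        return self._hla_index[hla]

    def peptide_index(self, peptide: str) -> int:
        return self._pep_index[peptide]

    def side_of(self, node: str) -> str:
        in_h = node in self._hla_index
        in_p = node in self._pep_index
        if in_h and in_p:
            raise ValueError(f"node name {node!r} is ambiguous (present on both sides)")
        if in_h:
            return "hla"
        if in_p:
            return "peptide"
        raise KeyError(f"unknown node {node!r}")

    def neighbors(self, node: str) -> set[str]:
        """Opposite-side nodes sharing an edge with ``node``."""
        if self.side_of(node) == "hla":
            row = self.W[self._hla_index[node]]
            return {self.peptide_names[j] for j in np.nonzero(row)[0]}
        col = self.W[:, self._pep_index[node]]
        return {self.hla_names[i] for i in np.nonzero(col)[0]}

    def degree(self, node: str) -> int:
        return len(self.neighbors(node))

    def mean_weight(self, node: str, exclude: tuple[str, str] | None = None) -> float:
        """Mean weight of the node's incident edges, optionally excluding one edge.

        ``exclude`` is an (hla, peptide) pair; it is ignored unless it touches
        ``node``.  Raises :class:`UndefinedMeanError` when no edge remains.
        """
        if self.side_of(node) == "hla":
            vec = self.W[self._hla_index[node]].copy()
            if exclude is not None and exclude[0] == node:
                vec[self._pep_index[exclude[1]]] = 0.0
        else:
            vec = self.W[:, self._pep_index[node]].copy()
            if exclude is not None and exclude[1] == node:
                vec[self._hla_index[exclude[0]]] = 0.0
        present = vec[vec != 0]
        if present.size == 0:
            raise UndefinedMeanError(f"node {node!r} has no incident edges after exclusion")
        return float(present.mean())

    def global_mean_weight(self) -> float:
        present = self.W[self.W != 0]
        if present.size == 0:
            raise UndefinedMeanError("empty network has no mean weight")
        return float(present.mean())

    # -- conversion and I/O ------------------------------------------------

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(hla_idx, pep_idx, weight) arrays over all edges, fixed order."""
        ii, jj = np.nonzero(self.W)
        return ii, jj, self.W[ii, jj]

    def to_igraph(self, weighted: bool = True):
        """Convert to an undirected igraph graph (HLA vertices first)."""
        import igraph as ig

        ii, jj, ww = self.edge_arrays()
        g = ig.Graph(
            n=self.n_hlas + self.n_peptides,
            edges=list(zip(ii.tolist(), (jj + self.n_hlas).tolist())),
        )
        g.vs["name"] = [HLA_PREFIX + h for h in self.hla_names] + [
            PEP_PREFIX + p for p in self.peptide_names
        ]
        g.vs["type"] = [0] * self.n_hlas + [1] * self.n_peptides
        g.es["weight"] = ww.tolist() if weighted else [1.0] * len(ww)
        return g

    def to_edgelist_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("hla\tpeptide\tweight\n")
            for hla, pep, w in self.edges():
                fh.write(f"{hla}\t{pep}\t{int(w)}\n")

    @classmethod
    def from_edgelist_tsv(cls, path) -> "BipartiteNetwork":
        import csv

        recs = []
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                recs.append((row["hla"], row["peptide"], float(row["weight"])))
        hlas = sorted({r[0] for r in recs})
        peps = sorted({r[1] for r in recs})
        W = np.zeros((len(hlas), len(peps)))
        hi = {h: i for i, h in enumerate(hlas)}
        pi = {p: i for i, p in enumerate(peps)}
        for h, p, w in recs:
            W[hi[h], pi[p]] = w
        return cls(hlas, peps, W)

    def to_graphml(self, path) -> None:
        """GraphML export for external viewers."""
        self.to_igraph().write_graphml(str(path))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"BipartiteNetwork({self.n_hlas} HLAs, {self.n_peptides} peptides, "
            f"{self.n_edges} edges, {self.n_positive} positive)"
        )


def build_network(records: Iterable[BindingRecord]) -> BipartiteNetwork:
    """Build the weighted bipartite network from aggregated, filtered records."""
    return BipartiteNetwork.from_records(records)
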