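"""Synthetic HLA-peptide binding data with planted modules.

The generator emulates the statistical structure the pipeline assumes: a
bipartite allele x peptide graph whose edges concentrate inside planted
modules, binary edge labels whose positive rate is module-dependent (high
within, low across), peptides of mixed lengths dominated by 9-mers with
per-module position-specific residue-category biases at the anchor positions
(P2 and the C-terminal position), and a gapless alignment of groove regions
whose contact residues carry a module signal.  Everything is reproducible
from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from hlanet.profiles import (
    ALIGNED_FIRST_RESIDUE,
    ALIGNED_LAST_RESIDUE,
    DEFAULT_SCHEME,
    AACategoryScheme,
    ContactResidueMap,
)
from hlanet.records import NEGATIVE, POSITIVE, BindingRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Peptide length mixture echoing the length distribution of curated class I
#: ligand data (9-mers dominate, then 10-mers).
DEFAULT_LENGTH_MIX: dict[int, float] = {
    7: 0.001, 8: 0.012, 9: 0.688, 10: 0.263, 11: 0.015, 12: 0.021,
}

#: Per-module anchor biases for 9-mers: position -> (category, strength).
#: Modules differ at P2 and P9, echoing anchor-position preferences.
DEFAULT_CATEGORY_BIAS: dict[int, dict[int, tuple[str, float]]] = {
    1: {2: ("apolar", 0.9), 9: ("apolar", 0.9)},
    2: {2: ("polar_charged", 0.9), 9: ("apolar", 0.9)},
    3: {2: ("apolar", 0.9), 9: ("polar_charged", 0.9)},
}


@dataclass
class GeneratorSpec:
    """Parameters of the planted-module generator.

    ``edge_prob_within``/``edge_prob_between`` control topology density
    inside vs across modules (each peptide is additionally guaranteed at
    least two within-module edges so the default presets pass the degree
    filter unchanged); ``pos_rate_within``/``pos_rate_between`` control the
    label signal.  ``within_mutation_rate`` is the per-residue mutation rate
    of module members away from their founder groove sequence
    (``founder_divergence`` separates founders at non-contact positions;
    contact positions are module-diagnostic by construction).
    """

    n_modules: int = 3
    hlas_per_module: int = 7
    peptides_per_module: int = 200
    edge_prob_within: float = 0.35
    edge_prob_between: float = 0.04
    pos_rate_within: float = 0.99
    pos_rate_between: float = 0.01
    peptide_length_mix: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_MIX)
    )
    category_bias: Mapping[int, Mapping[int, tuple[str, float]]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_CATEGORY_BIAS.items()}
    )
    within_mutation_rate: float = 0.05
    founder_divergence: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edge_prob_within", "edge_prob_between", "pos_rate_within",
                     "pos_rate_between", "within_mutation_rate", "founder_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = sum(self.peptide_length_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError("peptide_length_mix probabilities must sum to 1")

    def with_signal(self, t: float) -> "GeneratorSpec":
        """Anneal the planted label signal: t=1 keeps the spec's positive
        rates, t=0 collapses both to their midpoint (no label signal)."""
        if not 0.0 <= t <= 1.0:
            raise ValueError("t must lie in [0, 1]")
        mid = 0.5 * (self.pos_rate_within + self.pos_rate_between)
        return replace(
            self,
            pos_rate_within=mid + t * (self.pos_rate_within - mid),
            pos_rate_between=mid + t * (self.pos_rate_between - mid),
        )


def benchmark_small(seed: int = 0) -> GeneratorSpec:
    """Desk-scale preset: 3 modules, 21 alleles, 600 peptides."""
    return GeneratorSpec(seed=seed)


def unit_preset(seed: int = 0) -> GeneratorSpec:
    """Tiny preset (2 modules, 4 alleles, 8 peptides) for unit tests."""
    return GeneratorSpec(
        n_modules=2,
        hlas_per_module=2,
        peptides_per_module=4,
        edge_prob_within=0.9,
        edge_prob_between=0.05,
        seed=seed,
    )


def _rng(spec: GeneratorSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))


def hla_name(module_id: int, i: int) -> str:
    """Synthetic allele name for member ``i`` of a module (normalised form)."""
    return f"HLA-A*{70 + module_id}:{i + 1:02d}"


def _draw_peptide(rng: np.random.Generator, spec: GeneratorSpec, module_id: int) -> str:
    lengths = sorted(spec.peptide_length_mix)
    probs = np.array([spec.peptide_length_mix[l] for l in lengths])
    length = int(rng.choice(lengths, p=probs / probs.sum()))
    residues = [AA20[i] for i in rng.integers(0, 20, size=length)]
    if length == 9:
        bias = spec.category_bias.get(module_id, {})
        for pos, (category, strength) in bias.items():
            if rng.random() < strength:
                members = sorted(DEFAULT_SCHEME.members(category))
                residues[pos - 1] = members[int(rng.integers(0, len(members)))]
    return "".join(residues)


def generate_peptides(
    spec: GeneratorSpec, module_id: int, n: int, rng: np.random.Generator | None = None
) -> list[str]:
    """Draw ``n`` peptides with the module's length mix and anchor bias."""
    if rng is None:
        rng = _rng(spec, stream=1000 + module_id)
    return [_draw_peptide(rng, spec, module_id) for _ in range(n)]


def generate_network(spec: GeneratorSpec) -> tuple[list[BindingRecord], dict[str, int]]:
    """Generate planted-module binding records plus the ground-truth labels.

    Returns (records, labels); ``labels`` maps every allele and peptide name
    to its planted module id.  Within-module pairs are connected with
    probability ``edge_prob_within`` and labelled positive with probability
    ``pos_rate_within``; cross-module pairs use the ``_between`` rates.
    Every peptide is topped up to at least two within-module edges (and every
    allele to at least two edges), so the default presets pass the iterative
    degree filter unchanged.
    """
    rng = _rng(spec, stream=1)
    labels: dict[str, int] = {}
    hlas_by_module: dict[int, list[str]] = {}
    peptides_by_module: dict[int, list[str]] = {}
    seen_peptides: set[str] = set()
    for m in range(1, spec.n_modules + 1):
        hlas_by_module[m] = [hla_name(m, i) for i in range(spec.hlas_per_module)]
        for h in hlas_by_module[m]:
            labels[h] = m
        peps = []
        while len(peps) < spec.peptides_per_module:
            p = _draw_peptide(rng, spec, m)
            if p not in seen_peptides:
                seen_peptides.add(p)
                peps.append(p)
                labels[p] = m
        peptides_by_module[m] = peps

    edges: dict[tuple[str, str], bool] = {}

    def add_edge(h: str, p: str, positive_rate: float) -> None:
        edges[(h, p)] = bool(rng.random() < positive_rate)

    for m in range(1, spec.n_modules + 1):
        for p in peptides_by_module[m]:
            within = [h for h in hlas_by_module[m] if rng.random() < spec.edge_prob_within]
            # guarantee >= 2 within-module edges so the 2-core keeps every peptide
            if len(within) < 2:
                pool = [h for h in hlas_by_module[m] if h not in within]
                extra = rng.choice(len(pool), size=2 - len(within), replace=False)
                within += [pool[i] for i in extra]
            for h in within:
                add_edge(h, p, spec.pos_rate_within)
            for m2 in range(1, spec.n_modules + 1):
                if m2 == m:
                    continue
                for h in hlas_by_module[m2]:
                    if rng.random() < spec.edge_prob_between:
                        add_edge(h, p, spec.pos_rate_between)

    # allele top-up (relevant only for sparse custom specs)
    from collections import Counter

    hla_deg = Counter(h for h, _ in edges)
    for m in range(1, spec.n_modules + 1):
        for h in hlas_by_module[m]:
            while hla_deg[h] < 2:
                p = peptides_by_module[m][int(rng.integers(0, len(peptides_by_module[m])))]
                if (h, p) not in edges:
                    add_edge(h, p, spec.pos_rate_within)
                    hla_deg[h] += 1

    records = [
        BindingRecord(hla=h, peptide=p, label=POSITIVE if pos else NEGATIVE)
        for (h, p), pos in sorted(edges.items())
    ]
    return records, labels


def generate_hla_alignment(
    spec: GeneratorSpec,
    contact_map: ContactResidueMap | None = None,
) -> tuple[dict[str, str], ContactResidueMap]:
    """Generate a gapless groove-region alignment with a module signal.

    Each module has a founder sequence; members mutate away from it at
    ``within_mutation_rate`` per residue (contact positions mutate five times
    more slowly, concentrating the module signal there).  Founders share a
    common backbone diverged at rate ``founder_divergence`` at non-contact
    positions and carry module-diagnostic residues at every contact position,
    so with zero mutation the between-module pseudo-sequence identity at
    contact positions is 0.
    """
    if contact_map is None:
        contact_map = ContactResidueMap.default()
    rng = _rng(spec, stream=2)
    width = ALIGNED_LAST_RESIDUE - ALIGNED_FIRST_RESIDUE + 1  # residues 2..182
    contact_cols = {
        r - ALIGNED_FIRST_RESIDUE
        for residues in contact_map.positions.values()
        for r in residues
    }
    backbone = [AA20[i] for i in rng.integers(0, 20, size=width)]
    # module-diagnostic residues: at each contact column, module m gets a
    # distinct residue from a per-column shuffled alphabet
    contact_choice: dict[int, list[str]] = {}
    for col in sorted(contact_cols):
        order = rng.permutation(20)
        contact_choice[col] = [AA20[i] for i in order[: spec.n_modules]]

    alignment: dict[str, str] = {}
    for m in range(1, spec.n_modules + 1):
        founder = list(backbone)
        for col in range(width):
            if col in contact_cols:
                founder[col] = contact_choice[col][m - 1]
            elif rng.random() < spec.founder_divergence:
                founder[col] = AA20[int(rng.integers(0, 20))]
        for i in range(spec.hlas_per_module):
            seq = list(founder)
            for col in range(width):
                rate = spec.within_mutation_rate
                if col in contact_cols:
                    rate /= 5.0
                if rng.random() < rate:
                    alternatives = AA20.replace(seq[col], "")
                    seq[col] = alternatives[int(rng.integers(0, len(alternatives)))]
            alignment[hla_name(m, i)] = "".join(seq)
    return alignment, contact_map


def write_alignment_fasta(alignment: Mapping[str, str], path) -> None:
    """Write the gapless alignment as FASTA, one record per allele."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in alignment.items()]
    seqio_write(records, str(path), "fasta")


def read_alignment_fasta(path) -> dict[str, str]:
    """Read a gapless equal-length FASTA alignment named by allele."""
    from Bio import SeqIO

    out = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    lengths = {len(s) for s in out.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows differ in length (expected gapless equal-length rows)")
    return out


def write_module_truth_tsv(labels: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tmodule_id\n")
        for node, m in sorted(labels.items()):
            fh.write(f"{node}\t{m}\n")
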