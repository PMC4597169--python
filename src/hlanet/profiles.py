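"""Characterisation of the peptides and HLA alleles inside binding modules.

Peptides are profiled by length-bucket counts per module and by per-position
amino-acid category fractions (polar charged / polar uncharged / apolar).
Alleles are profiled through position-specific pseudo-sequences: for each
peptide position, the groove residues known to contact that position are
extracted from the gapless alignment of the peptide-binding region (mature
chain residues 2-182) and concatenated; pairwise identities of these
pseudo-sequences are then compared within vs between modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

POLAR_CHARGED = "polar_charged"
POLAR_UNCHARGED = "polar_uncharged"
APOLAR = "apolar"
CATEGORIES = (POLAR_CHARGED, POLAR_UNCHARGED, APOLAR)

LENGTH_BUCKETS = ("7", "8", "9", "10", "11", ">11")


@dataclass(frozen=True)
class AACategoryScheme:
    """Partition of the 20 standard residues into three physicochemical groups."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.mapping) != set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError("scheme must cover exactly the 20 standard residues")
        if not set(self.mapping.values()) <= set(CATEGORIES):
            raise ValueError(f"categories must be among {CATEGORIES}")

    def category(self, residue: str) -> str:
        return self.mapping[residue]

    def members(self, category: str) -> set[str]:
        return {aa for aa, c in self.mapping.items() if c == category}


#: Default scheme: polar charged (R, D, E, H, K), polar uncharged
#: (N, C, Q, G, S, T, Y) and apolar (A, I, L, M, F, P, W, V).
DEFAULT_SCHEME = AACategoryScheme(
    {
        **{aa: POLAR_CHARGED for aa in "RDEHK"},
        **{aa: POLAR_UNCHARGED for aa in "NCQGSTY"},
        **{aa: APOLAR for aa in "AILMFPWV"},
    }
)


def length_bucket(length: int) -> str:
    """Bucket a peptide length into 7/8/9/10/11/>11."""
    if length <= 6:
        raise ValueError(f"peptide length {length} below the 7-mer bucket")
    return str(length) if length <= 11 else ">11"


@dataclass
class ProfileTable:
    """Per-module peptide counts by length bucket, with column percentages.

    ``counts`` has one row per module (plus HLA counts); ``percent`` gives,
    for each length bucket, each module's share of that bucket's peptides
    (columns sum to 100 over modules).
    """

    counts: pd.DataFrame
    percent: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def length_distribution(partition, network) -> ProfileTable:
    """Tabulate peptides per module and length bucket, plus HLA counts.

    ``partition`` is a :class:`~hlanet.community.ModulePartition` covering
    every peptide node of ``network``.
    """
    modules = sorted(
        set(partition.peptide_modules.values()) | set(partition.hla_modules.values())
    )
    counts = pd.DataFrame(0, index=modules, columns=list(LENGTH_BUCKETS), dtype=int)
    for pep in network.peptide_names:
        m = partition.peptide_modules[pep]
        counts.loc[m, length_bucket(len(pep))] += 1
    counts["Total"] = counts[list(LENGTH_BUCKETS)].sum(axis=1)
    hla_counts = pd.Series(0, index=modules, dtype=int)
    for hla in network.hla_names:
        m = partition.hla_modules.get(hla)
        if m is not None:
            hla_counts[m] += 1
    counts["HLA count"] = hla_counts
    col_sums = counts[list(LENGTH_BUCKETS)].sum(axis=0)
    percent = counts[list(LENGTH_BUCKETS)].astype(float)
    for col in LENGTH_BUCKETS:
        total = col_sums[col]
        percent[col] = 100.0 * counts[col] / total if total else np.nan
    counts.index.name = "module"
    percent.index.name = "module"
    return ProfileTable(counts=counts, percent=percent)


def position_category_profile(
    peptides: Sequence[str],
    length: int,
    scheme: AACategoryScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Per-position fractions of the three residue categories.

    All peptides must have the stated length; rows are positions 1..length,
    columns the categories, each row summing to 1.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("no peptides given")
    for p in peptides:
        if len(p) != length:
            raise ValueError(f"peptide {p!r} does not have length {length}")
    out = pd.DataFrame(0.0, index=range(1, length + 1), columns=list(CATEGORIES))
    for p in peptides:
        for pos, aa in enumerate(p, start=1):
            out.loc[pos, scheme.category(aa)] += 1
    out /= len(peptides)
    out.index.name = "position"
    return out


# -- pseudo-sequences ------------------------------------------------------

#: First mature-chain residue number covered by an alignment row.  Rows span
#: residues 2-182, so 1-based row position i corresponds to residue i+1.
ALIGNED_FIRST_RESIDUE = 2
ALIGNED_LAST_RESIDUE = 182


@dataclass
class ContactResidueMap:
    """Groove residues contacting each peptide position of a 9-mer.

    Maps peptide position (1..9) to a list of 1-based mature-chain residue
    numbers (A*02:01 numbering, as in the class I structure literature).
    """

    positions: Mapping[int, list[int]]

    def __post_init__(self) -> None:
        for pos, residues in self.positions.items():
            if not residues:
                raise ValueError(f"peptide position {pos} has an empty contact list")
            for r in residues:
                if not ALIGNED_FIRST_RESIDUE <= r <= ALIGNED_LAST_RESIDUE:
                    raise ValueError(
                        f"contact residue {r} (peptide position {pos}) outside the "
                        f"aligned region {ALIGNED_FIRST_RESIDUE}-{ALIGNED_LAST_RESIDUE}"
                    )

    def residues(self, peptide_position: int) -> list[int]:
        if peptide_position not in self.positions:
            raise KeyError(f"no contact list for peptide position {peptide_position}")
        return sorted(self.positions[peptide_position])

    @classmethod
    def from_yaml(cls, path) -> "ContactResidueMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({int(k): [int(r) for r in v] for k, v in raw.items()})

    @classmethod
    def default(cls) -> "ContactResidueMap":
        """The packaged contact map (a synthetic reconstruction; see the file
        header in ``data/contact_positions_synthetic.yaml``)."""
        ref = resources.files("hlanet.data") / "contact_positions_synthetic.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


def extract_pseudo_sequence(
    alignment_row: str,
    contact_map: ContactResidueMap,
    peptide_position: int,
) -> str:
    """Concatenate the contact residues for one peptide position.

    ``alignment_row`` is the gapless residue 2-182 region of one allele;
    residues are taken in ascending residue-number order.
    """
    out = []
    for r in contact_map.residues(peptide_position):
        idx = r - ALIGNED_FIRST_RESIDUE
        if idx >= len(alignment_row):
            raise ValueError(f"contact residue {r} beyond alignment row of length {len(alignment_row)}")
        out.append(alignment_row[idx])
    return "".join(out)


def pseudo_sequences(
    alignment: Mapping[str, str],
    contact_map: ContactResidueMap,
    peptide_position: int,
) -> dict[str, str]:
    """Pseudo-sequence of every allele in the alignment for one peptide position."""
    return {
        name: extract_pseudo_sequence(row, contact_map, peptide_position)
        for name, row in alignment.items()
    }


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of matching positions between two equal-length sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    if not seq_a:
        raise ValueError("empty sequences")
    return sum(a == b for a, b in zip(seq_a, seq_b)) / len(seq_a)


def within_between_identity(
    hla_modules: Mapping[str, int],
    sequences: Mapping[str, str],
    test: str = "mannwhitney",
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare pseudo-sequence identities within vs between each module.

    For every module with >= 2 alleles: the mean pairwise identity among its
    members (within), the mean identity of pairs straddling the module
    boundary (between), and a one-sided p-value for within > between — a
    Mann-Whitney rank test by default, or a label-permutation test of the
    mean difference (``test="permutation"``).  Modules with a single allele
    get NaN means and no test; degenerate comparisons (no spread) report NaN.
    """
    if test not in ("mannwhitney", "permutation"):
        raise ValueError("test must be 'mannwhitney' or 'permutation'")
    alleles = [a for a in sequences if a in hla_modules]
    rows = []
    rng = np.random.default_rng(seed)
    for module in sorted(set(hla_modules[a] for a in alleles)):
        members = [a for a in alleles if hla_modules[a] == module]
        others = [a for a in alleles if hla_modules[a] != module]
        within = [
            pairwise_identity(sequences[a], sequences[b]) for a, b in combinations(members, 2)
        ]
        between = [
            pairwise_identity(sequences[a], sequences[b]) for a in members for b in others
        ]
        row = {
            "module": module,
            "n_hla": len(members),
            "n_within_pairs": len(within),
            "n_between_pairs": len(between),
            "within_mean": float(np.mean(within)) if within else np.nan,
            "between_mean": float(np.mean(between)) if between else np.nan,
            "p_value": np.nan,
        }
        if within and between:
            if test == "mannwhitney":
                pooled = within + between
                if len(set(pooled)) > 1:
                    from scipy.stats import mannwhitneyu

                    row["p_value"] = float(
                        mannwhitneyu(within, between, alternative="greater").pvalue
                    )
            else:
                row["p_value"] = _permutation_p(
                    members, others, sequences, rng, n_permutations
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("module")


def _permutation_p(members, others, sequences, rng, n_permutations) -> float:
    """Permutation p-value for mean(within) - mean(between) > 0 under random
    reassignment of module labels among the alleles."""
    alleles = list(members) + list(others)
    k = len(members)

    def diff(mem):
        mem_set = set(mem)
        oth = [a for a in alleles if a not in mem_set]
        w = [pairwise_identity(sequences[a], sequences[b]) for a, b in combinations(mem, 2)]
        b = [pairwise_identity(sequences[a], sequences[x]) for a in mem for x in oth]
        if not w or not b:
            return np.nan
        return np.mean(w) - np.mean(b)

    real = diff(members)
    if np.isnan(real):
        return float("nan")
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(alleles)[:k]
        d = diff(list(perm))
        if not np.isnan(d) and d >= real:
            count += 1
    return (1 + count) / (1 + n_permutations)


def highlight_nonmodal_residues(
    alignment: Mapping[str, str],
    scheme: AACategoryScheme = DEFAULT_SCHEME,
    first_residue_number: int = ALIGNED_FIRST_RESIDUE,
) -> pd.DataFrame:
    """Annotate residues differing from each column's most frequent residue.

    For every alignment column the modal residue (ties broken toward the
    alphabetically smallest) is blanked; every other residue is reported with
    its category.  Columns are numbered as mature-chain residue numbers
    starting at ``first_residue_number``.
    """
    names = list(alignment)
    if not names:
        return pd.DataFrame(columns=["allele", "residue_number", "residue", "category"])
    lengths = {len(alignment[n]) for n in names}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    (width,) = lengths
    rows = []
    for col in range(width):
        residues = [alignment[n][col] for n in names]
        freq: dict[str, int] = {}
        for r in residues:
            freq[r] = freq.get(r, 0) + 1
        best = max(freq.values())
        modal = min(r for r, c in freq.items() if c == best)
        for n, r in zip(names, residues):
            if r != modal:
                rows.append(
                    {
                        "allele": n,
                        "residue_number": col + first_residue_number,
                        "residue": r,
                        "category": scheme.category(r),
                    }
                )
    return pd.DataFrame(rows, columns=["allele", "residue_number", "residue", "category"])
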