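"""Reading, harmonising, aggregating and filtering qualitative binding records.

Raw binding assays come from heterogeneous curated databases (IEDB, SYFPEITHI,
MHCBN, AntiJen) with source-specific grade labels.  This module harmonises the
grades to a binary positive/negative call, collapses duplicate (HLA, peptide)
pairs by majority vote (ties count as positive), and iteratively removes
alleles and peptides supported by fewer than ``min_count`` records, i.e. it
retains the bipartite k-core of the record graph.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

POSITIVE = "positive"
NEGATIVE = "negative"

_SOURCES = ("IEDB", "SYFPEITHI", "MHCBN", "AntiJen", "generic")

# Source label -> binary call.  IEDB's graded positives all count as positive;
# AntiJen's "weak binder" counts as negative.  SYFPEITHI is a ligand database:
# every entry is a positive, whatever the label column says.
_LABEL_MAP: dict[str, dict[str, str]] = {
    "IEDB": {
        "positive-high": POSITIVE,
        "positive-intermediate": POSITIVE,
        "positive-low": POSITIVE,
        "positive": POSITIVE,
        "negative": NEGATIVE,
    },
    "MHCBN": {"positive": POSITIVE, "negative": NEGATIVE},
    "AntiJen": {
        "weak binder": NEGATIVE,
        "weak-binder": NEGATIVE,
        "binder": POSITIVE,
        "positive": POSITIVE,
        "negative": NEGATIVE,
    },
    "generic": {"positive": POSITIVE, "negative": NEGATIVE, "1": NEGATIVE, "2": POSITIVE},
}


class LabelError(ValueError):
    """Raised for a source label that cannot be harmonised."""


@dataclass(frozen=True)
class RawRecord:
    """One raw assay row: allele, peptide and a source-specific label."""

    hla: str
    peptide: str
    label: str
    source: str = "generic"

    def __post_init__(self) -> None:
        if not self.hla:
            raise ValueError("empty HLA allele name")
        if not self.peptide or not set(self.peptide) <= STANDARD_AA:
            raise ValueError(f"peptide {self.peptide!r} is not a standard amino-acid string")


@dataclass(frozen=True)
class BindingRecord:
    """One aggregated (HLA, peptide) pair with a binary consensus label.

    ``positive_fraction`` is the proportion of positives among the raw rows
    aggregated into this record; the label is positive iff it is >= 0.5.
    """

    hla: str
    peptide: str
    label: str
    n_evidence: int = 1
    positive_fraction: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.positive_fraction is None:
            object.__setattr__(self, "positive_fraction", 1.0 if self.label == POSITIVE else 0.0)
        expected = POSITIVE if self.positive_fraction >= 0.5 else NEGATIVE
        if self.label != expected:
            raise ValueError(
                f"label {self.label!r} inconsistent with positive_fraction {self.positive_fraction}"
            )

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE


@dataclass
class DialectConfig:
    """Column names and delimiter of a raw input table."""

    delimiter: str = "\t"
    hla_column: str = "hla"
    peptide_column: str = "peptide"
    label_column: str = "label"
    source_column: str | None = None
    default_source: str = "generic"


_OLD_STYLE = re.compile(r"^([A-Z]+)\*(\d{2})(\d{2}(?::?\d{2})*)$")


def normalize_allele(name: str) -> str:
    """Normalise an allele name to the ``HLA-X*nn:nn`` form (case-insensitive).

    Accepts names with or without the ``HLA-`` prefix and old-style 4-digit
    names without the colon (``A*0201`` -> ``HLA-A*02:01``).
    """
    name = name.strip().upper()
    if not name:
        raise ValueError("empty HLA allele name")
    if name.startswith("HLA-"):
        name = name[4:]
    m = _OLD_STYLE.match(name)
    if m and ":" not in name:
        locus, f1, rest = m.groups()
        fields = [f1] + [rest[i : i + 2] for i in range(0, len(rest), 2)]
        name = locus + "*" + ":".join(fields)
    return "HLA-" + name


def harmonize_label(source_label: str, source: str = "generic") -> str:
    """Map a source-specific grade to ``positive`` or ``negative``."""
    if source not in _SOURCES:
        raise LabelError(f"unknown source {source!r}; accepted: {_SOURCES}")
    if source == "SYFPEITHI":
        return POSITIVE
    table = _LABEL_MAP[source]
    key = source_label.strip().lower()
    if key not in table:
        raise LabelError(
            f"unrecognized label {source_label!r} for source {source}; "
            f"accepted: {sorted(table)}"
        )
    return table[key]


def read_records(path, dialect: DialectConfig | None = None) -> list[RawRecord]:
    """Read raw records from a delimited text file.

    Rows whose peptide contains non-standard residues are rejected with a
    warning carrying the line number; a missing required column is fatal.
    """
    dialect = dialect or DialectConfig()
    out: list[RawRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            logger.warning("%s: empty file", path)
            return out
        required = [dialect.hla_column, dialect.peptide_column, dialect.label_column]
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            hla = (row[dialect.hla_column] or "").strip()
            peptide = (row[dialect.peptide_column] or "").strip().upper()
            label = (row[dialect.label_column] or "").strip()
            source = dialect.default_source
            if dialect.source_column and row.get(dialect.source_column):
                source = row[dialect.source_column].strip()
            if not hla or not peptide:
                logger.warning("%s line %d: empty HLA or peptide, row rejected", path, lineno)
                continue
            if not set(peptide) <= STANDARD_AA:
                bad = sorted(set(peptide) - STANDARD_AA)
                logger.warning(
                    "%s line %d: peptide %r contains non-amino-acid characters %s, row rejected",
                    path, lineno, peptide, bad,
                )
                continue
            out.append(RawRecord(hla=hla, peptide=peptide, label=label, source=source))
    if not out:
        logger.warning("%s: no valid records read", path)
    return out


def aggregate_duplicates(records: Iterable[RawRecord | BindingRecord]) -> list[BindingRecord]:
    """Collapse duplicate (HLA, peptide) pairs by the proportion of positives.

    Labels must already be binary.  A pair is stored as positive when the
    proportion of positives is >= 0.5 (the boundary counts as positive).
    Allele names are normalised and peptides upper-cased before grouping.
    Idempotent: aggregating aggregated records leaves them unchanged.
    """
    pos = Counter()
    tot = Counter()
    for rec in records:
        key = (normalize_allele(rec.hla), rec.peptide.upper())
        if isinstance(rec, BindingRecord):
            weight = rec.n_evidence
            n_pos = round(rec.positive_fraction * rec.n_evidence)
        else:
            if rec.label not in (POSITIVE, NEGATIVE):
                raise LabelError(
                    f"label {rec.label!r} is not binary; harmonize labels before aggregation"
                )
            weight = 1
            n_pos = 1 if rec.label == POSITIVE else 0
        tot[key] += weight
        pos[key] += n_pos
    out = []
    for (hla, peptide), n in sorted(tot.items()):
        frac = pos[(hla, peptide)] / n
        label = POSITIVE if frac >= 0.5 else NEGATIVE
        out.append(
            BindingRecord(hla=hla, peptide=peptide, label=label, n_evidence=n, positive_fraction=frac)
        )
    return out


@dataclass
class FilterReport:
    """Per-iteration removal counts from the iterative degree filter."""

    iterations: list[dict] = field(default_factory=list)

    def add(self, n_hla: int, n_peptide: int, n_records: int) -> None:
        self.iterations.append(
            {"hlas_removed": n_hla, "peptides_removed": n_peptide, "records_removed": n_records}
        )

    def to_text(self) -> str:
        lines = ["iteration\thlas_removed\tpeptides_removed\trecords_removed"]
        for i, it in enumerate(self.iterations, start=1):
            lines.append(f"{i}\t{it['hlas_removed']}\t{it['peptides_removed']}\t{it['records_removed']}")
        return "\n".join(lines) + "\n"


def iterative_degree_filter(
    records: Sequence[BindingRecord],
    min_count: int = 2,
    *,
    with_report: bool = False,
):
    """Iteratively drop alleles and peptides with fewer than ``min_count`` records.

    Removal is repeated until a fixed point: the survivors form the unique
    maximal sub-network in which every HLA and every peptide carries at least
    ``min_count`` binding records (the bipartite k-core, k = ``min_count``).
    The result does not depend on removal order.
    """
    current = list(records)
    report = FilterReport()
    while True:
        hla_deg = Counter(r.hla for r in current)
        pep_deg = Counter(r.peptide for r in current)
        bad_hla = {h for h, d in hla_deg.items() if d < min_count}
        bad_pep = {p for p, d in pep_deg.items() if d < min_count}
        if not bad_hla and not bad_pep:
            break
        kept = [r for r in current if r.hla not in bad_hla and r.peptide not in bad_pep]
        report.add(len(bad_hla), len(bad_pep), len(current) - len(kept))
        current = kept
    if with_report:
        return current, report
    return current


def write_canonical_tsv(records: Sequence[BindingRecord], path) -> None:
    """Write the canonical 3-column table: hla, peptide, label with 2=positive, 1=negative."""
    with open(path, "w") as fh:
        fh.write("hla\tpeptide\tlabel\n")
        for r in records:
            fh.write(f"{r.hla}\t{r.peptide}\t{2 if r.is_positive else 1}\n")


def read_canonical_tsv(path) -> list[BindingRecord]:
    """Read the canonical 3-column table written by :func:`write_canonical_tsv`."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            lab = row["label"].strip()
            if lab not in {"1", "2"}:
                raise ValueError(f"canonical label must be 1 or 2, got {lab!r}")
            out.append(
                BindingRecord(
                    hla=row["hla"].strip(),
                    peptide=row["peptide"].strip().upper(),
                    label=POSITIVE if lab == "2" else NEGATIVE,
                )
            )
    return out
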