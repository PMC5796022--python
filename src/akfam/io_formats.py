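"""Readers and writers for the plain-text formats the pipeline touches.

Everything here is deliberately boring: FASTA via Biopython, tab-separated
tables via pandas, and small dataclasses that validate their own invariants.
The science lives in the downstream modules; this one just refuses to pass
malformed data along.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

GAP = "-"

PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_AMBIG = set("BJXZUO*")
NUCLEOTIDE_CHARS = set("ACGT")
NUCLEOTIDE_AMBIG = set("RYSWKMBDHVN")

#: standard 12-column tabular hit-table layout
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

DOMAIN_CATEGORIES = {"terminus", "kinase", "subdomain", "interdomain", "activation_loop"}

#: the twelve conserved protein-kinase catalytic subdomains
SUBDOMAIN_NAMES = ("I", "II", "III", "IV", "V", "VIA", "VIB", "VII", "VIII", "IX", "X", "XI")
N_SUBDOMAINS = 12
N_INTERDOMAINS = 11


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """One FASTA record; ``residues`` may contain '-' only inside alignments."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} has empty residues")

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


def _alphabet_sets(alphabet: str) -> tuple[set, set]:
    if alphabet == "protein":
        return PROTEIN_CHARS, PROTEIN_AMBIG
    if alphabet == "nucleotide":
        return NUCLEOTIDE_CHARS, NUCLEOTIDE_AMBIG
    raise ValueError(f"unknown alphabet {alphabet!r}")


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file, upper-casing residues and enforcing unique ids.

    Ambiguity codes (N, X, ...) are accepted but reported with a warning;
    any character outside the alphabet, its ambiguity codes and '-' is an
    error.
    """
    core, ambig = _alphabet_sets(alphabet)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    flagged: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        chars = set(residues)
        bad = chars - core - ambig - {GAP}
        if bad:
            raise FormatError(
                f"record {rec.id!r}: characters {sorted(bad)} outside the "
                f"{alphabet} alphabet"
            )
        if chars & ambig:
            flagged.append(rec.id)
        records.append(SequenceRecord(rec.id, rec.description, residues))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if flagged:
        warnings.warn(
            f"{len(flagged)} record(s) contain ambiguity codes: "
            + ", ".join(flagged[:5]) + ("..." if len(flagged) > 5 else "")
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


@dataclass
class HitRecord:
    """One row of a tabular homology-search hit table."""

    query_id: str
    subject_id: str
    percent_identity: float
    query_coverage: float | None
    bitscore: float
    evalue: float
    subject_species: str | None = None
    subject_description: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise FormatError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.query_coverage is not None and not 0.0 <= self.query_coverage <= 100.0:
            raise FormatError(f"query_coverage {self.query_coverage} outside [0, 100]")
        if self.evalue < 0:
            raise FormatError(f"negative evalue {self.evalue}")
        if self.bitscore < 0:
            raise FormatError(f"negative bitscore {self.bitscore}")


def _parse_float(raw: str, row: int, column: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise FormatError(f"row {row}: non-numeric {column} {raw!r}") from None


def read_hit_table(
    path: str | Path,
    has_coverage_column: bool = True,
    coverage_column: int = 13,
) -> list[HitRecord]:
    """Read a tab-separated 12-column hit table, optionally with a query-
    coverage column (1-based index ``coverage_column``, default 13)."""
    try:
        # na_filter off: ids like "null" or "NA" are real identifiers here
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#",
                         na_filter=False)
    except pd.errors.EmptyDataError:
        return []
    n_cols = df.shape[1]
    if n_cols < 12:
        raise FormatError(f"{path}: expected >= 12 tab-separated columns, found {n_cols}")
    if has_coverage_column and n_cols < coverage_column:
        raise FormatError(
            f"{path}: coverage column {coverage_column} requested but table has "
            f"{n_cols} columns"
        )
    hits: list[HitRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        cov = None
        if has_coverage_column:
            cov = _parse_float(row[coverage_column - 1], i, "query_coverage")
        hits.append(
            HitRecord(
                query_id=str(row[0]),
                subject_id=str(row[1]),
                percent_identity=_parse_float(row[2], i, "percent_identity"),
                query_coverage=cov,
                bitscore=_parse_float(row[11], i, "bitscore"),
                evalue=_parse_float(row[10], i, "evalue"),
            )
        )
    return hits


def write_hit_table(hits: Sequence[HitRecord], path: str | Path) -> None:
    """Write hits in the 12-column layout plus query coverage as column 13.

    Columns the HitRecord does not model (alignment coordinates etc.) are
    written as zeros so the table round-trips through :func:`read_hit_table`.
    """
    with open(path, "w") as fh:
        for h in hits:
            cells = [
                h.query_id, h.subject_id, repr(h.percent_identity),
                "0", "0", "0", "0", "0", "0", "0",
                repr(h.evalue), repr(h.bitscore),
            ]
            if h.query_coverage is not None:
                cells.append(repr(h.query_coverage))
            fh.write("\t".join(cells) + "\n")


_ORGANISM_RE = re.compile(r"\[([^\[\]]+)\]\s*$")


def parse_species(description: str) -> str | None:
    """Extract the bracketed organism field from a sequence description."""
    m = _ORGANISM_RE.search(description)
    return m.group(1) if m else None


def read_species_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping sequence/subject id -> species name."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#",
                     na_filter=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: species map needs two tab-separated columns")
    return dict(zip(df[0], df[1]))


@dataclass(frozen=True)
class Region:
    name: str
    start: int  # 1-based inclusive codon coordinate on the reference
    end: int
    category: str


@dataclass
class DomainMap:
    """Named regions in 1-based codon coordinates on one reference sequence.

    Regions within a category must not overlap; categories themselves may
    (the kinase domain contains the subdomains, interdomains and activation
    loop)."""

    reference_id: str
    regions: list[Region] = field(default_factory=list)
    strict: bool = True

    def __post_init__(self) -> None:
        for r in self.regions:
            if r.category not in DOMAIN_CATEGORIES:
                raise FormatError(f"region {r.name!r}: unknown category {r.category!r}")
            if r.start < 1:
                raise FormatError(f"region {r.name!r}: start {r.start} < 1")
            if r.start > r.end:
                raise FormatError(f"region {r.name!r}: start {r.start} > end {r.end}")
        by_cat: dict[str, list[Region]] = {}
        for r in self.regions:
            by_cat.setdefault(r.category, []).append(r)
        for cat, regs in by_cat.items():
            regs.sort(key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start <= a.end:
                    raise FormatError(
                        f"regions {a.name!r} and {b.name!r} overlap within "
                        f"category {cat!r}"
                    )
        # keep regions sorted by start within category, categories in input order
        order = {c: i for i, c in enumerate(dict.fromkeys(r.category for r in self.regions))}
        self.regions = sorted(self.regions, key=lambda r: (order[r.category], r.start))
        if self.strict:
            n_sub = len(by_cat.get("subdomain", []))
            if n_sub and n_sub != N_SUBDOMAINS:
                warnings.warn(
                    f"domain map lists {n_sub} kinase subdomains; the canonical "
                    f"catalytic domain has {N_SUBDOMAINS}"
                )
            n_inter = len(by_cat.get("interdomain", []))
            if n_inter and n_inter != N_INTERDOMAINS:
                warnings.warn(
                    f"domain map lists {n_inter} interdomains; {N_INTERDOMAINS} "
                    f"separate the canonical subdomains"
                )

    def by_category(self, category: str) -> list[Region]:
        return [r for r in self.regions if r.category == category]

    def __iter__(self):
        return iter(self.regions)


def read_domain_map(
    path: str | Path, reference_id: str | None = None, strict: bool = True
) -> DomainMap:
    """Read a TSV domain map with columns name, start, end, category.

    The reference sequence id may be given as a ``#reference=<id>`` comment
    line in the file or via the ``reference_id`` argument (which wins)."""
    ref_from_file = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#reference="):
                ref_from_file = line.strip().split("=", 1)[1]
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"name", "start", "end", "category"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: domain map missing columns {sorted(missing)}")
    ref = reference_id or ref_from_file or ""
    regions = [
        Region(str(row["name"]), int(row["start"]), int(row["end"]), str(row["category"]))
        for _, row in df.iterrows()
    ]
    return DomainMap(reference_id=ref, regions=regions, strict=strict)


def write_domain_map(dm: DomainMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        if dm.reference_id:
            fh.write(f"#reference={dm.reference_id}\n")
        fh.write("name\tstart\tend\tcategory\n")
        for r in dm.regions:
            fh.write(f"{r.name}\t{r.start}\t{r.end}\t{r.category}\n")


@dataclass
class IdentityMatrix:
    """Square percent-identity matrix; rows are queries, columns subjects.

    Query/subject asymmetry is allowed, so the matrix is not required to be
    symmetric; the diagonal must be 100 (self identity)."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise FormatError(
                f"identity matrix shape {self.values.shape} does not match "
                f"{n} ids"
            )
        if len(set(self.ids)) != n:
            raise FormatError("duplicate ids in identity matrix")
        if not np.allclose(np.diag(self.values), 100.0, atol=1e-6):
            raise FormatError("identity-matrix diagonal must be 100 (self identity)")
        if self.values.min() < -1e-9 or self.values.max() > 100.0 + 1e-9:
            raise FormatError("identity values outside [0, 100]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def read_identity_matrix(path: str | Path) -> IdentityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column ids differ")
    return IdentityMatrix(ids=[str(i) for i in df.index], values=df.to_numpy(dtype=float))


def write_identity_matrix(m: IdentityMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
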