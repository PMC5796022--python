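"""Codon-aware alignment projection.

A protein multiple alignment is used as a template to insert whole-codon
gaps into the matching unaligned coding sequences, yielding an in-frame
codon alignment in which every protein gap is '---' and every residue is
backed by its source codon. Translation of the projected rows must
reproduce the protein alignment exactly; any disagreement is reported with
its residue position rather than silently propagated, since a single
frameshift would corrupt every downstream substitution count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

from Bio.Data import CodonTable

from .io_formats import GAP, NUCLEOTIDE_CHARS, SequenceRecord

GAP_CODON = "---"


class ProjectionError(ValueError):
    """Protein alignment and coding sequence disagree."""


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 1) -> dict[str, str]:
    """Codon -> amino-acid map for an NCBI translation table; stop codons
    map to '*'."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


@lru_cache(maxsize=None)
def stop_codons(table_id: int = 1) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)


@lru_cache(maxsize=None)
def sense_codons(table_id: int = 1) -> tuple[str, ...]:
    return tuple(sorted(CodonTable.unambiguous_dna_by_id[table_id].forward_table))


def translate_codon(codon: str, table_id: int = 1) -> str:
    """Translate one codon; '---' -> '-', any ambiguity -> 'X'."""
    if codon == GAP_CODON:
        return GAP
    if GAP in codon:
        raise ProjectionError(f"half-gapped codon {codon!r}")
    if set(codon) - NUCLEOTIDE_CHARS:
        return "X"
    return genetic_code(table_id)[codon]


def translate_row(row: str, table_id: int = 1) -> str:
    """Translate a gapped nucleotide row codon by codon."""
    if len(row) % 3:
        raise ProjectionError(f"row length {len(row)} not divisible by 3")
    return "".join(translate_codon(row[i : i + 3], table_id) for i in range(0, len(row), 3))


@dataclass
class CodonAlignment:
    """Aligned coding sequences kept in frame: equal-length gapped rows,
    column count divisible by 3, gaps only as whole '---' codons."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids")
        if not self.rows:
            raise ValueError("empty alignment")
        L = len(self.rows[0])
        if L % 3:
            raise ValueError(f"alignment length {L} not divisible by 3")
        for rid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise ValueError(f"row {rid!r} length {len(row)} != {L}")
            for k in range(0, L, 3):
                codon = row[k : k + 3]
                if GAP in codon and codon != GAP_CODON:
                    raise ValueError(
                        f"row {rid!r}: partial gap in codon column {k // 3 + 1}"
                    )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def codon_columns(self) -> int:
        return len(self.rows[0]) // 3

    def row(self, rid: str) -> str:
        try:
            return self.rows[self.ids.index(rid)]
        except ValueError:
            raise KeyError(f"no row with id {rid!r}") from None

    def codon(self, row_index: int, codon_column: int) -> str:
        """Codon at a 0-based row index and 0-based codon column."""
        return self.rows[row_index][3 * codon_column : 3 * codon_column + 3]

    def row_codons(self, row_index: int) -> list[str]:
        r = self.rows[row_index]
        return [r[k : k + 3] for k in range(0, len(r), 3)]

    def subset(self, ids: Sequence[str]) -> "CodonAlignment":
        missing = [i for i in ids if i not in self.ids]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return CodonAlignment(list(ids), [self.row(i) for i in ids])

    def to_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(i, i, r) for i, r in zip(self.ids, self.rows)]

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord]) -> "CodonAlignment":
        return cls([r.id for r in records], [r.residues for r in records])


def _trim_terminal_stop(cds: str, n_residues: int, table_id: int) -> str:
    """Drop a trailing stop codon when the CDS is exactly one codon longer
    than the protein."""
    if len(cds) % 3:
        raise ProjectionError(f"coding sequence length {len(cds)} not divisible by 3")
    n_codons = len(cds) // 3
    if n_codons == n_residues + 1 and cds[-3:] in stop_codons(table_id):
        return cds[:-3]
    return cds


def project_gaps(
    protein_aln: Sequence[SequenceRecord],
    cds: Mapping[str, str],
    table_id: int = 1,
    max_mismatches: int = 0,
) -> CodonAlignment:
    """Insert whole-codon gaps into coding sequences guided by a protein
    alignment.

    Each aligned residue is replaced by its source codon, each protein gap
    by '---'. Terminal stop codons on the CDS are trimmed. By default any
    translation disagreement is an error naming the residue; setting
    ``max_mismatches`` tolerates up to that many (the codon from the CDS
    wins, with a warning) for real-world annotation noise.
    """
    ids, rows = [], []
    for rec in protein_aln:
        if rec.id not in cds:
            raise ProjectionError(f"no coding sequence for aligned id {rec.id!r}")
        protein = rec.residues.upper()
        ungapped = protein.replace(GAP, "")
        nt = cds[rec.id].upper().replace(GAP, "")
        nt = _trim_terminal_stop(nt, len(ungapped), table_id)
        if len(nt) != 3 * len(ungapped):
            raise ProjectionError(
                f"{rec.id!r}: coding length {len(nt)} nt does not match "
                f"{len(ungapped)} aligned residues (x3 = {3 * len(ungapped)})"
            )
        mismatches = 0
        out = []
        k = 0  # codon cursor into nt
        for col, aa in enumerate(protein):
            if aa == GAP:
                out.append(GAP_CODON)
                continue
            codon = nt[3 * k : 3 * k + 3]
            k += 1
            trans = translate_codon(codon, table_id)
            if trans == "*":
                raise ProjectionError(
                    f"{rec.id!r}: internal stop codon {codon} at residue {k}"
                )
            if trans != aa and not (trans == "X" or aa == "X"):
                mismatches += 1
                if mismatches > max_mismatches:
                    raise ProjectionError(
                        f"{rec.id!r}: codon {codon} translates to {trans!r} but the "
                        f"alignment has {aa!r} at residue {k} (column {col + 1})"
                    )
                warnings.warn(
                    f"{rec.id}: translation mismatch at residue {k} "
                    f"({codon}->{trans!r} vs {aa!r}); keeping the codon"
                )
            out.append(codon)
        ids.append(rec.id)
        rows.append("".join(out))
    return CodonAlignment(ids, rows)
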