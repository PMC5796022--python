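"""Homolog screening: threshold filtering, per-species deduplication and
cross-query merging of homology-search hit tables, plus the sequence
completeness criterion used before rate analysis.

All threshold comparisons are inclusive (>= / <=): a hit sitting exactly on
every boundary is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import HitRecord, SequenceRecord


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusive filtering thresholds for homology hits.

    Defaults are the screen used to assemble the kinase family: identity
    >= 40%, query coverage >= 50%, bit-score >= 250 bits, E-value <= 1e-3.
    ``min_completeness`` is the fraction of the reference coding length a
    sequence must cover to enter rate analysis (0.95)."""

    min_identity: float = 40.0
    min_coverage: float = 50.0
    min_bitscore: float = 250.0
    max_evalue: float = 1e-3
    min_completeness: float = 0.95

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage", "min_bitscore", "max_evalue"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{name} must be finite, got {v}")
        if not 0.0 <= self.min_completeness <= 1.0:
            raise ValueError("min_completeness must lie in [0, 1]")


def filter_hits(hits: Sequence[HitRecord], t: FilterThresholds | None = None) -> list[HitRecord]:
    """Keep exactly the hits passing all four thresholds, in input order."""
    t = t or FilterThresholds()
    kept = []
    for h in hits:
        if h.query_coverage is None:
            raise ValueError(
                f"hit {h.query_id}->{h.subject_id} has no query coverage; "
                "read the table with a coverage column"
            )
        if (
            h.percent_identity >= t.min_identity
            and h.query_coverage >= t.min_coverage
            and h.bitscore >= t.min_bitscore
            and h.evalue <= t.max_evalue
        ):
            kept.append(h)
    return kept


def dedupe_by_species(hits: Sequence[HitRecord]) -> list[HitRecord]:
    """Keep one hit per (query, species): highest bitscore, ties broken by
    lexicographically smallest subject_id. Output preserves input order of
    the surviving hits."""
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        if h.subject_species is None:
            raise ValueError(
                f"hit {h.query_id}->{h.subject_id} has no subject_species; "
                "supply a species map or parse descriptions first"
            )
        key = (h.query_id, h.subject_species)
        cur = best.get(key)
        if cur is None or (h.bitscore, _neg(h.subject_id)) > (cur.bitscore, _neg(cur.subject_id)):
            best[key] = h
    winners = set(map(id, best.values()))
    return [h for h in hits if id(h) in winners]


class _neg(str):
    """Inverts string comparison so max() prefers the lexicographically
    smallest subject_id on bitscore ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def merge_queries(per_query_hits: Mapping[str, Sequence[HitRecord]]) -> list[HitRecord]:
    """Union hit lists from several queries, one entry per subject_id.

    A subject hit by multiple queries keeps its highest-bitscore record
    (ties: lexicographically smallest query_id). Output sorted by
    subject_id for determinism."""
    best: dict[str, HitRecord] = {}
    for query in sorted(per_query_hits):
        for h in per_query_hits[query]:
            cur = best.get(h.subject_id)
            if cur is None or h.bitscore > cur.bitscore:
                best[h.subject_id] = h
    return [best[s] for s in sorted(best)]


def attach_species(
    hits: Sequence[HitRecord], species_map: Mapping[str, str] | None = None
) -> list[HitRecord]:
    """Fill subject_species from the bracketed organism field of the
    description, falling back to an explicit id->species mapping."""
    from .io_formats import parse_species
    from dataclasses import replace

    out = []
    for h in hits:
        sp = h.subject_species or parse_species(h.subject_description)
        if sp is None and species_map is not None:
            sp = species_map.get(h.subject_id)
        out.append(replace(h, subject_species=sp))
    return out


def apply_blocklist(hits: Sequence[HitRecord], keywords: Iterable[str]) -> list[HitRecord]:
    """Drop hits whose subject id or description contains any keyword
    (case-insensitive). Used to strip fusion-vector and artifact entries;
    the keyword list comes from configuration, not from code."""
    kws = [k.lower() for k in keywords]
    return [
        h
        for h in hits
        if not any(k in h.subject_id.lower() or k in h.subject_description.lower() for k in kws)
    ]


def filter_by_completeness(
    records: Sequence[SequenceRecord],
    reference_id: str,
    min_completeness: float = 0.95,
    unit: str = "codon",
) -> list[SequenceRecord]:
    """Keep coding sequences covering at least ``min_completeness`` of the
    reference's ungapped length. Lengths are measured in codons for
    nucleotide records (``unit='codon'``) or residues (``unit='residue'``)."""
    ref = next((r for r in records if r.id == reference_id), None)
    if ref is None:
        raise ValueError(f"reference {reference_id!r} not among records")
    div = 3 if unit == "codon" else 1
    ref_len = len(ref.ungapped) / div
    return [r for r in records if len(r.ungapped) / div >= min_completeness * ref_len]
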