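"""Pairwise dN/dS by Nei-Gojobori (1986) counting with Jukes-Cantor
correction.

The method splits every codon position into fractional synonymous and
nonsynonymous "sites" (the fraction of single-nucleotide changes at that
position that preserve the amino acid, mutational paths through stop codons
excluded and the remainder renormalized so each codon always contributes
exactly three sites). Observed differences between two codons are resolved
by enumerating every order in which the differing positions could have
changed, discarding orders that pass through a stop codon, and averaging
the synonymous/nonsynonymous step counts over the remaining orders.

Proportions pS = Sd/S and pN = Nd/N are then corrected for multiple hits
with the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p), which diverges at
p = 3/4 (saturation). omega = dN/dS measures selection: < 1 purifying,
~ 1 neutral, > 1 diversifying.

Columns where either sequence has a gap, an ambiguous base or a stop codon
are excluded pair by pair (pairwise deletion), so every pair uses the
maximum of its own comparable data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codon_align import CodonAlignment, genetic_code, stop_codons
from .io_formats import GAP, NUCLEOTIDE_CHARS

BASES = "ACGT"

#: how a defined-dN, zero-dS pair reports omega: dropped from summaries
#: (flagged) or reported as infinity
ZERO_DS_POLICIES = ("drop", "inf")


@dataclass(frozen=True)
class CodonPairCounts:
    """NG86 quantities for one sequence pair over a set of codon columns.

    S and N are fractional synonymous/nonsynonymous site counts (averaged
    over the two sequences), Sd and Nd pathway-averaged difference counts.
    S + N always equals 3 x compared_codons."""

    S: float
    N: float
    Sd: float
    Nd: float
    compared_codons: int

    def __add__(self, other: "CodonPairCounts") -> "CodonPairCounts":
        return CodonPairCounts(
            self.S + other.S,
            self.N + other.N,
            self.Sd + other.Sd,
            self.Nd + other.Nd,
            self.compared_codons + other.compared_codons,
        )


@dataclass(frozen=True)
class RateEstimate:
    """Jukes-Cantor-corrected substitution rates for one pair.

    Undefined quantities are ``nan`` with an explanatory flag:
    ``both_zero`` (identical sequences), ``dS_zero`` (nonsynonymous change
    without synonymous change: omega undefined/infinite), ``dN_zero``,
    ``saturated_S``/``saturated_N`` (proportion >= 3/4, correction
    diverges), ``insufficient_data`` (no comparable columns)."""

    pS: float
    pN: float
    dS: float
    dN: float
    omega: float
    flags: frozenset[str]

    @property
    def ok(self) -> bool:
        return "ok" in self.flags


def is_valid_codon(codon: str, table_id: int = 1) -> bool:
    """Ungapped, unambiguous and stop-free: usable for NG86 counting."""
    return (
        len(codon) == 3
        and not set(codon) - NUCLEOTIDE_CHARS
        and codon not in stop_codons(table_id)
    )


@lru_cache(maxsize=None)
def codon_sites(codon: str, table_id: int = 1) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Per position the synonymous fraction is the number of synonymous
    single-nucleotide changes divided by the number of changes not creating
    a stop codon; s is the sum over the three positions and n = 3 - s, so
    s + n = 3 exactly."""
    if not is_valid_codon(codon, table_id):
        raise ValueError(f"codon {codon!r} is gapped, ambiguous or a stop codon")
    code = genetic_code(table_id)
    stops = stop_codons(table_id)
    aa = code[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        viable = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in stops:
                continue
            viable += 1
            if code[alt] == aa:
                syn += 1
        if viable:
            s += syn / viable
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_differences(a: str, b: str, table_id: int = 1) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two
    codons.

    All orderings of the differing positions are enumerated; orderings
    whose intermediate codons are stops are excluded and the average taken
    over the rest. If every ordering is blocked, all are used with
    stop-involving steps counted as nonsynonymous."""
    for c in (a, b):
        if not is_valid_codon(c, table_id):
            raise ValueError(f"codon {c!r} is gapped, ambiguous or a stop codon")
    code = genetic_code(table_id)
    stops = stop_codons(table_id)
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        sd = nd = 0.0
        cur = a
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in stops and nxt != b:
                if not allow_stops:
                    return None
                nd += 1.0  # step through a stop: count nonsynonymous
            elif cur in stops:
                nd += 1.0
            elif code[cur] == code[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    orders = list(itertools.permutations(diff))
    results = [r for r in (walk(o, allow_stops=False) for o in orders) if r is not None]
    if not results:
        results = [walk(o, allow_stops=True) for o in orders]  # type: ignore[list-item]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - (4/3) p); nan at/after saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError(f"proportion {p} < 0")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class PairColumnStats:
    """Per-codon-column NG86 quantities for one pair, used for windowed and
    region-restricted estimates without recounting."""

    valid: np.ndarray  # bool, column comparable for this pair
    sites_s: np.ndarray  # (s_x + s_y) / 2 per column, 0 where invalid
    sd: np.ndarray
    nd: np.ndarray

    def counts(self, columns: Sequence[int] | None = None) -> CodonPairCounts:
        idx = np.arange(self.valid.size) if columns is None else np.asarray(columns, dtype=int)
        v = self.valid[idx]
        compared = int(v.sum())
        S = float(self.sites_s[idx].sum())
        return CodonPairCounts(
            S=S,
            N=3.0 * compared - S,
            Sd=float(self.sd[idx].sum()),
            Nd=float(self.nd[idx].sum()),
            compared_codons=compared,
        )


def pair_column_stats(x: str, y: str, table_id: int = 1) -> PairColumnStats:
    """Columnwise NG86 quantities for two equal-length gapped codon rows."""
    if len(x) != len(y):
        raise ValueError("rows differ in length")
    if len(x) % 3:
        raise ValueError("row length not divisible by 3")
    L = len(x) // 3
    valid = np.zeros(L, dtype=bool)
    sites_s = np.zeros(L)
    sd = np.zeros(L)
    nd = np.zeros(L)
    for k in range(L):
        cx = x[3 * k : 3 * k + 3]
        cy = y[3 * k : 3 * k + 3]
        if not (is_valid_codon(cx, table_id) and is_valid_codon(cy, table_id)):
            continue
        valid[k] = True
        sx, _ = codon_sites(cx, table_id)
        sy, _ = codon_sites(cy, table_id)
        sites_s[k] = (sx + sy) / 2.0
        sd[k], nd[k] = pathway_differences(cx, cy, table_id)
    return PairColumnStats(valid, sites_s, sd, nd)


def estimate_from_counts(
    counts: CodonPairCounts, zero_ds_policy: str = "drop"
) -> RateEstimate:
    """Turn NG86 counts into Jukes-Cantor-corrected rates with flags."""
    if zero_ds_policy not in ZERO_DS_POLICIES:
        raise ValueError(f"zero_ds_policy must be one of {ZERO_DS_POLICIES}")
    nan = math.nan
    if counts.compared_codons == 0:
        return RateEstimate(nan, nan, nan, nan, nan, frozenset({"insufficient_data"}))
    flags: set[str] = set()
    pS = counts.Sd / counts.S if counts.S > 0 else 0.0
    pN = counts.Nd / counts.N if counts.N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    if math.isnan(dS):
        flags.add("saturated_S")
    if math.isnan(dN):
        flags.add("saturated_N")
    omega = nan
    if not flags:
        if dS > 0:
            omega = dN / dS
            flags.add("ok" if dN > 0 else "dN_zero")
        elif dN == 0:
            flags.add("both_zero")
        else:
            flags.add("dS_zero")
            if zero_ds_policy == "inf":
                omega = math.inf
    return RateEstimate(pS, pN, dS, dN, omega, frozenset(flags))


def pairwise_dnds(
    x: str,
    y: str,
    columns: Sequence[int] | None = None,
    table_id: int = 1,
    zero_ds_policy: str = "drop",
) -> tuple[RateEstimate, CodonPairCounts]:
    """NG86 + Jukes-Cantor dN/dS for two gapped codon rows, optionally
    restricted to a 0-based codon-column subset."""
    counts = pair_column_stats(x, y, table_id).counts(columns)
    return estimate_from_counts(counts, zero_ds_policy), counts


RATE_TABLE_COLUMNS = [
    "id_a", "id_b", "compared_codons", "S", "N", "Sd", "Nd",
    "pS", "pN", "dS", "dN", "omega", "flags",
]


def all_pairs_dnds(
    aln: CodonAlignment,
    columns: Sequence[int] | None = None,
    pairs: Iterable[tuple[str, str]] | None = None,
    table_id: int = 1,
    zero_ds_policy: str = "drop",
) -> pd.DataFrame:
    """Rate estimates for every unordered pair of rows (or a given pair
    list), ordered lexicographically by (id_a, id_b) with id_a < id_b."""
    if pairs is None:
        if aln.n_rows < 2:
            raise ValueError("need at least two rows")
        pairs = itertools.combinations(sorted(aln.ids), 2)
    norm = sorted(tuple(sorted(p)) for p in pairs)
    records = []
    for id_a, id_b in norm:
        est, counts = pairwise_dnds(
            aln.row(id_a), aln.row(id_b), columns, table_id, zero_ds_policy
        )
        records.append(
            {
                "id_a": id_a,
                "id_b": id_b,
                "compared_codons": counts.compared_codons,
                "S": counts.S,
                "N": counts.N,
                "Sd": counts.Sd,
                "Nd": counts.Nd,
                "pS": est.pS,
                "pN": est.pN,
                "dS": est.dS,
                "dN": est.dN,
                "omega": est.omega,
                "flags": ";".join(sorted(est.flags)),
            }
        )
    return pd.DataFrame.from_records(records, columns=RATE_TABLE_COLUMNS)
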