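"""Synthetic test data with known truth.

Three generators cover the pipeline's inputs:

* ``simulate_family`` evolves a family of coding sequences from a random
  stop-free ancestor on a star phylogeny under region-specific selection
  intensity omega. Mutation proposals arrive per nucleotide site as a
  Poisson(mu) count per branch, the target base uniform over the three
  alternatives; proposals creating a stop codon are rejected, synonymous
  proposals are accepted, and nonsynonymous ones with probability
  min(omega, 1). Diversifying selection (omega > 1) is modeled by instead
  suppressing synonymous acceptance to 1/omega, so acceptance stays a
  probability; recovery tests must therefore compare against realized, not
  nominal, omega. Accepted substitutions are recorded per taxon and region
  as a truth table. No indels are simulated, so the family is born aligned.

* ``make_identity_fixture`` plants block structure (isoform-like clusters)
  in a percent-identity matrix with Gaussian jitter.

* ``make_hit_fixture`` builds hit tables with a known number of rows
  passing the identity/coverage/bitscore/E-value screen, including rows
  sitting exactly on the inclusive boundaries.

Everything is a pure function of its spec and seed: the same seed gives
byte-identical output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .codon_align import CodonAlignment, genetic_code, sense_codons, stop_codons
from .io_formats import GAP, HitRecord, IdentityMatrix, SequenceRecord
from .ng86 import codon_sites

BASES = "ACGT"


@dataclass(frozen=True)
class RegionOmega:
    """One simulated region: 1-based inclusive codon interval and its
    selection intensity."""

    name: str
    start: int
    end: int
    omega: float

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError(f"region {self.name!r}: omega must be >= 0")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"region {self.name!r}: bad interval ({self.start}, {self.end})")


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one simulated family.

    ``mu`` is the expected number of proposed point mutations per
    nucleotide site per branch; with neutral synonymous acceptance the
    realized pairwise dS on a star tree is about 2 * mu."""

    n_taxa: int
    length: int  # codons
    regions: tuple[RegionOmega, ...]
    mu: float
    table_id: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("need at least one taxon")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        covered = sorted((r.start, r.end) for r in self.regions)
        if not covered or covered[0][0] != 1 or covered[-1][1] != self.length:
            raise ValueError("regions must tile [1, length]")
        for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
            if s2 != e1 + 1:
                raise ValueError("regions must tile [1, length] without gaps or overlaps")

    @staticmethod
    def uniform(n_taxa: int, length: int, omega: float, mu: float, seed: int = 0,
                table_id: int = 1) -> "SimulationSpec":
        return SimulationSpec(
            n_taxa=n_taxa, length=length,
            regions=(RegionOmega("whole", 1, length, omega),),
            mu=mu, table_id=table_id, seed=seed,
        )


@dataclass
class FamilyTruth:
    """Realized substitution counts: one row per (taxon, region) with
    accepted synonymous/nonsynonymous counts, plus the ancestor's NG86 site
    totals per region (enough to compute realized per-region, per-pair
    rates without re-tracing the simulation)."""

    counts: pd.DataFrame  # taxon, region, syn_subs, nonsyn_subs
    region_sites: pd.DataFrame  # region, start, end, omega, S_sites, N_sites

    def realized_rates(self, taxon_a: str, taxon_b: str, region: str) -> tuple[float, float, float]:
        """Realized (dS, dN, omega) for one pair over one region: accepted
        substitutions on both branches divided by ancestor site counts."""
        c = self.counts
        rows = c[(c["region"] == region) & c["taxon"].isin([taxon_a, taxon_b])]
        if len(rows) != 2:
            raise KeyError(f"no counts for pair ({taxon_a}, {taxon_b}) in region {region!r}")
        site = self.region_sites.set_index("region").loc[region]
        ds = rows["syn_subs"].sum() / site["S_sites"]
        dn = rows["nonsyn_subs"].sum() / site["N_sites"]
        omega = dn / ds if ds > 0 else np.nan
        return float(ds), float(dn), float(omega)


@dataclass
class SimulatedFamily:
    spec: SimulationSpec
    ancestor: str  # ungapped codon string
    alignment: CodonAlignment
    truth: FamilyTruth


def _region_of(spec: SimulationSpec) -> list[RegionOmega]:
    """Per-codon region lookup (0-based codon index -> RegionOmega)."""
    lookup: list[RegionOmega] = [None] * spec.length  # type: ignore[list-item]
    for r in spec.regions:
        for k in range(r.start - 1, r.end):
            lookup[k] = r
    return lookup


def simulate_family(spec: SimulationSpec) -> SimulatedFamily:
    """Evolve a family under region-specific omega on a star tree."""
    rng = np.random.default_rng(spec.seed)
    code = genetic_code(spec.table_id)
    stops = stop_codons(spec.table_id)
    sense = sense_codons(spec.table_id)
    region_lookup = _region_of(spec)

    ancestor_codons = [sense[i] for i in rng.integers(0, len(sense), size=spec.length)]
    ancestor = "".join(ancestor_codons)

    ids = [f"t{i + 1}" for i in range(spec.n_taxa)]
    rows: list[str] = []
    records = []
    n_sites = 3 * spec.length
    for taxon in ids:
        codons = list(ancestor_codons)
        accepted = {r.name: [0, 0] for r in spec.regions}  # [syn, nonsyn]
        proposals = rng.poisson(spec.mu, size=n_sites)
        for site in np.flatnonzero(proposals):
            k, pos = divmod(int(site), 3)
            region = region_lookup[k]
            for _ in range(int(proposals[site])):
                cur = codons[k]
                base = cur[pos]
                alts = [b for b in BASES if b != base]
                target = alts[int(rng.integers(0, 3))]
                cand = cur[:pos] + target + cur[pos + 1 :]
                u = rng.random()  # drawn unconditionally to keep the stream aligned
                if cand in stops:
                    continue
                syn = code[cand] == code[cur]
                if spec.regions and region.omega <= 1.0:
                    p_accept = 1.0 if syn else region.omega
                else:
                    p_accept = (1.0 / region.omega) if syn else 1.0
                if u < p_accept:
                    codons[k] = cand
                    accepted[region.name][syn is False] += 1
        rows.append("".join(codons))
        for r in spec.regions:
            records.append(
                {
                    "taxon": taxon,
                    "region": r.name,
                    "syn_subs": accepted[r.name][0],
                    "nonsyn_subs": accepted[r.name][1],
                }
            )

    site_rows = []
    for r in spec.regions:
        s_total = 0.0
        for k in range(r.start - 1, r.end):
            s, _ = codon_sites(ancestor_codons[k], spec.table_id)
            s_total += s
        n_codons = r.end - r.start + 1
        site_rows.append(
            {
                "region": r.name, "start": r.start, "end": r.end, "omega": r.omega,
                "S_sites": s_total, "N_sites": 3.0 * n_codons - s_total,
            }
        )
    truth = FamilyTruth(
        counts=pd.DataFrame.from_records(records),
        region_sites=pd.DataFrame.from_records(site_rows),
    )
    return SimulatedFamily(spec, ancestor, CodonAlignment(ids, rows), truth)


def make_identity_fixture(
    n_per_block: int,
    blocks: int,
    within: float,
    between: float,
    noise_sd: float,
    seed: int = 0,
) -> tuple[IdentityMatrix, list[str]]:
    """Planted-block percent-identity matrix with Gaussian jitter.

    Returns the matrix and the block label of each sequence."""
    if not 0 <= between < within <= 100:
        raise ValueError("need 0 <= between < within <= 100")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = n_per_block * blocks
    labels = [f"B{b + 1}" for b in range(blocks) for _ in range(n_per_block)]
    ids = [f"B{b + 1}_s{i + 1}" for b in range(blocks) for i in range(n_per_block)]
    base = np.full((n, n), between)
    for b in range(blocks):
        lo, hi = b * n_per_block, (b + 1) * n_per_block
        base[lo:hi, lo:hi] = within
    values = base + rng.normal(0.0, noise_sd, size=(n, n))
    values = np.clip(values, 0.0, 100.0)
    np.fill_diagonal(values, 100.0)
    return IdentityMatrix(ids=ids, values=values), labels


def make_hit_fixture(
    n_pass: int,
    n_fail: int,
    seed: int = 0,
    thresholds: tuple[float, float, float, float] = (40.0, 50.0, 250.0, 1e-3),
) -> tuple[list[HitRecord], list[bool]]:
    """Hit table with exactly ``n_pass`` rows satisfying all four screening
    criteria and ``n_fail`` rows each violating at least one.

    The first passing row sits exactly on every inclusive boundary. Returns
    the hits (shuffled deterministically) and a parallel pass/fail truth
    list."""
    if n_pass < 0 or n_fail < 0:
        raise ValueError("counts must be >= 0")
    min_id, min_cov, min_bits, max_e = thresholds
    rng = np.random.default_rng(seed)
    hits: list[tuple[HitRecord, bool]] = []
    for i in range(n_pass):
        if i == 0:
            ident, cov, bits, ev = min_id, min_cov, min_bits, max_e
        else:
            ident = rng.uniform(min_id, 100.0)
            cov = rng.uniform(min_cov, 100.0)
            bits = rng.uniform(min_bits, 1500.0)
            ev = 10.0 ** rng.uniform(-180.0, np.log10(max_e))
        hits.append(
            (
                HitRecord(
                    query_id="query",
                    subject_id=f"pass_{i + 1}",
                    percent_identity=float(ident),
                    query_coverage=float(cov),
                    bitscore=float(bits),
                    evalue=float(ev),
                    subject_species=f"species_{i + 1}",
                ),
                True,
            )
        )
    for i in range(n_fail):
        ident = rng.uniform(min_id, 100.0)
        cov = rng.uniform(min_cov, 100.0)
        bits = rng.uniform(min_bits, 1500.0)
        ev = 10.0 ** rng.uniform(-180.0, np.log10(max_e))
        # violate one or more criteria, chosen at random
        which = rng.random(4) < 0.5
        if not which.any():
            which[int(rng.integers(0, 4))] = True
        if which[0]:
            ident = rng.uniform(0.0, np.nextafter(min_id, 0.0))
        if which[1]:
            cov = rng.uniform(0.0, np.nextafter(min_cov, 0.0))
        if which[2]:
            bits = rng.uniform(0.0, np.nextafter(min_bits, 0.0))
        if which[3]:
            ev = 10.0 ** rng.uniform(np.log10(max_e) + 0.01, 2.0)
        hits.append(
            (
                HitRecord(
                    query_id="query",
                    subject_id=f"fail_{i + 1}",
                    percent_identity=float(ident),
                    query_coverage=float(cov),
                    bitscore=float(bits),
                    evalue=float(ev),
                    subject_species=f"species_f{i + 1}",
                ),
                False,
            )
        )
    order = rng.permutation(len(hits))
    shuffled = [hits[i] for i in order]
    return [h for h, _ in shuffled], [p for _, p in shuffled]


def make_projection_fixture(
    n_rows: int,
    n_codons: int,
    aln_columns: int | None = None,
    seed: int = 0,
    table_id: int = 1,
    add_terminal_stop: bool = True,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Matched (protein alignment, coding sequences) with deterministically
    injected gap columns, for projection round-trip tests.

    Each row's ``n_codons`` residues are scattered over ``aln_columns``
    alignment columns (default 4/3 of the length, so roughly a quarter of
    each row is gaps)."""
    from .codon_align import translate_codon

    rng = np.random.default_rng(seed)
    sense = sense_codons(table_id)
    La = aln_columns if aln_columns is not None else max(n_codons + 1, (4 * n_codons) // 3)
    if La < n_codons:
        raise ValueError("aln_columns must be >= n_codons")
    stop_pool = sorted(stop_codons(table_id))
    records = []
    cds: dict[str, str] = {}
    for i in range(n_rows):
        rid = f"r{i + 1}"
        codons = [sense[j] for j in rng.integers(0, len(sense), size=n_codons)]
        positions = np.sort(rng.choice(La, size=n_codons, replace=False))
        row = [GAP] * La
        for pos, codon in zip(positions, codons):
            row[pos] = translate_codon(codon, table_id)
        nt = "".join(codons)
        if add_terminal_stop and i % 2 == 0:
            nt += stop_pool[i % len(stop_pool)]
        records.append(SequenceRecord(rid, rid, "".join(row)))
        cds[rid] = nt
    return records, cds
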