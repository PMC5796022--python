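"""Domain-partitioned selection summaries.

Regions (termini, kinase domain, subdomains, interdomains, activation loop)
are given in 1-based codon coordinates on one reference sequence; they are
mapped onto alignment codon columns by walking the reference row's non-gap
codons. Columns where the reference itself is gapped but which fall between
a region's first and last reference codon belong to the region, keeping
regions contiguous in alignment space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon_align import GAP_CODON, CodonAlignment
from .io_formats import DomainMap, Region
from .ng86 import all_pairs_dnds


def map_reference_regions(
    aln: CodonAlignment, reference_id: str, dm: DomainMap
) -> dict[str, tuple[int, int]]:
    """Map each region to a 1-based inclusive alignment codon-column
    interval anchored on the reference row."""
    if reference_id not in aln.ids:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    ref_idx = aln.ids.index(reference_id)
    codons = aln.row_codons(ref_idx)
    # alignment column (1-based) of the k-th non-gap reference codon
    col_of: list[int] = [c + 1 for c, codon in enumerate(codons) if codon != GAP_CODON]
    ref_len = len(col_of)
    out = {}
    for r in dm.regions:
        if r.end > ref_len:
            raise ValueError(
                f"region {r.name!r} ends at reference codon {r.end} but the "
                f"reference has only {ref_len} codons"
            )
        out[r.name] = (col_of[r.start - 1], col_of[r.end - 1])
    return out


@dataclass
class RegionSummary:
    """Per-region selection summary across pairs.

    Means and standard deviations (+/- 1 SD, sample) are over pairs with a
    defined value of each quantity; pairs with undefined omega (zero dS,
    saturation, no data) are excluded and reflected in ``n_pairs_used``."""

    name: str
    category: str
    start_col: int  # 1-based inclusive alignment codon columns
    end_col: int
    pairs: pd.DataFrame  # per-pair rate table for this region
    mean_dN: float
    sd_dN: float
    mean_dS: float
    sd_dS: float
    mean_omega: float
    sd_omega: float
    n_pairs_used: int


def _stats(series: pd.Series) -> tuple[float, float]:
    vals = series.to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return np.nan, np.nan
    sd = vals.std(ddof=1) if vals.size > 1 else np.nan
    return float(vals.mean()), float(sd)


def region_summaries(
    aln: CodonAlignment,
    reference_id: str,
    dm: DomainMap,
    groups: dict[str, list[str]] | None = None,
    group_pair: tuple[str, str] | None = None,
    table_id: int = 1,
    zero_ds_policy: str = "drop",
) -> list[RegionSummary]:
    """All-pairs rate summaries for every region of a domain map.

    ``groups`` with ``group_pair=(A, B)`` restricts to between-group pairs,
    one sequence from each group (e.g. cross-isoform comparisons);
    ``groups`` with a single named group via ``group_pair=(A, A)`` gives
    within-group pairs. Without groups, all pairs are used."""
    intervals = map_reference_regions(aln, reference_id, dm)
    pairs = None
    if group_pair is not None:
        if groups is None:
            raise ValueError("group_pair requires groups")
        a, b = group_pair
        if a == b:
            members = sorted(groups[a])
            pairs = [(x, y) for i, x in enumerate(members) for y in members[i + 1 :]]
        else:
            pairs = [
                tuple(sorted((x, y)))
                for x in groups[a]
                for y in groups[b]
                if x != y
            ]
    out = []
    for r in dm.regions:
        start, end = intervals[r.name]
        columns = list(range(start - 1, end))  # 0-based codon columns
        table = all_pairs_dnds(
            aln, columns=columns, pairs=pairs, table_id=table_id,
            zero_ds_policy=zero_ds_policy,
        )
        mean_dn, sd_dn = _stats(table["dN"])
        mean_ds, sd_ds = _stats(table["dS"])
        mean_om, sd_om = _stats(table["omega"])
        n_used = int(np.isfinite(table["omega"].to_numpy(dtype=float)).sum())
        out.append(
            RegionSummary(
                name=r.name,
                category=r.category,
                start_col=start,
                end_col=end,
                pairs=table,
                mean_dN=mean_dn, sd_dN=sd_dn,
                mean_dS=mean_ds, sd_dS=sd_ds,
                mean_omega=mean_om, sd_omega=sd_om,
                n_pairs_used=n_used,
            )
        )
    return out


def summaries_to_frame(summaries: list[RegionSummary]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "region": s.name,
                "category": s.category,
                "start_col": s.start_col,
                "end_col": s.end_col,
                "mean_dN": s.mean_dN, "sd_dN": s.sd_dN,
                "mean_dS": s.mean_dS, "sd_dS": s.sd_dS,
                "mean_omega": s.mean_omega, "sd_omega": s.sd_omega,
                "n_pairs_used": s.n_pairs_used,
            }
            for s in summaries
        ]
    )
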