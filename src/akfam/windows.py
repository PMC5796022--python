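"""Sliding-window dN/dS profiles over a codon alignment.

A window of w codon columns slides along the alignment (step 1 by default);
within each window the NG86 rates are computed for every pair in the chosen
row subset and averaged across pairs. Values are plotted at the window
center, start + (w - 1)/2 in 1-based codon-column coordinates. Pairs whose
rate is undefined in a window (no comparable columns, saturation, zero dS)
are excluded from that window's statistics; ``n_pairs`` reports how many
pairs contributed a defined omega.

Windowed means are the mean of per-pair ratios (mean-of-ratios); a
ratio-of-means variant (pooled counts across pairs, then one estimate) is
available for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_align import CodonAlignment
from .ng86 import (
    CodonPairCounts,
    estimate_from_counts,
    pair_column_stats,
)

PROFILE_COLUMNS = [
    "center", "start", "end",
    "mean_dN", "sd_dN", "mean_dS", "sd_dS", "mean_omega", "sd_omega", "n_pairs",
]


@dataclass
class WindowProfile:
    """Per-window averaged rates positioned at window centers."""

    window_size: int
    step: int
    table: pd.DataFrame  # PROFILE_COLUMNS

    @property
    def centers(self) -> np.ndarray:
        return self.table["center"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


def _mean_sd(values: list[float]) -> tuple[float, float]:
    if not values:
        return np.nan, np.nan
    arr = np.asarray(values, dtype=float)
    sd = arr.std(ddof=1) if arr.size > 1 else np.nan
    return float(arr.mean()), float(sd)


def sliding_profile(
    aln: CodonAlignment,
    window_size: int,
    step: int = 1,
    group: Sequence[str] | None = None,
    table_id: int = 1,
    zero_ds_policy: str = "drop",
    averaging: str = "mean_of_ratios",
) -> WindowProfile:
    """Windowed dN/dS profile over all pairs of ``group`` (default: all rows)."""
    if averaging not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError("averaging must be 'mean_of_ratios' or 'ratio_of_means'")
    sub = aln if group is None else aln.subset(sorted(group))
    if sub.n_rows < 2:
        raise ValueError("need at least two rows in the group")
    L = sub.codon_columns
    if window_size > L:
        raise ValueError(f"window of {window_size} codons exceeds alignment length {L}")
    if step < 1:
        raise ValueError("step must be >= 1")

    ids = sorted(sub.ids)
    stats = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            stats[(a, b)] = pair_column_stats(sub.row(a), sub.row(b), table_id)

    # prefix sums turn each window into O(1) per pair
    cum = {
        key: (
            np.concatenate(([0], np.cumsum(s.valid.astype(int)))),
            np.concatenate(([0.0], np.cumsum(s.sites_s))),
            np.concatenate(([0.0], np.cumsum(s.sd))),
            np.concatenate(([0.0], np.cumsum(s.nd))),
        )
        for key, s in stats.items()
    }

    rows = []
    for start in range(0, L - window_size + 1, step):
        end = start + window_size  # exclusive, 0-based
        dn, ds, om = [], [], []
        pooled = CodonPairCounts(0.0, 0.0, 0.0, 0.0, 0)
        for key in stats:
            cv, cs, csd, cnd = cum[key]
            compared = int(cv[end] - cv[start])
            S = float(cs[end] - cs[start])
            counts = CodonPairCounts(
                S=S,
                N=3.0 * compared - S,
                Sd=float(csd[end] - csd[start]),
                Nd=float(cnd[end] - cnd[start]),
                compared_codons=compared,
            )
            pooled = pooled + counts
            est = estimate_from_counts(counts, zero_ds_policy)
            if not np.isnan(est.dN):
                dn.append(est.dN)
            if not np.isnan(est.dS):
                ds.append(est.dS)
            if np.isfinite(est.omega):
                om.append(est.omega)
        if averaging == "ratio_of_means":
            pooled_est = estimate_from_counts(pooled, zero_ds_policy)
            mean_om, sd_om = pooled_est.omega, np.nan
            n_pairs = len(om)
        else:
            mean_om, sd_om = _mean_sd(om)
            n_pairs = len(om)
        mean_dn, sd_dn = _mean_sd(dn)
        mean_ds, sd_ds = _mean_sd(ds)
        rows.append(
            {
                "center": start + 1 + (window_size - 1) / 2.0,
                "start": start + 1,
                "end": end,  # 1-based inclusive
                "mean_dN": mean_dn, "sd_dN": sd_dn,
                "mean_dS": mean_ds, "sd_dS": sd_ds,
                "mean_omega": mean_om, "sd_omega": sd_om,
                "n_pairs": n_pairs,
            }
        )
    return WindowProfile(window_size, step, pd.DataFrame.from_records(rows, columns=PROFILE_COLUMNS))


def per_species_profiles(
    aln: CodonAlignment,
    species_map: Mapping[str, str],
    window_size: int,
    step: int = 1,
    **kwargs,
) -> dict[str, WindowProfile]:
    """One profile per species, each over that species' own paralog pairs.

    Species with fewer than two sequences cannot form a pair and are
    skipped with a warning."""
    groups: dict[str, list[str]] = {}
    for rid in aln.ids:
        try:
            groups.setdefault(species_map[rid], []).append(rid)
        except KeyError:
            raise KeyError(f"row {rid!r} missing from species map") from None
    out = {}
    for species in sorted(groups):
        members = groups[species]
        if len(members) < 2:
            warnings.warn(f"species {species!r} has {len(members)} sequence(s); skipped")
            continue
        out[species] = sliding_profile(aln, window_size, step, group=members, **kwargs)
    return out
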