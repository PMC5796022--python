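"""Unit and property tests for Nei-Gojobori counting and the Jukes-Cantor
correction, checked against an independent brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from akfam.codon_align import CodonAlignment, sense_codons
from akfam.ng86 import (
    all_pairs_dnds,
    codon_sites,
    estimate_from_counts,
    jukes_cantor,
    pair_column_stats,
    pairwise_dnds,
    pathway_differences,
)

from conftest import mutate_row, random_codon_row
from ng86_oracle import oracle_differences, oracle_pair, oracle_sites

SENSE = sense_codons(1)
codon_strategy = st.sampled_from(SENSE)


@pytest.mark.parametrize(
    "codon,expected_s",
    [
        ("GCT", 1.0),  # fourfold-degenerate third position
        ("TTT", 1.0 / 3.0),  # only TTT->TTC synonymous among non-stop neighbors
        ("ATG", 0.0),  # Met: every change is nonsynonymous
        ("TGG", 0.0),  # Trp: ditto, with stop neighbors renormalized away
    ],
)
def test_codon_sites_known_values(codon, expected_s):
    s, n = codon_sites(codon)
    assert s == pytest.approx(expected_s, abs=1e-12)
    assert s + n == pytest.approx(3.0, abs=1e-12)


@given(codon_strategy)
@settings(deadline=None)
def test_codon_sites_match_oracle_and_conserve(codon):
    s, n = codon_sites(codon)
    os, on = oracle_sites(codon)
    assert s == pytest.approx(os, abs=1e-12)
    assert n == pytest.approx(on, abs=1e-12)
    assert s + n == pytest.approx(3.0, abs=1e-12)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("TTT", "TTC", (1.0, 0.0)),  # single synonymous step
        ("TTT", "GTA", (0.5, 1.5)),  # two orderings, hand-enumerated
        ("AAA", "AAA", (0.0, 0.0)),
    ],
)
def test_pathway_differences_known_values(a, b, expected):
    assert pathway_differences(a, b) == pytest.approx(expected, abs=1e-12)


@given(codon_strategy, codon_strategy)
@settings(deadline=None, max_examples=300)
def test_pathway_differences_match_oracle(a, b):
    sd, nd = pathway_differences(a, b)
    osd, ond = oracle_differences(a, b)
    assert sd == pytest.approx(osd, abs=1e-12)
    assert nd == pytest.approx(ond, abs=1e-12)


@given(codon_strategy, codon_strategy)
@settings(deadline=None, max_examples=300)
def test_pathway_differences_symmetric_and_conserve_hamming(a, b):
    """Stop-free pathway averages are symmetric and sum to the number of
    differing positions."""
    sd_ab, nd_ab = pathway_differences(a, b)
    sd_ba, nd_ba = pathway_differences(b, a)
    hamming = sum(x != y for x, y in zip(a, b))
    assert sd_ab + nd_ab == pytest.approx(hamming, abs=1e-9)
    assert (sd_ab, nd_ab) == pytest.approx((sd_ba, nd_ba), abs=1e-12)


def test_worked_microexample_alanine_pair():
    """Ten GCT codons vs the same with one GCC: one synonymous difference on
    ten synonymous sites, Jukes-Cantor -(3/4)ln(1 - 4/30)."""
    x = "GCT" * 10
    y = "GCC" + "GCT" * 9
    est, counts = pairwise_dnds(x, y)
    assert (counts.S, counts.N, counts.Sd, counts.Nd) == (10.0, 20.0, 1.0, 0.0)
    assert est.pS == pytest.approx(0.1)
    assert est.dS == pytest.approx(-0.75 * math.log(1 - 4.0 / 30.0), abs=1e-12)
    assert est.dN == 0.0
    assert est.omega == 0.0
    assert est.flags == frozenset({"dN_zero"})


def test_identical_rows_flagged_both_zero():
    est, _ = pairwise_dnds("GCTAAA", "GCTAAA")
    assert est.dS == 0.0 and est.dN == 0.0
    assert math.isnan(est.omega)
    assert est.flags == frozenset({"both_zero"})


def test_single_codon_synonymous_saturates():
    """One synonymous difference on a third of a site: pS = 3 >= 3/4, the
    correction diverges."""
    est, counts = pairwise_dnds("TTT", "TTC")
    assert counts.S == pytest.approx(1.0 / 3.0)
    assert est.pS == pytest.approx(3.0)
    assert math.isnan(est.dS)
    assert "saturated_S" in est.flags


def test_zero_ds_policy():
    # nonsynonymous change only: GCT -> CCT (Ala -> Pro)
    x, y = "GCTGCT", "CCTGCT"
    est, _ = pairwise_dnds(x, y)
    assert "dS_zero" in est.flags and math.isnan(est.omega)
    est_inf, _ = pairwise_dnds(x, y, zero_ds_policy="inf")
    assert est_inf.omega == math.inf


def test_pairwise_deletion_excludes_gap_ambiguity_stop_columns():
    x = "GCT" + "---" + "NNN" + "AAA"
    y = "GCT" + "GCT" + "GCT" + "TAA"  # last column: stop in y
    _, counts = pairwise_dnds(x, y)
    assert counts.compared_codons == 1
    assert counts.S + counts.N == pytest.approx(3.0)


def test_column_subset_restriction():
    x = "GCTAAATTT"
    y = "GCCAAATTC"
    _, whole = pairwise_dnds(x, y)
    _, first = pairwise_dnds(x, y, columns=[0])
    _, rest = pairwise_dnds(x, y, columns=[1, 2])
    assert first.Sd + rest.Sd == pytest.approx(whole.Sd)
    assert first.S + rest.S == pytest.approx(whole.S)


def test_oracle_equivalence_on_random_pairs(rng):
    """Headline correctness check: 50 random stop-free 100-codon pairs match
    the brute-force oracle to 1e-9 on every NG86 quantity."""
    for _ in range(50):
        x = random_codon_row(rng, 100)
        y = mutate_row(rng, x, int(rng.integers(0, 60)))
        est, counts = pairwise_dnds(x, y)
        xc = [x[i : i + 3] for i in range(0, 300, 3)]
        yc = [y[i : i + 3] for i in range(0, 300, 3)]
        o = oracle_pair(xc, yc)
        assert counts.S == pytest.approx(o["S"], abs=1e-9)
        assert counts.N == pytest.approx(o["N"], abs=1e-9)
        assert counts.Sd == pytest.approx(o["Sd"], abs=1e-9)
        assert counts.Nd == pytest.approx(o["Nd"], abs=1e-9)
        assert est.pS == pytest.approx(o["pS"], abs=1e-9)
        assert est.pN == pytest.approx(o["pN"], abs=1e-9)
        for key, got in (("dS", est.dS), ("dN", est.dN)):
            if math.isnan(o[key]):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(o[key], abs=1e-9)


def test_site_conservation_property(rng):
    """S + N = 3 x compared codons on randomized rows with gaps."""
    for _ in range(200):
        n = int(rng.integers(2, 30))
        x = random_codon_row(rng, n)
        y = mutate_row(rng, x, int(rng.integers(0, n)))
        # gap out a random codon in x
        if rng.random() < 0.5:
            k = int(rng.integers(0, n))
            x = x[: 3 * k] + "---" + x[3 * k + 3 :]
        _, counts = pairwise_dnds(x, y)
        assert counts.S + counts.N == pytest.approx(3.0 * counts.compared_codons, abs=1e-9)


def test_count_additivity_over_disjoint_column_sets(rng):
    for _ in range(100):
        n = int(rng.integers(4, 40))
        x = random_codon_row(rng, n)
        y = mutate_row(rng, x, int(rng.integers(0, 2 * n)))
        cols = rng.permutation(n)
        split = int(rng.integers(1, n))
        a, b = sorted(cols[:split]), sorted(cols[split:])
        stats = pair_column_stats(x, y)
        total = stats.counts(a) + stats.counts(b)
        whole = stats.counts()
        assert total.S == pytest.approx(whole.S, abs=1e-9)
        assert total.N == pytest.approx(whole.N, abs=1e-9)
        assert total.Sd == pytest.approx(whole.Sd, abs=1e-9)
        assert total.Nd == pytest.approx(whole.Nd, abs=1e-9)
        assert total.compared_codons == whole.compared_codons


def test_jukes_cantor_monotone_and_saturates():
    ps = np.linspace(0.0, 0.74, 200)
    ds = [jukes_cantor(p) for p in ps]
    assert all(b > a for a, b in zip(ds, ds[1:]))
    assert math.isnan(jukes_cantor(0.75))
    with pytest.raises(ValueError):
        jukes_cantor(-0.1)


def test_all_pairs_table_symmetric_and_ordered(rng):
    rows = [random_codon_row(rng, 20)]
    for _ in range(3):
        rows.append(mutate_row(rng, rows[0], 5))
    aln = CodonAlignment(["d", "b", "a", "c"], rows)
    table = all_pairs_dnds(aln)
    assert len(table) == 6
    assert list(table["id_a"]) == sorted(table["id_a"])
    assert all(a < b for a, b in zip(table["id_a"], table["id_b"]))
    # symmetry: swapping rows changes nothing
    est_xy, _ = pairwise_dnds(rows[0], rows[1])
    est_yx, _ = pairwise_dnds(rows[1], rows[0])
    assert est_xy == est_yx


def test_insufficient_data_flag():
    est, counts = pairwise_dnds("---", "GCT")
    assert counts.compared_codons == 0
    assert est.flags == frozenset({"insufficient_data"})
    assert math.isnan(est.dS) and math.isnan(est.dN)


def test_estimate_rejects_unknown_policy():
    from akfam.ng86 import CodonPairCounts

    with pytest.raises(ValueError):
        estimate_from_counts(CodonPairCounts(1, 2, 0, 0, 1), zero_ds_policy="explode")
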