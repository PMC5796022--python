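"""Independent brute-force oracle for codon-pair substitution counting.

Deliberately written without importing any counting code from the package:
sites are enumerated change by change from the raw genetic-code table, and
differences by explicit enumeration of all substitution orderings. Slow and
obvious on purpose.
"""

from itertools import permutations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
AA = dict(_TABLE.forward_table)
STOPS = set(_TABLE.stop_codons)
for _s in STOPS:
    AA[_s] = "*"
BASES = "ACGT"


def oracle_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) sites by direct enumeration."""
    s = 0.0
    for pos in range(3):
        outcomes = []
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in STOPS:
                continue
            outcomes.append(AA[mutant] == AA[codon])
        if outcomes:
            s += sum(outcomes) / len(outcomes)
    return s, 3.0 - s


def oracle_differences(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences by explicit
    enumeration of substitution orderings; orderings through stop codons are
    excluded unless all are blocked, in which case stop steps count as
    nonsynonymous."""
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    clean, blocked = [], []
    for order in permutations(positions):
        cur = a
        sd = nd = 0.0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOPS or cur in STOPS:
                hit_stop = True
                nd += 1.0
            elif AA[cur] == AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (blocked if hit_stop else clean).append((sd, nd))
    use = clean if clean else blocked
    return (
        sum(x[0] for x in use) / len(use),
        sum(x[1] for x in use) / len(use),
    )


def oracle_pair(x_codons: list[str], y_codons: list[str]) -> dict:
    """Whole-pair NG86 quantities for lists of valid codons (no gaps,
    ambiguity or stops), with Jukes-Cantor correction."""
    import math

    S = N = Sd = Nd = 0.0
    for cx, cy in zip(x_codons, y_codons):
        sx, nx = oracle_sites(cx)
        sy, ny = oracle_sites(cy)
        S += (sx + sy) / 2.0
        N += (nx + ny) / 2.0
        sd, nd = oracle_differences(cx, cy)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0

    def jc(p):
        return math.nan if p >= 0.75 else -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN,
            "dS": jc(pS), "dN": jc(pN)}
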