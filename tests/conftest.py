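import numpy as np
import pytest

from akfam.codon_align import sense_codons


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_codon_row(rng, n_codons: int) -> str:
    """Uniform stop-free codon string."""
    sense = sense_codons(1)
    return "".join(sense[i] for i in rng.integers(0, len(sense), size=n_codons))


def mutate_row(rng, row: str, n_changes: int) -> str:
    """Apply point changes to a codon row, skipping any that would create a
    stop codon."""
    from akfam.codon_align import stop_codons

    stops = stop_codons(1)
    out = list(row)
    made = 0
    while made < n_changes:
        i = int(rng.integers(0, len(out)))
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == out[i]:
            continue
        k = 3 * (i // 3)
        codon = "".join(out[k : k + 3])
        cand = codon[: i - k] + alt + codon[i - k + 1 :]
        if cand in stops:
            continue
        out[i] = alt
        made += 1
    return "".join(out)
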