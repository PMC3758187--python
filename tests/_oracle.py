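"""Independent brute-force oracles used by the test suite.

Kept free of any import from the code paths they check: alignment
scores come from exhaustive enumeration of every global alignment, and
codon site counts from direct enumeration of the nine single-base
mutations classified with Biopython's translation table.
"""

from Bio.Seq import Seq


def enumerate_alignment_scores(a: str, b: str, match, mismatch, gap_open, gap_extend):
    """Yield the affine-gap score of every global alignment of a and b.

    A gap run of length L costs gap_open + (L-1)*gap_extend; end gaps
    are penalized like internal ones.
    """
    la, lb = len(a), len(b)

    def rec(i, j, prev, score):
        if i == la and j == lb:
            yield score
            return
        if i < la and j < lb:
            s = match if a[i] == b[j] else mismatch
            yield from rec(i + 1, j + 1, "M", score + s)
        if i < la:
            yield from rec(i + 1, j, "X", score - (gap_extend if prev == "X" else gap_open))
        if j < lb:
            yield from rec(i, j + 1, "Y", score - (gap_extend if prev == "Y" else gap_open))

    yield from rec(0, 0, None, 0.0)


def best_alignment_score(a, b, match=5.0, mismatch=-4.0, gap_open=10.0, gap_extend=0.5):
    return max(enumerate_alignment_scores(a, b, match, mismatch, gap_open, gap_extend))


def codon_sites_by_enumeration(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) fractional sites via direct enumeration."""
    aa = str(Seq(codon).translate())
    assert aa != "*"
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if str(Seq(mutant).translate()) == aa:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0
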