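"""Counting-based codon-wise dN/dS with a neutrality test.

A neutrally evolving provirus accrues nonsynonymous and synonymous
substitutions at the same per-site rate, so dN/dS ≈ 1; purifying
selection (expected for sequence still producing functional protein)
pushes the ratio below 1.  An orthologous, dead insertion should
therefore fail to reject neutrality.

The method is Nei–Gojobori-style counting: fractional synonymous and
nonsynonymous site counts per codon (each codon position weighted by
the fraction of its three possible single-base changes that are
synonymous; changes creating a stop count as nonsynonymous), observed
differences classified with equal-weight averaging over all mutational
pathways for multi-hit codons (pathways passing through a stop codon
are excluded unless all do), Jukes–Cantor correction of the pooled
proportions, and a z-test on dN − dS whose variance comes from a seeded
bootstrap over codons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

__all__ = [
    "CodonAlignment",
    "DnDsResult",
    "count_codon_sites",
    "pairwise_dnds",
    "alignment_dnds",
]

_CODE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


def _translate(codon: str) -> str | None:
    """Amino acid, or None for a stop codon."""
    return _CODE.get(codon)


def count_codon_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Each of the three positions contributes (synonymous single-base
    changes)/3 synonymous sites; mutations to stop codons are counted as
    nonsynonymous.  The two counts always sum to 3. E.g. GGG (4-fold
    third position) -> (1.0, 2.0); ATG -> (0.0, 3.0).
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"codon must be 3 unambiguous bases, got {codon!r}")
    aa = _translate(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if _translate(mutant) == aa:
                syn += 1.0
    syn /= 3.0
    return syn, 3.0 - syn


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, pathway-averaged."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _translate(nxt) is None:
                through_stop = True
                nd += 1
            elif _translate(nxt) == _translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, through_stop))
    usable = [p for p in paths if not p[2]] or paths
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def _jc_correct(p: float) -> float:
    """NG86 proportion -> distance.

    At or beyond saturation (p >= 3/4, where the correction is
    undefined) the uncorrected proportion is returned — this keeps tiny
    inputs (e.g. a single saturated codon) usable while staying
    monotone in p.
    """
    if p >= 0.75:
        return float(p)
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


@dataclass
class DnDsResult:
    """Outcome of a dN/dS comparison.

    ``ratio`` is NaN (flagged via ``ratio_defined``) when dS = 0.
    ``p_value`` tests H0: dN = dS; under neutrality it should be
    uniform-ish, so rejection at 0.05 should be rare.
    """

    dn: float
    ds: float
    ratio: float
    ratio_defined: bool
    z: float
    p_value: float
    n_codons: int
    sites_n: float
    sites_s: float
    per_codon_nd: np.ndarray | None = None
    per_codon_sd: np.ndarray | None = None


def _iter_codons(row: str):
    if len(row) % 3 != 0:
        raise ValueError(f"row length {len(row)} is not a multiple of 3")
    for i in range(0, len(row), 3):
        yield row[i : i + 3]


class CodonAlignment:
    """In-frame gapped codon rows (frame anchored at column 0).

    Gaps must occur in whole-codon units; codons containing a stop in
    any row are flagged (and skipped by the counting).
    """

    def __init__(self, rows: dict[str, str] | list[tuple[str, str]]):
        items = list(rows.items()) if isinstance(rows, dict) else list(rows)
        if len(items) < 2:
            raise ValueError("codon alignment needs at least 2 rows")
        self.ids = [i for i, _ in items]
        self.rows = [r.upper() for _, r in items]
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("rows have unequal lengths")
        self.length = lengths.pop()
        if self.length % 3 != 0:
            raise ValueError("alignment length not a multiple of 3")
        for rid, row in zip(self.ids, self.rows):
            for codon in _iter_codons(row):
                if "-" in codon and codon != "---":
                    raise ValueError(
                        f"row {rid!r}: gap splits codon {codon!r} "
                        "(gaps must cover whole codons)"
                    )
        self.stop_flags = [
            [c in _STOPS for c in _iter_codons(row)] for row in self.rows
        ]

    @property
    def n_codons(self) -> int:
        return self.length // 3


def _usable_codon(c: str) -> bool:
    return all(b in _BASES for b in c) and c not in _STOPS


def pairwise_dnds(
    row_a: str,
    row_b: str,
    n_boot: int = 1000,
    seed: int = 0,
    keep_per_codon: bool = False,
) -> DnDsResult:
    """Nei–Gojobori dN/dS between two equal-length in-frame rows.

    Codons containing a gap, an N or a stop in either row are skipped
    pairwise (frame is preserved because gaps must span whole codons).
    """
    row_a, row_b = row_a.upper(), row_b.upper()
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    nd_list, sd_list, n_list, s_list = [], [], [], []
    for ca, cb in zip(_iter_codons(row_a), _iter_codons(row_b)):
        if not (_usable_codon(ca) and _usable_codon(cb)):
            continue
        sa, na = count_codon_sites(ca)
        sb, nb = count_codon_sites(cb)
        sd, nd = _pathway_differences(ca, cb)
        nd_list.append(nd)
        sd_list.append(sd)
        n_list.append((na + nb) / 2.0)
        s_list.append((sa + sb) / 2.0)
    if not nd_list:
        raise ValueError("no usable codons (all gapped, ambiguous or stop)")
    nd = np.array(nd_list)
    sd = np.array(sd_list)
    nn = np.array(n_list)
    ss = np.array(s_list)
    n_codons = len(nd)

    dn = _jc_correct(nd.sum() / nn.sum()) if nn.sum() > 0 else 0.0
    ds = _jc_correct(sd.sum() / ss.sum()) if ss.sum() > 0 else 0.0

    # bootstrap over codons for the variance of dN - dS
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_codons, size=(n_boot, n_codons))
    bnd, bsd = nd[idx].sum(axis=1), sd[idx].sum(axis=1)
    bnn, bss = nn[idx].sum(axis=1), ss[idx].sum(axis=1)
    # a resample may draw only codons with zero synonymous (or zero
    # nonsynonymous) sites; such resamples carry no information and are
    # dropped
    valid = (bnn > 0) & (bss > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pn, ps = bnd[valid] / bnn[valid], bsd[valid] / bss[valid]
        dn_b = np.where(pn < 0.75, -0.75 * np.log(1 - np.minimum(4 * pn / 3, 1 - 1e-12)), pn)
        ds_b = np.where(ps < 0.75, -0.75 * np.log(1 - np.minimum(4 * ps / 3, 1 - 1e-12)), ps)
        diffs = dn_b - ds_b
    se = float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0
    if se == 0.0:
        z = 0.0
        p_value = 1.0 if dn == ds else 0.0
    else:
        z = (dn - ds) / se
        p_value = float(2.0 * stats.norm.sf(abs(z)))
    ratio_defined = ds > 0
    return DnDsResult(
        dn=float(dn),
        ds=float(ds),
        ratio=float(dn / ds) if ratio_defined else float("nan"),
        ratio_defined=ratio_defined,
        z=float(z),
        p_value=p_value,
        n_codons=n_codons,
        sites_n=float(nn.sum()),
        sites_s=float(ss.sum()),
        per_codon_nd=nd if keep_per_codon else None,
        per_codon_sd=sd if keep_per_codon else None,
    )


def alignment_dnds(aln: CodonAlignment, n_boot: int = 1000, seed: int = 0) -> DnDsResult:
    """Average pairwise dN/dS over all row pairs of a codon alignment.

    The summary ratio is the mean of the defined pairwise ratios and
    the summary p-value is the mean of the pairwise p-values.  Literal
    averaging of p-values is not a combination test with a calibrated
    null distribution — it is reported as a descriptive summary; the
    per-pair p-values carry the inferential content.
    """
    results = [
        pairwise_dnds(aln.rows[i], aln.rows[j], n_boot=n_boot, seed=seed + 7919 * (i * len(aln.rows) + j))
        for i, j in combinations(range(len(aln.rows)), 2)
    ]
    ratios = [r.ratio for r in results if r.ratio_defined]
    mean_ratio = float(np.mean(ratios)) if ratios else float("nan")
    mean_p = float(np.mean([r.p_value for r in results]))
    mean_dn = float(np.mean([r.dn for r in results]))
    mean_ds = float(np.mean([r.ds for r in results]))
    return DnDsResult(
        dn=mean_dn,
        ds=mean_ds,
        ratio=mean_ratio,
        ratio_defined=bool(ratios),
        z=float("nan"),
        p_value=mean_p,
        n_codons=int(np.mean([r.n_codons for r in results])),
        sites_n=float(np.mean([r.sites_n for r in results])),
        sites_s=float(np.mean([r.sites_s for r in results])),
    )
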