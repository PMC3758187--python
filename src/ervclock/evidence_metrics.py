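"""Orthology-evidence metrics over a multiple alignment.

Three computations support the case that an element is orthologous
across species rather than independently inserted:

* per-column conservation profiles (the histogram drawn beneath an
  alignment of the element and its flanks);
* region-wise pairwise identity matrices (identity between every pair
  of species over a fixed alignment window, gaps stripped pairwise);
* shared-SGE concordance: whether repeats inserted inside the element
  (MIRs, MERs, ...) occur in the same family, orientation and alignment
  position in every species that retains them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CoreIOError, Feature, MultipleAlignment

__all__ = [
    "ConservationProfile",
    "RegionSpec",
    "SgeConcordance",
    "conservation_profile",
    "region_identity_matrix",
    "sge_concordance",
    "features_to_alignment_windows",
]


@dataclass(frozen=True)
class RegionSpec:
    """A named 0-based half-open column window on an alignment."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoreIOError(f"region {self.name!r}: need 0 <= start < end")


@dataclass
class ConservationProfile:
    scores: np.ndarray  # per column, in [0, 1]
    n_rows: int
    mode: str

    def __post_init__(self) -> None:
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError("conservation scores must lie in [0, 1]")

    @property
    def n_columns(self) -> int:
        return len(self.scores)


def conservation_profile(msa: MultipleAlignment, mode: str = "majority") -> ConservationProfile:
    """Per-column conservation score in [0, 1].

    mode="majority": frequency of the most common non-gap residue among
    the rows with a non-gap residue at that column (all-gap columns
    score 0).  mode="pairwise": mean match fraction over all row pairs
    where neither row has a gap.  With the default denominator a column
    present in a single species scores 1.0 — sparse columns are not
    penalized for missing species; pass ``mode="majority_all"`` to
    divide by the total row count instead.
    """
    if mode not in ("majority", "majority_all", "pairwise"):
        raise ValueError(f"unknown conservation mode {mode!r}")
    # rows as a residue matrix
    mat = np.array([list(r.residues) for r in msa.rows])
    n_rows, n_cols = mat.shape
    scores = np.zeros(n_cols)
    for j in range(n_cols):
        col = mat[:, j]
        residues = col[col != "-"]
        if residues.size == 0:
            continue
        if mode in ("majority", "majority_all"):
            _, counts = np.unique(residues, return_counts=True)
            denom = n_rows if mode == "majority_all" else residues.size
            scores[j] = counts.max() / denom
        else:
            if residues.size < 2:
                continue
            _, counts = np.unique(residues, return_counts=True)
            n = residues.size
            matches = (counts * (counts - 1) // 2).sum()
            scores[j] = matches / (n * (n - 1) / 2)
    return ConservationProfile(scores=scores, n_rows=n_rows, mode=mode)


def region_identity_matrix(
    msa: MultipleAlignment,
    region: RegionSpec,
    gap_policy: str = "exclude",
) -> pd.DataFrame:
    """Pairwise percent identity between all species over one region.

    The region window is fixed on the alignment; for each pair, columns
    where either row carries a gap (or an N) are dropped and identity is
    computed over the rest — no re-alignment.  Pairs with zero
    comparable columns get NaN (a flagged cell, not a silent 0).  The
    diagonal is 100 and the matrix is symmetric.
    """
    if region.end > msa.n_columns:
        raise CoreIOError(
            f"region {region.name!r} [{region.start},{region.end}) exceeds "
            f"alignment length {msa.n_columns}"
        )
    ids = [r.id for r in msa.rows]
    sub = np.array([list(r.residues[region.start : region.end]) for r in msa.rows])
    n = len(ids)
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 100.0)
    for i in range(n):
        for k in range(i + 1, n):
            a, b = sub[i], sub[k]
            comparable = (a != "-") & (b != "-") & (a != "N") & (b != "N")
            if gap_policy == "count":
                comparable = ~((a == "-") & (b == "-")) & (a != "N") & (b != "N")
            m = comparable.sum()
            if m == 0:
                continue
            ident = 100.0 * ((a == b) & comparable).sum() / m
            out[i, k] = out[k, i] = ident
    return pd.DataFrame(out, index=ids, columns=ids)


@dataclass
class SgeConcordance:
    """Cross-species agreement record for one SGE family."""

    family: str
    strands: dict[str, str]          # species -> strand of its copy
    windows: dict[str, tuple[int, int]]  # species -> alignment column window
    present: list[str] = field(default_factory=list)
    absent: list[str] = field(default_factory=list)
    concordant: bool = False


def features_to_alignment_windows(
    msa: MultipleAlignment,
    features: dict[str, list[Feature]],
) -> dict[str, list[tuple[Feature, tuple[int, int]]]]:
    """Map per-species sequence-coordinate features to alignment columns.

    Each feature becomes a half-open column window spanning its first
    and last retained residues in that species' aligned row.
    """
    out: dict[str, list[tuple[Feature, tuple[int, int]]]] = {}
    for sp, feats in features.items():
        col_map = msa.seq_to_column_map(sp)
        mapped = []
        for f in feats:
            if f.end > len(col_map):
                raise CoreIOError(
                    f"feature {f.label!r} outside ungapped sequence of {sp!r}"
                )
            mapped.append((f, (col_map[f.start], col_map[f.end - 1] + 1)))
        out[sp] = mapped
    return out


def _windows_overlap(w1: tuple[int, int], w2: tuple[int, int], frac: float = 0.5) -> bool:
    inter = min(w1[1], w2[1]) - max(w1[0], w2[0])
    shorter = min(w1[1] - w1[0], w2[1] - w2[0])
    return inter >= frac * shorter


def sge_concordance(
    msa: MultipleAlignment,
    features: dict[str, list[Feature]],
    overlap_fraction: float = 0.5,
) -> list[SgeConcordance]:
    """Test whether shared SGE insertions support orthology.

    Features (sequence coordinates, keyed by species id matching the
    alignment rows) are grouped by family; a family is concordant iff
    every species that carries a copy has it on the same strand and all
    windows mutually overlap by at least ``overlap_fraction`` of the
    shorter window.  Absence from some species is tolerated and
    reported — lineage-specific deletion removes a repeat without
    breaking orthology of the rest.
    """
    all_species = [r.id for r in msa.rows]
    mapped = features_to_alignment_windows(msa, features)
    by_family: dict[str, dict[str, tuple[Feature, tuple[int, int]]]] = {}
    for sp, feats in mapped.items():
        for f, win in feats:
            fam = f.family or f.label
            by_family.setdefault(fam, {})[sp] = (f, win)
    results = []
    for fam, copies in sorted(by_family.items()):
        present = sorted(copies)
        strands = {sp: copies[sp][0].strand for sp in present}
        windows = {sp: copies[sp][1] for sp in present}
        same_strand = len(set(strands.values())) == 1
        wins = list(windows.values())
        overlapping = all(
            _windows_overlap(wins[i], wins[j], overlap_fraction)
            for i in range(len(wins))
            for j in range(i + 1, len(wins))
        )
        results.append(
            SgeConcordance(
                family=fam,
                strands=strands,
                windows=windows,
                present=present,
                absent=sorted(set(all_species) - set(present)),
                concordant=same_strand and overlapping,
            )
        )
    return results
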