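"""Domain types and file I/O.

The package works with four kinds of objects: DNA sequences
(:class:`NucSequence`), interval annotations on them (:class:`Feature`,
e.g. an LTR or a MIR repeat), a dated host phylogeny (:class:`HostTree`)
and multiple sequence alignments (:class:`MultipleAlignment`).  File
formats are FASTA for sequences, Newick (branch lengths in Myr) for the
host tree and GFF3 for annotations.

Coordinate convention: all in-memory coordinates are 0-based half-open;
GFF3 I/O converts to and from the 1-based inclusive convention of that
format.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

__all__ = [
    "CoreIOError",
    "Feature",
    "NucSequence",
    "HostTree",
    "MultipleAlignment",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "read_gff3",
    "write_gff3",
]

#: Residues accepted in unaligned sequences.
DNA_ALPHABET = frozenset("ACGTN")
#: '-' additionally allowed when a sequence is flagged as aligned.
ALIGNED_ALPHABET = DNA_ALPHABET | {"-"}


class CoreIOError(ValueError):
    """Malformed input data (bad characters, bad coordinates, bad files)."""


@dataclass(frozen=True)
class Feature:
    """An annotated interval on a sequence (LTR, SGE insertion, ORF...).

    Coordinates are 0-based half-open on the parent sequence.  ``family``
    groups features across species (e.g. two "MIR" insertions in two
    species that descend from the same ancestral insertion).  GFF3 has no
    "strandless" notion in our model: '.' strands read from file are
    stored as '+' with ``strand_known=False``.
    """

    label: str
    start: int
    end: int
    strand: str = "+"
    family: str = ""
    strand_known: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoreIOError(
                f"feature {self.label!r}: need 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise CoreIOError(f"feature {self.label!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class NucSequence:
    """A named DNA sequence with optional feature annotations.

    ``residues`` is an uppercase string over A,C,G,T,N; gap characters
    '-' are only legal when ``aligned=True``.
    """

    id: str
    residues: str
    features: list[Feature] = field(default_factory=list)
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise CoreIOError("sequence id must be non-empty")
        self.residues = self.residues.upper().replace("U", "T")
        alphabet = ALIGNED_ALPHABET if self.aligned else DNA_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            raise CoreIOError(
                f"sequence {self.id!r}: illegal characters {sorted(bad)}"
                + ("" if self.aligned else " (gaps require aligned=True)")
            )
        for f in self.features:
            if f.end > len(self.residues):
                raise CoreIOError(
                    f"feature {f.label!r} extends past end of sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "NucSequence":
        """Copy with gap columns removed (features dropped)."""
        return NucSequence(self.id, self.residues.replace("-", ""), [])


class MultipleAlignment:
    """An ordered list of equal-length aligned sequences.

    Rows are :class:`NucSequence` objects with ``aligned=True``.
    """

    def __init__(self, rows: list[NucSequence]):
        if len(rows) < 2:
            raise CoreIOError("alignment needs at least 2 rows")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise CoreIOError(f"rows have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in rows]
        if len(set(ids)) != len(ids):
            raise CoreIOError("duplicate row ids in alignment")
        self.rows = [replace(r, aligned=True) for r in rows]
        self.n_columns = lengths.pop()

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def row(self, seq_id: str) -> NucSequence:
        for r in self.rows:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.rows)

    def seq_to_column_map(self, seq_id: str) -> list[int]:
        """For one row, the alignment column of each ungapped residue."""
        return [j for j, c in enumerate(self.row(seq_id).residues) if c != "-"]


class HostTree:
    """A rooted, dated host phylogeny with per-branch neutral rates.

    Branch lengths are in Myr.  Each branch carries a neutral
    substitution rate in substitutions/site/year; by default a single
    global rate applies to every branch (``rates`` may map node labels —
    leaf names or internal labels — to per-branch overrides for the
    branch above that node).
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        default_rate: float = 4.5e-9,
        rates: dict[str, float] | None = None,
    ):
        self.tree = tree
        if default_rate <= 0:
            raise CoreIOError("neutral rate must be > 0")
        self.default_rate = default_rate
        self.rates = dict(rates or {})
        for label, r in self.rates.items():
            if r <= 0:
                raise CoreIOError(f"rate for {label!r} must be > 0")
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise CoreIOError("duplicate leaf labels in tree")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise CoreIOError("tree has a branch with no length")
            if edge.length < 0:
                raise CoreIOError("negative branch length")

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def rate_for(self, node: dendropy.Node) -> float:
        label = None
        if node.taxon is not None:
            label = node.taxon.label
        elif node.label:
            label = node.label
        return self.rates.get(label, self.default_rate)

    def root_age(self) -> float:
        """Maximum root-to-leaf path length (Myr before present)."""
        return max(
            leaf.distance_from_root() for leaf in self.tree.leaf_node_iter()
        )

    def mrca(self, leaf_labels: list[str]) -> dendropy.Node:
        return self.tree.mrca(taxon_labels=leaf_labels)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike, aligned: bool = False) -> list[NucSequence]:
    """Read a multi-FASTA file into :class:`NucSequence` records.

    Residues are uppercased and U is canonicalized to T.  Duplicate ids,
    empty files and characters outside {A,C,G,T,N} (plus '-' when
    ``aligned``) raise :class:`CoreIOError`.
    """
    seqs: list[NucSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise CoreIOError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seqs.append(NucSequence(rec.id, str(rec.seq), aligned=aligned))
    if not seqs:
        raise CoreIOError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: list[NucSequence], path: str | os.PathLike, width: int = 60) -> None:
    """Write sequences as wrapped multi-FASTA (gaps written verbatim)."""
    if not seqs:
        raise CoreIOError("refusing to write an empty FASTA file")
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Newick


def read_newick(
    path: str | os.PathLike,
    default_rate: float = 4.5e-9,
    rates: dict[str, float] | None = None,
) -> HostTree:
    """Read a rooted Newick tree whose branch lengths are in Myr.

    Rates are not part of the Newick format; supply them via
    ``default_rate``/``rates`` (typically from a config file).
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise CoreIOError(f"could not parse Newick file {path}: {exc}") from exc
    return HostTree(tree, default_rate=default_rate, rates=rates)


def tree_from_newick_string(
    newick: str,
    default_rate: float = 4.5e-9,
    rates: dict[str, float] | None = None,
) -> HostTree:
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise CoreIOError(f"could not parse Newick string: {exc}") from exc
    return HostTree(tree, default_rate=default_rate, rates=rates)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | os.PathLike) -> dict[str, list[Feature]]:
    """Read GFF3 annotations, keyed by sequence id.

    GFF3 1-based inclusive coordinates are converted to 0-based
    half-open.  Strand '.' is stored as '+' with ``strand_known=False``.
    """
    out: dict[str, list[Feature]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                gf = feature_from_line(line)
            except Exception as exc:
                raise CoreIOError(f"bad GFF3 line {line!r}: {exc}") from exc
            if gf.end < gf.start:
                raise CoreIOError(f"GFF3 line with end < start: {line!r}")
            if gf.strand not in ("+", "-", "."):
                raise CoreIOError(f"GFF3 line with bad strand: {line!r}")
            attrs = dict(gf.attributes)
            label = attrs.get("Name", attrs.get("ID", [gf.featuretype]))[0]
            family = attrs.get("family", [""])[0]
            feat = Feature(
                label=label,
                start=gf.start - 1,
                end=gf.end,
                strand="+" if gf.strand == "." else gf.strand,
                family=family,
                strand_known=gf.strand != ".",
            )
            out.setdefault(gf.seqid, []).append(feat)
    return out


def write_gff3(
    features: dict[str, list[Feature]],
    path: str | os.PathLike,
    source: str = "ervclock",
) -> None:
    """Write annotations as GFF3 (1-based inclusive, version header)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid in features:
            for f in features[seqid]:
                strand = f.strand if f.strand_known else "."
                attrs = f"Name={f.label}"
                if f.family:
                    attrs += f";family={f.family}"
                fh.write(
                    "\t".join(
                        [
                            seqid,
                            source,
                            "dispersed_repeat",
                            str(f.start + 1),
                            str(f.end),
                            ".",
                            strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
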