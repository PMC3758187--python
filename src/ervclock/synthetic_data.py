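"""Forward simulator of provirus endogenization and neutral evolution.

The generative model: a provirus (5' LTR + internal region + 3' LTR,
with the two LTRs identical at insertion) integrates into an ancestral
genome at ``t_integration`` Ma, flanked by host DNA.  The sequence then
evolves neutrally — first along the stem lineage down to the root of
the host tree, then along every branch — with Jukes–Cantor
substitutions at the branch's neutral rate: over a branch of duration
``t`` Myr at rate ``mu`` substitutions/site/year, each site substitutes
with probability ``p = (3/4)(1 − exp(−4·mu·t·1e6/3))``.

On top of the substitution clock the simulator supports the events that
shape real ancient elements:

* SGE insertions (MIRs, MERs, secondary proviruses) spliced in at a
  stated time and element position — events on the stem lineage are
  inherited by every species, events on a branch only by that clade;
* solo-LTR formation: recombination between the two LTRs of a
  previously inserted secondary provirus deletes one LTR plus the
  internal sequence, leaving a single LTR in the affected clade;
* lineage-restricted indels (off by default) with a geometric length
  distribution;
* a crude selection switch: within a designated ORF window,
  nonsynonymous substitutions are accepted with a reduced probability,
  emulating purifying selection for power tests of the dN/dS module.

Every alignment column that ever existed is tracked as an object, so
the true multiple alignment and the final coordinates of every feature
come from coordinate bookkeeping, never from re-alignment.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    Feature,
    HostTree,
    MultipleAlignment,
    NucSequence,
    tree_from_newick_string,
    write_fasta,
    write_gff3,
)
from .selection_test import _BASES, _CODE

__all__ = [
    "SgeEvent",
    "RecombEvent",
    "IndelModel",
    "OrfSpec",
    "SimConfig",
    "SimTruth",
    "simulate",
    "expected_divergence",
    "evolve_neutral_codon_rows",
    "fixture_suite",
    "eleven_species_config",
]

_BASE_TUPLE = ("A", "C", "G", "T")


def jc_substitution_probability(t_myr: float, mu: float) -> float:
    """Per-site substitution probability over one lineage segment."""
    if t_myr < 0:
        raise ValueError("negative time segment")
    return 0.75 * (1.0 - math.exp(-4.0 * mu * t_myr * 1e6 / 3.0))


def expected_divergence(t_myr: float, mu: float) -> float:
    """Expected observed percent divergence of two lineages split t Myr ago.

    Each lineage evolves independently for ``t_myr``, so the pair is
    separated by ``2·t`` of per-lineage time:
    ``100 × (3/4)(1 − exp(−(8/3)·mu·1e6·t))``.  Saturates at 75%.
    """
    if t_myr < 0:
        raise ValueError("negative time")
    return 100.0 * 0.75 * (1.0 - math.exp(-(8.0 / 3.0) * mu * 1e6 * t_myr))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SgeEvent:
    """One selfish-element insertion into the evolving provirus.

    ``position`` is in ancestral element coordinates (0 = first base of
    the 5' LTR).  ``clade`` is None for an insertion on the stem
    lineage (inherited by all species) or a tuple of leaf labels whose
    MRCA stem branch carries the event.  ``ltr_len`` > 0 turns the
    insert into a secondary provirus (LTR–internal–LTR) whose LTRs can
    later recombine into a solo LTR.
    """

    family: str
    length: int
    time: float  # Ma
    position: int
    strand: str = "+"
    clade: tuple[str, ...] | None = None
    ltr_len: int = 0

    def total_length(self) -> int:
        return self.length + 2 * self.ltr_len if self.ltr_len else self.length


@dataclass(frozen=True)
class RecombEvent:
    """LTR–LTR recombination collapsing a secondary provirus to a solo LTR."""

    clade: tuple[str, ...]
    time: float  # Ma
    target_family: str


@dataclass(frozen=True)
class IndelModel:
    """Indel rate relative to the substitution rate; geometric lengths."""

    rate: float = 0.0
    mean_length: float = 3.0


@dataclass(frozen=True)
class OrfSpec:
    """A reading-frame window (element coordinates) under selection.

    ``nonsyn_rel`` scales the acceptance probability of nonsynonymous
    substitutions inside the window (1.0 = neutral).
    """

    start: int
    end: int
    nonsyn_rel: float = 1.0


@dataclass
class SimConfig:
    newick: str
    t_integration: float  # Ma
    rate: float = 4.5e-9  # substitutions/site/year, all branches
    rates: dict[str, float] = field(default_factory=dict)
    ltr_len: int = 500
    internal_len: int = 5500
    flank5_len: int = 800
    flank3_len: int = 800
    sge_events: list[SgeEvent] = field(default_factory=list)
    recomb_events: list[RecombEvent] = field(default_factory=list)
    indel: IndelModel = field(default_factory=IndelModel)
    orf: OrfSpec | None = None

    @property
    def element_len(self) -> int:
        return 2 * self.ltr_len + self.internal_len

    def host_tree(self) -> HostTree:
        rate = self.rate if self.rate > 0 else 4.5e-9  # placeholder; 0 handled in simulate
        return tree_from_newick_string(self.newick, default_rate=rate, rates=self.rates)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["sge_events"] = [
            SgeEvent(**{**e, "clade": tuple(e["clade"]) if e.get("clade") else None})
            for e in d.get("sge_events", [])
        ]
        d["recomb_events"] = [
            RecombEvent(clade=tuple(e["clade"]), time=e["time"], target_family=e["target_family"])
            for e in d.get("recomb_events", [])
        ]
        if "indel" in d:
            d["indel"] = IndelModel(**d["indel"])
        if d.get("orf"):
            d["orf"] = OrfSpec(**d["orf"])
        return cls(**d)


# ---------------------------------------------------------------------------
# internal machinery


class _Col:
    """One alignment column; identity is the only state."""

    __slots__ = ()


@dataclass
class _SimFeature:
    label: str
    family: str
    strand: str
    cols: list  # list[_Col], immutable once created
    kind: str   # "region", "ltr", "sge", "sec_ltr5", "sec_ltr3", "sec_internal", "orf"


class _Genome:
    """Per-lineage state: parallel column and residue lists + features."""

    def __init__(self, cols: list, residues: list, features: list[_SimFeature]):
        self.cols = cols
        self.residues = residues
        self.features = features

    def copy(self) -> "_Genome":
        return _Genome(list(self.cols), list(self.residues), list(self.features))

    def col_positions(self) -> dict[int, int]:
        return {id(c): i for i, c in enumerate(self.cols)}


@dataclass
class SimTruth:
    """Complete provenance of one simulation run."""

    t_integration: float
    seed: int
    rate: float
    branch_substitutions: dict[str, int]
    sge_log: list[dict]
    recomb_log: list[dict]
    indel_log: list[dict]
    feature_coordinates: dict[str, dict[str, tuple[int, int]]]  # species -> label -> (start, end)

    def to_dict(self) -> dict:
        return {
            "t_integration": self.t_integration,
            "seed": self.seed,
            "rate": self.rate,
            "branch_substitutions": self.branch_substitutions,
            "sge_log": self.sge_log,
            "recomb_log": self.recomb_log,
            "indel_log": self.indel_log,
            "feature_coordinates": {
                sp: {k: list(v) for k, v in d.items()}
                for sp, d in self.feature_coordinates.items()
            },
        }


class _Simulator:
    def __init__(self, config: SimConfig, seed: int):
        self.cfg = config
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.tree = config.host_tree()
        self.rate_zero = config.rate == 0
        self.master: list = []          # global column order
        self.orig_index: dict[int, int] = {}  # id(col) -> ancestral coordinate
        self.branch_subs: dict[str, int] = {}
        self.sge_log: list[dict] = []
        self.recomb_log: list[dict] = []
        self.indel_log: list[dict] = []

    # -- setup ------------------------------------------------------------

    def _random_seq(self, n: int) -> list:
        return [_BASE_TUPLE[i] for i in self.rng.integers(0, 4, size=n)]

    def _build_ancestor(self) -> _Genome:
        cfg = self.cfg
        ltr = self._random_seq(cfg.ltr_len)
        internal = self._random_seq(cfg.internal_len)
        flank5 = self._random_seq(cfg.flank5_len)
        flank3 = self._random_seq(cfg.flank3_len)
        residues = flank5 + ltr + internal + list(ltr) + flank3  # LTRs identical
        cols = [_Col() for _ in residues]
        self.master = list(cols)
        self.orig_index = {id(c): i for i, c in enumerate(cols)}
        o5 = cfg.flank5_len
        feats = [
            _SimFeature("5'flank", "flank", "+", cols[:o5], "region"),
            _SimFeature("5'LTR", "LTR", "+", cols[o5 : o5 + cfg.ltr_len], "ltr"),
            _SimFeature(
                "internal",
                "internal",
                "+",
                cols[o5 + cfg.ltr_len : o5 + cfg.ltr_len + cfg.internal_len],
                "region",
            ),
            _SimFeature(
                "3'LTR",
                "LTR",
                "+",
                cols[o5 + cfg.ltr_len + cfg.internal_len : o5 + cfg.element_len],
                "ltr",
            ),
            _SimFeature("3'flank", "flank", "+", cols[o5 + cfg.element_len :], "region"),
        ]
        if cfg.orf is not None:
            feats.append(
                _SimFeature(
                    "ORF",
                    "orf",
                    "+",
                    cols[o5 + cfg.orf.start : o5 + cfg.orf.end],
                    "orf",
                )
            )
        return _Genome(cols, residues, feats)

    # -- node ages and event scheduling -----------------------------------

    def _annotate_ages(self):
        root = self.tree.tree.seed_node
        self._depth = {}
        for node in self.tree.tree.preorder_node_iter():
            if node is root:
                self._depth[node] = 0.0
            else:
                self._depth[node] = self._depth[node.parent_node] + (node.edge.length or 0.0)
        self.root_age = max(self._depth[leaf] for leaf in self.tree.tree.leaf_node_iter())
        self.age = {n: self.root_age - d for n, d in self._depth.items()}
        names = {}
        i = 0
        for node in self.tree.tree.preorder_node_iter():
            if node.taxon is not None:
                names[node] = node.taxon.label
            elif node.label:
                names[node] = node.label
            else:
                names[node] = f"internal_{i}"
                i += 1
        self.node_name = names

    def _schedule_events(self):
        """Attach each event to its edge (None = stem above the root)."""
        cfg = self.cfg
        self.edge_events: dict = {}
        for ev in list(cfg.sge_events) + list(cfg.recomb_events):
            clade = ev.clade if isinstance(ev, SgeEvent) else ev.clade
            if clade is None:
                top, bot = cfg.t_integration, self.root_age
                key = None
            else:
                node = self.tree.mrca(list(clade))
                if node is None:
                    raise ValueError(f"clade {clade} not found in tree")
                if node is self.tree.tree.seed_node:
                    top, bot, key = cfg.t_integration, self.root_age, None
                else:
                    top = self.age[node.parent_node]
                    bot = self.age[node]
                    key = node
            if not (bot <= ev.time <= top):
                raise ValueError(
                    f"event at {ev.time} Ma does not fall on its edge "
                    f"({bot}-{top} Ma)"
                )
            self.edge_events.setdefault(key, []).append(ev)
        for events in self.edge_events.values():
            events.sort(key=lambda e: -e.time)

    # -- evolution --------------------------------------------------------

    def _mutate(self, genome: _Genome, t_myr: float, rate: float, branch: str):
        if t_myr <= 0 or self.rate_zero or rate == 0:
            return
        p = jc_substitution_probability(t_myr, rate)
        n = len(genome.residues)
        hits = np.nonzero(self.rng.random(n) < p)[0]
        if hits.size == 0:
            return
        orf = self.cfg.orf
        orf_cols = None
        if orf is not None and orf.nonsyn_rel < 1.0:
            for f in genome.features:
                if f.kind == "orf":
                    pos = genome.col_positions()
                    orf_cols = [pos[id(c)] for c in f.cols if id(c) in pos]
        count = 0
        alt = self.rng.integers(0, 3, size=hits.size)
        for k, i in enumerate(hits):
            old = genome.residues[i]
            if old not in _BASE_TUPLE:  # N — never substituted
                continue
            choices = [b for b in _BASE_TUPLE if b != old]
            new = choices[alt[k]]
            if orf_cols is not None and i in orf_cols:
                j = orf_cols.index(i)
                frame = j - (j % 3)
                if frame + 3 <= len(orf_cols):
                    codon_idx = orf_cols[frame : frame + 3]
                    old_codon = "".join(genome.residues[x] for x in codon_idx)
                    new_codon = "".join(
                        new if x == i else genome.residues[x] for x in codon_idx
                    )
                    if (
                        all(b in _BASES for b in old_codon)
                        and all(b in _BASES for b in new_codon)
                        and _CODE.get(old_codon) != _CODE.get(new_codon)
                    ):
                        if self.rng.random() >= orf.nonsyn_rel:
                            continue  # nonsynonymous change rejected
            genome.residues[i] = new
            count += 1
        self.branch_subs[branch] = self.branch_subs.get(branch, 0) + count

    def _apply_indels(self, genome: _Genome, t_myr: float, rate: float, branch: str):
        model = self.cfg.indel
        if model.rate <= 0 or t_myr <= 0 or self.rate_zero:
            return
        expected_subs = jc_substitution_probability(t_myr, rate) * len(genome.residues)
        n_events = self.rng.poisson(model.rate * expected_subs)
        for _ in range(n_events):
            length = int(self.rng.geometric(1.0 / model.mean_length))
            pos = int(self.rng.integers(0, max(len(genome.residues) - length, 1)))
            if self.rng.random() < 0.5:
                del genome.cols[pos : pos + length]
                del genome.residues[pos : pos + length]
                self.indel_log.append(
                    {"branch": branch, "kind": "del", "pos": pos, "len": length}
                )
            else:
                new_cols = [_Col() for _ in range(length)]
                anchor = genome.cols[pos] if pos < len(genome.cols) else None
                mpos = self.master.index(anchor) if anchor is not None else len(self.master)
                self.master[mpos:mpos] = new_cols
                genome.cols[pos:pos] = new_cols
                genome.residues[pos:pos] = self._random_seq(length)
                self.indel_log.append(
                    {"branch": branch, "kind": "ins", "pos": pos, "len": length}
                )

    # -- events -----------------------------------------------------------

    def _insertion_point(self, genome: _Genome, element_pos: int) -> int:
        """Index in genome.cols where ancestral element coordinate maps."""
        target = element_pos + self.cfg.flank5_len
        for i, c in enumerate(genome.cols):
            oi = self.orig_index.get(id(c))
            if oi is not None and oi >= target:
                return i
        return len(genome.cols)

    def _apply_sge(self, ev: SgeEvent, genome: _Genome, branch: str):
        at = self._insertion_point(genome, ev.position)
        if ev.ltr_len > 0:
            ltr = self._random_seq(ev.ltr_len)
            internal = self._random_seq(ev.length)
            residues = ltr + internal + list(ltr)
        else:
            residues = self._random_seq(ev.length)
        new_cols = [_Col() for _ in residues]
        anchor = genome.cols[at] if at < len(genome.cols) else None
        mpos = self.master.index(anchor) if anchor is not None else len(self.master)
        self.master[mpos:mpos] = new_cols
        genome.cols[at:at] = new_cols
        genome.residues[at:at] = residues
        if ev.ltr_len > 0:
            genome.features.extend(
                [
                    _SimFeature(ev.family, ev.family, ev.strand, new_cols, "sge"),
                    _SimFeature(
                        f"{ev.family}_LTR5", ev.family, ev.strand,
                        new_cols[: ev.ltr_len], "sec_ltr5",
                    ),
                    _SimFeature(
                        f"{ev.family}_internal", ev.family, ev.strand,
                        new_cols[ev.ltr_len : ev.ltr_len + ev.length], "sec_internal",
                    ),
                    _SimFeature(
                        f"{ev.family}_LTR3", ev.family, ev.strand,
                        new_cols[ev.ltr_len + ev.length :], "sec_ltr3",
                    ),
                ]
            )
        else:
            genome.features.append(
                _SimFeature(ev.family, ev.family, ev.strand, new_cols, "sge")
            )
        self.sge_log.append(
            {
                "family": ev.family,
                "time": ev.time,
                "position": ev.position,
                "strand": ev.strand,
                "length": ev.total_length(),
                "branch": branch,
            }
        )

    def _apply_recomb(self, ev: RecombEvent, genome: _Genome, branch: str):
        ltr5 = ltr3 = None
        for f in genome.features:
            if f.family == ev.target_family and f.kind == "sec_ltr5":
                ltr5 = f
            if f.family == ev.target_family and f.kind == "sec_ltr3":
                ltr3 = f
        if ltr5 is None or ltr3 is None:
            raise ValueError(
                f"recombination target {ev.target_family!r} has no LTR pair "
                "in this lineage"
            )
        pos = genome.col_positions()
        start = min(pos[id(c)] for c in ltr5.cols if id(c) in pos)
        stop = min(pos[id(c)] for c in ltr3.cols if id(c) in pos)
        n_removed = stop - start
        del genome.cols[start:stop]
        del genome.residues[start:stop]
        # the surviving 3' copy is the solo LTR
        genome.features = [
            f for f in genome.features
            if not (f.family == ev.target_family and f.kind in ("sec_ltr5", "sec_internal", "sge"))
        ]
        for f in genome.features:
            if f.family == ev.target_family and f.kind == "sec_ltr3":
                f.label = f"{ev.target_family}_soloLTR"
                f.kind = "solo_ltr"
        self.recomb_log.append(
            {
                "family": ev.target_family,
                "time": ev.time,
                "branch": branch,
                "removed_bp": n_removed,
            }
        )

    # -- traversal --------------------------------------------------------

    def _evolve_edge(self, genome: _Genome, key, top: float, bot: float, rate: float, branch: str):
        t_cursor = top
        for ev in self.edge_events.get(key, []):
            self._mutate(genome, t_cursor - ev.time, rate, branch)
            self._apply_indels(genome, t_cursor - ev.time, rate, branch)
            if isinstance(ev, SgeEvent):
                self._apply_sge(ev, genome, branch)
            else:
                self._apply_recomb(ev, genome, branch)
            t_cursor = ev.time
        self._mutate(genome, t_cursor - bot, rate, branch)
        self._apply_indels(genome, t_cursor - bot, rate, branch)

    def run(self):
        self._annotate_ages()
        self._schedule_events()
        if self.cfg.t_integration < self.root_age:
            raise ValueError(
                f"t_integration ({self.cfg.t_integration} Ma) predates the "
                f"tree root ({self.root_age} Ma)"
            )
        ancestor = self._build_ancestor()
        stem_rate = self.tree.default_rate if not self.rate_zero else 0.0
        self._evolve_edge(
            ancestor, None, self.cfg.t_integration, self.root_age, stem_rate, "stem"
        )
        leaves: dict[str, _Genome] = {}

        def descend(node, genome: _Genome):
            for child in node.child_nodes():
                g = genome.copy()
                rate = self.tree.rate_for(child) if not self.rate_zero else 0.0
                branch = self.node_name[child]
                self._evolve_edge(
                    g, child, self.age[node], self.age[child], rate, branch
                )
                if child.is_leaf():
                    leaves[self.node_name[child]] = g
                else:
                    descend(child, g)

        descend(self.tree.tree.seed_node, ancestor)
        return self._collect(leaves)

    # -- output -----------------------------------------------------------

    def _collect(self, leaves: dict[str, _Genome]):
        live_cols = set()
        for g in leaves.values():
            live_cols.update(id(c) for c in g.cols)
        order = [c for c in self.master if id(c) in live_cols]
        col_rank = {id(c): i for i, c in enumerate(order)}

        seqs: dict[str, NucSequence] = {}
        rows: list[NucSequence] = []
        feature_coords: dict[str, dict[str, tuple[int, int]]] = {}
        for name in sorted(leaves):
            g = leaves[name]
            pos = g.col_positions()
            feats = []
            coords = {}
            for f in g.features:
                surviving = sorted(pos[id(c)] for c in f.cols if id(c) in pos)
                if not surviving:
                    continue
                start, end = surviving[0], surviving[-1] + 1
                coords[f.label] = (start, end)
                feats.append(
                    Feature(
                        label=f.label, start=start, end=end,
                        strand=f.strand, family=f.family,
                    )
                )
            feature_coords[name] = coords
            seqs[name] = NucSequence(name, "".join(g.residues), feats)
            gapped = ["-"] * len(order)
            for c, r in zip(g.cols, g.residues):
                gapped[col_rank[id(c)]] = r
            rows.append(NucSequence(name, "".join(gapped), aligned=True))

        truth_aln = MultipleAlignment(rows)
        truth = SimTruth(
            t_integration=self.cfg.t_integration,
            seed=self.seed,
            rate=self.cfg.rate,
            branch_substitutions=dict(sorted(self.branch_subs.items())),
            sge_log=self.sge_log,
            recomb_log=self.recomb_log,
            indel_log=self.indel_log,
            feature_coordinates=feature_coords,
        )
        return seqs, truth_aln, truth


def simulate(config: SimConfig, seed: int):
    """Run the forward simulation.

    Returns ``(sequences, truth_alignment, truth)`` where ``sequences``
    maps species name to an annotated ungapped :class:`NucSequence`,
    ``truth_alignment`` is the bookkeeping-derived MSA and ``truth``
    records every event.  A fixed seed gives byte-identical output.
    """
    return _Simulator(config, seed).run()


# ---------------------------------------------------------------------------
# light-weight codon evolution for the selection tests


def evolve_neutral_codon_rows(
    n_codons: int,
    t_myr: float,
    mu: float,
    seed: int,
    n_rows: int = 2,
    nonsyn_rel: float = 1.0,
) -> list[str]:
    """Evolve ``n_rows`` in-frame rows from one stop-free ancestor.

    Star genealogy: every row evolves independently for ``t_myr`` Myr at
    rate ``mu`` under Jukes–Cantor, so any two rows are separated by
    ``2·t_myr`` of per-lineage time.  ``nonsyn_rel`` < 1 thins
    nonsynonymous changes (codon-at-a-time), emulating purifying
    selection.  Mutations creating stop codons are allowed — downstream
    counting is expected to skip them, as it would for real dead ERVs.
    """
    rng = np.random.default_rng(seed)
    sense = sorted(_CODE)  # 61 sense codons
    ancestor = [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]
    p = jc_substitution_probability(t_myr, mu)
    rows = []
    for _ in range(n_rows):
        row = []
        for codon in ancestor:
            cur = codon
            for posn in range(3):
                if rng.random() >= p:
                    continue
                old = cur[posn]
                choices = [b for b in _BASES if b != old]
                new = choices[rng.integers(0, 3)]
                cand = cur[:posn] + new + cur[posn + 1 :]
                if nonsyn_rel < 1.0 and _CODE.get(cand) != _CODE.get(cur):
                    if rng.random() >= nonsyn_rel:
                        continue
                cur = cand
            row.append(cur)
        rows.append("".join(row))
    return rows


# ---------------------------------------------------------------------------
# canonical fixture


#: An 11-species placental-mammal tree: Afrotheria (elephant, manatee,
#: aardvark, golden mole), Xenarthra (armadillo) and Boreoeutheria
#: (human, chimpanzee, pig, horse, two bats), rooted 104 Ma.
MAMMAL_TREE_NEWICK = (
    "(((elephant:60,manatee:60):15,(aardvark:70,golden_mole:70):5):29,"
    "(armadillo:100,(((pig:80,horse:80):5,"
    "(bat_carollia:65,bat_pteropus:65):20):10,"
    "(human:8,chimpanzee:8):87):5):4);"
)

AFROTHERIA = ("elephant", "manatee", "aardvark", "golden_mole")


def eleven_species_config(
    t_integration: float = 130.0,
    rate: float = 4.5e-9,
    ltr_len: int = 500,
    internal_len: int = 5500,
) -> SimConfig:
    """The canonical 11-species scenario.

    A provirus integrated at 130 Ma into the ancestor of the placental
    mammals; three SGEs (two MIRs and an MER3) inserted on the stem, so
    all 11 species share them; a secondary provirus inserted on the
    Afrotherian stem that recombined into a solo LTR, so only the
    Afrotheria carry it.
    """
    return SimConfig(
        newick=MAMMAL_TREE_NEWICK,
        t_integration=t_integration,
        rate=rate,
        ltr_len=ltr_len,
        internal_len=internal_len,
        sge_events=[
            SgeEvent(family="MIR.1", length=180, time=120.0, position=4000),
            SgeEvent(family="MER3.1", length=200, time=115.0, position=4450),
            SgeEvent(family="MIR.2", length=180, time=112.0, position=4750),
            SgeEvent(
                family="ERVsec",
                length=600,
                time=95.0,
                position=2300,
                clade=AFROTHERIA,
                ltr_len=450,
            ),
        ],
        recomb_events=[
            RecombEvent(clade=AFROTHERIA, time=90.0, target_family="ERVsec")
        ],
    )


def two_species_config(
    t_integration: float = 130.0,
    t_host: float = 104.0,
    rate: float = 4.5e-9,
    ltr_len: int = 500,
    internal_len: int = 1000,
    flank_len: int = 200,
) -> SimConfig:
    """Minimal human/elephant-style pair for estimator recovery runs."""
    return SimConfig(
        newick=f"(speciesA:{t_host},speciesB:{t_host});",
        t_integration=t_integration,
        rate=rate,
        ltr_len=ltr_len,
        internal_len=internal_len,
        flank5_len=flank_len,
        flank3_len=flank_len,
    )


def fixture_suite(out_dir: str | os.PathLike, seed: int) -> dict[str, str]:
    """Write the canonical scenario to disk (FASTA/GFF3/Newick/JSON).

    Deterministic: the same seed yields byte-identical files.  Returns
    the mapping of artifact names to paths.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    cfg = eleven_species_config()
    seqs, truth_aln, truth = simulate(cfg, seed=seed)
    paths = {
        "sequences": os.path.join(out_dir, "elements.fasta"),
        "alignment": os.path.join(out_dir, "truth_alignment.fasta"),
        "annotations": os.path.join(out_dir, "annotations.gff3"),
        "tree": os.path.join(out_dir, "host_tree.nwk"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_fasta([seqs[k] for k in sorted(seqs)], paths["sequences"])
    write_fasta(list(truth_aln), paths["alignment"])
    write_gff3({k: seqs[k].features for k in sorted(seqs)}, paths["annotations"])
    with open(paths["tree"], "w") as fh:
        fh.write(MAMMAL_TREE_NEWICK + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
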