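# Methods

## The dating model

An endogenous provirus carries two LTRs that are identical at
integration and thereafter evolve independently at the host's neutral
rate. For an insertion orthologous in two host species A and B:

- **same-LTR divergence** `d_same` — e.g. 5′LTR(A) vs 5′LTR(B) — has
  accrued along two lineages since the species split at `t_host`;
- **cross-LTR divergence** `d_cross` — the mean of 5′LTR(A) vs 3′LTR(B)
  and 5′LTR(B) vs 3′LTR(A) — has accrued along two lineages since the
  integration itself.

The estimator is

```
d_pre           = max(d_cross − d_same, 0)        [%]
t_pre           = d_pre / (2 · mu_pct)            [Myr]
t_integration   = t_host + t_pre                  [Ma]
```

with `mu_pct = mu · 1e6 · 100` the per-lineage rate in %/Myr (so
4.5e-9 subs/site/yr → 0.45 %/Myr; the conversion is printed in every
result's provenance because the 10⁶·100 factor is the classic unit
trap). The factor 2 counts both diverging lineages. A negative
subtraction — possible through sampling noise — clamps to zero with a
flag, so an estimate never predates the host split it is anchored on.

Assumptions: strict neutrality of both LTRs, a single clock rate shared
by the lineages compared, no gene conversion or recombination between
LTRs, and a correct host divergence date. `t_host` and `mu` are always
user inputs, never constants — host dates in the literature differ
(e.g. a 104–110 Ma window for the placental radiation) and the rate is
a proxy borrowed from a fast-generation mammal.

### Raw vs corrected divergences

By default the arithmetic runs on observed (uncorrected) percent
divergence, reproducing the classic back-of-envelope form. Observed
divergence saturates (toward 75% under Jukes–Cantor), so for old
elements the raw estimator is biased downward; at a true integration of
130 Ma with a 104 Ma host split and mu = 4.5e-9 the expected observed
divergences (~59% cross, ~53% same) yield ≈110 Ma. The
`correct_multiple_hits=True` mode first converts each observed
divergence to a Jukes–Cantor distance, `d = −75·ln(1 − 4p/300)` (in
%), which makes the estimator unbiased under the simulator's model;
validation and recovery experiments therefore run in corrected mode,
while the reference-input computations use the raw mode they were
printed with.

## Alignment and divergence measurement

Global alignment is Needleman–Wunsch with affine gaps via Biopython's
`PairwiseAligner`, defaults match +5 / mismatch −4 / gap open 10 /
gap extend 0.5 (a gap of length L costs `open + (L−1)·extend`; end gaps
are penalized like internal ones). Among co-optimal alignments the
aligner's first traceback is taken, with arguments canonicalized by
(length, sequence) order so that alignment and all column statistics
are symmetric under swapping inputs and bit-reproducible across runs.
The test suite pins the optimum against exhaustive enumeration of all
global alignments for short pairs.

Percent divergence is the fraction of non-identical compared columns.
Columns containing N are never compared; columns containing a gap are
excluded by default (`gap_policy="exclude"`) or counted as differences
(`"count"`). Identity is defined as 100 − divergence under the same
policy, exactly.

**Divergence at saturation.** For sequences beyond roughly 50% true
divergence, permissive gap penalties let a global aligner manufacture
gaps that pair up chance matches, deflating observed divergence well
below even its saturated expectation. The package therefore exposes
`UNGAPPED_PARAMS` (gap penalties no gap can repay at these lengths):
when comparing sequences whose length differences are known to be
substitution-free — such as the simulator's indel-free LTRs — this
reduces the comparison to the positional one the clock model assumes.
All validation experiments use it; for real, indel-containing LTRs the
default parameters apply and the gap policy is stated in the result
provenance.

## Orthology evidence metrics

- **Conservation profile**: per alignment column, the frequency of the
  most common non-gap residue among rows with a residue there
  (`majority`, default). The denominator excludes gap rows so columns
  missing from some species are not penalized; `majority_all` (divide
  by all rows) and `pairwise` (mean pairwise match fraction) are
  selectable because histogram conventions differ between viewers.
  All-gap columns score 0.
- **Region identity matrix**: a fixed column window is projected onto
  each species pair, columns where either row has a gap (or N) are
  dropped pairwise — no re-alignment, so region boundaries stay
  comparable across pairs — and percent identity is computed. Pairs
  with zero comparable columns are flagged NaN, never silently 0.
- **SGE concordance**: repeat annotations are mapped to alignment
  windows via each species' gap structure, grouped by family label, and
  called concordant iff all present copies share strand and all window
  pairs overlap by ≥ 50% of the shorter window. The 50% threshold
  operationalizes "same location" — insertions at the same ancestral
  site stay heavily overlapping even after lineage-specific indels,
  while independent insertions of the same family essentially never
  overlap. Absence in a subset of species is reported, not penalized:
  lineage-specific deletion removes a marker without breaking
  orthology.

## dN/dS neutrality test

Nei–Gojobori-style counting: per codon, each position contributes
(synonymous single-base changes)/3 synonymous sites (changes to stop
codons count as nonsynonymous); observed differences between codon
pairs are classified by averaging over all mutational pathways with
equal weights, excluding pathways through stop codons unless all are.
Codons containing a gap, N or stop in either row are skipped pairwise
(gaps must cover whole codons, keeping frame). Pooled proportions are
Jukes–Cantor corrected (falling back to the raw proportion at or
beyond saturation, where the correction is undefined); H0: dN = dS is
tested with a z-statistic whose variance comes from a seeded bootstrap
over codons (default 1000 resamples; resamples with zero synonymous or
nonsynonymous sites are dropped as uninformative). This counting
method was chosen over a likelihood codon model because every piece is
verifiable by enumeration; the choice trades some power for
auditability. Multi-row alignments report the mean of pairwise ratios
and the mean of pairwise p-values; the averaged p is a descriptive
summary, not a calibrated combination test — per-pair p-values carry
the inference.

On neutral simulations at 108 codons the empirical size at α = 0.05 is
≈ 2–5%; with nonsynonymous changes thinned to 0.2× the test detects
purifying selection in essentially all replicates at the same scale.

## The simulator

`synthetic_data.simulate` builds an ancestral sequence
(flank + LTR + internal + identical LTR + flank, all i.i.d. random),
evolves it down the stem lineage from `t_integration` to the root of a
dated, ultrametric host tree, then recursively along every branch.
Substitutions follow Jukes–Cantor: over a lineage segment of `t` Myr at
rate `mu`/site/yr each site substitutes with probability
`(3/4)(1 − exp(−4·mu·t·1e6/3))`, with the replacement base uniform over
the other three. The closed-form companion `expected_divergence(t, mu)
= 75·(1 − exp(−(8/3)·mu·1e6·t))` (two lineages of `t` each) is used in
the clock-linearity tests.

Event machinery: every alignment column ever created is a tracked
object, and insertions splice new columns into a global column order,
so the true multiple alignment and every feature's final coordinates
come from bookkeeping, never from re-alignment. SGE insertions are
fresh random sequences with recorded family/orientation — no real
repeat consensus is needed, since the metrics only use positions and
labels. Insertions on the stem are inherited by all species; insertions
on a branch only by that clade. A secondary provirus (LTR–internal–LTR)
can later suffer LTR–LTR recombination in a clade, deleting one LTR
plus the internal region and leaving a solo LTR. Indels (geometric
lengths, rate relative to the substitution rate) are off by default so
the dating experiments see clean LTRs; they exist to stress the
evidence metrics. A crude selection switch thins nonsynonymous
substitutions within a designated ORF window for dN/dS power tests.

Default scenario (`eleven_species_config`): 11 placental mammals —
four Afrotherians, an armadillo, and six Boreoeutherians — on an
ultrametric tree rooted at 104 Ma; provirus of 500 bp LTRs and 5.5 kb
internal region integrated at 130 Ma; two MIRs and one MER3 inserted on
the stem (120–112 Ma) so all species share them; a secondary provirus
on the Afrotherian stem (95 Ma) recombined to a solo LTR at 90 Ma.
Rate 4.5e-9/site/yr on every branch. These defaults mirror the
inferred history of the oldest known ERV orthologue; what the simulator
does **not** emulate: rate variation among sites and lineages, indel
realism (real alignments were manually curated), gene conversion
between LTRs, recombination between paralogous copies, and
population-level fixation dynamics. Passing recovery tests therefore
show the estimator is correct under its own model assumptions, not that
real data meet them — gene conversion in particular would shrink
cross-LTR divergence and push estimates toward the host date.

## Validation experiments and problem sizes

- Parameter recovery: 30 two-species replicates (500 bp LTRs, truth
  130 Ma, host split 104 Ma, mu 4.5e-9), full pipeline in corrected
  mode; mean estimate within ±10 Myr of truth, truth inside the
  empirical 2.5–97.5% band (typical run: mean ≈ 130.5 Ma, sd ≈ 12 Myr).
  Replicate sd is dominated by the Jukes–Cantor correction's variance
  amplification near saturation.
- Aligner oracle: 500 random pairs of length ≤ 8, score equality
  against exhaustive enumeration of every global alignment.
- Neutrality-test size: 200 neutral replicates at 108 codons.
- Clock linearity: 50 replicates at t ∈ {10, 50, 100} Myr, mean
  observed divergence within 3 SE of the closed form.

Sizes were chosen to keep each experiment's Monte-Carlo error well
below the tolerance it checks while completing in seconds.

## Numerical and convention choices

- Coordinates 0-based half-open internally; GFF3 I/O converts to/from
  1-based inclusive; GFF3 strand "." is stored as "+" with
  `strand_known=False` and round-trips back to ".".
- Newick branch lengths are Myr; neutral rates live in configuration
  (one global default with per-branch overrides), not in the tree file.
- `N` residues are excluded from every divergence/identity/codon count.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; the fixture suite is byte-identical for a
  fixed seed.
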