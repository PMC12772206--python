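# Methods

`gaptract` models an in-vitro mismatch-repair (MMR) excision experiment on a
circular heteroduplex plasmid and implements the computational readouts of
that experiment: restriction-digest repair quantification, forward
simulation of strand-specific excision gaps, mapping of those gaps by
single-strand-specific cytidine deamination, and the summary statistics
computed over the mapped tracts. This note records the models, the
parameters that matter, the numerical choices, and the known limitations.

## Coordinate conventions

All coordinates are 0-based positions on the *nicked* strand of the circular
plasmid, read 5'->3'. Intervals are half-open `[start, end)` and may wrap
past the origin (`end <= start`); interval length is `(end - start) mod L`.
The full circle is not representable as one interval; full-circle excision
is rejected upstream. The continuous (template) strand is the reverse
complement of the nicked strand. An *eligible cytidine* is a
continuous-strand C, i.e. a reference G in nicked-strand orientation. The
continuous strand runs antiparallel, so the 5' neighbour of the C paired
with nicked-strand position `p` sits at nicked coordinate `p + 1`.

## Substrate and digestion model

A `PlasmidSubstrate` carries the nicked-strand sequence, the nick, the
mispair, per-enzyme cut positions, and which strand's copy of a
mispair-overlapping site is intact (`mispair_readout`). `build_substrate`
plants one recognition motif per requested enzyme and draws the background
i.i.d., locally rerolling background bases until no motif occurs a second
time anywhere on the circle; the result is deterministic per seed.
Degenerate recognition sites (NspI, AflIII) are planted as one concrete
instance.

Digestion is a complete circular digest: `n` cut positions yield `n`
fragments summing to the plasmid length; zero cuts leave one full-length
circle. A mispair-overlapping site cuts only in a `repaired` molecule and
only if its intact copy reads the continuous strand (the repair template);
this encodes heteroduplex site disruption as a per-strand boolean rather
than re-deriving it from sequence, because which strand each diagnostic
enzyme reports is a property of the substrate design. `percent_repair` is
mass-weighted by default (gel-stain intensity is mass-like); molar tables
are converted by length-weighting.

The packaged fixture substrate is 2,900 nt with ScaI/PstI arcs of 1,800 and
1,100 nt and the nick 276 nt 5' of the mispair, so a repaired molecule
yields the 1.8/1.1 kb diagnostic fragments and an unrepaired heteroduplex
stays full length. The fixture reproduces arc lengths and readout logic,
not any particular laboratory sequence.

## Excision simulators

Three mechanisms generate per-molecule `GapSet`s (disjoint excised
intervals on the nicked strand), each with molecule-indexed RNG substreams
so results are independent of execution order and reproducible per seed.

- **exo1** — one polar gap per molecule starting exactly at the nick and
  extending 5'->3'; tract length defaults to uniform over [327, 832] nt,
  the support observed for exonucleolytic tracts on this substrate
  geometry.
- **mlh_pms1_mixture** — a phenomenological two-component mixture. With
  probability `polar_probability` (default 0.40) the molecule receives one
  nick-initiated gap with length uniform over [385, 767] nt. Otherwise it
  receives `k` dispersed gaps, `k` from a zero-truncated Poisson (mean 1.6,
  capped at 6, matching the 1-6 gaps per molecule seen by electron
  microscopy), placed uniformly and disjointly by rejection sampling with
  bounded retries (on failure `k` is reduced with a warning). Dispersed gap
  lengths default to a log-normal with median 17 nt truncated to [1, 132]
  nt; only the median and range of short tracts are constrained
  empirically, so a right-skewed family matching those order statistics was
  chosen, with sigma = 1.0 placing the truncation bounds near +-2.5 sigma.
- **mlh_pms1_nick_dissociation** — a mechanistic mode: extra nicks
  (Poisson count at `nick_rate`, uniform distinct positions) join the
  preexisting nick; every circular inter-nick fragment shorter than
  `dissociation_threshold` (default 30 nt, the scale at which short
  oligonucleotides dissociate from the duplex) is lost, and adjacent losses
  coalesce into one gap. A lone nick produces no gap; the longest fragment
  is always retained as a guard against losing the whole molecule. No
  spatial law for nicking is asserted beyond uniformity.

The mixture and mechanistic modes are both provided deliberately: whether
long polar gaps arise from processive nicking or a distinct complex is an
open mechanistic question, and the simulator does not take a position.

## Deamination model

Inside each gap the nicked strand is absent, leaving continuous-strand
cytidines single-stranded. Each deaminates independently with a probability
keyed by its preceding continuous-strand base — by class
(`pyrimidine-C` / `purine-C`, defaults 0.9 / 0.3, reflecting the enzyme's
preference for pyrimidine-preceded cytidines) or by full dinucleotide when
given. Deamination probability is zero inside *protected intervals*,
modelling hairpin-forming regions whose stem is not single-stranded.
Fill-in replication fixes each C->U deterministically, so a deaminated
position appears in the emitted clone as G>A in nicked-strand orientation.
Clones are emitted full length in nicked-strand orientation with the truth
`GapSet` attached.

`nicked_strand_deamination_probability` (default 0) is a contamination
knob: gaps remove the nicked strand, so no nicked-strand cytidine is
genuinely exposed in this model; setting it above zero injects C>T calls
for testing the strand-exclusivity invariant, nothing more.

Protection intervals come from a deliberately naive inverted-repeat finder
(stem >= `stem_min`, loop <= `loop_max`, bounded mismatches, circular,
symmetric under reverse complement). It is a structural proxy, not a
thermodynamic folding prediction, and is documented as such.

## Calling and tract segmentation

Clones must equal the reference in length (pure-substitution contract);
indel-containing clones are rejected rather than aligned, because silent
indel tolerance would corrupt downstream tract logic. Assembly rotation is
normalised by locating an exact reference 30-mer at a unique offset in the
doubled clone; successive anchors are tried so a substitution inside one
anchor is harmless. Each mismatch is classified: ref G -> clone A is
continuous-strand deamination, ref C -> clone T is nicked-strand
deamination, anything else is background. Clones with more than
`max_other` (default 2) background substitutions are QC-flagged but their
deamination events are never removed. The reference is the fill-in
product, so the mispair position itself never scores.

Segmentation operates on the eligible-cytidine sequence:

1. *Initial tracts* are maximal circular runs of eligible positions that
   are all deaminated; each spans first to last event, inclusive.
   Single-event tracts have length 1 nt.
2. *Merging*: adjacent tracts separated by at most `max_skip` (default 3)
   nondeaminated eligible cytidines merge, iterated to a fixed point
   around the circle; each skipped cytidine is recorded with its preceding
   continuous-strand base, since escape from deamination is
   context-biased. The threshold is a parameter because only the realized
   skip statistics, not the rule itself, are constrained by observation.
3. *Classification*: a clone is `polar_nick_initiated` iff it has exactly
   one merged tract whose 5'-most event lies within `nick_window`
   (default 25 nt) 3' of the nick; any other event-bearing clone is
   `dispersed`.

Degenerate circular cases are resolved explicitly: if every inter-tract
separation is mergeable (or every eligible position is deaminated), the
circle is broken at the largest separation — most skipped cytidines first,
then widest nucleotide distance, then first in coordinate order — so the
result is always a set of linear tracts. Event lists are kept in span
order across the break. Increasing `max_skip` never increases the tract
count, and old spans nest inside new ones.

## Summary statistics

Tract-length statistics use the lower median for even counts (a convention
choice, documented rather than asserted). Positional deamination fractions
condition on coverage: the denominator at a position counts clones whose
merged tract span covers it, so dispersed clones contribute only within
their spans; uncovered positions are null. By default all covering clones
enter the denominator regardless of classification. Dinucleotide fractions
count eligible cytidines inside coverage, outside protected intervals,
keyed both by preceding (N-C) and following (C-N) base on the continuous
strand; the headline pyrimidine-vs-purine contrast uses the preceding
base. The electron-microscopy calibration converts contour length to
nucleotides at 116.6 nm per 1,000 nt (uncertainty 14.7 nm), with exact
round-tripping to within half a nucleotide's nm.

**Estimator caveat.** Fractions conditioned on *called* tract spans are
upward-biased: spans begin and end at observed events, and separations
longer than `max_skip` are excluded from coverage, both of which remove
non-events from the denominator (measured at roughly +0.02 / +0.05 for
0.9 / 0.3 context probabilities). This is a property of the estimator, not
a bug. `dinucleotide_fraction` therefore also accepts event-independent
coverage (e.g. simulator truth gaps), which is what the parameter-recovery
validation uses; tables over called spans are descriptive.

**Classification caveat.** At sub-unity deamination probabilities, a long
polar footprint occasionally contains more than `max_skip` consecutive
nondeaminated eligible cytidines and splits into several tracts, which the
strict one-merged-tract rule then labels dispersed. The polar clone
fraction recovered end-to-end is therefore a lower bound on the generating
mixture weight unless deamination is efficient; mixture-weight validation
is done on the simulator's origin tags, where the empirical fraction
converges binomially to `polar_probability`.

## Validation problem sizes

The test suite validates exact ground-truth recovery (deamination
probability 1, no protection) over 100 random substrates with identifiable
gap configurations — gaps separated by more than `max_skip` eligible
cytidines, internal gaps outside the nick window, an eligible cytidine
available near the nick — since without identifiability exact recovery is
not well-posed. Segmentation is checked against an independent exhaustive
event-linkage oracle over 1,000 randomized clones on toy references up to
200 nt. Statistical recovery uses 10,000 molecules for the mixture weight,
200 clones for context probabilities, and 1,000 clones for strand
exclusivity. The end-to-end pipeline is exercised at 500 clones.

## What the generator does not emulate

Sequencing error, indels and chimeric assemblies; replication infidelity
beyond the deterministic C->U -> G>A readout; deaminase processivity and
kinetics; thermodynamic secondary structure (the inverted-repeat proxy has
no energy model); ligation efficiency; and selection against clones whose
gaps disable plasmid replication or selection markers — in real data very
long gaps are depleted for this reason, so simulated long-gap tails are
fuller than sequenced ones. Passing tests demonstrate correctness of the
algorithms under the stated generative model, not fidelity of that model
to every property of real sequencing data.
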