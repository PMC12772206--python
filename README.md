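# gaptract

Strand-specific mapping and simulation of mismatch-repair (MMR) excision
gaps on circular heteroduplex plasmids, using cytidine-deamination
footprints.

## The problem

Reconstituted MMR reactions repair a circular plasmid that carries a
mispair and a single-strand nick: the nicked strand is excised across the
mispair and resynthesized from the continuous strand. Where excision
happened, the continuous strand is transiently single-stranded — and a
single-strand-specific cytidine deaminase (APOBEC3A) marks exactly those
regions. After fill-in and replication, each deaminated continuous-strand
C reads out in a sequenced clone as a G>A substitution in nicked-strand
orientation, so whole-plasmid sequencing of individual clones turns each
molecule's excision gaps into a mapped substitution footprint.

`gaptract` is for people analysing or modelling such experiments. It
provides:

- a circular substrate model with restriction-digest repair readouts
  (`digest`, `percent_repair`);
- forward simulators for three excision mechanisms — a single polar
  5'->3' gap from the nick (Exo1-style), a polar/dispersed mixture
  (long nick-initiated gaps in ~40% of molecules, 1-6 short scattered
  gaps in the rest), and a mechanistic nick-dissociation mode — followed
  by context-dependent deamination with hairpin protection
  (`simulate_clones`);
- a strand-aware substitution caller for full-length clone sequences
  (`call_events`: G>A = continuous-strand deamination, C>T =
  nicked-strand deamination, everything else QC background);
- the tract algorithm (`segment_clone`): maximal runs of deaminated
  eligible cytidines, merging across at most `max_skip` nondeaminated
  cytidines (skip contexts recorded), and polar/dispersed classification
  against a nick-proximity window;
- summary statistics: tract-length order statistics, positional and
  dinucleotide deamination fractions, skipped-cytidine context counts,
  gap-count histograms, and the electron-microscopy calibration
  116.6 nm per 1,000 nt (`nm_to_nt` / `nt_to_nm`).

Coordinates are 0-based, half-open, circular (explicit `wraps` flag), on
the nicked strand 5'->3'. See `docs/methods.md` for the models,
parameter defaults and their rationale, and known limitations.

## Worked example

```python
import gaptract as g

sub = g.default_fixture_substrate()
print(sorted(g.digest(sub, "repaired", ["ScaI", "PstI"]).lengths))
print(g.digest(sub, "unrepaired_heteroduplex", ["ScaI", "PstI"]).lengths)

exc = g.ExcisionModelParams(mechanism="mlh_pms1_mixture", seed=1)
dea = g.DeaminationModelParams(seed=1, use_protection=False)
clones = g.simulate_clones(sub, exc, dea, 200)
labels = [g.segment_clone(g.call_events(c, sub), sub)[1].label for c in clones]
print({l: labels.count(l) for l in set(labels)})
print("37 nm of ssDNA =", g.nm_to_nt(37.0), "nt")
```

prints

```
[1100, 1800]
[2900]
{'dispersed': 178, 'no_events': 11, 'polar_nick_initiated': 11}
37 nm of ssDNA = 317 nt
```

The repaired molecule's ScaI+PstI double digest yields the 1.8/1.1 kb
diagnostic fragments while the unrepaired heteroduplex stays full length
(the mispair disrupts the continuous-strand PstI site). Of 200 simulated
mixture clones, 84 truly carry a polar nick-initiated gap; at the default
context probabilities (0.9 pyrimidine-C / 0.3 purine-C) most polar
footprints split on nondeaminated runs longer than `max_skip`, so the
strict one-tract polar rule recovers only a fraction of them — the
classified polar count is a lower bound, as discussed in
`docs/methods.md`. The last line converts an electron-microscopy contour
length to nucleotides with the single-stranded-circle calibration.

The same pipeline is scriptable from a shell:

```sh
gaptract simulate --config run.yaml --out sim/
gaptract call  --reference sim/reference.fasta --annotations sim/reference.yaml \
               --clones sim/clones.fasta --out called/
gaptract stats --reference sim/reference.fasta --annotations sim/reference.yaml \
               --clones sim/clones.fasta --out stats/
gaptract fetch --dest data/zenodo-17107465   # optional, needs network
```

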