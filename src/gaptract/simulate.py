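"""Forward simulation of excision gaps and single-strand cytidine deamination.

Three excision mechanisms are modelled on a nicked circular heteroduplex:

``exo1``
    A single polar gap per molecule starting exactly at the preexisting
    nick and resecting 5'->3' along the nicked strand, with tract length
    drawn from a configurable distribution (default uniform over the
    327-832 nt support observed for Exo1 tracts).

``mlh_pms1_mixture``
    A phenomenological two-component mixture: with probability
    ``polar_probability`` (default 0.40) the molecule receives one long
    nick-initiated polar gap; otherwise it receives one or more short
    dispersed gaps placed uniformly around the circle.

``mlh_pms1_nick_dissociation``
    A mechanistic mode: additional nicks are scattered on the nicked
    strand (Poisson count, uniform positions) and any inter-nick fragment
    shorter than a dissociation threshold is lost, converting runs of
    closely spaced nicks into gaps.

Deamination then converts continuous-strand cytidines inside gaps to
uracil with a context-dependent probability; after fill-in and replication
these read out as G>A substitutions in nicked-strand orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .intervals import CircularInterval
from .substrate import COMPLEMENT, PlasmidSubstrate

PYRIMIDINES = {"C", "T"}
PURINES = {"A", "G"}


# ---------------------------------------------------------------------------
# Distribution specs

@dataclass(frozen=True)
class DistSpec:
    """A small declarative distribution over positive integers.

    kinds: ``fixed`` (value), ``uniform_int`` (low, high inclusive),
    ``lognormal_int`` (median, sigma, truncated to [low, high] by
    resampling), ``zero_truncated_poisson`` (mean of the untruncated law,
    resampled into [1, max]).
    """

    kind: str
    params: Mapping[str, float] = field(default_factory=dict)

    def sample(self, rng: np.random.Generator) -> int:
        p = self.params
        if self.kind == "fixed":
            return int(p["value"])
        if self.kind == "uniform_int":
            return int(rng.integers(int(p["low"]), int(p["high"]) + 1))
        if self.kind == "lognormal_int":
            low, high = int(p.get("low", 1)), int(p["high"])
            mu = np.log(p["median"])
            for _ in range(10_000):
                x = int(round(float(rng.lognormal(mu, p.get("sigma", 1.0)))))
                if low <= x <= high:
                    return x
            raise RuntimeError("lognormal truncation rejected all draws")
        if self.kind == "zero_truncated_poisson":
            hi = int(p.get("max", np.inf))
            for _ in range(10_000):
                k = int(rng.poisson(p["mean"]))
                if 1 <= k <= hi:
                    return k
            raise RuntimeError("zero-truncated Poisson rejected all draws")
        raise ValueError(f"unknown distribution kind {self.kind!r}")


def fixed(value: int) -> DistSpec:
    return DistSpec("fixed", {"value": value})


def uniform_int(low: int, high: int) -> DistSpec:
    return DistSpec("uniform_int", {"low": low, "high": high})


# ---------------------------------------------------------------------------
# Domain types

@dataclass
class GapSet:
    """Excised (single-stranded) regions of one molecule's nicked strand."""

    molecule_id: str
    gaps: list[CircularInterval] = field(default_factory=list)
    origin_tags: list[str] = field(default_factory=list)  # nick_initiated | internal

    def validate(self, circle: int) -> None:
        if len(self.gaps) != len(self.origin_tags):
            raise ValueError("one origin tag per gap required")
        for i, g in enumerate(self.gaps):
            if g.length(circle) < 1:
                raise ValueError("zero-length gap")
            for h in self.gaps[i + 1:]:
                if g.overlaps(h, circle):
                    raise ValueError(f"gaps {g} and {h} overlap")


@dataclass
class NickSet:
    """All nick positions on one molecule (includes the preexisting nick)."""

    molecule_id: str
    nick_positions: list[int] = field(default_factory=list)


@dataclass
class ExcisionModelParams:
    mechanism: str = "mlh_pms1_mixture"
    exo1_tract_length_dist: DistSpec = field(default_factory=lambda: uniform_int(327, 832))
    polar_probability: float = 0.40
    polar_length_dist: DistSpec = field(default_factory=lambda: uniform_int(385, 767))
    dispersed_gap_count_dist: DistSpec = field(
        default_factory=lambda: DistSpec("zero_truncated_poisson", {"mean": 1.6, "max": 6}))
    dispersed_gap_length_dist: DistSpec = field(
        default_factory=lambda: DistSpec("lognormal_int", {"median": 17, "sigma": 1.0, "low": 1, "high": 132}))
    nick_rate: float = 10.0
    dissociation_threshold: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.polar_probability <= 1.0:
            raise ValueError("polar_probability must be in [0, 1]")
        if self.dissociation_threshold < 1:
            raise ValueError("dissociation_threshold must be >= 1")
        if self.nick_rate < 0:
            raise ValueError("nick_rate must be >= 0")


@dataclass
class DeaminationModelParams:
    """Context-dependent deamination probabilities for continuous-strand Cs.

    ``context_probability`` is keyed either by preceding-base class
    (``pyrimidine-C`` / ``purine-C``) or by full preceding dinucleotide
    (``A-C``, ``T-C``, ``G-C``, ``C-C``); full keys win over class keys.
    Contexts are read on the continuous strand.
    """

    context_probability: Mapping[str, float] = field(
        default_factory=lambda: {"pyrimidine-C": 0.9, "purine-C": 0.3})
    use_protection: bool = True
    nicked_strand_deamination_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.context_probability.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"probability for {k} outside [0, 1]")
        if not 0.0 <= self.nicked_strand_deamination_probability <= 1.0:
            raise ValueError("nicked_strand_deamination_probability outside [0, 1]")

    def probability_for(self, preceding_base: str) -> float:
        full = f"{preceding_base}-C"
        if full in self.context_probability:
            return float(self.context_probability[full])
        cls = "pyrimidine-C" if preceding_base in PYRIMIDINES else "purine-C"
        return float(self.context_probability.get(cls, 0.0))


@dataclass
class CloneSequence:
    """One sequenced clone, full length, in nicked-strand orientation."""

    clone_id: str
    sequence: str
    truth: GapSet | None = None
    truth_deaminated: list[int] | None = None


# ---------------------------------------------------------------------------
# Excision simulators

def _molecule_rng(seed: int, index: int) -> np.random.Generator:
    # per-molecule substream: results independent of execution order
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def simulate_exo1(
    substrate: PlasmidSubstrate,
    params: ExcisionModelParams,
    n_molecules: int,
) -> list[GapSet]:
    """One polar 5'->3' gap per molecule, starting exactly at the nick."""
    L = substrate.length
    out = []
    for i in range(n_molecules):
        rng = _molecule_rng(params.seed, i)
        n = params.exo1_tract_length_dist.sample(rng)
        if n >= L:
            raise ValueError(f"tract length {n} >= plasmid length {L}: full-circle excision unsupported")
        gap = CircularInterval(substrate.nick_position, (substrate.nick_position + n) % L)
        out.append(GapSet(molecule_id=f"mol{i:05d}", gaps=[gap], origin_tags=["nick_initiated"]))
    return out


def _place_dispersed(
    rng: np.random.Generator,
    L: int,
    k: int,
    length_dist: DistSpec,
    max_tries: int = 200,
) -> list[CircularInterval]:
    """Rejection-sample ``k`` disjoint gaps uniform on the circle.

    If placement fails after bounded retries, k is reduced with a warning.
    """
    while k > 0:
        for _ in range(max_tries):
            gaps: list[CircularInterval] = []
            ok = True
            for _ in range(k):
                n = length_dist.sample(rng)
                if n >= L:
                    ok = False
                    break
                s = int(rng.integers(0, L))
                g = CircularInterval(s, (s + n) % L)
                if any(g.overlaps(h, L) for h in gaps):
                    ok = False
                    break
                gaps.append(g)
            if ok:
                return gaps
        warnings.warn(f"could not place {k} disjoint gaps; reducing to {k - 1}")
        k -= 1
    return []


def simulate_mlh_mixture(
    substrate: PlasmidSubstrate,
    params: ExcisionModelParams,
    n_molecules: int,
) -> list[GapSet]:
    """Two-component gap mixture: polar nick-initiated vs dispersed short gaps."""
    L = substrate.length
    out = []
    for i in range(n_molecules):
        rng = _molecule_rng(params.seed, i)
        if rng.random() < params.polar_probability:
            n = params.polar_length_dist.sample(rng)
            if n >= L:
                raise ValueError(f"polar tract length {n} >= plasmid length {L}")
            gap = CircularInterval(substrate.nick_position, (substrate.nick_position + n) % L)
            out.append(GapSet(f"mol{i:05d}", [gap], ["nick_initiated"]))
        else:
            k = params.dispersed_gap_count_dist.sample(rng)
            gaps = _place_dispersed(rng, L, k, params.dispersed_gap_length_dist)
            out.append(GapSet(f"mol{i:05d}", gaps, ["internal"] * len(gaps)))
    return out


def simulate_nick_dissociation(
    substrate: PlasmidSubstrate,
    params: ExcisionModelParams,
    n_molecules: int,
) -> tuple[list[NickSet], list[GapSet]]:
    """Gaps from dissociation of short oligonucleotides between close nicks.

    Extra nicks (Poisson count, uniform distinct positions) join the
    preexisting nick; every circular inter-nick fragment shorter than
    ``dissociation_threshold`` is lost and adjacent losses coalesce into
    one gap. A lone nick produces no gap. As a guard against losing the
    whole molecule, the longest fragment is always retained.
    """
    L = substrate.length
    if params.dissociation_threshold > L:
        raise ValueError(f"dissociation_threshold {params.dissociation_threshold} exceeds plasmid length {L}")
    nicksets, gapsets = [], []
    for i in range(n_molecules):
        rng = _molecule_rng(params.seed, i)
        n_extra = int(rng.poisson(params.nick_rate))
        positions = {substrate.nick_position}
        while len(positions) < n_extra + 1:
            positions.add(int(rng.integers(0, L)))
        nicks = sorted(positions)
        nicksets.append(NickSet(f"mol{i:05d}", nicks))
        gapsets.append(GapSet(f"mol{i:05d}", *_dissociate(nicks, L, params.dissociation_threshold,
                                                          substrate.nick_position)))
    return nicksets, gapsets


def _dissociate(
    nicks: list[int], L: int, threshold: int, primary_nick: int,
) -> tuple[list[CircularInterval], list[str]]:
    m = len(nicks)
    if m < 2:
        return [], []
    frags = [CircularInterval(nicks[j], nicks[(j + 1) % m]) for j in range(m)]
    lost = [f.length(L) < threshold for f in frags]
    if all(lost):
        keep = max(range(m), key=lambda j: frags[j].length(L))
        lost[keep] = False
    # coalesce circular runs of lost fragments into gaps
    gaps: list[CircularInterval] = []
    tags: list[str] = []
    j = 0
    seen = 0
    # start scanning at a retained fragment so runs never split across the seam
    start = next(j for j in range(m) if not lost[j])
    j = (start + 1) % m
    run_start: int | None = None
    while seen < m:
        if lost[j]:
            if run_start is None:
                run_start = frags[j].start
            run_end = frags[j].end
        elif run_start is not None:
            gaps.append(CircularInterval(run_start, run_end))
            tags.append("nick_initiated" if run_start == primary_nick else "internal")
            run_start = None
        j = (j + 1) % m
        seen += 1
    if run_start is not None:
        gaps.append(CircularInterval(run_start, run_end))
        tags.append("nick_initiated" if run_start == primary_nick else "internal")
    return gaps, tags


# ---------------------------------------------------------------------------
# Deamination

def simulate_deamination(
    substrate: PlasmidSubstrate,
    gapset: GapSet,
    dea_params: DeaminationModelParams,
    rng: np.random.Generator | None = None,
) -> CloneSequence:
    """Deaminate exposed continuous-strand cytidines and emit the clone.

    Inside each gap the nicked strand is removed, leaving the continuous
    strand single-stranded. Each continuous-strand C there (a reference G
    in nicked-strand orientation) deaminates with a probability set by its
    preceding continuous-strand base, unless it lies in a protected
    (hairpin-prone) interval. Fill-in replication fixes each C->U as a G>A
    substitution in the emitted nicked-strand sequence.
    """
    gapset.validate(substrate.length)
    if rng is None:
        rng = np.random.default_rng(dea_params.seed)
    L = substrate.length
    seq = list(substrate.sequence_nicked_strand)
    protected = substrate.protected_intervals if dea_params.use_protection else []
    deaminated: list[int] = []
    for gap in gapset.gaps:
        for p in gap.positions(L):
            if seq[p] == "G":
                if any(iv.contains(p, L) for iv in protected):
                    continue
                prev, _ = substrate.continuous_context(p)
                if rng.random() < dea_params.probability_for(prev):
                    seq[p] = "A"
                    deaminated.append(p)
            elif seq[p] == "C" and dea_params.nicked_strand_deamination_probability > 0:
                # contamination knob: deamination of residual nicked-strand Cs
                if rng.random() < dea_params.nicked_strand_deamination_probability:
                    seq[p] = "T"
    return CloneSequence(
        clone_id=gapset.molecule_id,
        sequence="".join(seq),
        truth=gapset,
        truth_deaminated=sorted(deaminated),
    )


def simulate_clones(
    substrate: PlasmidSubstrate,
    excision: ExcisionModelParams,
    deamination: DeaminationModelParams,
    n_molecules: int,
) -> list[CloneSequence]:
    """Full forward run: excision (per mechanism) then deamination."""
    if excision.mechanism == "exo1":
        gapsets = simulate_exo1(substrate, excision, n_molecules)
    elif excision.mechanism == "mlh_pms1_mixture":
        gapsets = simulate_mlh_mixture(substrate, excision, n_molecules)
    elif excision.mechanism == "mlh_pms1_nick_dissociation":
        _, gapsets = simulate_nick_dissociation(substrate, excision, n_molecules)
    else:
        raise ValueError(f"unknown mechanism {excision.mechanism!r}")
    clones = []
    for i, gs in enumerate(gapsets):
        rng = _molecule_rng(deamination.seed + 1_000_003, i)
        clones.append(simulate_deamination(substrate, gs, deamination, rng=rng))
    return clones


# ---------------------------------------------------------------------------
# Naive inverted-repeat (hairpin) finder

def find_protected_intervals(
    sequence: str,
    stem_min: int = 6,
    loop_max: int = 8,
    mismatches: int = 0,
) -> list[CircularInterval]:
    """Intervals covering hairpin-capable inverted repeats on a circle.

    A deliberately naive proxy for secondary-structure prediction: for
    every candidate loop midpoint the stem is extended outward while bases
    pair (allowing up to ``mismatches`` mismatched rungs); stems of at
    least ``stem_min`` with loops of at most ``loop_max`` are reported as
    one interval covering the whole hairpin. Overlapping hits are merged.
    Deterministic; symmetric under reverse complement.
    """
    if stem_min < 3:
        raise ValueError("stem_min must be >= 3")
    sequence = sequence.upper()
    L = len(sequence)
    hits: list[CircularInterval] = []
    for c in range(L):  # c = first position after the left stem
        for loop in range(0, loop_max + 1):
            stem = 0
            bad = 0
            # left stem grows to lower coords from c-1; right stem from c+loop
            while stem < L // 2:
                a = sequence[(c - 1 - stem) % L]
                b = sequence[(c + loop + stem) % L]
                if COMPLEMENT[a] != b:
                    bad += 1
                    if bad > mismatches:
                        break
                stem += 1
            # trim trailing mismatched rungs
            while stem > 0:
                a = sequence[(c - stem) % L]
                b = sequence[(c + loop + stem - 1) % L]
                if COMPLEMENT[a] == b:
                    break
                stem -= 1
            if stem >= stem_min:
                hits.append(CircularInterval((c - stem) % L, (c + loop + stem) % L))
    if not hits:
        return []
    from .intervals import merge_overlapping

    return merge_overlapping(hits, L)
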