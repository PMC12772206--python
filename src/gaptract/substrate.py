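"""Circular heteroduplex plasmid substrates and restriction-digest readouts.

The substrate models the circular double-stranded plasmids used in
reconstituted mismatch-repair reactions: one strand (the "nicked" strand)
carries a preexisting single-strand nick either 5' or 3' of a mispaired
base; the complementary "continuous" strand is intact and serves as the
repair template. Coordinates are 0-based on the nicked strand, 5'->3'.

Restriction digestion is the classical repair readout: the mispair disrupts
an enzyme site on one strand, repair from the continuous-strand template
restores it, and the appearance of the two sub-fragments of a double digest
reports percent repair.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import CircularInterval, circular_distance

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Representative recognition motifs. Degenerate enzymes (NspI RCATGY,
#: AflIII ACRYGT) are planted as a single concrete instance.
ENZYME_MOTIFS: dict[str, str] = {
    "ScaI": "AGTACT",
    "PstI": "CTGCAG",
    "NaeI": "GCCGGC",
    "XhoI": "CTCGAG",
    "NsiI": "ATGCAT",
    "SacI": "GAGCTC",
    "ApaI": "GGGCCC",
    "NotI": "GCGGCCGC",
    "NspI": "GCATGC",
    "AflIII": "ACATGT",
}

MISPAIR_TYPES = ("CC", "AC", "TG", "plusT", "plusTGC", "plusACGC")
NICK_SIDES = ("five_prime_of_mispair", "three_prime_of_mispair")
MOLECULE_STATES = ("covalently_closed", "repaired", "unrepaired_heteroduplex")


class SubstrateConfigError(ValueError):
    """Raised for impossible substrate configurations (site collisions etc.)."""


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass
class PlasmidSubstrate:
    """A circular heteroduplex plasmid in nicked-strand coordinates.

    Attributes
    ----------
    sequence_nicked_strand : str
        The nicked ("top") strand 5'->3'; the continuous strand is its
        reverse complement with no nick. This is also the fill-in product
        sequence used as the reference for clone comparison (the mispair is
        resolved toward the continuous-strand template).
    enzyme_sites : dict
        Enzyme name -> sorted cut positions on the circle. Positions are
        the 0-based start of the recognition motif.
    mispair_readout : dict
        Enzyme name -> which strand's copy of a mispair-overlapping site is
        intact ("continuous" or "nicked"). A site reading the continuous
        strand is restored by correct repair; a site reading the nicked
        strand never cuts in correctly repaired molecules.
    protected_intervals : list of CircularInterval
        Regions prone to secondary structure on the continuous strand,
        where deamination is suppressed.
    """

    name: str
    sequence_nicked_strand: str
    nick_position: int
    nick_side: str
    mispair_position: int
    mispair_type: str = "plusT"
    enzyme_sites: dict[str, list[int]] = field(default_factory=dict)
    mispair_readout: dict[str, str] = field(default_factory=dict)
    protected_intervals: list[CircularInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        seq = self.sequence_nicked_strand.upper()
        if set(seq) - set("ACGT"):
            bad = sorted(set(seq) - set("ACGT"))
            raise ValueError(f"sequence contains non-ACGT characters: {bad}")
        self.sequence_nicked_strand = seq
        L = self.length
        for label, pos in (("nick", self.nick_position), ("mispair", self.mispair_position)):
            if not 0 <= pos < L:
                raise ValueError(f"{label} position {pos} outside circle of length {L}")
        if self.nick_side not in NICK_SIDES:
            raise ValueError(f"nick_side must be one of {NICK_SIDES}")
        if self.mispair_type not in MISPAIR_TYPES:
            raise ValueError(f"mispair_type must be one of {MISPAIR_TYPES}")
        for enz, sites in self.enzyme_sites.items():
            for p in sites:
                if not 0 <= p < L:
                    raise ValueError(f"{enz} site at {p} outside circle of length {L}")
            self.enzyme_sites[enz] = sorted(sites)
        for enz, strand in self.mispair_readout.items():
            if strand not in ("continuous", "nicked"):
                raise ValueError(f"mispair_readout[{enz}] must be 'continuous' or 'nicked'")

    @property
    def length(self) -> int:
        return len(self.sequence_nicked_strand)

    @property
    def sequence_continuous_strand(self) -> str:
        return reverse_complement(self.sequence_nicked_strand)

    def base(self, pos: int) -> str:
        return self.sequence_nicked_strand[pos % self.length]

    def eligible_cytidine_positions(self) -> list[int]:
        """Positions where the continuous strand carries a cytidine.

        In nicked-strand coordinates these are the reference G positions:
        the cytidines a single-strand deaminase can act on when the nicked
        strand is excised.
        """
        return [i for i, b in enumerate(self.sequence_nicked_strand) if b == "G"]

    def continuous_context(self, pos: int) -> tuple[str, str]:
        """(preceding, following) bases around the continuous-strand C at ``pos``.

        The continuous strand runs antiparallel, so its 5' neighbour of the
        cytidine paired with nicked-strand position ``pos`` sits at nicked
        coordinate ``pos + 1`` and its 3' neighbour at ``pos - 1``.
        """
        L = self.length
        prev = COMPLEMENT[self.base((pos + 1) % L)]
        nxt = COMPLEMENT[self.base((pos - 1) % L)]
        return prev, nxt

    def rotated(self, k: int) -> "PlasmidSubstrate":
        """Substrate with the origin moved by ``k`` (annotations follow)."""
        L = self.length
        k %= L
        seq = self.sequence_nicked_strand[k:] + self.sequence_nicked_strand[:k]
        return dataclasses.replace(
            self,
            sequence_nicked_strand=seq,
            nick_position=(self.nick_position - k) % L,
            mispair_position=(self.mispair_position - k) % L,
            enzyme_sites={e: sorted((p - k) % L for p in ps) for e, ps in self.enzyme_sites.items()},
            protected_intervals=[iv.shifted(-k, L) for iv in self.protected_intervals],
        )


# ---------------------------------------------------------------------------
# Substrate construction


@dataclass
class SubstrateConfig:
    """Specification for a synthetic substrate with planted enzyme sites."""

    length: int = 2900
    sites: Mapping[str, int] = field(default_factory=dict)  # enzyme -> motif start
    nick_position: int = 0
    nick_side: str = "five_prime_of_mispair"
    mispair_position: int = 0
    mispair_type: str = "plusT"
    mispair_readout: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0
    name: str = "synthetic-substrate"
    gc_fraction: float = 0.5


def build_substrate(config: SubstrateConfig) -> PlasmidSubstrate:
    """Generate a random circular sequence with each requested site planted once.

    Recognition motifs are written at their requested positions, the
    background is drawn i.i.d., and background draws are locally rerolled
    until no motif has a second occurrence anywhere on the circle. The
    result is deterministic for a fixed seed.
    """
    L = config.length
    if L < 1000:
        raise SubstrateConfigError(f"substrate length {L} < 1000 nt")
    placements: list[tuple[str, int, str]] = []
    for enz, pos in config.sites.items():
        if enz not in ENZYME_MOTIFS:
            raise SubstrateConfigError(
                f"unknown enzyme {enz!r}; known: {sorted(ENZYME_MOTIFS)}")
        placements.append((enz, pos % L, ENZYME_MOTIFS[enz]))
    # pairwise non-overlap check on the circle
    for i, (e1, p1, m1) in enumerate(placements):
        for e2, p2, m2 in placements[i + 1:]:
            d = circular_distance(p1, p2, L)
            if d < len(m1) or circular_distance(p2, p1, L) < len(m2):
                raise SubstrateConfigError(
                    f"sites {e1} at {p1} and {e2} at {p2} overlap")

    rng = np.random.default_rng(config.seed)
    bases = np.array(list("ACGT"))
    p_gc = config.gc_fraction
    probs = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])
    seq = list(rng.choice(bases, size=L, p=probs))
    fixed = np.zeros(L, dtype=bool)
    for _, pos, motif in placements:
        for j, b in enumerate(motif):
            seq[(pos + j) % L] = b
            fixed[(pos + j) % L] = True

    wanted: dict[str, set[int]] = {}
    for _, pos, motif in placements:
        wanted.setdefault(motif, set()).add(pos)
    if wanted:
        pad = max(len(m) for m in wanted) - 1
        for _ in range(200):
            text = "".join(seq)
            doubled = text + text[:pad]
            extra: list[tuple[int, str]] = []
            for m, keep in wanted.items():
                for s in _find_all(doubled, m, L) - keep:
                    extra.append((s, m))
            if not extra:
                break
            for s, m in extra:
                span = [(s + j) % L for j in range(len(m))]
                free = [q for q in span if not fixed[q]]
                if not free:
                    raise SubstrateConfigError(
                        f"motif {m} forced by overlapping planted sites at {s}")
                for q in free:
                    seq[q] = rng.choice(bases, p=probs)
        else:
            raise SubstrateConfigError("could not eliminate spurious motif occurrences")

    sub = PlasmidSubstrate(
        name=config.name,
        sequence_nicked_strand="".join(seq),
        nick_position=config.nick_position % L,
        nick_side=config.nick_side,
        mispair_position=config.mispair_position % L,
        mispair_type=config.mispair_type,
        enzyme_sites={e: [p] for e, p, _ in placements},
        mispair_readout=dict(config.mispair_readout),
    )
    return sub


def _find_all(doubled: str, motif: str, circle: int) -> set[int]:
    hits: set[int] = set()
    i = doubled.find(motif)
    while i != -1:
        if i < circle:
            hits.add(i)
        i = doubled.find(motif, i + 1)
    return hits


def default_fixture_substrate(seed: int = 7) -> PlasmidSubstrate:
    """The packaged 2,900-nt readout fixture.

    ScaI and PstI sit 1,800/1,100 nt apart so a ScaI+PstI double digest of a
    repaired molecule yields the diagnostic 1.8 and 1.1 kb fragments; the
    NaeI nick is 276 nt 5' of the mispair, which overlaps the PstI site read
    on the continuous strand (repair restores it).
    """
    mispair = 1100
    nick = (mispair - 276) % 2900
    cfg = SubstrateConfig(
        length=2900,
        sites={"ScaI": 0, "PstI": 1100, "NaeI": nick},
        nick_position=nick,
        nick_side="five_prime_of_mispair",
        mispair_position=mispair,
        mispair_type="CC",
        mispair_readout={"PstI": "continuous", "XhoI": "nicked"},
        seed=seed,
        name="fixture-2900-CC-5prime-nick",
    )
    return build_substrate(cfg)


# ---------------------------------------------------------------------------
# Digestion


class FragmentTable:
    """Fragment lengths with mass-like or molar amounts.

    Thin wrapper over a DataFrame with columns ``length`` and ``amount``.
    ``units`` is ``"molar"`` (per-molecule counts, as produced by digest)
    or ``"mass"`` (gel-stain-intensity proxy, length-weighted).
    """

    def __init__(self, rows: Iterable[tuple[int, float]], units: str = "molar") -> None:
        if units not in ("molar", "mass"):
            raise ValueError("units must be 'molar' or 'mass'")
        df = pd.DataFrame(list(rows), columns=["length", "amount"])
        if (df["amount"] < 0).any():
            raise ValueError("fragment amounts must be nonnegative")
        self.frame = df.groupby("length", as_index=False)["amount"].sum()
        self.units = units

    @classmethod
    def from_amounts(cls, amounts: Mapping[int, float], units: str = "mass") -> "FragmentTable":
        return cls(list(amounts.items()), units=units)

    @property
    def lengths(self) -> list[int]:
        return self.frame["length"].tolist()

    def mass(self) -> pd.Series:
        """Amounts on the mass scale, indexed by fragment length."""
        df = self.frame
        w = df["amount"] * df["length"] if self.units == "molar" else df["amount"]
        return pd.Series(w.values, index=df["length"].values)

    def __repr__(self) -> str:  # pragma: no cover
        return f"FragmentTable({dict(zip(self.frame['length'], self.frame['amount']))}, units={self.units!r})"


def digest(
    substrate: PlasmidSubstrate,
    molecule_state: str,
    enzymes: Sequence[str],
) -> FragmentTable:
    """Complete circular digest of one molecular species.

    ``n`` cut positions on the circle yield ``n`` fragments whose lengths
    sum to the plasmid length; zero cuts leave one full-length circle. A
    mispair-overlapping site (listed in ``substrate.mispair_readout``) is
    heteroduplex-disrupted: it cuts only in a ``repaired`` molecule and
    only if its intact copy is on the continuous strand, the repair
    template.
    """
    if molecule_state not in MOLECULE_STATES:
        raise ValueError(f"molecule_state must be one of {MOLECULE_STATES}")
    cuts: list[int] = []
    for enz in enzymes:
        if enz not in substrate.enzyme_sites and enz not in ENZYME_MOTIFS:
            known = sorted(set(substrate.enzyme_sites) | set(ENZYME_MOTIFS))
            raise KeyError(f"unknown enzyme {enz!r}; known enzymes: {known}")
        for pos in substrate.enzyme_sites.get(enz, []):
            readout = substrate.mispair_readout.get(enz)
            site_len = len(ENZYME_MOTIFS.get(enz, "")) or 6
            at_mispair = readout is not None and CircularInterval(
                pos, (pos + site_len) % substrate.length
            ).contains(substrate.mispair_position, substrate.length)
            if at_mispair and not (molecule_state == "repaired" and readout == "continuous"):
                continue
            cuts.append(pos)
    cuts = sorted(set(cuts))
    L = substrate.length
    if not cuts:
        return FragmentTable([(L, 1.0)])
    lengths = [
        circular_distance(cuts[i], cuts[(i + 1) % len(cuts)], L) or L
        for i in range(len(cuts))
    ]
    return FragmentTable([(n, 1.0) for n in lengths])


def percent_repair(
    fragments: FragmentTable,
    repaired_lengths: Iterable[int],
    substrate_length: int,
) -> float:
    """Percent repair from a fragment quantification.

    100 x (mass in repair-diagnostic fragments) / (that mass + mass at the
    uncut substrate length). Mass-weighted by default because gel-stain
    quantification is mass-like; molar tables are converted.
    """
    mass = fragments.mass()
    repaired = float(mass.reindex(sorted(set(repaired_lengths))).fillna(0.0).sum())
    unrepaired = float(mass.get(substrate_length, 0.0))
    total = repaired + unrepaired
    if total <= 0:
        raise ZeroDivisionError("no mass in repaired or substrate-length fragments")
    return 100.0 * repaired / total
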