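"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from gaptract import (
    CircularInterval,
    PlasmidSubstrate,
    default_fixture_substrate,
)
from gaptract.intervals import circular_distance


@pytest.fixture(scope="session")
def fixture_substrate() -> PlasmidSubstrate:
    return default_fixture_substrate(seed=7)


def random_substrate(rng: np.random.Generator, length: int = 1200,
                     nick: int | None = None) -> PlasmidSubstrate:
    """A bare random circular substrate (no planted sites) for property tests."""
    seq = "".join(rng.choice(list("ACGT"), size=length))
    if nick is None:
        nick = int(rng.integers(0, length))
    return PlasmidSubstrate(
        name="random",
        sequence_nicked_strand=seq,
        nick_position=nick,
        nick_side="five_prime_of_mispair",
        mispair_position=(nick + length // 4) % length,
        mispair_type="plusT",
    )


def segment_oracle(ref_seq: str, events: set[int], max_skip: int):
    """Independent exhaustive segmentation: event-linkage formulation.

    Two circularly consecutive deamination events belong to the same merged
    tract iff at most ``max_skip`` nondeaminated eligible cytidines lie
    strictly between them (0 between-cytidines means the same initial run).
    If every consecutive pair is linked the circle is broken at the pair
    with the most skipped cytidines (ties: widest nt separation).

    Returns (partition, spans): a set of frozensets of event positions and,
    when the break is unambiguous, a set of (first, last) span endpoints
    (None entries where ambiguous).
    """
    L = len(ref_seq)
    eligible = [i for i, b in enumerate(ref_seq) if b == "G"]
    ev = sorted(p for p in events if p in set(eligible))
    if not ev:
        return set(), set()
    m = len(ev)
    between = []
    for j in range(m):
        a, b = ev[j], ev[(j + 1) % m]
        d = circular_distance(a, b, L)
        k = sum(1 for p in eligible if 0 < circular_distance(a, p, L) < d)
        between.append(k)
    linked = [between[j] <= max_skip for j in range(m)]
    if m == 1:
        return {frozenset(ev)}, {(ev[0], ev[0])}
    if all(linked):
        key = [(between[j], circular_distance(ev[j], ev[(j + 1) % m], L)) for j in range(m)]
        best = max(key)
        j = key.index(best)
        ambiguous = key.count(best) > 1
        part = {frozenset(ev)}
        spans = {None} if ambiguous else {(ev[(j + 1) % m], ev[j])}
        return part, spans
    # break the circle at any unlinked pair and chain linearly
    start = next(j for j in range(m) if not linked[j])
    groups, cur = [], [ev[(start + 1) % m]]
    for k in range(1, m):
        j = (start + k) % m
        if linked[j]:
            cur.append(ev[(j + 1) % m])
        else:
            groups.append(cur)
            cur = [ev[(j + 1) % m]]
    groups.append(cur)
    part = {frozenset(gp) for gp in groups}
    spans = {(gp[0], gp[-1]) for gp in groups}
    return part, spans


def recovery_case(rng: np.random.Generator, length: int = 1500,
                  max_skip: int = 3, nick_window: int = 25):
    """A random substrate plus identifiable ground-truth gap sets.

    Returns (substrate, cases) where cases is a list of (GapSet, expected
    label). Identifiability constraints — without which exact recovery is
    not well-posed — mirror the algorithm's documented assumptions:
    an eligible cytidine exists within the nick window (so a polar gap is
    recognisable), internal gaps keep their first eligible cytidine out of
    the nick window, every gap contains at least one eligible cytidine,
    and adjacent gaps are separated by more than ``max_skip`` eligible
    cytidines so merging cannot fuse distinct gaps.
    """
    from gaptract.simulate import GapSet

    while True:
        sub = random_substrate(rng, length)
        if any(sub.base((sub.nick_position + d) % length) == "G"
               for d in range(nick_window + 1)):
            break
    eligible = sub.eligible_cytidine_positions()
    L = length

    polar_len = int(rng.integers(385, min(768, L - 100)))
    polar = GapSet("polar", [CircularInterval(sub.nick_position,
                                              (sub.nick_position + polar_len) % L)],
                   ["nick_initiated"])

    elig_set = set(eligible)

    def spaced(gaps: list[CircularInterval]) -> bool:
        firsts_lasts = []
        for g in gaps:
            inside = [p for p in g.positions(L) if p in elig_set]
            if not inside:
                return False
            if circular_distance(sub.nick_position, inside[0], L) <= nick_window:
                return False
            firsts_lasts.append((inside[0], inside[-1]))
        firsts_lasts.sort()
        m = len(firsts_lasts)
        for j in range(m):
            a = firsts_lasts[j][1]
            b = firsts_lasts[(j + 1) % m][0]
            d = circular_distance(a, b, L)
            k = sum(1 for p in eligible if 0 < circular_distance(a, p, L) < d)
            if k <= max_skip:
                return False
        return True

    k = int(rng.integers(1, 4))
    for _ in range(500):
        gaps = []
        ok = True
        for _ in range(k):
            n = int(rng.integers(5, 120))
            s = int(rng.integers(0, L))
            g = CircularInterval(s, (s + n) % L)
            if any(g.overlaps(h, L) for h in gaps):
                ok = False
                break
            gaps.append(g)
        if ok and spaced(gaps):
            break
    else:
        raise RuntimeError("could not place identifiable internal gaps")
    internal = GapSet("internal", gaps, ["internal"] * len(gaps))
    return sub, [(polar, "polar_nick_initiated"), (internal, "dispersed")]


def trimmed_gap_endpoints(gap: CircularInterval, substrate: PlasmidSubstrate):
    """Truth gap trimmed to its first/last eligible-cytidine positions."""
    elig = set(substrate.eligible_cytidine_positions())
    inside = [p for p in gap.positions(substrate.length) if p in elig]
    if not inside:
        return None
    return inside[0], inside[-1]
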