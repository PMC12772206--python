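"""Excision-tract assignment, merging and polar/dispersed classification.

A deamination footprint maps an excision gap only where the exposed
continuous strand carries cytidines, so tracts are defined on the set of
*eligible* positions (reference Gs in nicked-strand orientation):

1. Initial tracts are maximal circular runs of eligible positions that
   are all deaminated; each spans from its first to its last event.
2. Adjacent tracts separated by at most ``max_skip`` nondeaminated
   eligible cytidines are merged (skipped cytidines are recorded with
   their preceding continuous-strand base, since deamination escape is
   context-biased). Merging runs to a fixed point around the circle.
3. A clone is classified polar/nick-initiated when it carries exactly one
   merged tract whose 5'-most event lies within a small window 3' of the
   preexisting nick; any other event-bearing clone is dispersed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calls import CloneCallSet, StrandClass
from .intervals import CircularInterval, circular_distance, signed_distance
from .substrate import PlasmidSubstrate

DEFAULT_MAX_SKIP = 3
DEFAULT_NICK_WINDOW = 25


@dataclass
class Tract:
    """A called excision tract: first-to-last deamination event, inclusive."""

    clone_id: str
    span: CircularInterval            # [first_event, last_event + 1)
    n_events: int
    eligible_cytidines: int           # eligible positions within the span
    event_positions: list[int] = field(default_factory=list)
    merged_from: list[CircularInterval] = field(default_factory=list)
    skipped_cytidines: list[tuple[int, str]] = field(default_factory=list)

    def length_nt(self, circle: int) -> int:
        """Span length in nt, first to last event inclusive."""
        return self.span.length(circle)

    @property
    def first_event(self) -> int:
        return self.event_positions[0]

    @property
    def last_event(self) -> int:
        return self.event_positions[-1]


@dataclass
class CloneClassification:
    clone_id: str
    label: str                        # polar_nick_initiated | dispersed | no_events | excluded_qc
    n_tracts: int = 0
    longest_tract_nt: int = 0
    distance_first_event_to_nick: int | None = None  # signed, 3' positive


def _circular_runs(flags: list[bool]) -> list[list[int]]:
    """Indices of maximal circular runs of True."""
    n = len(flags)
    if n == 0 or not any(flags):
        return []
    if all(flags):
        return [list(range(n))]
    # start scanning right after a False so runs never split across the seam
    start = next(i for i in range(n) if not flags[i])
    runs: list[list[int]] = []
    cur: list[int] = []
    for k in range(1, n + 1):
        i = (start + k) % n
        if flags[i]:
            cur.append(i)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    return runs


def assign_initial_tracts(
    calls: CloneCallSet,
    reference: PlasmidSubstrate,
) -> list[Tract]:
    """Maximal runs of consecutive eligible cytidines that are all deaminated.

    Isolated single events become 1-nt tracts. Only continuous-strand
    deamination events participate; events at non-eligible positions
    cannot occur by construction of the calling rule.
    """
    L = reference.length
    eligible = reference.eligible_cytidine_positions()
    if not eligible:
        return []
    event_set = set(calls.positions(StrandClass.CONTINUOUS))
    flags = [p in event_set for p in eligible]
    tracts = []
    for run in _circular_runs(flags):
        pos = [eligible[i] for i in run]
        span = _span_of(pos, eligible, L)
        # when every eligible position is deaminated the circle break is
        # chosen inside _span_of; rotate events to start at the span start
        i = pos.index(span.start)
        pos = pos[i:] + pos[:i]
        tracts.append(
            Tract(
                clone_id=calls.clone_id,
                span=span,
                n_events=len(pos),
                eligible_cytidines=len(pos),
                event_positions=pos,
            )
        )
    # keep circular order by first event
    return sorted(tracts, key=lambda t: t.first_event)


def _span_of(event_positions: list[int], eligible: list[int], L: int) -> CircularInterval:
    first, last = event_positions[0], event_positions[-1]
    if len(event_positions) == len(eligible):
        # every eligible position deaminated: break the circle at the
        # longest inter-event arc so the span stays representable
        m = len(event_positions)
        gaps = [circular_distance(event_positions[j], event_positions[(j + 1) % m], L)
                for j in range(m)]
        j = max(range(m), key=gaps.__getitem__)
        first = event_positions[(j + 1) % m]
        last = event_positions[j]
    return CircularInterval.from_span(first, last, L)


def merge_tracts(
    tracts: list[Tract],
    reference: PlasmidSubstrate,
    max_skip: int = DEFAULT_MAX_SKIP,
) -> list[Tract]:
    """Merge adjacent tracts separated by <= ``max_skip`` nondeaminated Cs.

    Works circularly and runs to fixed point. Each merge records the
    sub-tract spans and every skipped cytidine with its preceding
    continuous-strand base. If every inter-tract separation is mergeable
    the clone would collapse to a full-circle tract; the largest
    separation (by skipped count, then nt) is kept as the break instead.
    """
    if max_skip < 0:
        raise ValueError("max_skip must be >= 0")
    if len(tracts) <= 1:
        return list(tracts)
    L = reference.length
    eligible = reference.eligible_cytidine_positions()
    tracts = sorted(tracts, key=lambda t: t.first_event)
    m = len(tracts)
    # eligible, nondeaminated cytidines strictly between consecutive tracts
    seps: list[list[int]] = []
    for j in range(m):
        a = tracts[j].last_event
        b = tracts[(j + 1) % m].first_event
        between = [p for p in eligible if 0 < circular_distance(a, p, L) < circular_distance(a, b, L)]
        seps.append(between)
    mergeable = [len(s) <= max_skip for s in seps]
    if all(mergeable):
        j = max(range(m), key=lambda j: (len(seps[j]), circular_distance(
            tracts[j].last_event, tracts[(j + 1) % m].first_event, L)))
        mergeable[j] = False
    # group tracts into circular chains connected by mergeable separations
    merged: list[Tract] = []
    start = next(j for j in range(m) if not mergeable[(j - 1) % m])
    chain = [start]
    order = [(start + k) % m for k in range(1, m + 1)]
    for j in order:
        if mergeable[(j - 1) % m] and j != start:
            chain.append(j)
        else:
            merged.append(_merge_chain([tracts[c] for c in chain],
                                       [seps[c] for c in chain[:-1]],
                                       reference, L))
            chain = [j]
        if j == start:
            break
    return sorted(merged, key=lambda t: t.first_event)


def _merge_chain(
    chain: list[Tract],
    skips: list[list[int]],
    reference: PlasmidSubstrate,
    L: int,
) -> Tract:
    if len(chain) == 1:
        return chain[0]
    events: list[int] = []
    for t in chain:
        events.extend(t.event_positions)
    skipped = [
        (p, reference.continuous_context(p)[0]) for sep in skips for p in sep
    ]
    span = CircularInterval.from_span(chain[0].first_event, chain[-1].last_event, L)
    eligible_in_span = sum(1 for p in reference.eligible_cytidine_positions()
                           if span.contains(p, L))
    sub_spans = []
    for t in chain:
        sub_spans.extend(t.merged_from or [t.span])
    prior_skips = [s for t in chain for s in t.skipped_cytidines]
    return Tract(
        clone_id=chain[0].clone_id,
        span=span,
        n_events=len(events),
        eligible_cytidines=eligible_in_span,
        event_positions=events,
        merged_from=sub_spans,
        skipped_cytidines=prior_skips + skipped,
    )


def classify_clone(
    tracts: list[Tract],
    reference: PlasmidSubstrate,
    nick_window: int = DEFAULT_NICK_WINDOW,
    clone_id: str | None = None,
    qc_excluded: bool = False,
) -> CloneClassification:
    """Polar/nick-initiated vs dispersed vs no-events classification.

    Polar requires exactly one merged tract whose 5'-most event lies
    within ``nick_window`` nt 3' of the preexisting nick.
    """
    cid = clone_id or (tracts[0].clone_id if tracts else "")
    if qc_excluded:
        return CloneClassification(cid, "excluded_qc", n_tracts=len(tracts))
    if not tracts:
        return CloneClassification(cid, "no_events")
    L = reference.length
    longest = max(t.length_nt(L) for t in tracts)
    # the tract nearest 3' of the nick defines the headline distance
    lead = min(tracts, key=lambda t: circular_distance(reference.nick_position, t.first_event, L))
    dist = signed_distance(reference.nick_position, lead.first_event, L)
    label = "dispersed"
    if len(tracts) == 1:
        d3 = circular_distance(reference.nick_position, tracts[0].first_event, L)
        if d3 <= nick_window:
            label = "polar_nick_initiated"
    return CloneClassification(
        cid, label, n_tracts=len(tracts), longest_tract_nt=longest,
        distance_first_event_to_nick=dist,
    )


def segment_clone(
    calls: CloneCallSet,
    reference: PlasmidSubstrate,
    max_skip: int = DEFAULT_MAX_SKIP,
    nick_window: int = DEFAULT_NICK_WINDOW,
) -> tuple[list[Tract], CloneClassification]:
    """assign -> merge -> classify for one clone."""
    initial = assign_initial_tracts(calls, reference)
    merged = merge_tracts(initial, reference, max_skip=max_skip)
    cls = classify_clone(merged, reference, nick_window=nick_window,
                         clone_id=calls.clone_id, qc_excluded=calls.qc_excluded)
    return merged, cls
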