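"""Strand-assigned substitution calling of whole-plasmid clones vs reference.

After excision, deamination, fill-in and replication, deamination of the
continuous strand reads out in a sequenced clone (reported in nicked-strand
orientation) as a G>A substitution; deamination of the nicked strand would
read out as C>T. Everything else is background ("other") and feeds QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

from .substrate import COMPLEMENT, PlasmidSubstrate, reverse_complement
from .simulate import CloneSequence


class StrandClass(str, Enum):
    CONTINUOUS = "continuous_strand_deamination"   # ref G -> clone A
    NICKED = "nicked_strand_deamination"           # ref C -> clone T
    OTHER = "other_substitution"


@dataclass(frozen=True)
class CallEvent:
    position: int  # 0-based, nicked-strand frame
    ref_base: str
    alt_base: str
    strand_class: StrandClass


@dataclass
class CloneCallSet:
    clone_id: str
    events: list[CallEvent] = field(default_factory=list)
    qc_excluded: bool = False

    @property
    def n_other(self) -> int:
        return sum(1 for e in self.events if e.strand_class is StrandClass.OTHER)

    def positions(self, strand_class: StrandClass = StrandClass.CONTINUOUS) -> list[int]:
        return [e.position for e in self.events if e.strand_class is strand_class]


class CloneAlignmentError(ValueError):
    """Clone cannot be anchored to the reference (length mismatch / indel)."""


ANCHOR_K = 30


def _anchor_rotation(clone_seq: str, reference_seq: str) -> int:
    """Rotation offset r such that clone[r:]+clone[:r] aligns to the reference.

    Whole-plasmid assemblies start at an arbitrary point on the circle; we
    anchor them by locating an exact reference 30-mer in the doubled clone.
    Successive reference offsets are tried until a 30-mer matches at
    exactly one rotation (a 30-mer hit by a substitution simply fails and
    the next anchor is tried).
    """
    L = len(reference_seq)
    doubled = clone_seq + clone_seq[: ANCHOR_K - 1]
    for off in range(0, L, ANCHOR_K):
        kmer = (reference_seq + reference_seq)[off: off + ANCHOR_K]
        hits = []
        i = doubled.find(kmer)
        while i != -1 and len(hits) < 3:
            if i < L:
                hits.append(i)
            i = doubled.find(kmer, i + 1)
        if len(hits) == 1:
            return (hits[0] - off) % L
    raise CloneAlignmentError(
        "no unique 30-mer anchor between clone and reference; "
        "clone may contain indels or be unrelated")


def call_events(clone: CloneSequence, reference: PlasmidSubstrate) -> CloneCallSet:
    """Positionwise substitution calls for one clone.

    The clone must be the same length as the reference (pure-substitution
    contract; indel-containing clones are rejected, not aligned). Rotation
    is normalised by exact 30-mer anchoring before diffing. The reference
    is the fill-in product, so the mispair position itself never scores.
    """
    ref = reference.sequence_nicked_strand
    seq = clone.sequence.upper()
    if len(seq) != len(ref):
        raise CloneAlignmentError(
            f"clone {clone.clone_id}: length {len(seq)} != reference {len(ref)}; "
            "indel-containing clones require alignment and are not supported")
    for i, b in enumerate(seq):
        if b not in COMPLEMENT:
            raise ValueError(f"clone {clone.clone_id}: non-ACGT base {b!r} at position {i}")
    if seq != ref:
        r = _anchor_rotation(seq, ref)
        if r:
            seq = seq[r:] + seq[:r]
    events = []
    for i, (a, b) in enumerate(zip(ref, seq)):
        if a == b:
            continue
        if a == "G" and b == "A":
            cls = StrandClass.CONTINUOUS
        elif a == "C" and b == "T":
            cls = StrandClass.NICKED
        else:
            cls = StrandClass.OTHER
        events.append(CallEvent(i, a, b, cls))
    return CloneCallSet(clone_id=clone.clone_id, events=events)


def filter_artifacts(calls: CloneCallSet, max_other: int = 2) -> CloneCallSet:
    """QC-flag clones whose non-deamination substitution count exceeds tolerance.

    The default tolerates up to two background substitutions per clone;
    deamination events themselves are never removed.
    """
    return replace(calls, qc_excluded=calls.n_other > max_other)


def call_all(
    clones: list[CloneSequence],
    reference: PlasmidSubstrate,
    max_other: int = 2,
) -> list[CloneCallSet]:
    return [filter_artifacts(call_events(c, reference), max_other) for c in clones]
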