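"""Summary statistics over clones and tracts, and EM length calibration.

Covers the standard readouts of a deamination-footprinting experiment:
tract-length order statistics, the polar/dispersed split, per-position
deamination fractions conditioned on tract coverage, dinucleotide-context
deamination fractions (with secondary-structure regions excluded),
skipped-cytidine context counts from merge provenance, gap-count
histograms, and the electron-microscopy nm<->nt conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calls import CloneCallSet, StrandClass
from .intervals import CircularInterval
from .simulate import GapSet, PYRIMIDINES
from .substrate import PlasmidSubstrate
from .tracts import Tract


def lower_median(values: Sequence[float]) -> float:
    """Median with the lower-of-the-two convention for even counts."""
    if not len(values):
        raise ValueError("median of empty sequence")
    s = sorted(values)
    return s[(len(s) - 1) // 2]


# ---------------------------------------------------------------------------
# Tract statistics

def tract_length_stats(
    tracts_by_sample: Mapping[str, Sequence[Tract]],
    circle: int,
) -> pd.DataFrame:
    """Per-sample tract length median (lower convention), min, max, n."""
    rows = []
    for sample, tracts in tracts_by_sample.items():
        lengths = [t.length_nt(circle) for t in tracts]
        if not lengths:
            rows.append({"sample": sample, "median_nt": np.nan, "min_nt": np.nan,
                         "max_nt": np.nan, "n": 0, "note": "empty group"})
            continue
        rows.append({
            "sample": sample,
            "median_nt": lower_median(lengths),
            "min_nt": min(lengths),
            "max_nt": max(lengths),
            "n": len(lengths),
            "note": "",
        })
    return pd.DataFrame(rows, columns=["sample", "median_nt", "min_nt", "max_nt", "n", "note"])


def polar_fraction(classifications: Iterable) -> float:
    """Fraction of event-bearing, QC-passing clones classified polar."""
    labels = [c.label for c in classifications
              if c.label in ("polar_nick_initiated", "dispersed")]
    if not labels:
        raise ValueError("no event-bearing clones to classify")
    return sum(1 for l in labels if l == "polar_nick_initiated") / len(labels)


# ---------------------------------------------------------------------------
# Positional deamination fraction

def positional_fraction(
    calls_by_clone: Mapping[str, CloneCallSet],
    tracts_by_clone: Mapping[str, Sequence[Tract]],
    reference: PlasmidSubstrate,
) -> pd.DataFrame:
    """Per-position deamination fraction among tract-covering clones.

    For each continuous-strand cytidine position the denominator counts
    clones whose merged tract span covers the position; the numerator
    counts those with a deamination event there. Positions never covered
    get a null fraction.
    """
    L = reference.length
    eligible = reference.eligible_cytidine_positions()
    n_cov = dict.fromkeys(eligible, 0)
    n_dea = dict.fromkeys(eligible, 0)
    for clone_id, tracts in tracts_by_clone.items():
        calls = calls_by_clone.get(clone_id)
        events = set(calls.positions(StrandClass.CONTINUOUS)) if calls else set()
        covered: set[int] = set()
        for t in tracts:
            covered.update(p for p in eligible if t.span.contains(p, L))
        for p in covered:
            n_cov[p] += 1
            if p in events:
                n_dea[p] += 1
    rows = [{
        "position": p,
        "n_deaminated": n_dea[p],
        "n_covering": n_cov[p],
        "fraction": (n_dea[p] / n_cov[p]) if n_cov[p] else np.nan,
    } for p in eligible]
    return pd.DataFrame(rows, columns=["position", "n_deaminated", "n_covering", "fraction"])


# ---------------------------------------------------------------------------
# Dinucleotide context fractions

PRECEDING_KEYS = ("A-C", "T-C", "G-C", "C-C")
FOLLOWING_KEYS = ("C-A", "C-T", "C-C", "C-G")


def dinucleotide_fraction(
    calls_by_clone: Mapping[str, CloneCallSet],
    tracts_by_clone: Mapping[str, Sequence[Tract]],
    reference: PlasmidSubstrate,
    protected_intervals: Sequence[CircularInterval] | None = None,
) -> pd.DataFrame:
    """Deaminated fraction of continuous-strand cytidines by dinucleotide.

    Counts run over eligible cytidines inside the given coverage, after
    excluding protected (secondary-structure-prone) intervals. Every
    cytidine is keyed twice: once by its preceding base (N-C) and once by
    its following base (C-N), both read on the continuous strand.

    Coverage per clone may be given as Tracts (descriptive tables over
    called spans) or as raw CircularIntervals (e.g. known single-stranded
    regions). Called tract spans start and end at observed events, so
    fractions conditioned on them are slightly inflated; unbiased
    parameter recovery requires event-independent coverage such as
    simulator truth gaps.
    """
    L = reference.length
    if protected_intervals is None:
        protected_intervals = reference.protected_intervals
    eligible = reference.eligible_cytidine_positions()
    unmasked = [p for p in eligible
                if not any(iv.contains(p, L) for iv in protected_intervals)]
    keys = [("preceding", k) for k in PRECEDING_KEYS] + [("following", k) for k in FOLLOWING_KEYS]
    n_elig: dict[tuple[str, str], int] = {k: 0 for k in keys}
    n_dea: dict[tuple[str, str], int] = {k: 0 for k in keys}
    for clone_id, tracts in tracts_by_clone.items():
        calls = calls_by_clone.get(clone_id)
        events = set(calls.positions(StrandClass.CONTINUOUS)) if calls else set()
        spans = [t.span if isinstance(t, Tract) else t for t in tracts]
        in_span = [p for p in unmasked if any(s.contains(p, L) for s in spans)]
        for p in in_span:
            prev, nxt = reference.continuous_context(p)
            for key in (("preceding", f"{prev}-C"), ("following", f"C-{nxt}")):
                n_elig[key] += 1
                if p in events:
                    n_dea[key] += 1
    rows = [{
        "context": ctx,
        "orientation": ori,
        "n_deaminated": n_dea[(ori, ctx)],
        "n_eligible": n_elig[(ori, ctx)],
        "fraction": (n_dea[(ori, ctx)] / n_elig[(ori, ctx)]) if n_elig[(ori, ctx)] else np.nan,
    } for ori, ctx in keys]
    return pd.DataFrame(rows, columns=["context", "orientation", "n_deaminated",
                                       "n_eligible", "fraction"])


def context_class_fraction(dinuc: pd.DataFrame) -> dict[str, float]:
    """Pyrimidine-C vs purine-C deamination fractions from a preceding-key table."""
    out = {}
    pre = dinuc[dinuc["orientation"] == "preceding"]
    for cls, bases in (("pyrimidine-C", PYRIMIDINES), ("purine-C", {"A", "G"})):
        sel = pre[pre["context"].isin({f"{b}-C" for b in bases})]
        n_e = sel["n_eligible"].sum()
        out[cls] = float(sel["n_deaminated"].sum() / n_e) if n_e else float("nan")
    return out


# ---------------------------------------------------------------------------
# Skipped-cytidine contexts from merge provenance

@dataclass
class SkipContextSummary:
    purine_c: int
    pyrimidine_c: int
    median_skips_per_merge: float | None


def skip_context_summary(merged_tracts: Iterable[Tract]) -> SkipContextSummary:
    """Context counts of merge-skipped cytidines and the median skips per merge.

    A "merge event" is one merged tract with recorded provenance; its skip
    count is the number of skipped cytidines it absorbed.
    """
    purine = pyrimidine = 0
    per_merge: list[int] = []
    for t in merged_tracts:
        if not t.merged_from:
            continue
        per_merge.append(len(t.skipped_cytidines))
        for _, prev in t.skipped_cytidines:
            if prev in PYRIMIDINES:
                pyrimidine += 1
            else:
                purine += 1
    med = lower_median(per_merge) if per_merge else None
    return SkipContextSummary(purine_c=purine, pyrimidine_c=pyrimidine,
                              median_skips_per_merge=med)


# ---------------------------------------------------------------------------
# Gap-count histogram

def gap_count_histogram(
    gapsets: Iterable[GapSet] | None = None,
    tracts_by_clone: Mapping[str, Sequence[Tract]] | None = None,
    circle: int | None = None,
) -> pd.DataFrame:
    """Molecules binned by gap (or tract) count, with per-bin lengths.

    Accepts either simulator truth (GapSets) or called tracts. Molecules
    with zero gaps are reported in bin 0.
    """
    counts: dict[int, int] = {}
    lengths: dict[int, list[int]] = {}
    if gapsets is not None:
        items = [( [g.length(circle) for g in gs.gaps] ) for gs in gapsets]
    elif tracts_by_clone is not None:
        items = [[t.length_nt(circle) for t in ts] for ts in tracts_by_clone.values()]
    else:
        items = []
    for ls in items:
        k = len(ls)
        counts[k] = counts.get(k, 0) + 1
        lengths.setdefault(k, []).extend(ls)
    rows = [{
        "n_gaps": k,
        "n_molecules": counts[k],
        "median_length_nt": lower_median(lengths[k]) if lengths.get(k) else np.nan,
        "min_length_nt": min(lengths[k]) if lengths.get(k) else np.nan,
        "max_length_nt": max(lengths[k]) if lengths.get(k) else np.nan,
    } for k in sorted(counts)]
    return pd.DataFrame(rows, columns=["n_gaps", "n_molecules", "median_length_nt",
                                       "min_length_nt", "max_length_nt"])


# ---------------------------------------------------------------------------
# Electron-microscopy calibration

@dataclass(frozen=True)
class EMCalibration:
    """Contour-length calibration from single-stranded circular standards."""

    nm_per_kilont: float = 116.6
    uncertainty_nm: float = 14.7

    def __post_init__(self) -> None:
        if self.nm_per_kilont <= 0:
            raise ValueError("calibration scale must be positive")


def nm_to_nt(length_nm: float, cal: EMCalibration = EMCalibration()) -> int:
    """Measured contour length (nm) to nucleotides, rounded to nearest."""
    if length_nm < 0:
        raise ValueError("length_nm must be >= 0")
    return int(round(length_nm / cal.nm_per_kilont * 1000.0))


def nt_to_nm(length_nt: float, cal: EMCalibration = EMCalibration()) -> float:
    if length_nt < 0:
        raise ValueError("length_nt must be >= 0")
    return length_nt * cal.nm_per_kilont / 1000.0
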