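"""Intrinsic-disorder calling and interval algebra.

Two routes provide disorder intervals.  The faithful route imports the
output of an external consensus predictor as an annotation table (label
``disorder``).  The built-in surrogate is a windowed fold-index profile
combining mean hydropathy and mean net charge: low-hydropathy, highly
charged windows score negative (disordered).  Imported annotations take
precedence over the surrogate when both are given.

Per-residue surrogate score::

    score_i = 2.785 * <H>_i - |<R>_i| - 1.151

with ``<H>`` the window mean of Kyte–Doolittle hydropathy rescaled to
[0, 1] via (KD + 4.5) / 9, and ``<R>`` the window mean net charge
(K, R: +1; D, E: -1; H: +0.5).  Windows are truncated (not padded) at the
termini.  ``score < 0`` marks a residue as disordered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .seqio import ProteinRecord, RegionAnnotation, SeqIOError

_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0, "H": 0.5}


@dataclass(frozen=True)
class DisorderProfile:
    protein_id: str
    scores: np.ndarray  # one value per residue
    window: int
    method: str = "fold-index-surrogate"


@dataclass(frozen=True)
class DisorderRegionSet:
    """Sorted, merged, in-bounds 1-based inclusive intervals."""

    protein_id: str
    intervals: tuple[tuple[int, int], ...]
    source: str = ""

    def __post_init__(self) -> None:
        prev_end = 0
        for a, b in self.intervals:
            if a < 1 or b < a:
                raise SeqIOError(f"bad interval {a}..{b}")
            if a <= prev_end:
                raise SeqIOError("intervals must be sorted and non-overlapping")
            prev_end = b


def foldindex_profile(record: ProteinRecord, window: int = 51) -> DisorderProfile:
    """Windowed hydropathy–charge disorder profile (see module docstring).

    Residues without a hydropathy value (X) contribute a neutral rescaled
    hydropathy of 0.5 and zero charge.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    seq = record.sequence
    if len(seq) < 3:
        raise ValueError("sequence shorter than 3 residues")
    hydro = np.array([(KYTE_DOOLITTLE.get(a, 0.0) + 4.5) / 9.0 for a in seq])
    charge = np.array([_CHARGE.get(a, 0.0) for a in seq])
    half = window // 2
    # cumulative sums give truncated-window means at the termini
    csum_h = np.concatenate([[0.0], np.cumsum(hydro)])
    csum_r = np.concatenate([[0.0], np.cumsum(charge)])
    n = len(seq)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    width = hi - lo
    mean_h = (csum_h[hi] - csum_h[lo]) / width
    mean_r = (csum_r[hi] - csum_r[lo]) / width
    scores = 2.785 * mean_h - np.abs(mean_r) - 1.151
    return DisorderProfile(protein_id=record.id, scores=scores, window=window)


def call_regions(profile: DisorderProfile, min_length: int = 5) -> DisorderRegionSet:
    """Maximal runs of negative score of length >= min_length; runs separated
    by fewer than 3 residues are merged."""
    neg = profile.scores < 0
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(neg):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start + 1, i))
            start = None
    if start is not None:
        runs.append((start + 1, len(neg)))
    runs = [(a, b) for a, b in runs if b - a + 1 >= min_length]
    merged: list[tuple[int, int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] - 1 < 3:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return DisorderRegionSet(profile.protein_id, tuple(merged),
                             source=profile.method)


def import_regions(annotations: Iterable[RegionAnnotation],
                   protein_id: str,
                   length: int | None = None) -> DisorderRegionSet:
    """Union of imported ``disorder`` annotations for one protein."""
    ivs = sorted(
        (a.start, a.end) for a in annotations
        if a.protein_id == protein_id and a.label == "disorder"
    )
    if length is not None:
        for a, b in ivs:
            if b > length:
                raise SeqIOError(f"{protein_id}: disorder interval {a}..{b} "
                                 f"exceeds length {length}")
    return DisorderRegionSet(protein_id, _merge(ivs), source="imported")


def merge_region_sets(primary: DisorderRegionSet,
                      secondary: DisorderRegionSet) -> DisorderRegionSet:
    """Interval union of two region sets for the same protein (commutative)."""
    if primary.protein_id != secondary.protein_id:
        raise ValueError("region sets belong to different proteins")
    ivs = sorted(list(primary.intervals) + list(secondary.intervals))
    return DisorderRegionSet(primary.protein_id, _merge(ivs),
                             source=f"{primary.source}+{secondary.source}")


def _merge(intervals: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[tuple[int, int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return tuple(merged)


def overlaps(interval: tuple[int, int], regions: DisorderRegionSet) -> bool:
    """Does a 1-based inclusive interval intersect any region?"""
    a, b = interval
    return any(a <= e and s <= b for s, e in regions.intervals)
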