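"""Polycistron inference from per-base read coverage.

Consecutive CDS are called as one candidate polycistron when every
intergenic base between them is covered by at least one uniquely mapped
read (read-based coverage: the unsequenced inner mate gap contributes
nothing unless ``fragment_span=True``).  Zero-coverage loci flanking a run
are evidential — they are reported as flags, not required for a call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .align import STATUS_UNIQUE, PairAssignment
from .reference import CdsFeature


@dataclass
class CoverageTrack:
    """Per-base integer coverage over one contig."""

    contig_id: str
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=np.int64)

    @property
    def length(self) -> int:
        return int(self.cov.size)

    def write_bedgraph(self, path: str | Path) -> None:
        """Write as bedGraph (runs of equal coverage collapsed)."""
        with open(path, "w") as fh:
            cov = self.cov
            if cov.size == 0:
                return
            change = np.nonzero(np.diff(cov))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [cov.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{self.contig_id}\t{s}\t{e}\t{int(cov[s])}\n")


@dataclass(frozen=True)
class PolycistronCall:
    """A maximal run of consecutive CDS with no zero-coverage gap inside."""

    members: tuple[str, ...]
    contig_id: str
    start: int  # first member's start
    end: int  # last member's end
    left_flank_zero: bool
    right_flank_zero: bool

    @property
    def n_members(self) -> int:
        return len(self.members)


def coverage_track(
    assignments: Sequence[PairAssignment],
    contig_id: str,
    contig_length: int,
    fragment_span: bool = False,
) -> CoverageTrack:
    """Accumulate read-based coverage from unique assignments on one contig.

    Each aligned mate interval adds 1 per base; overlapping mates of a pair
    count twice (this is what a genome browser displays).  With
    ``fragment_span=True`` the whole outer fragment interval adds 1 instead.
    Raises when an interval falls outside the contig.
    """
    diff = np.zeros(contig_length + 1, dtype=np.int64)
    for a in assignments:
        if a.status != STATUS_UNIQUE or a.contig_id != contig_id:
            continue
        if fragment_span:
            intervals = [
                (min(a.mate1_start, a.mate2_start), max(a.mate1_end, a.mate2_end))
            ]
        else:
            intervals = [
                (a.mate1_start, a.mate1_end),
                (a.mate2_start, a.mate2_end),
            ]
        for s, e in intervals:
            if s < 0 or e > contig_length:
                raise ValueError(
                    f"interval [{s}, {e}) outside contig {contig_id!r}"
                )
            diff[s] += 1
            diff[e] -= 1
    return CoverageTrack(contig_id, np.cumsum(diff[:-1]))


def zero_runs(track: CoverageTrack) -> list[tuple[int, int]]:
    """Maximal, disjoint, sorted intervals of zero coverage."""
    zero = track.cov == 0
    if zero.size == 0:
        return []
    edges = np.nonzero(np.diff(zero.astype(np.int8)))[0] + 1
    bounds = np.concatenate(([0], edges, [zero.size]))
    return [
        (int(s), int(e))
        for s, e in zip(bounds[:-1], bounds[1:])
        if zero[s]
    ]


def call_polycistrons(
    track: CoverageTrack,
    cds_features: Sequence[CdsFeature],
    same_strand_required: bool = True,
    min_depth: int = 1,
    flank_window: int = 50,
) -> list[PolycistronCall]:
    """Merge consecutive covered CDS across gap bases of depth >= min_depth.

    ``cds_features`` must be the track's contig's CDS sorted by start
    (raises otherwise).  CDS whose whole span has zero coverage are excluded
    from calls.  Adjacent CDS merge iff (same strand, when required) and no
    base strictly between them has coverage < ``min_depth``; an empty gap
    merges.  Flags record whether a zero-coverage base exists within
    ``flank_window`` bases outside each end of the run.
    """
    feats = [f for f in cds_features if f.contig_id == track.contig_id]
    if any(b.start < a.start for a, b in zip(feats, feats[1:])):
        raise ValueError("CDS features must be sorted by start")
    cov = track.cov
    covered = [f for f in feats if f.end <= cov.size and cov[f.start : f.end].max(initial=0) > 0]

    runs: list[list[CdsFeature]] = []
    for f in covered:
        if runs:
            prev = runs[-1][-1]
            gap_ok = (
                f.start <= prev.end
                or bool((cov[prev.end : f.start] >= min_depth).all())
            )
            strand_ok = (not same_strand_required) or f.strand == prev.strand
            if gap_ok and strand_ok:
                runs[-1].append(f)
                continue
        runs.append([f])

    calls = []
    for run in runs:
        start, end = run[0].start, run[-1].end
        left = cov[max(0, start - flank_window) : start]
        right = cov[end : min(cov.size, end + flank_window)]
        calls.append(
            PolycistronCall(
                members=tuple(f.cds_id for f in run),
                contig_id=track.contig_id,
                start=start,
                end=end,
                left_flank_zero=bool((left == 0).any()),
                right_flank_zero=bool((right == 0).any()),
            )
        )
    return calls


def write_bed(calls: Sequence[PolycistronCall], path: str | Path) -> None:
    """One BED record per call; member ids joined with ',' in the name."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.contig_id}\t{c.start}\t{c.end}\t{','.join(c.members)}\n"
            )
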