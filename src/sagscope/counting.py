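"""Union-mode, non-strand-specific fragment counting.

The feature set of a pair is the union, over both aligned mates, of every
CDS overlapping at least one aligned base (the unsequenced inner fragment
gap does not contribute).  Exactly one feature -> the fragment counts for
it; none -> ``no_feature``; several -> ``ambiguous``.  Non-uniquely mapped
pairs are discarded into ``not_unique``.  This reproduces htseq-count's
``-m union -s no`` fragment-level semantics, which is why the TSV output
uses the ``__``-prefixed class-tally dialect.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .align import (
    STATUS_MULTI,
    STATUS_OUT_OF_BOUNDS,
    STATUS_QC_REMOVED,
    STATUS_UNIQUE,
    STATUS_UNMAPPED,
    PairAssignment,
)
from .reference import CdsFeature

TALLY_KEYS = (
    "no_feature",
    "ambiguous",
    "not_unique",
    "not_aligned",
    "out_of_bounds",
    "qc_removed",
)

_TSV_TALLY_NAMES = {
    "no_feature": "__no_feature",
    "ambiguous": "__ambiguous",
    "not_unique": "__alignment_not_unique",
    "not_aligned": "__not_aligned",
    "out_of_bounds": "__frag_out_of_bounds",
    "qc_removed": "__qc_removed",
}


@dataclass
class CountTable:
    """Per-CDS fragment counts plus unassigned-class tallies."""

    counts: dict[str, int]
    tallies: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in TALLY_KEYS}
    )

    @property
    def total_assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def n_pairs(self) -> int:
        """Assigned counts + class tallies: equals the evaluated pair count."""
        return self.total_assigned + sum(self.tallies.values())

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for cid in self.counts:
                fh.write(f"{cid}\t{self.counts[cid]}\n")
            for key in TALLY_KEYS:
                fh.write(f"{_TSV_TALLY_NAMES[key]}\t{self.tallies[key]}\n")


class CdsIntervalIndex:
    """Overlap queries against a CDS set (general, overlap-tolerant)."""

    def __init__(self, cds_features: Sequence[CdsFeature]):
        ids = [f.cds_id for f in cds_features]
        if len(set(ids)) != len(ids):
            raise ValueError("CDS id collision in feature set")
        self._per_contig: dict[str, tuple[list[int], list[tuple[int, int, str, str]]]] = {}
        by_contig: dict[str, list[CdsFeature]] = {}
        for f in cds_features:
            by_contig.setdefault(f.contig_id, []).append(f)
        for contig, feats in by_contig.items():
            feats.sort(key=lambda f: (f.start, f.end, f.cds_id))
            starts = [f.start for f in feats]
            rows = []
            running_max = 0
            for f in feats:
                running_max = max(running_max, f.end)
                rows.append((f.end, running_max, f.cds_id, f.strand))
            self._per_contig[contig] = (starts, rows)

    def overlapping(
        self, contig_id: str, start: int, end: int, strand: str | None = None
    ) -> set[str]:
        """CDS ids overlapping [start, end) by >= 1 base on ``contig_id``."""
        entry = self._per_contig.get(contig_id)
        if entry is None or start >= end:
            return set()
        starts, rows = entry
        hits: set[str] = set()
        i = bisect_left(starts, end) - 1
        while i >= 0:
            f_end, run_max, cds_id, f_strand = rows[i]
            if run_max <= start:
                break  # nothing to the left can still reach into [start, end)
            if f_end > start and (strand is None or f_strand == strand):
                hits.add(cds_id)
            i -= 1
        return hits


def count_fragments(
    assignments: Iterable[PairAssignment],
    cds_features: Sequence[CdsFeature],
    stranded: bool = False,
) -> CountTable:
    """Count uniquely assigned fragments per CDS in union mode.

    ``stranded=False`` (the contract for non-stranded libraries) ignores CDS
    strand entirely; with ``stranded=True`` only CDS on the fragment's plus
    strand (the strand of mate 1) are eligible.
    """
    index = CdsIntervalIndex(cds_features)
    table = CountTable(counts={f.cds_id: 0 for f in cds_features})
    t = table.tallies
    for a in assignments:
        if a.status == STATUS_UNIQUE:
            strand = a.strand if stranded else None
            feats = index.overlapping(
                a.contig_id, a.mate1_start, a.mate1_end, strand
            ) | index.overlapping(a.contig_id, a.mate2_start, a.mate2_end, strand)
            feats &= table.counts.keys()
            if not feats:
                t["no_feature"] += 1
            elif len(feats) == 1:
                table.counts[next(iter(feats))] += 1
            else:
                t["ambiguous"] += 1
        elif a.status == STATUS_MULTI:
            t["not_unique"] += 1
        elif a.status == STATUS_UNMAPPED:
            t["not_aligned"] += 1
        elif a.status == STATUS_OUT_OF_BOUNDS:
            t["out_of_bounds"] += 1
        elif a.status == STATUS_QC_REMOVED:
            t["qc_removed"] += 1
        else:
            raise ValueError(f"unknown assignment status {a.status!r}")
    return table


def representation_fraction(
    table: CountTable, cds_ids: Iterable[str] | None = None
) -> float:
    """Fraction of CDS represented by at least one fragment.

    ``cds_ids`` restricts the denominator (e.g. to the target genome's CDS);
    default is every CDS in the table.  Raises on an empty universe.
    """
    ids = list(cds_ids) if cds_ids is not None else list(table.counts)
    if not ids:
        raise ValueError("representation fraction undefined for zero CDS")
    covered = sum(1 for i in ids if table.counts.get(i, 0) >= 1)
    return covered / len(ids)
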