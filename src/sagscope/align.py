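"""Desk-scale paired-end read assignment.

A seed-and-extend aligner against the reference set: exact k-mer seeds,
ungapped extension counting mismatches, forward–reverse (FR) orientation,
fragment-length bounds (default 20–450 bp, the outer distance between mate
ends, matching the SAM TLEN magnitude convention) and a strict uniqueness
rule — a pair with two or more equally best placements is *multi* and is
discarded downstream, never resolved by randomness.

This intentionally implements only the contractual semantics of the
production mapper it stands in for (fragment bounds + uniqueness); there is
no gapped alignment and no base-quality-aware scoring.  SAM import/export
is provided for interoperating with external mappers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .reference import ReferenceSet, reverse_complement

STATUS_UNIQUE = "unique"
STATUS_MULTI = "multi"
STATUS_UNMAPPED = "unmapped"
STATUS_OUT_OF_BOUNDS = "frag_out_of_bounds"
STATUS_QC_REMOVED = "qc_removed"

STATUSES = (
    STATUS_UNIQUE,
    STATUS_MULTI,
    STATUS_UNMAPPED,
    STATUS_OUT_OF_BOUNDS,
    STATUS_QC_REMOVED,
)


@dataclass(frozen=True)
class AssignParams:
    seed_k: int = 21
    max_mismatch: int = 2
    min_frag: int = 20
    max_frag: int = 450
    require_unique: bool = True

    def __post_init__(self) -> None:
        if self.min_frag > self.max_frag:
            raise ValueError("min_frag must be <= max_frag")
        if self.seed_k < 8:
            raise ValueError("seed_k must be >= 8")


@dataclass(frozen=True)
class PairAssignment:
    """Outcome of assigning one read pair.

    Coordinates are present iff ``status == "unique"``.  ``strand`` is the
    reference strand of mate 1; ``fragment_length`` is the outer distance
    (rightmost mate end − leftmost mate start).
    """

    fragment_id: str
    status: str
    genome_id: str | None = None
    contig_id: str | None = None
    mate1_start: int | None = None
    mate1_end: int | None = None
    mate2_start: int | None = None
    mate2_end: int | None = None
    strand: str | None = None
    mismatches: tuple[int, int] | None = None
    fragment_length: int | None = None


class SeedIndex:
    """Exact k-mer index over the forward strand of every contig.

    Reverse-complement hits are found at query time by also seeding the
    read's reverse complement.  Content is a pure function of the reference
    set (insertion order of contigs does not matter).
    """

    def __init__(self, refset: ReferenceSet, seed_k: int):
        self.k = seed_k
        self.contigs = refset.contig_sequences
        self.contig_genome = refset.contig_to_genome
        shortest = min((len(s) for s in self.contigs.values()), default=seed_k)
        if seed_k > shortest:
            raise ValueError("seed_k exceeds the shortest contig")
        table: dict[str, list[tuple[str, int]]] = {}
        for cid in sorted(self.contigs):
            seq = self.contigs[cid]
            for pos in range(len(seq) - seed_k + 1):
                table.setdefault(seq[pos : pos + seed_k], []).append((cid, pos))
        self._table = table

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._table.get(kmer, [])

    def n_positions(self) -> int:
        return sum(len(v) for v in self._table.values())


def build_index(refset: ReferenceSet, seed_k: int = 21) -> SeedIndex:
    return SeedIndex(refset, seed_k)


def _mismatches(a: str, b: str, cap: int) -> int:
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > cap:
                return mm
    return mm


def _read_candidates(
    seq: str, index: SeedIndex, max_mismatch: int
) -> list[tuple[str, int, str, int]]:
    """All (contig, start, strand, mismatches) placements of one read.

    Seeds are taken at every non-overlapping offset plus the read's tail, so
    by pigeonhole a read with <= floor(len/k)-ish mismatches always has a
    clean seed; the seeding positions do not depend on ``max_mismatch`` so
    the candidate universe is fixed and raising the mismatch budget can only
    admit more placements.
    """
    L, k = len(seq), index.k
    if L < k:
        return []
    offsets = list(range(0, L - k + 1, k))
    if offsets[-1] != L - k:
        offsets.append(L - k)
    out: list[tuple[str, int, str, int]] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        seen: set[tuple[str, int]] = set()
        for off in offsets:
            for cid, pos in index.lookup(s[off : off + k]):
                start = pos - off
                ref = index.contigs[cid]
                if start < 0 or start + L > len(ref):
                    continue
                key = (cid, start)
                if key in seen:
                    continue
                seen.add(key)
                mm = _mismatches(s, ref[start : start + L], max_mismatch)
                if mm <= max_mismatch:
                    out.append((cid, start, strand, mm))
    return out


def assign_pair(
    pair: tuple[str, str, str],
    index: SeedIndex,
    params: AssignParams = AssignParams(),
) -> PairAssignment:
    """Assign one (id, mate1_seq, mate2_seq) pair to the reference.

    A valid placement needs both mates on one contig in FR orientation with
    the inferred fragment length inside ``[min_frag, max_frag]``; the best
    placement minimises total mismatches.  Exactly one best → *unique*; ties
    → *multi*; none, but an FR placement outside the fragment bounds exists
    → *frag_out_of_bounds*; otherwise *unmapped*.  Deterministic.
    """
    fid, s1, s2 = pair
    c1 = _read_candidates(s1, index, params.max_mismatch)
    c2 = _read_candidates(s2, index, params.max_mismatch)
    by_contig: dict[str, list[tuple[int, str, int]]] = {}
    for cid, start, strand, mm in c2:
        by_contig.setdefault(cid, []).append((start, strand, mm))

    placements = []
    saw_out_of_bounds = False
    L1, L2 = len(s1), len(s2)
    for cid, start1, strand1, mm1 in c1:
        for start2, strand2, mm2 in by_contig.get(cid, []):
            if strand1 == strand2:
                continue
            if strand1 == "+":
                plus_start, minus_start = start1, start2
            else:
                plus_start, minus_start = start2, start1
            if plus_start > minus_start:
                continue  # FR orientation: plus-strand mate leftmost
            frag = max(start1 + L1, start2 + L2) - plus_start
            if not (params.min_frag <= frag <= params.max_frag):
                saw_out_of_bounds = True
                continue
            placements.append(
                (mm1 + mm2, cid, start1, strand1, mm1, start2, strand2, mm2, frag)
            )

    if not placements:
        status = STATUS_OUT_OF_BOUNDS if saw_out_of_bounds else STATUS_UNMAPPED
        return PairAssignment(fragment_id=fid, status=status)

    best_score = min(p[0] for p in placements)
    best = [p for p in placements if p[0] == best_score]
    if len(best) > 1:
        return PairAssignment(fragment_id=fid, status=STATUS_MULTI)
    _, cid, start1, strand1, mm1, start2, strand2, mm2, frag = best[0]
    return PairAssignment(
        fragment_id=fid,
        status=STATUS_UNIQUE,
        genome_id=index.contig_genome[cid],
        contig_id=cid,
        mate1_start=start1,
        mate1_end=start1 + len(s1),
        mate2_start=start2,
        mate2_end=start2 + len(s2),
        strand=strand1,
        mismatches=(mm1, mm2),
        fragment_length=frag,
    )


def assign_pairs(
    pairs: Iterable[tuple[str, str, str]],
    index: SeedIndex,
    params: AssignParams = AssignParams(),
) -> list[PairAssignment]:
    return [assign_pair(p, index, params) for p in pairs]


def qc_removed_assignments(removed: Iterable[tuple[str, str]]) -> list[PairAssignment]:
    """Represent QC-removed pairs so class tallies stay conserved downstream."""
    return [PairAssignment(fragment_id=fid, status=STATUS_QC_REMOVED) for fid, _ in removed]


# -- SAM interoperability ------------------------------------------------


def write_sam(
    assignments: Sequence[PairAssignment],
    refset: ReferenceSet,
    path: str | Path,
    sequences: dict[str, tuple[str, str]] | None = None,
) -> None:
    """Write assignments as SAM: one record per mate, TLEN signed.

    Unique pairs become proper pairs; every other status is written as an
    unmapped pair carrying its class in the ``ZS`` tag so the full input is
    recoverable.  ``sequences`` optionally maps fragment_id -> (seq1, seq2)
    to embed read sequences (otherwise SEQ is '*').
    """
    contig_seqs = refset.contig_sequences
    names = sorted(contig_seqs)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(contig_seqs[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for a in assignments:
            s1, s2 = (sequences or {}).get(a.fragment_id, (None, None))
            if a.status == STATUS_UNIQUE:
                rev1 = a.strand == "-"
                leftmost = min(a.mate1_start, a.mate2_start)
                rightmost = max(a.mate1_end, a.mate2_end)
                for is_read1 in (True, False):
                    rec = pysam.AlignedSegment()
                    rec.query_name = a.fragment_id
                    rec.reference_id = tid[a.contig_id]
                    rec.next_reference_id = tid[a.contig_id]
                    if is_read1:
                        start, end, mm = a.mate1_start, a.mate1_end, a.mismatches[0]
                        mstart = a.mate2_start
                        rev, mrev = rev1, not rev1
                        seq = s1
                    else:
                        start, end, mm = a.mate2_start, a.mate2_end, a.mismatches[1]
                        mstart = a.mate1_start
                        rev, mrev = not rev1, rev1
                        seq = s2
                    rec.reference_start = start
                    rec.next_reference_start = mstart
                    flag = 0x1 | 0x2 | (0x40 if is_read1 else 0x80)
                    if rev:
                        flag |= 0x10
                    if mrev:
                        flag |= 0x20
                    rec.flag = flag
                    rlen = end - start
                    rec.cigarstring = f"{rlen}M"
                    tlen = rightmost - leftmost
                    rec.template_length = tlen if start == leftmost else -tlen
                    if seq is not None:
                        rec.query_sequence = (
                            reverse_complement(seq) if rev else seq
                        )
                    rec.set_tag("NM", mm)
                    out.write(rec)
            else:
                for is_read1 in (True, False):
                    rec = pysam.AlignedSegment()
                    rec.query_name = a.fragment_id
                    rec.flag = 0x1 | 0x4 | 0x8 | (0x40 if is_read1 else 0x80)
                    rec.reference_id = -1
                    rec.reference_start = -1
                    seq = s1 if is_read1 else s2
                    if seq is not None:
                        rec.query_sequence = seq
                    rec.set_tag("ZS", a.status)
                    out.write(rec)


def read_sam(path: str | Path, refset: ReferenceSet) -> list[PairAssignment]:
    """Import mapper output (SAM) as pair assignments.

    Primary, properly mated records become *unique* assignments; unmapped
    pairs recover their class from the ``ZS`` tag when present (our own
    dialect), else *unmapped*.  Secondary/supplementary records are ignored.
    """
    contig_genome = refset.contig_to_genome
    mates: dict[str, dict[bool, pysam.AlignedSegment]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_name not in mates:
                order.append(rec.query_name)
            mates.setdefault(rec.query_name, {})[rec.is_read1] = rec

    out: list[PairAssignment] = []
    for fid in order:
        pair = mates[fid]
        r1, r2 = pair.get(True), pair.get(False)
        if r1 is None or r2 is None or r1.is_unmapped or r2.is_unmapped:
            status = STATUS_UNMAPPED
            rec = r1 or r2
            if rec is not None and rec.has_tag("ZS"):
                status = str(rec.get_tag("ZS"))
            out.append(PairAssignment(fragment_id=fid, status=status))
            continue
        contig = r1.reference_name
        leftmost = min(r1.reference_start, r2.reference_start)
        rightmost = max(r1.reference_end, r2.reference_end)
        out.append(
            PairAssignment(
                fragment_id=fid,
                status=STATUS_UNIQUE,
                genome_id=contig_genome.get(contig),
                contig_id=contig,
                mate1_start=r1.reference_start,
                mate1_end=r1.reference_end,
                mate2_start=r2.reference_start,
                mate2_end=r2.reference_end,
                strand="-" if r1.is_reverse else "+",
                mismatches=(
                    int(r1.get_tag("NM")) if r1.has_tag("NM") else 0,
                    int(r2.get_tag("NM")) if r2.has_tag("NM") else 0,
                ),
                fragment_length=rightmost - leftmost,
            )
        )
    return out
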