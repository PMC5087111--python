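"""Read quality processing.

Two threshold rules: each read is truncated at the first base whose Phred
score falls below a floor (default 20), then any pair in which either mate
ends up shorter than a minimum length (default 16 bp) is removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable


@dataclass(frozen=True)
class QcParams:
    phred_floor: int = 20
    min_read_len: int = 16

    def __post_init__(self) -> None:
        if self.phred_floor < 0:
            raise ValueError("phred_floor must be >= 0")
        if self.min_read_len < 1:
            raise ValueError("min_read_len must be >= 1")


def quality_truncate(
    seq: str, qual: str, phred_floor: int = 20
) -> tuple[str, str]:
    """Keep the prefix strictly before the first base with Phred < floor.

    ``qual`` is a Phred+33 string of the same length as ``seq``.  Idempotent:
    the surviving prefix contains no base below the floor.
    """
    if len(seq) != len(qual):
        raise ValueError("sequence and quality strings differ in length")
    for i, q in enumerate(qual):
        if ord(q) - 33 < phred_floor:
            return seq[:i], qual[:i]
    return seq, qual


def filter_pair(
    mate1: tuple[str, str], mate2: tuple[str, str], qc: QcParams = QcParams()
) -> tuple[bool, str | None]:
    """Pair filter applied after truncation.

    Returns ``(kept, reason)``; a pair is removed iff either mate is shorter
    than ``qc.min_read_len``.
    """
    for name, (seq, _qual) in (("mate1", mate1), ("mate2", mate2)):
        if len(seq) < qc.min_read_len:
            return False, f"{name}_short"
    return True, None


def process_pairs(
    pairs: Iterable[tuple[str, str, str, str, str]],
    qc: QcParams = QcParams(),
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str]]]:
    """Truncate + filter a stream of (id, seq1, qual1, seq2, qual2).

    Returns the kept pairs as (id, seq1, seq2) and a list of
    (id, removal_reason) records for the pairs that failed.
    """
    kept: list[tuple[str, str, str]] = []
    removed: list[tuple[str, str]] = []
    for fid, s1, q1, s2, q2 in pairs:
        t1 = quality_truncate(s1, q1, qc.phred_floor)
        t2 = quality_truncate(s2, q2, qc.phred_floor)
        ok, reason = filter_pair(t1, t2, qc)
        if ok:
            kept.append((fid, t1[0], t2[0]))
        else:
            removed.append((fid, reason or "removed"))
    return kept, removed
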