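"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (all-positions scans, nested loops)
and shares no code with the library paths it validates.
"""

from __future__ import annotations

import numpy as np

from sagscope.reference import ReferenceSet, reverse_complement


def oracle_read_placements(seq, contigs, max_mismatch):
    """Every (contig, start, strand, mismatches) placement by full scan."""
    out = []
    L = len(seq)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for cid, ref in contigs.items():
            for start in range(len(ref) - L + 1):
                mm = sum(1 for a, b in zip(s, ref[start : start + L]) if a != b)
                if mm <= max_mismatch:
                    out.append((cid, start, strand, mm))
    return out


def oracle_assign_pair(pair, refset: ReferenceSet, params):
    """All-positions paired placement with FR orientation + bounds + ties."""
    fid, s1, s2 = pair
    contigs = refset.contig_sequences
    c1 = oracle_read_placements(s1, contigs, params.max_mismatch)
    c2 = oracle_read_placements(s2, contigs, params.max_mismatch)
    placements = []
    saw_oob = False
    for cid1, st1, sd1, mm1 in c1:
        for cid2, st2, sd2, mm2 in c2:
            if cid1 != cid2 or sd1 == sd2:
                continue
            plus_start = st1 if sd1 == "+" else st2
            minus_start = st2 if sd1 == "+" else st1
            if plus_start > minus_start:
                continue
            frag = max(st1 + len(s1), st2 + len(s2)) - plus_start
            if params.min_frag <= frag <= params.max_frag:
                placements.append((mm1 + mm2, cid1, st1, sd1, st2, frag))
            else:
                saw_oob = True
    if not placements:
        return ("frag_out_of_bounds" if saw_oob else "unmapped", None)
    best_score = min(p[0] for p in placements)
    best = [p for p in placements if p[0] == best_score]
    if len(best) > 1:
        return ("multi", None)
    return ("unique", best[0])


def oracle_union_count(assignments, cds_features):
    """Union-mode fragment counting by nested interval scans."""
    counts = {f.cds_id: 0 for f in cds_features}
    tallies = {"no_feature": 0, "ambiguous": 0, "other": 0}
    for a in assignments:
        if a.status != "unique":
            tallies["other"] += 1
            continue
        feats = set()
        for s, e in ((a.mate1_start, a.mate1_end), (a.mate2_start, a.mate2_end)):
            for f in cds_features:
                if f.contig_id == a.contig_id and f.start < e and f.end > s:
                    feats.add(f.cds_id)
        if not feats:
            tallies["no_feature"] += 1
        elif len(feats) == 1:
            counts[feats.pop()] += 1
        else:
            tallies["ambiguous"] += 1
    return counts, tallies


def oracle_zero_runs(cov):
    """Linear scan for maximal zero-coverage intervals."""
    runs, start = [], None
    for i, v in enumerate(cov):
        if v == 0 and start is None:
            start = i
        elif v != 0 and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(cov)))
    return runs


def oracle_polycistrons(cov, feats, same_strand_required=True):
    """Exhaustive gap scan: member-id tuples of every call, in order."""
    cov = np.asarray(cov)
    covered = [f for f in feats if cov[f.start : f.end].max(initial=0) > 0]
    calls, current = [], []
    for f in covered:
        if current:
            prev = current[-1]
            gap = cov[prev.end : f.start]
            ok = (len(gap) == 0 or (gap > 0).all()) and (
                not same_strand_required or f.strand == prev.strand
            )
            if ok:
                current.append(f)
                continue
            calls.append(tuple(x.cds_id for x in current))
            current = []
        current.append(f)
    if current:
        calls.append(tuple(x.cds_id for x in current))
    return calls
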