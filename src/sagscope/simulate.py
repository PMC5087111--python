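"""Synthetic community generator and ground-truthed read simulator.

This module emulates the input world of the pipeline: a multi-genome
symbiont community embedded in a host metatranscriptome.  It produces

* random reference genomes with non-overlapping CDS annotations,
* per-CDS relative transcription weights (log-normal, heavy-tailed, so a
  "highly expressed" tail exists), and
* paired-end fragments (101 bp reads, ~149 bp mean insert by default,
  matching Illumina HiSeq 2000 libraries) with substitution errors and
  Phred qualities, every fragment's true origin recorded.

The truth table, not the read id, is the contract for downstream
evaluation, although ids also encode ``genome:cds:serial`` provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import (
    CapacityError,
    CdsFeature,
    Genome,
    ReferenceSet,
    merge_reference_sets,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TRUTH_COLUMNS = [
    "fragment_id",
    "genome_id",
    "contig_id",
    "cds_id",
    "frag_start",
    "frag_end",
    "insert_size",
    "n_errors",
]


@dataclass(frozen=True)
class FragmentTruth:
    """One simulated fragment: both mates plus its recorded true origin."""

    fragment_id: str
    genome_id: str
    contig_id: str
    cds_id: str
    frag_start: int
    frag_end: int
    mate1_seq: str
    mate2_seq: str
    mate1_qual: str
    mate2_qual: str
    insert_size: int
    n_errors: int

    @property
    def mate1_interval(self) -> tuple[int, int]:
        return (self.frag_start, self.frag_start + len(self.mate1_seq))

    @property
    def mate2_interval(self) -> tuple[int, int]:
        return (self.frag_end - len(self.mate2_seq), self.frag_end)


@dataclass
class ExpressionWeights:
    """Relative per-CDS transcription weights, normalised to sum to 1."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.fromiter(self.weights.values(), dtype=float)
        if (vals < 0).any():
            raise ValueError("expression weights must be non-negative")
        if vals.size and abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("expression weights must sum to 1")

    @classmethod
    def from_mapping(cls, raw: Mapping[str, float]) -> "ExpressionWeights":
        total = float(sum(raw.values()))
        if total <= 0:
            raise ValueError("weights must have positive total")
        return cls({k: v / total for k, v in raw.items()})


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def generate_references(
    n_genomes: int,
    contig_lengths: int | Sequence[int] = 20_000,
    n_cds_per_genome: int = 20,
    hk_fraction: float = 0.2,
    annotated_fraction: float = 0.7,
    cds_length_range: tuple[int, int] = (300, 1500),
    seed: int = 0,
    genome_ids: Sequence[str] | None = None,
) -> ReferenceSet:
    """Generate random genomes with non-overlapping CDS annotations.

    Each genome is a single contig (``<genome_id>_c0``).  ``hk_fraction`` and
    ``annotated_fraction`` are converted to per-genome counts by flooring.
    Raises :class:`CapacityError` when the requested CDS cannot be placed
    with at least one intergenic base between neighbours.
    """
    rng = np.random.default_rng(seed)
    if isinstance(contig_lengths, int):
        contig_lengths = [contig_lengths] * n_genomes
    if len(contig_lengths) != n_genomes:
        raise ValueError("contig_lengths must match n_genomes")
    if genome_ids is None:
        genome_ids = [f"genome{i + 1}" for i in range(n_genomes)]

    refset = ReferenceSet()
    lo, hi = cds_length_range
    n_hk = int(np.floor(hk_fraction * n_cds_per_genome))
    n_ann = int(np.floor(annotated_fraction * n_cds_per_genome))
    for gid, clen in zip(genome_ids, contig_lengths):
        contig_id = f"{gid}_c0"
        seq = _random_sequence(rng, clen)
        refset.genomes.append(Genome(gid, {contig_id: seq}))

        n = n_cds_per_genome
        if n == 0:
            continue
        lengths = rng.integers(lo, hi + 1, n)
        slack = clen - int(lengths.sum())
        if slack < n + 1:
            raise CapacityError(
                f"cannot place {n} CDS totalling {lengths.sum()} bp "
                f"in a {clen} bp contig with intergenic gaps"
            )
        # distribute the slack over n+1 gaps, each at least 1 bp
        gaps = rng.multinomial(slack - (n + 1), [1.0 / (n + 1)] * (n + 1)) + 1
        hk_idx = set(rng.choice(n, size=n_hk, replace=False).tolist())
        ann_idx = set(rng.choice(n, size=n_ann, replace=False).tolist())
        pos = 0
        for i in range(n):
            pos += int(gaps[i])
            start, end = pos, pos + int(lengths[i])
            cds_id = f"{gid}_cds{i + 1:03d}"
            refset.cds.append(
                CdsFeature(
                    cds_id=cds_id,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    annotated=i in ann_idx,
                )
            )
            if i in hk_idx:
                refset.housekeeping_ids.add(cds_id)
            pos = end
    refset.validate(check_overlap=True)
    return refset


def generate_community(
    n_symbionts: int = 4,
    contig_length: int = 20_000,
    n_cds_per_genome: int = 20,
    host_contig_length: int = 40_000,
    host_n_cds: int = 40,
    seed: int = 0,
    **kwargs,
) -> tuple[ReferenceSet, list[str]]:
    """Symbiont genomes plus one host-background genome.

    Returns the merged :class:`ReferenceSet` and the list of *target* genome
    ids (the symbionts).  The host genome is part of the simulation universe
    — its transcripts compete for reads — but is excluded from the retrieval
    target set, emulating host mRNA background in a metatranscriptome.
    """
    symbionts = generate_references(
        n_symbionts,
        contig_lengths=contig_length,
        n_cds_per_genome=n_cds_per_genome,
        seed=seed,
        **kwargs,
    )
    host_kwargs = {k: v for k, v in kwargs.items() if k != "hk_fraction"}
    host = generate_references(
        1,
        contig_lengths=host_contig_length,
        n_cds_per_genome=host_n_cds,
        hk_fraction=0.0,
        seed=seed + 1,
        genome_ids=["host"],
        **host_kwargs,
    )
    return merge_reference_sets(symbionts, host), symbionts.genome_ids


def sample_expression(
    refset: ReferenceSet,
    lognormal_mu: float = 0.0,
    lognormal_sigma: float = 1.0,
    seed: int = 0,
) -> ExpressionWeights:
    """Draw log-normal relative transcription weights for every CDS.

    ``sigma = 0`` gives equal weights.  Weights are normalised over the whole
    community (all genomes, host included).
    """
    if lognormal_sigma < 0:
        raise ValueError("lognormal_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    ids = [f.cds_id for f in refset.cds]
    raw = np.exp(lognormal_mu + lognormal_sigma * rng.standard_normal(len(ids)))
    return ExpressionWeights.from_mapping(dict(zip(ids, raw)))


def _qual_string(
    rng: np.random.Generator, length: int, qual_model: str, qual_phred: int
) -> str:
    if qual_model == "constant":
        return chr(33 + qual_phred) * length
    if qual_model == "decay":
        # linear drop of 2 Phred per base after a seeded breakpoint,
        # floored at Phred 2 — exercises threshold-based quality truncation
        bp = int(rng.integers(length // 2, length + 1))
        quals = [qual_phred] * bp + [
            max(2, qual_phred - 2 * (i + 1)) for i in range(length - bp)
        ]
        return "".join(chr(33 + q) for q in quals)
    raise ValueError(f"unknown qual_model {qual_model!r}")


def simulate_fragments(
    refset: ReferenceSet,
    weights: ExpressionWeights,
    n_fragments: int,
    read_len: int = 101,
    insert_mean: float = 149.0,
    insert_sd: float = 30.0,
    error_rate: float = 0.0,
    qual_model: str = "constant",
    qual_phred: int = 38,
    intergenic_rate: float = 0.0,
    seed: int = 0,
) -> list[FragmentTruth]:
    """Simulate ground-truthed paired-end fragments.

    Each fragment picks a CDS ~ Multinomial(weights), an insert length ~
    Normal(insert_mean, insert_sd) rounded and clipped into
    ``[read_len, CDS length]``, and a uniform start within the CDS.  Mate 1
    is the fragment's 5' ``read_len`` bases; mate 2 is the reverse complement
    of its 3' ``read_len`` bases (FR orientation; with the default 149 bp
    insert the mates overlap, as in the emulated libraries).  A CDS shorter
    than ``read_len`` yields truncated reads equal to the whole CDS, so reads
    stay genomic substrings.  Substitution errors hit each read base
    independently with probability ``error_rate``; no indels.

    With ``intergenic_rate > 0`` that fraction of fragments is drawn
    uniformly from whole contigs instead (``cds_id`` empty in the truth),
    emulating read-through/background transcription across gene boundaries.
    """
    if n_fragments < 0:
        raise ValueError("n_fragments must be >= 0")
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    by_id = refset.cds_by_id
    cds_list = [by_id[f.cds_id] for f in refset.cds if f.cds_id in weights.weights]
    if not cds_list and n_fragments and intergenic_rate < 1.0:
        raise ValueError("no CDS carries a weight")
    p = np.array([weights.weights[f.cds_id] for f in cds_list], dtype=float)
    if p.size:
        p = p / p.sum()
    seqs = refset.contig_sequences
    contig_genome = refset.contig_to_genome
    contig_ids = sorted(seqs)
    contig_lens = np.array([len(seqs[c]) for c in contig_ids], dtype=float)

    idx = rng.choice(len(cds_list), size=n_fragments, p=p) if p.size else np.zeros(
        n_fragments, dtype=int
    )
    inserts = np.rint(rng.normal(insert_mean, insert_sd, n_fragments)).astype(int)
    intergenic = (
        rng.random(n_fragments) < intergenic_rate
        if intergenic_rate > 0
        else np.zeros(n_fragments, dtype=bool)
    )

    out: list[FragmentTruth] = []
    for i in range(n_fragments):
        if intergenic[i]:
            ci = int(rng.choice(len(contig_ids), p=contig_lens / contig_lens.sum()))
            contig_id = contig_ids[ci]
            clen = int(contig_lens[ci])
            ins = max(read_len, min(int(inserts[i]), clen))
            start = int(rng.integers(0, clen - ins + 1))
            genome_id, cds_id = contig_genome[contig_id], ""
        else:
            f = cds_list[idx[i]]
            contig_id = f.contig_id
            genome_id, cds_id = contig_genome[contig_id], f.cds_id
            ins = max(read_len, min(int(inserts[i]), f.length_bp))
            if f.length_bp < read_len:
                ins = f.length_bp
            start = f.start + int(rng.integers(0, f.length_bp - ins + 1))
        end = start + ins
        frag = seqs[contig_id][start:end]
        rl = min(read_len, ins)
        m1 = frag[:rl]
        m2 = reverse_complement(frag)[:rl]
        n_err = 0
        if error_rate > 0:
            m1, e1 = _mutate(rng, m1, error_rate)
            m2, e2 = _mutate(rng, m2, error_rate)
            n_err = e1 + e2
        fid = f"{genome_id}:{cds_id or 'intergenic'}:{i:06d}"
        out.append(
            FragmentTruth(
                fragment_id=fid,
                genome_id=genome_id,
                contig_id=contig_id,
                cds_id=cds_id,
                frag_start=start,
                frag_end=end,
                mate1_seq=m1,
                mate2_seq=m2,
                mate1_qual=_qual_string(rng, len(m1), qual_model, qual_phred),
                mate2_qual=_qual_string(rng, len(m2), qual_model, qual_phred),
                insert_size=ins,
                n_errors=n_err,
            )
        )
    return out


def _mutate(
    rng: np.random.Generator, seq: str, error_rate: float
) -> tuple[str, int]:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for j in hit:
        choices = _BASES[_BASES != arr[j]]
        arr[j] = rng.choice(choices)
    return arr.tobytes().decode(), int(hit.size)


# -- persistence ---------------------------------------------------------


def write_fastq_pair(
    fragments: Sequence[FragmentTruth], path1: str | Path, path2: str | Path
) -> None:
    """Write both mates as Phred+33 FASTQ files (byte-deterministic)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for fr in fragments:
            f1.write(f"@{fr.fragment_id}/1\n{fr.mate1_seq}\n+\n{fr.mate1_qual}\n")
            f2.write(f"@{fr.fragment_id}/2\n{fr.mate2_seq}\n+\n{fr.mate2_qual}\n")


def read_fastq_pair(
    path1: str | Path, path2: str | Path
) -> list[tuple[str, str, str, str, str]]:
    """Read mate files; yields (fragment_id, seq1, qual1, seq2, qual2)."""
    from Bio import SeqIO

    out = []
    for r1, r2 in zip(
        SeqIO.parse(str(path1), "fastq"), SeqIO.parse(str(path2), "fastq")
    ):
        fid = r1.id.rsplit("/", 1)[0]
        q1 = "".join(
            chr(q + 33) for q in r1.letter_annotations["phred_quality"]
        )
        q2 = "".join(
            chr(q + 33) for q in r2.letter_annotations["phred_quality"]
        )
        out.append((fid, str(r1.seq), q1, str(r2.seq), q2))
    return out


def write_truth_table(
    fragments: Sequence[FragmentTruth], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for fr in fragments:
            fh.write(
                "\t".join(
                    [
                        fr.fragment_id,
                        fr.genome_id,
                        fr.contig_id,
                        fr.cds_id,
                        str(fr.frag_start),
                        str(fr.frag_end),
                        str(fr.insert_size),
                        str(fr.n_errors),
                    ]
                )
                + "\n"
            )


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"cds_id": str})


def assignments_from_truth(fragments: Sequence[FragmentTruth]) -> list:
    """Turn simulated fragments into perfect unique pair assignments.

    Bypasses alignment: useful for exercising the counting and expression
    stages at scale, where (on error-free, repeat-free references) the
    internal aligner provably reproduces exactly these placements.
    """
    from .align import PairAssignment

    out = []
    for fr in fragments:
        m1s, m1e = fr.mate1_interval
        m2s, m2e = fr.mate2_interval
        out.append(
            PairAssignment(
                fragment_id=fr.fragment_id,
                status="unique",
                genome_id=fr.genome_id,
                contig_id=fr.contig_id,
                mate1_start=m1s,
                mate1_end=m1e,
                mate2_start=m2s,
                mate2_end=m2e,
                strand="+",
                mismatches=(0, 0),
                fragment_length=fr.insert_size,
            )
        )
    return out
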