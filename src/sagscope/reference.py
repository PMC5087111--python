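"""Reference genomes with CDS annotations.

A :class:`ReferenceSet` bundles one or more genomes (each a set of named
contigs), their protein-coding features (CDS) and a housekeeping-gene list.
It plays two roles in the pipeline: the mapping target for read assignment
and the feature universe for fragment counting.  In the application this
package was written for, the genomes are single amplified genomes (SAGs) of
an uncultivated symbiont plus the host background.

Coordinates are 0-based half-open internally.  GFF3 on disk is 1-based
inclusive and is converted on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class CapacityError(ValueError):
    """Requested features do not fit in the available sequence."""


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature on a contig.

    ``start``/``end`` follow the 0-based half-open convention.  ``annotated``
    records whether the gene carries a functional annotation (KO/COG/Pfam in
    the real data); it drives the annotation-contrast statistic.
    """

    cds_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    annotated: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid CDS interval [{self.start}, {self.end}) for {self.cds_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """A named genome: an ordered mapping of contig id to sequence."""

    genome_id: str
    contigs: dict[str, str]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class ReferenceSet:
    """Genomes + CDS features + housekeeping flags.

    The generator guarantees that no two CDS on the same contig overlap; the
    reader does not require it (``validate`` checks it only on request).
    """

    genomes: list[Genome] = field(default_factory=list)
    cds: list[CdsFeature] = field(default_factory=list)
    housekeeping_ids: set[str] = field(default_factory=set)

    # -- lookups ---------------------------------------------------------

    @property
    def contig_sequences(self) -> dict[str, str]:
        return {cid: seq for g in self.genomes for cid, seq in g.contigs.items()}

    @property
    def contig_to_genome(self) -> dict[str, str]:
        return {cid: g.genome_id for g in self.genomes for cid in g.contigs}

    @property
    def cds_by_id(self) -> dict[str, CdsFeature]:
        return {f.cds_id: f for f in self.cds}

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    def cds_on_contig(self, contig_id: str) -> list[CdsFeature]:
        """CDS features of one contig, sorted by start coordinate."""
        return sorted(
            (f for f in self.cds if f.contig_id == contig_id), key=lambda f: f.start
        )

    def cds_of_genome(self, genome_id: str) -> list[CdsFeature]:
        contigs = set()
        for g in self.genomes:
            if g.genome_id == genome_id:
                contigs.update(g.contigs)
        return [f for f in self.cds if f.contig_id in contigs]

    def cds_lengths(self, cds_ids: Iterable[str] | None = None) -> dict[str, int]:
        by_id = self.cds_by_id
        ids = list(cds_ids) if cds_ids is not None else list(by_id)
        return {i: by_id[i].length_bp for i in ids}

    # -- invariants ------------------------------------------------------

    def validate(self, check_overlap: bool = False) -> None:
        """Raise ``ValueError`` on any broken structural invariant."""
        seqs = self.contig_sequences
        seen: set[str] = set()
        for f in self.cds:
            if f.cds_id in seen:
                raise ValueError(f"duplicate CDS id {f.cds_id!r}")
            seen.add(f.cds_id)
            if f.contig_id not in seqs:
                raise ValueError(f"CDS {f.cds_id!r} on unknown contig {f.contig_id!r}")
            if f.end > len(seqs[f.contig_id]):
                raise ValueError(f"CDS {f.cds_id!r} extends past its contig")
        missing = self.housekeeping_ids - seen
        if missing:
            raise ValueError(f"housekeeping ids without a CDS: {sorted(missing)}")
        if check_overlap:
            for contig_id in seqs:
                feats = self.cds_on_contig(contig_id)
                for a, b in zip(feats, feats[1:]):
                    if b.start < a.end:
                        raise ValueError(
                            f"overlapping CDS {a.cds_id!r} and {b.cds_id!r}"
                        )

    # -- persistence -----------------------------------------------------

    def write_fasta(self, path: str | Path) -> None:
        records = []
        for g in self.genomes:
            for cid, seq in g.contigs.items():
                records.append(
                    SeqRecord(Seq(seq), id=cid, description=f"genome={g.genome_id}")
                )
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    def write_gff3(self, path: str | Path) -> None:
        # 1-based inclusive on disk; attributes round-trip annotation and
        # housekeeping flags.
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genomes:
                for cid in g.contigs:
                    for f in self.cds_on_contig(cid):
                        attrs = (
                            f"ID={f.cds_id};"
                            f"annotated={'true' if f.annotated else 'false'};"
                            f"housekeeping={'true' if f.cds_id in self.housekeeping_ids else 'false'}"
                        )
                        fh.write(
                            "\t".join(
                                [
                                    cid,
                                    "sagscope",
                                    "CDS",
                                    str(f.start + 1),
                                    str(f.end),
                                    ".",
                                    f.strand,
                                    ".",
                                    attrs,
                                ]
                            )
                            + "\n"
                        )

    @classmethod
    def from_files(cls, fasta: str | Path, gff3: str | Path) -> "ReferenceSet":
        """Read a reference set written by :meth:`write_fasta`/:meth:`write_gff3`.

        Contigs are grouped into genomes via the ``genome=`` token in the
        FASTA description (contigs without one become single-contig genomes
        named after themselves).
        """
        genomes: dict[str, Genome] = {}
        for rec in SeqIO.parse(str(fasta), "fasta"):
            gid = rec.id
            for token in rec.description.split():
                if token.startswith("genome="):
                    gid = token.split("=", 1)[1]
            genomes.setdefault(gid, Genome(gid, {})).contigs[rec.id] = str(rec.seq)

        cds: list[CdsFeature] = []
        hk: set[str] = set()
        with open(gff3) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) != 9 or cols[2] != "CDS":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
                )
                cds_id = attrs.get("ID", f"{cols[0]}:{cols[3]}-{cols[4]}")
                feat = CdsFeature(
                    cds_id=cds_id,
                    contig_id=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6] if cols[6] in ("+", "-") else "+",
                    annotated=attrs.get("annotated", "true") == "true",
                )
                cds.append(feat)
                if attrs.get("housekeeping") == "true":
                    hk.add(cds_id)
        refset = cls(genomes=list(genomes.values()), cds=cds, housekeeping_ids=hk)
        refset.validate()
        return refset


def merge_reference_sets(*refsets: ReferenceSet) -> ReferenceSet:
    """Combine disjoint reference sets (e.g. symbiont genomes + host background)."""
    merged = ReferenceSet()
    for rs in refsets:
        merged.genomes.extend(rs.genomes)
        merged.cds.extend(rs.cds)
        merged.housekeeping_ids |= rs.housekeeping_ids
    merged.validate()
    return merged
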