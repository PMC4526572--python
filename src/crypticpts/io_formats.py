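"""Genome/annotation input, gene-context extraction and table output.

Internal coordinates are 0-based half-open throughout; GFF3 is read and
written with its native 1-based closed convention. A *gene context* is the
transcript-oriented string ``coding tail + stop codon + downstream UTR`` on
which every downstream analysis operates. Where 3'-UTRs are not annotated the
UTR is defined operationally as the ``utr_nt`` bases downstream of the stop
codon (default 150).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .translation import STOP_CODONS

logger = logging.getLogger("crypticpts")

_NT = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomeRecord:
    """One FASTA record, uppercased, over the A/C/G/T/N alphabet."""

    record_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.record_id!r}: empty sequence")
        bad = set(self.sequence) - _NT
        if bad:
            raise ValueError(
                f"record {self.record_id!r}: disallowed characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A protein-coding gene: strand and CDS intervals in transcription order.

    ``cds_intervals`` are genomic 0-based half-open and sorted in transcription
    order (genomically descending for the minus strand). ``stop_codon_included``
    records whether the CDS spans cover the stop codon (the common GFF3 case).
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    stop_codon_included: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if not self.cds_intervals:
            raise ValueError(f"gene {self.gene_id!r}: no CDS intervals")
        ivs = [(int(a), int(b)) for a, b in self.cds_intervals]
        for a, b in ivs:
            if not 0 <= a < b:
                raise ValueError(f"gene {self.gene_id!r}: bad interval ({a}, {b})")
        genomic = sorted(ivs)
        for (_, b1), (a2, _) in zip(genomic, genomic[1:]):
            if a2 < b1:
                raise ValueError(f"gene {self.gene_id!r}: overlapping CDS intervals")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if ivs != expected:
            raise ValueError(
                f"gene {self.gene_id!r}: intervals not in transcription order"
            )
        self.cds_intervals = ivs

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds_intervals)


@dataclass
class GeneContext:
    """Coding tail + stop codon + downstream UTR, transcript orientation.

    ``stop_start`` indexes the first base of the annotated stop codon within
    ``seq`` and sits on a codon boundary of the coding frame. ``coord_map``
    (optional) gives the genomic position of each context base for BED export.
    """

    gene_id: str
    seq: str
    stop_start: int
    chrom: str | None = None
    strand: str | None = None
    coord_map: list[int] | None = field(default=None, repr=False, compare=False)
    utr_len: int = field(init=False)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if self.stop_start % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id!r}: stop_start {self.stop_start} not on a codon boundary"
            )
        stop = self.seq[self.stop_start : self.stop_start + 3]
        if stop not in STOP_CODONS:
            raise ValueError(
                f"gene {self.gene_id!r}: annotated stop codon is {stop!r}, "
                "not TAA/TAG/TGA"
            )
        if self.coord_map is not None and len(self.coord_map) != len(self.seq):
            raise ValueError(f"gene {self.gene_id!r}: coord_map length mismatch")
        self.utr_len = len(self.seq) - self.stop_start - 3


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased and U is mapped to T; characters outside
    A/C/G/T/N raise a format error naming the record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"record {rec.id!r}: empty sequence in {path}")
        records.append(GenomeRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.record_id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


_STOP_TAG = re.compile(r"stop_start=(\d+)")


def read_context_fasta(path: str | Path) -> list[GeneContext]:
    """Read per-gene context FASTA; headers must carry ``stop_start=<int>``."""
    contexts = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _STOP_TAG.search(rec.description)
        if not m:
            raise ValueError(
                f"context record {rec.id!r}: header lacks a 'stop_start=<int>' tag"
            )
        contexts.append(GeneContext(rec.id, str(rec.seq), int(m.group(1))))
    return contexts


def write_context_fasta(contexts: Iterable[GeneContext], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ctx in contexts:
            fh.write(f">{ctx.gene_id} stop_start={ctx.stop_start}\n{ctx.seq}\n")


def read_gff(path: str | Path) -> list[GeneModel]:
    """Read GFF3 CDS features into gene models.

    CDS features are grouped by their ``Parent`` (falling back to ``ID``);
    1-based closed coordinates become 0-based half-open; minus-strand interval
    order is flipped to transcription order. Genes whose total CDS length is
    not a multiple of 3 are excluded with a logged warning. The CDS spans are
    assumed to include the stop codon.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID")
        if not parents:
            logger.warning("CDS feature without Parent/ID at %s:%s skipped", feat.seqid, feat.start)
            continue
        key = parents[0]
        entry = grouped.setdefault(
            key, {"chrom": feat.seqid, "strand": feat.strand, "ivs": []}
        )
        entry["ivs"].append((feat.start - 1, feat.end))
    genes: list[GeneModel] = []
    for gid, entry in grouped.items():
        ivs = sorted(entry["ivs"])
        if entry["strand"] == "-":
            ivs = ivs[::-1]
        total = sum(b - a for a, b in ivs)
        if total % 3 != 0:
            logger.warning(
                "gene %r: CDS length %d not a multiple of 3; excluded", gid, total
            )
            continue
        genes.append(GeneModel(gid, entry["chrom"], entry["strand"], ivs))
    return genes


def write_gff(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 mRNA + CDS features (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            genomic = sorted(g.cds_intervals)
            gstart, gend = genomic[0][0] + 1, genomic[-1][1]
            fh.write(
                f"{g.chrom}\tcrypticpts\tmRNA\t{gstart}\t{gend}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for a, b in genomic:
                fh.write(
                    f"{g.chrom}\tcrypticpts\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t0\tParent={g.gene_id}\n"
                )


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def extract_context(
    genome: GenomeRecord,
    gene: GeneModel,
    tail_nt: int = 30,
    utr_nt: int = 150,
) -> GeneContext:
    """Extract ``last tail_nt coding bases + stop codon + utr_nt downstream``.

    Minus-strand genes are reverse-complemented into transcript orientation;
    the context therefore satisfies ``stop_start == tail_nt`` (less when the
    CDS is shorter than ``tail_nt + 3``). A downstream region shorter than
    ``utr_nt`` yields a truncated context with a logged warning; an annotated
    stop codon that is not TAA/TAG/TGA is a hard error naming the gene.
    """
    if tail_nt % 3 != 0:
        raise ValueError("tail_nt must be a multiple of 3")
    if gene.chrom != genome.record_id:
        raise ValueError(
            f"gene {gene.gene_id!r} is on {gene.chrom!r}, not {genome.record_id!r}"
        )
    n = len(genome.sequence)
    for a, b in gene.cds_intervals:
        if b > n:
            raise ValueError(f"gene {gene.gene_id!r} exceeds genome bounds")

    # transcript bases and their genomic positions, transcription order
    bases: list[str] = []
    positions: list[int] = []
    for a, b in gene.cds_intervals:
        if gene.strand == "+":
            bases.append(genome.sequence[a:b])
            positions.extend(range(a, b))
        else:
            bases.append(_revcomp(genome.sequence[a:b]))
            positions.extend(range(b - 1, a - 1, -1))
    cds = "".join(bases)

    genomic = sorted(gene.cds_intervals)
    if gene.strand == "+":
        down_from = genomic[-1][1]
        down_span = min(utr_nt + (0 if gene.stop_codon_included else 3), n - down_from)
        downstream = genome.sequence[down_from : down_from + down_span]
        down_pos = list(range(down_from, down_from + down_span))
    else:
        down_to = genomic[0][0]
        down_span = min(utr_nt + (0 if gene.stop_codon_included else 3), down_to)
        downstream = _revcomp(genome.sequence[down_to - down_span : down_to])
        down_pos = list(range(down_to - 1, down_to - down_span - 1, -1))

    if not gene.stop_codon_included:
        cds += downstream[:3]
        positions += down_pos[:3]
        downstream, down_pos = downstream[3:], down_pos[3:]

    if len(cds) < 3:
        raise ValueError(f"gene {gene.gene_id!r}: CDS shorter than a stop codon")
    stop = cds[-3:]
    if stop not in STOP_CODONS:
        raise ValueError(
            f"gene {gene.gene_id!r}: annotated stop codon is {stop!r}, not TAA/TAG/TGA"
        )
    take = min(tail_nt, len(cds) - 3)
    utr = downstream[:utr_nt]
    if len(utr) < utr_nt:
        logger.warning(
            "gene %r: only %d nt downstream available (requested %d)",
            gene.gene_id, len(utr), utr_nt,
        )
    seq = cds[-(take + 3):] + utr
    coord_map = positions[-(take + 3):] + down_pos[: len(utr)]
    return GeneContext(
        gene_id=gene.gene_id,
        seq=seq,
        stop_start=take,
        chrom=gene.chrom,
        strand=gene.strand,
        coord_map=coord_map,
    )


HIT_COLUMNS = [
    "gene_id", "frame", "motif_start", "tripeptide", "stop_after_motif",
    "interrupted", "context", "context_complete", "isoform_tail",
]

VARIANT_COLUMNS = [
    "gene_id", "kind", "position", "ref_base", "alt_base",
    "equivalence_class_id", "creates_inframe_motif",
    "resulting_isoform_tail", "resulting_seq",
]


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    """Write a hit table as TSV, rows sorted by (gene_id, frame, motif_start)."""
    df = hits.reindex(columns=HIT_COLUMNS)
    df = df.sort_values(["gene_id", "frame", "motif_start"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"gene_id": str, "tripeptide": str, "context": str, "isoform_tail": str},
    )
    if len(df):
        for col in ("frame", "motif_start", "stop_after_motif"):
            df[col] = df[col].astype(int)
        for col in ("interrupted", "context_complete"):
            df[col] = df[col].astype(bool)
    return df.reindex(columns=HIT_COLUMNS)


def write_variants(variants: pd.DataFrame, path: str | Path) -> None:
    df = variants.reindex(columns=VARIANT_COLUMNS)
    df = df.sort_values(["gene_id", "kind", "position", "alt_base"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_variants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if len(df):
        df["position"] = df["position"].astype(int)
        df["creates_inframe_motif"] = df["creates_inframe_motif"] == "True"
    return df.reindex(columns=VARIANT_COLUMNS)


def hits_to_bed(
    hits: pd.DataFrame,
    contexts: Mapping[str, GeneContext],
    path: str | Path,
) -> None:
    """Export motif genomic spans (tripeptide + stop, 12 nt) as BED6.

    Requires contexts extracted from a genome (``coord_map`` present).
    """
    lines = []
    for row in hits.itertuples(index=False):
        ctx = contexts[row.gene_id]
        if ctx.coord_map is None or ctx.chrom is None:
            raise ValueError(f"gene {row.gene_id!r}: context lacks genomic coordinates")
        p = ctx.stop_start + 3 + int(row.motif_start)
        span = ctx.coord_map[p : p + 12]
        if len(span) < 12:
            raise ValueError(f"gene {row.gene_id!r}: motif span exceeds context")
        start, end = min(span), max(span) + 1
        name = f"{row.gene_id}|{row.tripeptide}|frame+{row.frame}"
        lines.append((ctx.chrom, start, end, name, 0, ctx.strand))
    lines.sort()
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in lines:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
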