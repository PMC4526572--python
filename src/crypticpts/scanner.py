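"""Cryptic PTS1 search in gene contexts.

The scan looks, in every reading frame relative to the coding frame, for a
grammar-matching tripeptide immediately followed by a stop codon whose first
codon starts within a window downstream of the annotated stop codon (30 nt by
default, the span the motif search used).

Frames are labelled relative to the CDS frame: frame 0 is the coding frame
continued across the annotated stop via read-through (a single bypass), and
frames +1/+2 are shifted by one and two bases, beginning at the shifted-frame
codon that overlaps the annotated stop codon — so a cryptic tripeptide may
partially overlap the coding tail. A hit is *interrupted* when another
same-frame stop codon lies strictly between the annotated stop locus and the
motif's first codon; such hits are unreachable by a single frameshift or
read-through event and are flagged (or filtered with ``drop_interrupted``).

``motif_start`` is measured from the first base after the annotated stop
codon (0-based); ``offset_origin="stop_start"`` counts from the stop codon's
first base instead, since published downstream distances do not pin the
convention down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import (
    GeneContext,
    extract_context,
    read_context_fasta,
    read_fasta,
    read_gff,
)
from .motif import (
    ContextPeptide,
    DEFAULT_GRAMMAR,
    MotifGrammar,
    extract_context_peptide,
)
from .translation import READTHROUGH_TABLE, STOP_CODONS, codon_aa

logger = logging.getLogger("crypticpts")


@dataclass(frozen=True)
class CrypticHit:
    """One cryptic-motif occurrence in a gene context."""

    gene_id: str
    frame: int  # 0, 1 or 2, relative to the CDS frame
    tripeptide: str
    motif_start: int  # offset of the tripeptide's first base (see module doc)
    stop_after_motif: int  # context coordinate of the terminating stop codon
    interrupted: bool
    context: ContextPeptide
    isoform_tail: str

    def to_row(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "frame": self.frame,
            "motif_start": self.motif_start,
            "tripeptide": self.tripeptide,
            "stop_after_motif": self.stop_after_motif,
            "interrupted": self.interrupted,
            "context": self.context.residues,
            "context_complete": self.context.complete,
            "isoform_tail": self.isoform_tail,
        }


def _isoform_tail(seq: str, s: int, frame: int, p: int) -> str:
    """Implied alternative C-terminus ending in the motif tripeptide.

    Frame 0: coding tail, then the read-through residue for the annotated
    stop, then downstream residues through the tripeptide. Shifted frames:
    coding-frame residues up to the shift point, then shifted-frame residues
    from the codon overlapping the annotated stop through the tripeptide.
    """
    if frame == 0:
        pre = [codon_aa(seq[q : q + 3]) for q in range(0, s, 3)]
        mid = [READTHROUGH_TABLE[seq[s : s + 3]]]
        post = [codon_aa(seq[q : q + 3]) for q in range(s + 3, p + 9, 3)]
        return "".join(pre + mid + post)
    p0 = s - 3 + frame
    pre = [codon_aa(seq[q : q + 3]) for q in range(0, max(p0 - 2, 0), 3)]
    shifted = [codon_aa(seq[q : q + 3]) for q in range(p0, p + 9, 3)]
    return "".join(pre + shifted)


def scan_context(
    ctx: GeneContext,
    grammar: MotifGrammar = DEFAULT_GRAMMAR,
    window_nt: int = 30,
    drop_interrupted: bool = False,
    offset_origin: str = "after_stop",
) -> list[CrypticHit]:
    """Find cryptic tripeptide+stop motifs in one gene context.

    Returns hits sorted by (frame, motif_start); empty list when none. With
    ``drop_interrupted`` hits separated from the annotated stop by an extra
    same-frame stop codon are filtered out.
    """
    if offset_origin not in ("after_stop", "stop_start"):
        raise ValueError(f"unknown offset_origin {offset_origin!r}")
    seq, s = ctx.seq, ctx.stop_start
    if ctx.utr_len + 3 < window_nt:
        logger.warning(
            "gene %r: UTR (%d nt) shorter than the %d nt scan window",
            ctx.gene_id, ctx.utr_len, window_nt,
        )
    origin = s + 3 if offset_origin == "after_stop" else s
    hits: list[CrypticHit] = []
    for frame in (0, 1, 2):
        # first admissible codon start: frame 0 continues past the annotated
        # stop; shifted frames begin at the codon overlapping it
        p_min = s + 3 if frame == 0 else s - 3 + frame
        interrupt_from = s + 3 if frame == 0 else s - 3 + frame
        p = max(p_min, 0)
        while p + 12 <= len(seq):
            if p - origin >= window_nt:
                break
            tri = codon_aa(seq[p : p + 3]) + codon_aa(seq[p + 3 : p + 6]) + codon_aa(seq[p + 6 : p + 9])
            if (
                "*" not in tri
                and "X" not in tri
                and grammar.matches(tri)
                and seq[p + 9 : p + 12] in STOP_CODONS
            ):
                interrupted = any(
                    seq[q : q + 3] in STOP_CODONS
                    for q in range(interrupt_from, p, 3)
                )
                tail = _isoform_tail(seq, s, frame, p)
                hits.append(
                    CrypticHit(
                        gene_id=ctx.gene_id,
                        frame=frame,
                        tripeptide=tri,
                        motif_start=p - origin,
                        stop_after_motif=p + 9,
                        interrupted=interrupted,
                        context=extract_context_peptide(tail),
                        isoform_tail=tail,
                    )
                )
            p += 3
    hits.sort(key=lambda h: (h.frame, h.motif_start))
    if drop_interrupted:
        hits = [h for h in hits if not h.interrupted]
    return hits


def hits_to_frame(hits: Iterable[CrypticHit]) -> pd.DataFrame:
    from .io_formats import HIT_COLUMNS

    rows = [h.to_row() for h in hits]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def scan_contexts(
    contexts: Sequence[GeneContext],
    grammar: MotifGrammar = DEFAULT_GRAMMAR,
    window_nt: int = 30,
    drop_interrupted: bool = False,
    offset_origin: str = "after_stop",
) -> tuple[pd.DataFrame, dict]:
    """Scan many contexts; returns (hit table, per-genome summary).

    The summary counts candidates before any ``drop_interrupted`` filtering,
    so interrupted candidates are counted even when excluded from the table.
    """
    from .conservation import summarize_genome

    all_hits: list[CrypticHit] = []
    for ctx in contexts:
        all_hits.extend(
            scan_context(ctx, grammar, window_nt, drop_interrupted=False,
                         offset_origin=offset_origin)
        )
    df = hits_to_frame(all_hits)
    summary = summarize_genome(df, n_genes_total=len(contexts))
    if drop_interrupted and len(df):
        df = df[~df["interrupted"]].reset_index(drop=True)
    return df, summary


def scan_genome(
    fasta: str | Path,
    gff: str | Path | None = None,
    contexts: str | Path | None = None,
    grammar: MotifGrammar = DEFAULT_GRAMMAR,
    window_nt: int = 30,
    drop_interrupted: bool = False,
    tail_nt: int = 30,
    utr_nt: int = 150,
    offset_origin: str = "after_stop",
) -> tuple[pd.DataFrame, dict, list[GeneContext]]:
    """Scan a genome (FASTA + GFF3) or a per-gene context FASTA.

    With ``gff`` given, ``fasta`` is a genome and contexts are extracted per
    gene model; otherwise ``contexts`` (or ``fasta`` itself) is read as a
    context FASTA whose headers carry ``stop_start=<int>``. Returns the hit
    table, the per-genome summary and the contexts scanned.
    """
    if gff is not None:
        genomes = {g.record_id: g for g in read_fasta(fasta)}
        ctx_list = []
        for gene in read_gff(gff):
            genome = genomes.get(gene.chrom)
            if genome is None:
                logger.warning("gene %r: chromosome %r not in FASTA; skipped",
                               gene.gene_id, gene.chrom)
                continue
            try:
                ctx_list.append(extract_context(genome, gene, tail_nt, utr_nt))
            except ValueError as exc:
                logger.warning("gene %r excluded: %s", gene.gene_id, exc)
    else:
        ctx_list = read_context_fasta(contexts if contexts is not None else fasta)
    df, summary = scan_contexts(
        ctx_list, grammar, window_nt, drop_interrupted, offset_origin
    )
    return df, summary, ctx_list
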