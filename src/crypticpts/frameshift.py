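"""Genetic imprinting of phenotypic frameshifts: indels, substitutions, slippage.

A +1-frame cryptic motif expressed transiently by ribosomal slippage can be
made permanent ("imprinted") by a single-nucleotide deletion upstream of the
stop codon, which places the motif in the coding frame. This module
enumerates such deletions (collapsing equivalent ones — any deletion within a
homopolymer run yields the same sequence), links them to scanned +1-frame
hits, enumerates single-base substitutions that strengthen a stop-adjacent
terminal tripeptide (e.g. NKF* -> NKL*), and detects the homopolymer runs
near the stop codon where polymerase/ribosome slippage is most likely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import groupby

from .io_formats import GeneContext
from .motif import DEFAULT_GRAMMAR, MotifGrammar
from .scanner import CrypticHit, scan_context
from .translation import codon_aa, translate_to_stop

logger = logging.getLogger("crypticpts")


@dataclass(frozen=True)
class VariantEvent:
    """A single-nucleotide deletion or substitution and its consequence."""

    kind: str  # "deletion" | "substitution"
    position: int  # 0-based index in GeneContext.seq
    ref_base: str
    alt_base: str  # "" for deletions
    resulting_seq: str
    resulting_isoform_tail: str
    creates_inframe_motif: bool
    equivalence_class_id: str
    gene_id: str = ""

    def to_row(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "kind": self.kind,
            "position": self.position,
            "ref_base": self.ref_base,
            "alt_base": self.alt_base,
            "equivalence_class_id": self.equivalence_class_id,
            "creates_inframe_motif": self.creates_inframe_motif,
            "resulting_isoform_tail": self.resulting_isoform_tail,
            "resulting_seq": self.resulting_seq,
        }


@dataclass(frozen=True)
class SlippageSite:
    """A maximal homonucleotide run near the stop codon (half-open coords)."""

    start: int
    end: int
    base: str
    run_length: int
    distance_to_stop: int  # bases between run end and the stop codon
    gene_id: str = ""


def _inframe_consequence(
    resulting_seq: str, grammar: MotifGrammar
) -> tuple[str, bool]:
    """Coding-frame product of a mutated context and whether it ends in a motif."""
    peptide, terminated = translate_to_stop(resulting_seq, 0)
    creates = terminated and len(peptide) >= 3 and grammar.matches(peptide[-3:])
    return peptide, creates


def enumerate_deletions(
    ctx: GeneContext,
    upstream_window: int = 30,
    grammar: MotifGrammar = DEFAULT_GRAMMAR,
) -> list[VariantEvent]:
    """All single-base deletions in the window upstream of the stop codon.

    One event per deletable position; deletions yielding byte-identical
    sequences (anywhere within one homopolymer run) share an equivalence
    class. ``creates_inframe_motif`` is True iff the mutated coding-frame
    translation terminates in a grammar-matching tripeptide+stop.
    """
    if upstream_window < 1:
        raise ValueError("upstream_window must be >= 1")
    s = ctx.stop_start
    start = s - upstream_window
    if start < 0:
        logger.warning(
            "gene %r: upstream window %d exceeds available %d nt; truncated",
            ctx.gene_id, upstream_window, s,
        )
        start = 0
    by_seq: dict[str, list[int]] = {}
    for d in range(start, s):
        rs = ctx.seq[:d] + ctx.seq[d + 1 :]
        by_seq.setdefault(rs, []).append(d)
    events: list[VariantEvent] = []
    for rs, positions in by_seq.items():
        first = min(positions)
        class_id = f"del_{ctx.seq[first]}{first}"
        tail, creates = _inframe_consequence(rs, grammar)
        for d in positions:
            events.append(
                VariantEvent(
                    kind="deletion",
                    position=d,
                    ref_base=ctx.seq[d],
                    alt_base="",
                    resulting_seq=rs,
                    resulting_isoform_tail=tail,
                    creates_inframe_motif=creates,
                    equivalence_class_id=class_id,
                    gene_id=ctx.gene_id,
                )
            )
    events.sort(key=lambda e: e.position)
    return events


def deletion_classes(events: list[VariantEvent]) -> dict[str, VariantEvent]:
    """One representative event per equivalence class, keyed by class id."""
    reps: dict[str, VariantEvent] = {}
    for e in events:
        reps.setdefault(e.equivalence_class_id, e)
    return reps


def imprinting_map(
    ctx: GeneContext,
    grammar: MotifGrammar = DEFAULT_GRAMMAR,
    upstream_window: int = 30,
    window_nt: int = 30,
    hits: list[CrypticHit] | None = None,
) -> list[dict]:
    """Link each +1-frame cryptic hit to the deletion classes imprinting it.

    For every +1-frame hit, lists the deletion equivalence classes whose
    mutated coding-frame product terminates in the very same tripeptide
    (``linked_classes``), alongside classes whose product stops prematurely
    (``premature_stop_classes``) — for an interrupted hit every class falls
    in the latter group. Returns one record per +1-frame hit; empty when the
    context has none.
    """
    if hits is None:
        hits = scan_context(ctx, grammar, window_nt)
    reps = deletion_classes(enumerate_deletions(ctx, upstream_window, grammar))
    records: list[dict] = []
    for hit in hits:
        if hit.frame != 1:
            continue
        linked = sorted(
            cid
            for cid, rep in reps.items()
            if rep.creates_inframe_motif
            and rep.resulting_isoform_tail[-3:] == hit.tripeptide
        )
        premature = sorted(
            cid
            for cid, rep in reps.items()
            if not (
                rep.creates_inframe_motif
                and rep.resulting_isoform_tail[-3:] == hit.tripeptide
            )
        )
        records.append(
            {
                "gene_id": ctx.gene_id,
                "frame": hit.frame,
                "motif_start": hit.motif_start,
                "tripeptide": hit.tripeptide,
                "hit_interrupted": hit.interrupted,
                "linked_classes": linked,
                "premature_stop_classes": premature,
                "n_deletion_classes": len(reps),
            }
        )
    return records


_BASES = "ACGT"


def substitutions_to_motif(
    ctx: GeneContext,
    grammar: MotifGrammar = DEFAULT_GRAMMAR,
    position: int = 2,
) -> list[VariantEvent]:
    """Single-base substitutions upgrading the stop-adjacent tripeptide.

    Examines the three coding-frame codons immediately before the annotated
    stop. When the terminal tripeptide already fully matches the grammar the
    list is empty. Otherwise the codon at ``position`` (0/1/2 within the
    tripeptide; default the C-terminal codon, whose residue dominates
    targeting strength) is mutated: every single-base neighbour translating
    to a *different* amino acid that the grammar accepts at that position
    becomes an event — e.g. a terminal Phe codon yields exactly the three
    one-base Leu codons.
    """
    if position not in (0, 1, 2):
        raise ValueError("position must be 0, 1 or 2")
    s = ctx.stop_start
    if s < 9:
        logger.warning("gene %r: coding tail shorter than 3 codons; no substitution scan",
                       ctx.gene_id)
        return []
    tri = "".join(codon_aa(ctx.seq[q : q + 3]) for q in range(s - 9, s, 3))
    if "*" in tri or "X" in tri:
        return []
    if grammar.matches(tri):
        return []
    codon_start = s - 9 + 3 * position
    codon = ctx.seq[codon_start : codon_start + 3]
    orig_aa = codon_aa(codon)
    accepted = grammar.positions[position]
    events: list[VariantEvent] = []
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            new_codon = codon[:i] + b + codon[i + 1 :]
            aa = codon_aa(new_codon)
            if aa == orig_aa or aa == "*" or aa not in accepted:
                continue
            pos = codon_start + i
            rs = ctx.seq[:pos] + b + ctx.seq[pos + 1 :]
            tail, creates = _inframe_consequence(rs, grammar)
            events.append(
                VariantEvent(
                    kind="substitution",
                    position=pos,
                    ref_base=codon[i],
                    alt_base=b,
                    resulting_seq=rs,
                    resulting_isoform_tail=tail,
                    creates_inframe_motif=creates,
                    equivalence_class_id=f"sub_{pos}{codon[i]}>{b}",
                    gene_id=ctx.gene_id,
                )
            )
    events.sort(key=lambda e: (e.position, e.alt_base))
    return events


def find_slippage_sites(
    ctx: GeneContext,
    min_run: int = 3,
    search_window: int | None = None,
) -> list[SlippageSite]:
    """Maximal homopolymer runs of length >= ``min_run`` upstream of the stop.

    ``search_window`` restricts the search to that many bases immediately
    before the stop codon (default: the whole upstream region). Sites are
    sorted by start coordinate.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    s = ctx.stop_start
    region_start = 0 if search_window is None else max(0, s - search_window)
    region = ctx.seq[region_start:s]
    sites: list[SlippageSite] = []
    offset = region_start
    for base, grp in groupby(region):
        run = len(list(grp))
        if run >= min_run:
            sites.append(
                SlippageSite(
                    start=offset,
                    end=offset + run,
                    base=base,
                    run_length=run,
                    distance_to_stop=s - (offset + run),
                    gene_id=ctx.gene_id,
                )
            )
        offset += run
    return sites
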