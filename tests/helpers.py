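"""Independent oracles and random-input builders shared across tests."""

from __future__ import annotations

import numpy as np

from crypticpts.io_formats import GeneContext
from crypticpts.motif import MotifGrammar
from crypticpts.translation import SENSE_CODONS, translate

_STOPS = ("TAA", "TAG", "TGA")


def oracle_scan(ctx: GeneContext, grammar: MotifGrammar, window_nt: int = 30) -> set:
    """Naive all-frames enumeration of tripeptide+stop motifs.

    Translates each full frame to a peptide string and pattern-matches three
    grammar-accepted residues followed by ``*`` — an independent route to the
    scanner's codon walk. Returns tuples
    (frame, motif_start, tripeptide, interrupted, stop_codon_index).
    """
    seq, s = ctx.seq, ctx.stop_start
    out = set()
    for f in (0, 1, 2):
        pep = translate(seq, f)
        q0 = s + 3 if f == 0 else s - 3 + f  # first admissible codon start
        j0 = (q0 - f) // 3
        for i in range(len(pep) - 3):
            tri = pep[i : i + 3]
            if "*" in tri or "X" in tri or pep[i + 3] != "*":
                continue
            if not grammar.matches(tri):
                continue
            p = f + 3 * i
            if p < q0 or p - (s + 3) >= window_nt:
                continue
            interrupted = "*" in pep[j0:i]
            out.add((f, p - (s + 3), tri, interrupted, p + 9))
    return out


def hit_tuples(hits) -> set:
    return {
        (h.frame, h.motif_start, h.tripeptide, h.interrupted, h.stop_after_motif)
        for h in hits
    }


def brute_force_deletion_seqs(seq: str, positions: range) -> set[str]:
    """Distinct sequences reachable by deleting one base at the given positions."""
    return {seq[:d] + seq[d + 1 :] for d in positions}


def count_maximal_runs(s: str) -> int:
    runs = 1 if s else 0
    for a, b in zip(s, s[1:]):
        if a != b:
            runs += 1
    return runs


def random_context(
    rng: np.random.Generator,
    plant_prob: float = 0.5,
    grammar: MotifGrammar | None = None,
    utr_nt: int = 45,
    gene_id: str = "rand",
) -> GeneContext:
    """Random small context, optionally seeded with motif-like material.

    Injected tripeptide codons land at arbitrary (unaligned) UTR positions so
    that hits arise in all frames, interrupted or not, without any truth
    bookkeeping — inputs for oracle-equivalence checks, not a benchmark.
    """
    tail = "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), 5))
    stop = _STOPS[rng.integers(0, 3)]
    utr = list("ACGT"[i] for i in rng.integers(0, 4, utr_nt))
    if grammar is not None and rng.random() < plant_prob:
        from crypticpts.synthetic import _encode_peptide

        pool = grammar.accepted_tripeptides()
        tri = pool[rng.integers(0, len(pool))]
        insert = _encode_peptide(rng, tri) + _STOPS[rng.integers(0, 3)]
        pos = int(rng.integers(0, max(1, utr_nt - 12)))
        utr[pos : pos + 12] = insert
    return GeneContext(gene_id, tail + stop + "".join(utr), len(tail))
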