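"""Synthetic yeast-like genomes with planted cryptic motifs and truth tables.

The generator emulates the gene architecture the analyses operate on: a
single-exon CDS ending in a stop codon followed by a 150 nt 3'-UTR, at
yeast-like base composition (GC 0.38). A chosen fraction of genes carries a
planted tripeptide+stop motif at a chosen frame and offset; a fraction of
those is interrupted by an extra same-frame stop codon; an optional
homopolymer run is written immediately upstream of the stop. Background
sequence is rejection-sampled so that no unplanted grammar hit exists inside
the scan window, making the emitted truth table exact rather than
probabilistic. Planted/interrupted counts are taken as rounded fractions of
the gene count, so prevalence summaries reproduce the requested proportions by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GeneContext,
    GeneModel,
    GenomeRecord,
    write_context_fasta,
    write_fasta,
    write_gff,
)
from .motif import DEFAULT_GRAMMAR, MotifGrammar
from .scanner import scan_context
from .translation import SENSE_CODONS, codon_aa

_AA_TO_CODONS: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _AA_TO_CODONS.setdefault(codon_aa(_c), []).append(_c)

_MAX_ATTEMPTS = 1000


@dataclass(frozen=True)
class PlantSpec:
    """Generation parameters; the defaults are the benchmark conditions."""

    n_genes: int = 200
    fraction_planted: float = 0.2
    frame_distribution: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    offset_range: tuple[int, int] = (0, 30)  # motif_start within [lo, hi)
    fraction_interrupted: float = 0.4
    slippage_run: tuple[str, int] | None = None
    tripeptide_pool: tuple[str, ...] | None = None  # default: all grammar-accepted
    gc_content: float = 0.38
    seed: int = 0
    tail_nt: int = 30
    utr_nt: int = 150
    window_nt: int = 30
    minus_strand_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("fraction_planted", "fraction_interrupted", "gc_content",
                     "minus_strand_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.frame_distribution) - 1.0) > 1e-9:
            raise ValueError("frame_distribution must sum to 1")
        lo, hi = self.offset_range
        if not 0 <= lo < hi <= self.window_nt:
            raise ValueError("offset_range must satisfy 0 <= lo < hi <= window_nt")
        if self.tail_nt % 3 != 0 or self.tail_nt < 9:
            raise ValueError("tail_nt must be a multiple of 3, >= 9")
        if hi + 12 > self.utr_nt + 3:
            raise ValueError("offset window too close to the UTR end for a motif")


@dataclass
class SyntheticGenome:
    records: list[GenomeRecord]
    genes: list[GeneModel]
    contexts: list[GeneContext]
    truth: pd.DataFrame


def _rand_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ATGC"), size=n, p=[p[0], p[3], p[2], p[1]]))


def _rand_sense_codons(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _encode_peptide(rng: np.random.Generator, peptide: str) -> str:
    return "".join(
        _AA_TO_CODONS[aa][rng.integers(0, len(_AA_TO_CODONS[aa]))] for aa in peptide
    )


def _feasible_offsets(frame: int, lo: int, hi: int, interrupted: bool) -> list[int]:
    """Offsets congruent with the frame grid, leaving room for an extra stop."""
    floor = frame + 3 if interrupted else 0
    return [o for o in range(lo, hi) if o % 3 == frame and o >= floor]


def _build_planted_utr(
    rng: np.random.Generator,
    spec: PlantSpec,
    frame: int,
    offset: int,
    tripeptide: str,
    interrupted: bool,
) -> str:
    """UTR with tripeptide codons + stop at the given frame/offset."""
    utr = list(_rand_bases(rng, spec.utr_nt, spec.gc_content))
    p = offset  # UTR-local coordinate of the motif's first base
    motif = _encode_peptide(rng, tripeptide) + ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    utr[p : p + 12] = motif
    if interrupted:
        # same-frame stop strictly between the annotated stop and the motif
        grid = list(range(frame - 3 if frame else 0, p - 2, 3))
        starts = [q for q in grid if q >= 0 and q + 3 <= p]
        q = starts[rng.integers(0, len(starts))]
        utr[q : q + 3] = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    return "".join(utr)


def _expected_hits(truth_row: dict) -> set[tuple]:
    if not truth_row["planted"]:
        return set()
    return {
        (
            truth_row["frame"],
            truth_row["motif_start"],
            truth_row["tripeptide"],
            truth_row["interrupted"],
        )
    }


def generate(
    spec: PlantSpec,
    grammar: MotifGrammar = DEFAULT_GRAMMAR,
    outdir: str | Path | None = None,
) -> SyntheticGenome:
    """Generate a synthetic genome, gene models, contexts and a truth table.

    Deterministic under ``spec.seed``. With ``outdir`` given, writes
    ``genome.fasta``, ``genes.gff3``, ``contexts.fasta`` and ``truth.tsv``.
    Raises when a gene cannot be realised within 1000 rejection attempts
    (infeasible spec).
    """
    rng = np.random.default_rng(spec.seed)
    n_planted = round(spec.n_genes * spec.fraction_planted)
    n_interrupted = round(n_planted * spec.fraction_interrupted)
    order = rng.permutation(spec.n_genes)
    planted_ids = set(order[:n_planted])
    interrupted_ids = set(order[:n_interrupted])

    pool = (
        list(spec.tripeptide_pool)
        if spec.tripeptide_pool is not None
        else grammar.accepted_tripeptides()
    )
    for tri in pool:
        if not grammar.matches(tri):
            raise ValueError(f"tripeptide_pool entry {tri!r} outside the grammar")

    records: list[GenomeRecord] = []
    genes: list[GeneModel] = []
    contexts: list[GeneContext] = []
    truth_rows: list[dict] = []
    lo, hi = spec.offset_range

    for i in range(spec.n_genes):
        gene_id = f"g{i:04d}"
        planted = i in planted_ids
        interrupted = i in interrupted_ids
        frame = offset = None
        tripeptide = ""
        if planted:
            frame = int(rng.choice(3, p=list(spec.frame_distribution)))
            feasible = _feasible_offsets(frame, lo, hi, interrupted)
            if not feasible:
                raise ValueError(
                    f"no feasible offset in [{lo}, {hi}) for frame {frame}"
                    f"{' (interrupted)' if interrupted else ''}"
                )
            offset = int(feasible[rng.integers(0, len(feasible))])
            tripeptide = pool[rng.integers(0, len(pool))]

        seq = None
        for _attempt in range(_MAX_ATTEMPTS):
            tail = _rand_sense_codons(rng, spec.tail_nt // 3)
            if planted and spec.slippage_run is not None:
                base, run = spec.slippage_run
                if run >= spec.tail_nt:
                    raise ValueError("slippage run longer than the coding tail")
                tail = tail[: spec.tail_nt - run] + base * run
                if (
                    tail[spec.tail_nt - run - 1] == base  # run must stay maximal
                    or "*" in [codon_aa(tail[k : k + 3]) for k in range(0, len(tail), 3)]
                ):
                    continue
            stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
            if planted:
                utr = _build_planted_utr(rng, spec, frame, offset, tripeptide, interrupted)
            else:
                utr = _rand_bases(rng, spec.utr_nt, spec.gc_content)
            cand = tail + stop + utr
            ctx = GeneContext(gene_id=gene_id, seq=cand, stop_start=spec.tail_nt)
            found = {
                (h.frame, h.motif_start, h.tripeptide, h.interrupted)
                for h in scan_context(ctx, grammar, spec.window_nt)
            }
            expected = _expected_hits(
                {
                    "planted": planted,
                    "frame": frame,
                    "motif_start": offset,
                    "tripeptide": tripeptide,
                    "interrupted": interrupted,
                }
            )
            if found == expected:
                seq = cand
                break
        if seq is None:
            raise ValueError(
                f"gene {gene_id}: no admissible sequence in {_MAX_ATTEMPTS} attempts "
                "(infeasible spec)"
            )

        pad5 = _rand_bases(rng, 20, spec.gc_content)
        pad3 = _rand_bases(rng, 10, spec.gc_content)
        contig = pad5 + seq + pad3
        cds_start = len(pad5)
        cds_end = cds_start + spec.tail_nt + 3  # coding tail + stop only
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        if strand == "-":
            from Bio.Seq import Seq

            L = len(contig)
            contig = str(Seq(contig).reverse_complement())
            cds_start, cds_end = L - cds_end, L - cds_start
        chrom = f"chr_{gene_id}"
        records.append(GenomeRecord(chrom, contig))
        genes.append(GeneModel(gene_id, chrom, strand, [(cds_start, cds_end)]))
        contexts.append(GeneContext(gene_id=gene_id, seq=seq, stop_start=spec.tail_nt))
        run_len = spec.slippage_run[1] if (planted and spec.slippage_run) else 0
        truth_rows.append(
            {
                "gene_id": gene_id,
                "planted": planted,
                "frame": frame if planted else -1,
                "motif_start": offset if planted else -1,
                "tripeptide": tripeptide,
                "interrupted": interrupted if planted else False,
                "slippage_run_length": run_len,
            }
        )

    truth = pd.DataFrame(truth_rows)
    out = SyntheticGenome(records=records, genes=genes, contexts=contexts, truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, outdir / "genome.fasta")
        write_gff(genes, outdir / "genes.gff3")
        write_context_fasta(contexts, outdir / "contexts.fasta")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return out


# ---------------------------------------------------------------------------
# worked-example fixtures
# ---------------------------------------------------------------------------

#: minimal context with a single +1-frame SKL motif one base into the UTR
SKL_PLUS1_SEQ = "GAATAAGTCTAAACTATAA"

#: coding tail ending in the 3x3-repeat stretch AAATCCCAAA before the stop
REPEAT_3X3_SEQ = "ATGGCAAATCCCAAA" + "TAA" + "GTCGATGTCGAT"

#: 6T slippage run before the stop with a +1-frame AKL motif in the UTR;
#: the documented mutagenesis window for this fixture is the 6-base run
POLYT6_AKL_SEQ = "ATGAAGTTTTTT" + "TAA" + "AGCTAAATTATAACGC"

#: terminal NKF* tripeptide (Phe codon TTC), one base from a stronger Leu
NKF_TTC_SEQ = "ATGAAGAATAAATTC" + "TAA" + "GCAGCAGCA"

#: terminal NKF* with the other Phe codon (TTT)
NKF_TTT_SEQ = "ATGAAGAATAAATTT" + "TAA" + "GCAGCAGCA"


def make_example_fixtures(outdir: str | Path | None = None) -> dict[str, GeneContext]:
    """Small worked-example contexts used throughout the tests and docs.

    With ``outdir`` given, writes them as ``examples.fasta`` (context FASTA).
    The companion C-terminal 12-mer peptides of the pre-duplication IDP2
    genes ship separately as packaged data (see ``load_idp2_peptides``).
    """
    contexts = {
        "skl_plus1": GeneContext("skl_plus1", SKL_PLUS1_SEQ, 3),
        "repeat_3x3": GeneContext("repeat_3x3", REPEAT_3X3_SEQ, 15),
        "polyT6_akl": GeneContext("polyT6_akl", POLYT6_AKL_SEQ, 12),
        "nkf_ttc": GeneContext("nkf_ttc", NKF_TTC_SEQ, 15),
        "nkf_ttt": GeneContext("nkf_ttt", NKF_TTT_SEQ, 15),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_context_fasta(contexts.values(), outdir / "examples.fasta")
    return contexts


def load_idp2_peptides() -> pd.DataFrame:
    """Reference C-terminal 12-mers of pre-duplication yeast IDP2 genes.

    Columns: species, gene_id, inframe_cterm, cryptic_plus1_cterm (empty where
    no cryptic +1-frame peptide exists, as for K. lactis).
    """
    from importlib import resources

    ref = resources.files("crypticpts.data") / "idp2_cterm_peptides.tsv"
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, comment="#", keep_default_na=False)
    return df
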