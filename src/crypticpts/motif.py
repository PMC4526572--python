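"""PTS1 tripeptide motif grammars and context-peptide scoring.

A peroxisomal targeting signal type 1 (PTS1) is a C-terminal tripeptide
immediately followed by the stop codon. A grammar holds one amino-acid set
per position; a tripeptide matches when every residue is in its positional
set. Grammars are built by positional union over training tripeptides, the
same construction used to assemble the genome-search motif from known
peroxisomal proteins.

Three grammars are bundled:

``search``
    (S/A/C/E/I/H/Q)-(K/R/H)-(L/F), the permissive union used for systematic
    3'-UTR scanning.
``canonical``
    (S/A/C)-(K/R/H)-(L/M), the textbook PTS1 consensus.
``union``
    the union of the two, (S/A/C/E/I/H/Q)-(K/R/H)-(L/M/F); the default, since
    both cryptic-motif analyses (e.g. the ARM and CKL termini) fall under it.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

AMINO_ACIDS: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MotifGrammar:
    """Per-position amino-acid sets for the C-terminal tripeptide."""

    pos1: frozenset[str]
    pos2: frozenset[str]
    pos3: frozenset[str]
    requires_stop: bool = True

    def __post_init__(self) -> None:
        for i, s in enumerate(self.positions, start=1):
            if not s:
                raise ValueError(f"position {i} set is empty")
            bad = set(s) - AMINO_ACIDS
            if bad:
                raise ValueError(f"position {i} contains non-amino-acid letters: {sorted(bad)}")

    @property
    def positions(self) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
        return (self.pos1, self.pos2, self.pos3)

    def matches(self, tripeptide: str) -> bool:
        """True iff each residue of a 3-letter peptide is in its positional set."""
        if len(tripeptide) != 3:
            raise ValueError(f"tripeptide must have length 3, got {tripeptide!r}")
        return all(aa in s for aa, s in zip(tripeptide.upper(), self.positions))

    def accepted_tripeptides(self) -> list[str]:
        """All tripeptides the grammar accepts (|pos1|*|pos2|*|pos3| strings)."""
        return [
            "".join(t)
            for t in product(sorted(self.pos1), sorted(self.pos2), sorted(self.pos3))
        ]

    @property
    def cardinality(self) -> int:
        return len(self.pos1) * len(self.pos2) * len(self.pos3)


SEARCH_GRAMMAR = MotifGrammar(frozenset("SACEIHQ"), frozenset("KRH"), frozenset("LF"))
CANONICAL_GRAMMAR = MotifGrammar(frozenset("SAC"), frozenset("KRH"), frozenset("LM"))
UNION_GRAMMAR = MotifGrammar(frozenset("SACEIHQ"), frozenset("KRH"), frozenset("LMF"))
DEFAULT_GRAMMAR = UNION_GRAMMAR

GRAMMAR_MODES: dict[str, MotifGrammar] = {
    "search": SEARCH_GRAMMAR,
    "canonical": CANONICAL_GRAMMAR,
    "union": UNION_GRAMMAR,
}


def get_grammar(mode: str = "union", custom: MotifGrammar | None = None) -> MotifGrammar:
    """Resolve a grammar by mode name (``search``/``canonical``/``union``/``custom``)."""
    if mode == "custom":
        if custom is None:
            raise ValueError("grammar mode 'custom' requires a MotifGrammar instance")
        return custom
    try:
        return GRAMMAR_MODES[mode]
    except KeyError:
        raise ValueError(
            f"unknown grammar mode {mode!r}; expected one of "
            f"{sorted(GRAMMAR_MODES)} or 'custom'"
        ) from None


def build_grammar(training_tripeptides: Iterable[str]) -> MotifGrammar:
    """Positional-union grammar from training tripeptides.

    Deterministic regardless of input order; every training tripeptide matches
    the grammar built from it.
    """
    tris = [t.upper() for t in training_tripeptides]
    if not tris:
        raise ValueError("training set is empty")
    for t in tris:
        if len(t) != 3:
            raise ValueError(f"training tripeptide must have length 3, got {t!r}")
        bad = set(t) - AMINO_ACIDS
        if bad:
            raise ValueError(f"training tripeptide {t!r} contains {sorted(bad)}")
    return MotifGrammar(
        frozenset(t[0] for t in tris),
        frozenset(t[1] for t in tris),
        frozenset(t[2] for t in tris),
    )


def load_training_tripeptides(path: str | Path | None = None) -> list[str]:
    """Training tripeptides from a TSV with a ``tripeptide`` or ``c_terminus`` column.

    With ``path=None`` the bundled placeholder table is used (a synthetic
    stand-in for the unpublished 20-gene training list; its positional unions
    equal the documented search grammar). A ``c_terminus`` column may carry
    longer C-terminal peptides, of which the last three residues are taken.
    """
    if path is None:
        ref = resources.files("crypticpts.data") / "pts1_training_tripeptides.synthetic.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    rows = [r for r in text.splitlines() if r.strip() and not r.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    tris: list[str] = []
    for row in reader:
        pep = (row.get("tripeptide") or row.get("c_terminus") or "").strip()
        if not pep:
            raise ValueError(f"row without tripeptide/c_terminus: {row!r}")
        tris.append(pep[-3:].upper())
    if not tris:
        raise ValueError("training table contains no peptides")
    return tris


@dataclass(frozen=True)
class ContextPeptide:
    """Up to 12 C-terminal residues of an isoform, motif tripeptide last."""

    residues: str
    complete: bool  # True iff the full 12-mer was available


def extract_context_peptide(isoform: str) -> ContextPeptide:
    """Last ``min(12, len)`` residues of an isoform ending in the motif."""
    if len(isoform) < 3:
        raise ValueError(
            f"isoform must carry at least the 3-residue motif, got {isoform!r}"
        )
    residues = isoform[-12:]
    return ContextPeptide(residues=residues, complete=len(residues) == 12)


class PositionalLogOdds:
    """Add-one positional log-odds score over the last three residues.

    Per position the score term is ``log((count + 1) / (n + 20)) - log(1/20)``
    against a uniform background. The values are NOT comparable to any
    external PTS1 predictor's scores; this is a ranking aid only.
    """

    def __init__(self, training_tripeptides: Sequence[str]):
        if not training_tripeptides:
            raise ValueError("training set is empty")
        self.n = len(training_tripeptides)
        self.counts: list[Counter[str]] = [
            Counter(t[i] for t in training_tripeptides) for i in range(3)
        ]

    def __call__(self, tripeptide: str) -> float:
        if len(tripeptide) != 3:
            raise ValueError("tripeptide must have length 3")
        score = 0.0
        for i, aa in enumerate(tripeptide.upper()):
            p = (self.counts[i][aa] + 1) / (self.n + 20)
            score += math.log(p) - math.log(1 / 20)
        return score


def _indicator(peptide: ContextPeptide, grammar: MotifGrammar) -> float:
    return 1.0 if grammar.matches(peptide.residues[-3:]) else 0.0


def _logodds(peptide: ContextPeptide, training: Sequence[str]) -> float:
    return PositionalLogOdds(training)(peptide.residues[-3:])


SCORERS: Mapping[str, Callable[..., float]] = {"indicator": _indicator, "logodds": _logodds}


def score_context(
    peptide: ContextPeptide,
    scorer: str = "indicator",
    *,
    grammar: MotifGrammar = DEFAULT_GRAMMAR,
    training: Sequence[str] | None = None,
) -> float:
    """Score a context peptide with a registered scorer.

    ``indicator`` (default) returns 1.0/0.0 grammar membership of the terminal
    tripeptide; ``logodds`` needs ``training`` tripeptides. External predictors
    can be plugged in by registering a callable in :data:`SCORERS`.
    """
    try:
        fn = SCORERS[scorer]
    except KeyError:
        raise ValueError(f"unknown scorer {scorer!r}; registered: {sorted(SCORERS)}") from None
    if scorer == "indicator":
        return fn(peptide, grammar)
    if scorer == "logodds":
        if training is None:
            training = load_training_tripeptides()
        return fn(peptide, training)
    return fn(peptide)
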