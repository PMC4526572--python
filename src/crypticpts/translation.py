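"""Codon translation with stop-codon read-through.

Standard nuclear genetic code only. Ribosomal read-through of a stop codon is
modelled by the near-cognate substitutions observed in yeast: UAA/UAG are
decoded as glutamine and UGA as arginine. Codons containing anything outside
A/C/G/T (e.g. N) translate to ``X`` and can never match a motif or a stop.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_STANDARD = unambiguous_dna_by_id[1]

#: codon -> amino acid for the 61 sense codons; stop codons map to "*".
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD.stop_codons})

#: the three standard stop codons (TAA, TAG, TGA).
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: stop codon -> amino acid inserted on ribosomal read-through.
READTHROUGH_TABLE: dict[str, str] = {"TAA": "Q", "TAG": "Q", "TGA": "R"}

SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.forward_table))


def codon_aa(codon: str) -> str:
    """Amino acid for one triplet; ``*`` for stops, ``X`` for ambiguous."""
    return CODON_TO_AA.get(codon, "X")


def translate(nt: str, frame: int = 0) -> str:
    """Translate ``nt`` from offset ``frame`` (0/1/2).

    Stop codons are rendered as ``*`` and translation continues past them;
    a trailing partial codon is dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame!r}")
    nt = nt.upper().replace("U", "T")
    return "".join(codon_aa(nt[i : i + 3]) for i in range(frame, len(nt) - 2, 3))


def readthrough_translate(nt: str, frame: int = 0, max_readthrough: int = 1) -> str:
    """Translate, bypassing up to ``max_readthrough`` stop codons.

    The first ``max_readthrough`` stop codons encountered are replaced per
    :data:`READTHROUGH_TABLE` and translation continues; the next stop
    terminates translation and is not included in the output.
    """
    if max_readthrough < 0:
        raise ValueError("max_readthrough must be >= 0")
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame!r}")
    nt = nt.upper().replace("U", "T")
    out: list[str] = []
    budget = max_readthrough
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if codon in STOP_CODONS:
            if budget > 0:
                out.append(READTHROUGH_TABLE[codon])
                budget -= 1
            else:
                break
        else:
            out.append(codon_aa(codon))
    return "".join(out)


def translate_to_stop(nt: str, frame: int = 0) -> tuple[str, bool]:
    """Translate until the first stop codon.

    Returns ``(peptide, terminated)`` where ``terminated`` is True iff a stop
    codon was actually reached before the sequence ran out.
    """
    nt = nt.upper().replace("U", "T")
    out: list[str] = []
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if codon in STOP_CODONS:
            return "".join(out), True
        out.append(codon_aa(codon))
    return "".join(out), False
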