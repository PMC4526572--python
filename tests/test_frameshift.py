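import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crypticpts.io_formats import GeneContext
from crypticpts.frameshift import (
    deletion_classes,
    enumerate_deletions,
    find_slippage_sites,
    imprinting_map,
    substitutions_to_motif,
)
from crypticpts.motif import UNION_GRAMMAR
from crypticpts.scanner import scan_context
from crypticpts.synthetic import PlantSpec, generate
from crypticpts.translation import codon_aa, translate_to_stop

from helpers import brute_force_deletion_seqs, count_maximal_runs


def test_repeat_stretch_collapses_to_four_classes(examples):
    events = enumerate_deletions(examples["repeat_3x3"], upstream_window=10)
    assert len(events) == 10
    classes = deletion_classes(events)
    assert len(classes) == 4  # runs AAA / T / CCC / AAA


def test_homopolymer_window_is_one_class():
    ctx = GeneContext("t6", "GCAGCA" + "TTTTTT" + "TAA" + "GCTGCTGCT", 12)
    events = enumerate_deletions(ctx, upstream_window=6)
    assert len(events) == 6
    assert len({e.equivalence_class_id for e in events}) == 1
    assert len({e.resulting_seq for e in events}) == 1


def test_deletion_exposes_plus1_motif_in_frame(examples):
    # deleting any base of the first codon of the SKL example puts the +1
    # SKL motif into the coding frame
    events = enumerate_deletions(examples["skl_plus1"], upstream_window=3)
    assert len(events) == 3
    assert len(deletion_classes(events)) == 2  # G vs the AA run
    for e in events:
        assert e.creates_inframe_motif
        assert e.resulting_isoform_tail.endswith("SKL")


def test_deletion_window_truncated_with_warning(examples, caplog):
    events = enumerate_deletions(examples["skl_plus1"], upstream_window=50)
    assert len(events) == 3  # only 3 coding bases exist upstream of the stop
    with pytest.raises(ValueError):
        enumerate_deletions(examples["skl_plus1"], upstream_window=0)


@settings(derandomize=True, max_examples=150)
@given(window=st.text(alphabet="ACGT", min_size=10, max_size=50))
def test_deletion_class_closed_form_matches_brute_force(window):
    """Distinct single-deletion outcomes = number of maximal runs in the window."""
    pad = "G" if window[0] != "G" else "C"
    prefix = pad * (3 - (len(window) % 3) or 3)  # codon-align, break edge runs
    seq = prefix + window + "TAA" + "GCTGCT"
    ctx = GeneContext("w", seq, len(prefix) + len(window))
    events = enumerate_deletions(ctx, upstream_window=len(window))
    assert len(events) == len(window)
    n_classes = len({e.equivalence_class_id for e in events})
    assert n_classes == count_maximal_runs(window)
    brute = brute_force_deletion_seqs(seq, range(len(prefix), len(prefix) + len(window)))
    assert n_classes == len(brute)
    assert {e.resulting_seq for e in events} == brute


def test_imprinting_links_the_T_run_to_the_akl_hit(examples):
    records = imprinting_map(examples["polyT6_akl"], upstream_window=6)
    assert len(records) == 1
    rec = records[0]
    assert rec["tripeptide"] == "AKL" and not rec["hit_interrupted"]
    assert rec["linked_classes"] == ["del_T6"]
    assert rec["premature_stop_classes"] == []
    assert rec["n_deletion_classes"] == 1


def test_imprinting_empty_without_plus1_hits():
    ctx = GeneContext("none", "AAGAAG" + "TAA" + "AAAAAAAAAAAA", 6)
    assert imprinting_map(ctx) == []


def test_imprinting_flags_interrupted_hit_classes_as_premature():
    # +1 SKL hit behind an interrupting +1-frame TAA: deletions reach the
    # interrupting stop first, so no class links to the motif
    ctx = GeneContext("i", "GAAGAA" + "TAA" + "ATAATCTAAACTATAAC", 6)
    records = imprinting_map(ctx, upstream_window=6)
    assert len(records) == 1
    rec = records[0]
    assert rec["hit_interrupted"]
    assert rec["linked_classes"] == []
    assert len(rec["premature_stop_classes"]) == rec["n_deletion_classes"] > 0


def test_frame_algebra_deletions_put_plus1_motifs_in_frame():
    """Any upstream deletion maps a clean +1 hit into frame unless it
    creates a premature in-frame stop."""
    spec = PlantSpec(
        n_genes=30, fraction_planted=1.0, fraction_interrupted=0.0,
        frame_distribution=(0.0, 1.0, 0.0), seed=13,
    )
    data = generate(spec)
    checked = 0
    for ctx, row in zip(data.contexts, data.truth.itertuples()):
        (hit,) = scan_context(ctx, UNION_GRAMMAR)
        p = ctx.stop_start + 3 + hit.motif_start
        expected_len = (p + 8) // 3  # residues up to the motif stop, post-deletion
        for e in enumerate_deletions(ctx, upstream_window=ctx.stop_start):
            tail, terminated = translate_to_stop(e.resulting_seq, 0)
            assert terminated
            if len(tail) == expected_len:
                assert tail.endswith(hit.tripeptide)
                assert e.creates_inframe_motif
            else:  # the deletion created a stop before the motif
                assert len(tail) < expected_len
            checked += 1
    assert checked > 100


@pytest.mark.parametrize(
    "fixture, phe_codon, leu_codons",
    [
        ("nkf_ttc", "TTC", {"TTA", "TTG", "CTC"}),
        ("nkf_ttt", "TTT", {"TTA", "TTG", "CTT"}),
    ],
)
def test_phe_to_leu_substitutions(examples, fixture, phe_codon, leu_codons):
    ctx = examples[fixture]
    events = substitutions_to_motif(ctx, UNION_GRAMMAR)
    assert len(events) == 3
    s = ctx.stop_start
    new_codons = set()
    for e in events:
        assert s - 3 <= e.position < s  # confined to the terminal codon
        codon = list(ctx.seq[s - 3 : s])
        codon[e.position - (s - 3)] = e.alt_base
        new_codons.add("".join(codon))
        assert e.resulting_isoform_tail.endswith("L")
    assert new_codons == leu_codons


def test_substitution_oracle_over_nine_neighbors(examples):
    """Independent enumeration of all 9 single-base codon neighbours."""
    for fixture in ("nkf_ttc", "nkf_ttt"):
        ctx = examples[fixture]
        s = ctx.stop_start
        codon = ctx.seq[s - 3 : s]
        expected = set()
        for i in range(3):
            for b in "ACGT":
                if b == codon[i]:
                    continue
                new = codon[:i] + b + codon[i + 1 :]
                aa = codon_aa(new)
                if aa != codon_aa(codon) and aa in UNION_GRAMMAR.pos3:
                    expected.add((s - 3 + i, b))
        got = {(e.position, e.alt_base) for e in substitutions_to_motif(ctx)}
        assert got == expected and len(got) == 3


def test_substitutions_empty_when_tripeptide_matches():
    # terminal SKL already matches: nothing to upgrade
    ctx = GeneContext("skl", "ATGAAGAGTAAATTA" + "TAA" + "GCAGCAGCA", 15)
    assert substitutions_to_motif(ctx, UNION_GRAMMAR) == []


def test_substitution_position_argument(examples):
    # targeting position 1 of N-K-F: Asn codon AAT -> Ser (AGT) or His (CAT)
    events = substitutions_to_motif(examples["nkf_ttc"], UNION_GRAMMAR, position=0)
    residues = {codon_aa(e.resulting_seq[6:9]) for e in events}
    assert residues and residues <= UNION_GRAMMAR.pos1


def test_slippage_sites_examples(examples):
    sites = find_slippage_sites(examples["repeat_3x3"], min_run=3)
    assert [(s.base, s.run_length) for s in sites] == [("A", 3), ("C", 3), ("A", 3)]
    assert all(s.end <= examples["repeat_3x3"].stop_start for s in sites)
    t6 = find_slippage_sites(examples["polyT6_akl"], min_run=3)
    assert [(s.base, s.run_length, s.distance_to_stop) for s in t6] == [("T", 6, 0)]


def test_slippage_no_sites_in_alternating_sequence():
    ctx = GeneContext("ac", "ACACAC" + "TAA" + "GCTGCT", 6)
    assert find_slippage_sites(ctx, min_run=3) == []
    with pytest.raises(ValueError):
        find_slippage_sites(ctx, min_run=1)


def test_slippage_search_window_limits_region(examples):
    # restricting to the last 4 bases of the repeat stretch sees only one A run
    sites = find_slippage_sites(examples["repeat_3x3"], min_run=3, search_window=4)
    assert [(s.base, s.run_length) for s in sites] == [("A", 3)]
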