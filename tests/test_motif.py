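import math

import pytest
from hypothesis import given, settings, strategies as st

from crypticpts.motif import (
    AMINO_ACIDS,
    CANONICAL_GRAMMAR,
    MotifGrammar,
    PositionalLogOdds,
    SEARCH_GRAMMAR,
    UNION_GRAMMAR,
    build_grammar,
    extract_context_peptide,
    get_grammar,
    load_training_tripeptides,
    score_context,
)

aa = st.sampled_from(sorted(AMINO_ACIDS))
tripeptides = st.lists(
    st.text(alphabet=sorted(AMINO_ACIDS), min_size=3, max_size=3),
    min_size=1, max_size=15,
)


def test_build_grammar_positional_union():
    g = build_grammar(["SKL", "AKL", "CKF", "EHL", "IRL", "HKL", "QKL"])
    assert g.pos1 == frozenset("SACEIHQ")
    assert g.pos2 == frozenset("KHR")
    assert g.pos3 == frozenset("LF")


def test_build_grammar_singleton_and_errors():
    g = build_grammar(["SKL"])
    assert (g.pos1, g.pos2, g.pos3) == (frozenset("S"), frozenset("K"), frozenset("L"))
    with pytest.raises(ValueError):
        build_grammar([])
    with pytest.raises(ValueError):
        build_grammar(["SK"])
    with pytest.raises(ValueError):
        build_grammar(["SKB"])


@settings(derandomize=True, max_examples=100)
@given(tris=tripeptides)
def test_build_grammar_order_invariant_idempotent_and_covers_training(tris):
    g = build_grammar(tris)
    assert g == build_grammar(sorted(tris)) == build_grammar(tris[::-1])
    assert all(g.matches(t) for t in tris)
    # rebuilding from everything the grammar accepts is a fixed point
    assert build_grammar(g.accepted_tripeptides()) == g


@settings(derandomize=True, max_examples=50)
@given(tris=tripeptides)
def test_grammar_cardinality_matches_brute_force_enumeration(tris):
    g = build_grammar(tris)
    accepted = [
        a + b + c
        for a in sorted(AMINO_ACIDS)
        for b in sorted(AMINO_ACIDS)
        for c in sorted(AMINO_ACIDS)
        if g.matches(a + b + c)
    ]
    assert len(accepted) == g.cardinality == len(g.pos1) * len(g.pos2) * len(g.pos3)
    assert accepted == sorted(g.accepted_tripeptides())


@pytest.mark.parametrize(
    "tri, grammar, expected",
    [
        ("CKL", UNION_GRAMMAR, True),   # canonical peroxisomal IDP3 terminus
        ("AAL", UNION_GRAMMAR, False),  # Ala at position 2 is never accepted
        ("ARM", SEARCH_GRAMMAR, False),  # Met absent from the search grammar
        ("ARM", UNION_GRAMMAR, True),
        ("SKL", CANONICAL_GRAMMAR, True),
        ("NKF", UNION_GRAMMAR, False),
    ],
)
def test_matches(tri, grammar, expected):
    assert grammar.matches(tri) is expected


def test_matches_rejects_bad_length():
    with pytest.raises(ValueError):
        UNION_GRAMMAR.matches("SKLL")


def test_get_grammar_modes():
    assert get_grammar("search") is SEARCH_GRAMMAR
    assert get_grammar("union") is UNION_GRAMMAR
    custom = MotifGrammar(frozenset("S"), frozenset("K"), frozenset("L"))
    assert get_grammar("custom", custom) is custom
    with pytest.raises(ValueError):
        get_grammar("bogus")
    with pytest.raises(ValueError):
        get_grammar("custom")


def test_bundled_training_table_reproduces_search_grammar():
    tris = load_training_tripeptides()
    assert len(tris) == 20
    assert build_grammar(tris) == SEARCH_GRAMMAR


def test_extract_context_peptide():
    full = extract_context_peptide("MRLFVNKKKQAKL")
    assert full.residues == "RLFVNKKKQAKL" and full.complete
    short = extract_context_peptide("MKAKL")
    assert short.residues == "MKAKL" and not short.complete
    with pytest.raises(ValueError):
        extract_context_peptide("KL")


def test_indicator_scorer_and_unknown_scorer():
    hit = extract_context_peptide("RLFVNKKKQAKL")
    miss = extract_context_peptide("KRLDSEFKSSFN")
    assert score_context(hit, "indicator", grammar=UNION_GRAMMAR) == 1.0
    assert score_context(miss, "indicator", grammar=UNION_GRAMMAR) == 0.0
    with pytest.raises(ValueError):
        score_context(hit, "nope")


def test_logodds_prefers_training_residues():
    training = ["SKL", "AKL", "SKF"]
    scorer = PositionalLogOdds(training)
    for t in training:
        assert scorer(t) > scorer("WWW")  # residues absent from training
    # via the registry, on a context peptide
    s_hit = score_context(extract_context_peptide("MMMSKL"), "logodds", training=training)
    s_miss = score_context(extract_context_peptide("MMMWWW"), "logodds", training=training)
    assert s_hit > s_miss
    assert math.isfinite(s_hit) and math.isfinite(s_miss)
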