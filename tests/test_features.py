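"""Tokenizer, negation cues/scopes, scope-position features, neutral rules,
connectors, modality markers and p-value extraction."""

from __future__ import annotations

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snprex.corpus import Label, Source, Span
from snprex.features import (
    DEFAULT_CONNECTOR_LEXICON,
    DEFAULT_NEUTRAL_RULES,
    NeutralRule,
    PositionalFeatures,
    blind_entities,
    classify_event_position,
    detect_clause_connectors,
    detect_modality_markers,
    detect_negation,
    detect_neutral,
    extract_pvalues,
    positional_features,
    tokenize,
)

from conftest import make_candidate, make_sentence


class TestTokenize:
    def test_empty(self):
        assert tokenize("") == []

    def test_two_tokens(self):
        spans = tokenize("rs1051730 variant")
        assert len(spans) == 2
        assert spans[0] == Span(0, 9)

    @settings(derandomize=True, max_examples=100)
    @given(st.text(max_size=60))
    def test_surfaces_reconstruct_input_without_whitespace(self, text):
        surfaces = "".join(text[s:e] for s, e in tokenize(text))
        assert surfaces == re.sub(r"\s+", "", text)

    @settings(derandomize=True, max_examples=50)
    @given(st.text(max_size=60))
    def test_spans_ordered_and_disjoint(self, text):
        spans = tokenize(text)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
            assert s1 < e1


class TestNegation:
    def test_no_associations_example(self):
        sent = make_sentence(
            "There were no associations between APOE polymorphisms and serum "
            "HDL-C, APO-CIII, and triglycerides",
            snps=("APOE polymorphisms",),
            phenotypes=("serum HDL-C",),
        )
        events = detect_negation(sent, mode=Source.HEURISTIC)
        assert len(events) == 1
        assert events[0].cue_text == "no"
        # both mentions fall inside the heuristic scope
        for ent in sent.entities:
            assert ent.span.intersects(events[0].scope_span)

    def test_no_cue_token_yields_empty(self):
        sent = make_sentence("rs1 was associated with obesity", snps=("rs1",),
                             phenotypes=("obesity",))
        assert detect_negation(sent, mode=Source.HEURISTIC) == []

    def test_cue_must_be_whole_token(self):
        sent = make_sentence("the notable knot was nothing", snps=(), phenotypes=())
        assert detect_negation(sent, mode=Source.HEURISTIC) == []

    def test_scope_ends_before_clause_connector(self):
        sent = make_sentence("X but not Y here, although Z follows")
        events = detect_negation(sent, mode=Source.HEURISTIC)
        (ev,) = events
        assert ev.cue_text == "not"
        assert sent.text[ev.scope_span.start : ev.scope_span.end].strip(" ,") == "Y here"
        assert ev.scope_span.end <= sent.text.index("although")

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_heuristic_scope_never_crosses_connector(self, seed):
        import random

        rng = random.Random(seed)
        words = ["alpha", "no", "beta", "because", "gamma", "not", "delta", "although"]
        text = " ".join(rng.choice(words) for _ in range(rng.randint(1, 12)))
        sent = make_sentence(text)
        connectors = detect_clause_connectors(sent)
        for ev in detect_negation(sent, mode=Source.HEURISTIC):
            for conn in connectors:
                if conn.span.start >= ev.scope_span.start:
                    assert ev.scope_span.end <= conn.span.start

    def test_gold_mode_requires_annotations(self):
        sent = make_sentence("no association", gold_annotated=False)
        with pytest.raises(ValueError, match="gold"):
            detect_negation(sent, mode=Source.GOLD)

    def test_gold_mode_returns_annotations_unchanged(self, synthetic_corpus):
        corpus, _ = synthetic_corpus
        _, sent = next(iter(corpus.sentences()))
        assert detect_negation(sent, mode=Source.GOLD) == sent.negations


class TestPositionalFeatures:
    def test_rs1051730_example_one_left_one_inside(self):
        sent = make_sentence(
            "Moreover, the rs1051730 variant may not merely operate as a marker "
            "for dependence or heaviness of smoking",
            snps=("rs1051730",),
            phenotypes=("dependence or heaviness of smoking",),
        )
        cand = make_candidate(sent)
        events = detect_negation(sent, mode=Source.HEURISTIC)
        feats = positional_features(cand, events, is_neutral=False)
        assert feats.one_left_one_inside
        assert not feats.both_inside
        assert not feats.one_right_one_inside

    def test_no_events_all_scope_features_false(self):
        sent = make_sentence("rs1 raises obesity", snps=("rs1",), phenotypes=("obesity",))
        feats = positional_features(make_candidate(sent), [], is_neutral=False)
        assert feats.scope_values() == (False,) * 6

    def test_both_inside_scope(self):
        sent = make_sentence("no link of rs1 with obesity", snps=("rs1",),
                             phenotypes=("obesity",))
        events = detect_negation(sent, mode=Source.HEURISTIC)
        feats = positional_features(make_candidate(sent), events, is_neutral=False)
        assert feats.scope_values() == (True, False, False, False, False, False)

    @settings(derandomize=True, max_examples=200)
    @given(
        snp=st.tuples(st.integers(0, 40), st.integers(1, 10)),
        phen=st.tuples(st.integers(0, 40), st.integers(1, 10)),
        scope=st.tuples(st.integers(0, 40), st.integers(1, 10)),
    )
    def test_six_positions_partition_is_exhaustive_and_exclusive(self, snp, phen, scope):
        """For any spans exactly one of the six possibilities holds."""
        s = Span(snp[0], snp[0] + snp[1])
        p = Span(phen[0], phen[0] + phen[1])
        sc = Span(scope[0], scope[0] + scope[1])
        kind = classify_event_position(s, p, sc)
        assert kind in PositionalFeatures._SCOPE_FIELDS
        # cross-check against an independent case analysis
        def pos(span):
            if span.start < sc.end and span.end > sc.start:
                return "in"
            return "L" if span.start < sc.start else "R"
        combo = (pos(s), pos(p))
        expected = {
            ("in", "in"): "both_inside",
            ("L", "L"): "both_left",
            ("R", "R"): "both_right",
            ("L", "in"): "one_left_one_inside",
            ("in", "L"): "one_left_one_inside",
            ("R", "in"): "one_right_one_inside",
            ("in", "R"): "one_right_one_inside",
            ("L", "R"): "one_left_one_right",
            ("R", "L"): "one_left_one_right",
        }[combo]
        assert kind == expected


class TestNeutralRules:
    def test_study_setup_sentence_matches(self):
        sent = make_sentence(
            "We genotyped rs123 in patients with asthma",
            snps=("rs123",), phenotypes=("asthma",),
        )
        flag, rule_id = detect_neutral(make_candidate(sent), sent)
        assert flag
        assert rule_id == "genotyped"

    def test_empty_rule_set_never_matches(self):
        sent = make_sentence("We genotyped rs123 in patients with asthma",
                             snps=("rs123",), phenotypes=("asthma",))
        assert detect_neutral(make_candidate(sent), sent, rules=()) == (False, None)

    def test_assertive_association_does_not_match(self):
        sent = make_sentence(
            "rs123 was significantly associated with asthma",
            snps=("rs123",), phenotypes=("asthma",),
        )
        assert detect_neutral(make_candidate(sent), sent) == (False, None)

    def test_invariant_to_entity_surfaces(self):
        results = []
        for snp, phen in (("rs1", "asthma"), ("rs999999", "late-onset diabetes")):
            sent = make_sentence(
                f"We genotyped {snp} in patients with {phen}",
                snps=(snp,), phenotypes=(phen,),
            )
            results.append(detect_neutral(make_candidate(sent), sent))
        assert results[0] == results[1]

    def test_blinding_replaces_surfaces(self):
        sent = make_sentence("rs1 causes asthma", snps=("rs1",), phenotypes=("asthma",))
        assert blind_entities(sent) == "[SNP] causes [PHENOTYPE]"

    def test_entity_surface_matching_rule_word_does_not_fire(self):
        """A phenotype surface containing a rule word is blinded away."""
        sent = make_sentence(
            "rs1 was associated with measured blood pressure",
            snps=("rs1",), phenotypes=("measured blood pressure",),
        )
        assert detect_neutral(make_candidate(sent), sent) == (False, None)

    def test_rule_patterns_compile(self):
        for rule in DEFAULT_NEUTRAL_RULES:
            rule.compiled()


class TestClauseConnectors:
    def test_although_is_concessive(self):
        found = detect_clause_connectors("although X was small, Y held")
        assert len(found) == 1
        assert found[0].is_concessive
        assert found[0].text.lower() == "although"

    def test_plain_coordination_is_not_a_connector(self):
        assert detect_clause_connectors("X and Y") == []

    def test_multiword_phrase_wins_over_substring(self):
        found = detect_clause_connectors("even though it rained")
        assert len(found) == 1
        assert found[0].text.lower() == "even though"

    def test_because_not_concessive(self):
        (conn,) = detect_clause_connectors("X because Y")
        assert not conn.is_concessive

    def test_counts_match_generator_bookkeeping(self, synthetic_corpus):
        corpus, ledger = synthetic_corpus
        for _doc, sent in corpus.sentences():
            from snprex.corpus import enumerate_candidates

            for cand in enumerate_candidates(sent):
                entry = ledger.entries[cand.candidate_id]
                found = detect_clause_connectors(sent)
                assert [c.text for c in found] == entry.connector_texts
                assert any(c.is_concessive for c in found) == entry.has_concessive


class TestModalityMarkers:
    def test_may_detected(self):
        sent = make_sentence("the variant may not merely operate as a marker")
        markers = detect_modality_markers(sent, mode=Source.HEURISTIC)
        assert [m.text for m in markers] == ["may"]

    def test_assertive_sentence_empty(self):
        sent = make_sentence("the variant raises risk")
        assert detect_modality_markers(sent, mode=Source.HEURISTIC) == []

    def test_empty_lexicon_empty_result(self):
        sent = make_sentence("this may or may not happen")
        assert detect_modality_markers(sent, lexicon=(), mode=Source.HEURISTIC) == []

    def test_gold_mode_requires_annotations(self):
        sent = make_sentence("may happen", gold_annotated=False)
        with pytest.raises(ValueError):
            detect_modality_markers(sent, mode=Source.GOLD)


class TestPValues:
    def test_no_pvalue(self):
        assert extract_pvalues("no p-value here") == []

    @pytest.mark.parametrize(
        "text, comparator, value",
        [
            ("P < 0.001", "<", 0.001),
            ("p = 3.2 × 10−5", "=", 3.2e-5),
            ("p=0.05", "=", 0.05),
            ("P ≤ 0.01", "<=", 0.01),
            ("p > 0.05", ">", 0.05),
            ("p-value = 0.032", "=", 0.032),
            ("P values < 0.05", "<", 0.05),
            ("p = 1.5e-4", "=", 1.5e-4),
            ("p < 5 x 10(-8)", "<", 5e-8),
        ],
    )
    def test_patterns_parse(self, text, comparator, value):
        mentions = extract_pvalues(f"associated with obesity ({text})")
        assert len(mentions) == 1
        assert mentions[0].comparator == comparator
        assert mentions[0].value == pytest.approx(value)

    def test_span_covers_the_mention(self):
        text = "risk rose (P < 0.001) overall"
        (m,) = extract_pvalues(text)
        assert text[m.span.start : m.span.end] == "P < 0.001"
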