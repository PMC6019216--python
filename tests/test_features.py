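"""The seven feature families and vector assembly."""

import pytest

from metaknow.corpus_io import Span
from metaknow.features import (
    GROUPS,
    FeatureConfig,
    assemble,
    constituency_features,
    dependency_features,
    lexical_features,
    mk_extra_features,
    participant_features,
    parse_tree_features,
    sentence_features,
    structural_features,
    vectors_to_frame,
)
from metaknow.lexicon import load_lexicon, match_clues
from metaknow.linguistic import LinguisticLayer, Token
from metaknow.synthetic import _make_layer


def layer_from(*pairs):
    tokens, cursor = [], 0
    for i, (w, p) in enumerate(pairs):
        tokens.append(Token(i, Span(cursor, cursor + len(w)), w, p))
        cursor += len(w) + 1
    return LinguisticLayer(tokens)


class TestSentenceFeatures:
    def test_token_and_char_counts(self):
        layer = layer_from(("IL-17", "NN"), ("is", "VBZ"), ("a", "DT"),
                           ("critical", "JJ"), ("factor", "NN"), (".", "."))
        out = sentence_features(layer)
        assert out["SE1"] == 6
        assert out["SE2"] == len("IL-17 is a critical factor .")
        assert out["SE3"] == pytest.approx((5 + 2 + 1 + 8 + 6 + 1) / 6)

    def test_noun_verb_ratio(self):
        layer = layer_from(("cells", "NNS"), ("bind", "VBP"), ("drugs", "NNS"))
        assert sentence_features(layer)["SE5"] == 2.0

    def test_zero_denominator_sentinel(self):
        layer = layer_from(("green", "JJ"), ("ideas", "NNS"))
        out = sentence_features(layer)
        assert out["SE5"] == -1  # no verbs
        assert out["SE7"] == -1  # no adverbs
        assert out["SE6"] == 1.0


class TestStructuralFeatures:
    def test_nested_event(self, layered_doc):
        assoc = layered_doc.association_map()["E2"]
        out = structural_features(assoc, layered_doc)
        assert out["ST1"] is True  # theme is an event
        assert out["ST6"] == 1 and out["ST7"] == 1
        assert out["ST5"] is True

    def test_inner_event_is_participant_elsewhere(self, layered_doc):
        out = structural_features(layered_doc.association_map()["E1"], layered_doc)
        assert out["ST3"] is True
        assert out["ST5"] is True

    def test_relation_static_values(self, layered_doc):
        out = structural_features(layered_doc.association_map()["R1"], layered_doc)
        assert out["ST1"] is False and out["ST3"] is False
        assert out["ST6"] == 1 and out["ST7"] == 1
        assert out["ST2"] == 1  # second sentence


class TestParticipantFeatures:
    def test_event_valued_theme(self, layered_doc):
        out = participant_features(layered_doc.association_map()["E2"], layered_doc)
        assert out["PA3"] is True   # theme is the inner event
        assert out["PA4"] is False  # cause is an entity

    def test_entity_participants(self, layered_doc):
        out = participant_features(layered_doc.association_map()["E1"], layered_doc)
        assert out["PA3"] is False and out["PA4"] is False
        assert out["PA1"] == "NN"  # NF-kappaB head token

    def test_missing_cause_absence_default(self, layered_doc):
        out = participant_features(layered_doc.association_map()["E1"], layered_doc)
        assert out["PA2"] == "NONE"


class TestLexicalFeatures:
    def test_no_clue_defaults(self, layered_doc, small_lexicon):
        out = lexical_features(layered_doc.association_map()["E2"], layered_doc,
                               small_lexicon)
        assert out["L1"] == -1 and out["L2"] is False and out["L16"] == 0
        assert out["L3"] == "NONE"

    def test_clue_present(self, layered_doc, small_lexicon):
        lex = load_lexicon("dependent\tKnowledgeType\tAnalysis\tAnalysis\n")
        assoc = layered_doc.association_map()["E1"]  # trigger "activation"
        out = lexical_features(assoc, layered_doc, lex)
        assert out["L2"] is True and out["L16"] == 1
        assert out["L3"] == "dependent"
        assert out["L1"] == 4  # tokens between "activation" (1) and "dependent" (5)
        assert out["L5"] == 4  # clue after trigger: positive signed offset
        assert out["L13"] is True  # Analysis context flag

    def test_trigger_contains_cue(self, layered_doc):
        lex = load_lexicon("dependent\tKnowledgeType\tAnalysis\n")
        assoc = layered_doc.association_map()["E2"]  # trigger IS "dependent"
        out = lexical_features(assoc, layered_doc, lex)
        assert out["L7"] is True and out["L1"] == 0

    def test_indicator_block_covers_lexicon(self, layered_doc, small_lexicon):
        out = lexical_features(layered_doc.association_map()["E2"], layered_doc,
                               small_lexicon)
        ln_keys = [k for k in out if k.startswith("LN[")]
        assert len(ln_keys) == len(small_lexicon.indicator_keys())


class TestTreeAndGraphFeatures:
    def _nk_sentence_doc(self, tiny_corpus):
        """First generated association whose sentence carries a clue prefix."""
        from metaknow.lexicon import default_lexicon

        lex = default_lexicon()
        for doc in tiny_corpus:
            for assoc in doc.associations:
                layer = doc.linguistic[assoc.sentence_index]
                matches = match_clues(layer.tokens, lex)
                if matches:
                    return doc, assoc, matches
        raise AssertionError("no clue-bearing sentence generated")

    def test_constituency_clue_commands_trigger(self, tiny_corpus):
        doc, assoc, matches = self._nk_sentence_doc(tiny_corpus)
        out = constituency_features(assoc, doc, matches)
        assert out["C1"] is True  # prefix clue s-commands everything

    def test_constituency_no_clues_all_false(self, layered_doc, small_lexicon):
        assoc = layered_doc.association_map()["E1"]
        out = constituency_features(assoc, layered_doc, [])
        assert not any(out.values())

    def test_dependency_path_buckets(self, tiny_corpus):
        doc, assoc, matches = self._nk_sentence_doc(tiny_corpus)
        out = dependency_features(assoc, doc, matches)
        assert any(out.values())  # clue within three hops of trigger/participant

    def test_dependency_no_clues_all_false(self, layered_doc):
        out = dependency_features(layered_doc.association_map()["E1"], layered_doc, [])
        assert not any(out.values())

    def test_parse_tree_distances(self, layered_doc):
        assoc = layered_doc.association_map()["E1"]  # theme NF-kappaB, no cause
        out = parse_tree_features(assoc, layered_doc)
        assert out["PT1"] > 0 and out["PT3"] >= 1
        assert out["PT2"] == -1 and out["PT4"] == -1  # no cause


class TestMKExtra:
    def test_binarized_uncertainty(self, layered_doc):
        out = mk_extra_features(layered_doc.association_map()["E2"])
        assert out == {"MK_source": "Current", "MK_type": "Observation",
                       "MK_uncertainty": "Certain"}

    def test_unannotated_association(self, layered_doc):
        out = mk_extra_features(layered_doc.association_map()["E1"])
        assert out["MK_type"] == "NONE"


class TestAssemble:
    def test_default_kt_config_excludes_participants(self, layered_doc, small_lexicon):
        vec = assemble(layered_doc.association_map()["E2"], layered_doc,
                       small_lexicon, FeatureConfig.knowledge_type_default())
        assert not any(k.startswith("PA") for k in vec.features)
        assert "SE1" in vec.features and "C1" in vec.features

    def test_hyperdimension_config_appends_mk_extra(self, layered_doc, small_lexicon):
        vec = assemble(layered_doc.association_map()["E2"], layered_doc,
                       small_lexicon, FeatureConfig.hyperdimension())
        assert "MK_source" in vec.features

    def test_only_lexical(self, layered_doc, small_lexicon):
        vec = assemble(layered_doc.association_map()["E2"], layered_doc,
                       small_lexicon, FeatureConfig.only("lexical"))
        assert all(k.startswith(("L", "LN[")) for k in vec.features)

    @pytest.mark.parametrize("group", [g for g in GROUPS if g != "mk_extra"])
    def test_ablation_disjoint_union(self, layered_doc, small_lexicon, group):
        assoc = layered_doc.association_map()["E2"]
        full = assemble(assoc, layered_doc, small_lexicon, FeatureConfig.all_features())
        without = assemble(assoc, layered_doc, small_lexicon, FeatureConfig.all_except(group))
        only = assemble(assoc, layered_doc, small_lexicon, FeatureConfig.only(group))
        assert set(without.features) & set(only.features) == set()
        assert set(without.features) | set(only.features) == set(full.features)

    def test_deterministic_serialization(self, layered_doc, small_lexicon):
        assoc = layered_doc.association_map()["E2"]
        a = assemble(assoc, layered_doc, small_lexicon)
        b = assemble(assoc, layered_doc, small_lexicon)
        assert a.serialize() == b.serialize()

    def test_missing_layer_named_in_error(self, nested_event_doc, small_lexicon):
        assoc = nested_event_doc.association_map()["E2"]
        with pytest.raises(ValueError, match="linguistic layer missing"):
            assemble(assoc, nested_event_doc, small_lexicon)

    def test_relation_assembly_static_structural(self, tiny_relation_corpus, small_lexicon):
        doc = tiny_relation_corpus[0]
        vec = assemble(doc.associations[0], doc, small_lexicon)
        assert vec.features["ST6"] == 1 and vec.features["ST7"] == 1

    def test_export_frame(self, layered_doc, small_lexicon):
        vecs = [assemble(a, layered_doc, small_lexicon)
                for a in layered_doc.associations]
        frame = vectors_to_frame(vecs)
        assert frame.shape[0] == 3
        assert list(frame.columns) == list(vecs[0].features)


class TestSentinelAudit:
    def test_absence_sentinels_do_not_collide(self, tiny_corpus, small_lexicon):
        """Computed values never equal their absence sentinel."""
        from metaknow.lexicon import default_lexicon

        lex = default_lexicon()
        for doc in tiny_corpus[:6]:
            for assoc in doc.associations:
                vec = assemble(assoc, doc, lex).features
                if vec["L2"]:
                    assert vec["L1"] >= 0
                    assert vec["L5"] != -9999
                for key in ("PT1", "PT2", "PT3", "PT4"):
                    assert vec[key] == -1 or vec[key] >= 0
                for key in ("SE5", "SE6", "SE7", "SE8", "SE9", "SE10"):
                    assert vec[key] == -1 or vec[key] >= 0
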