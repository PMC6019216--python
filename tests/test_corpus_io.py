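"""Standoff parsing, serialization round trips, association tables."""

import pytest

from metaknow.corpus_io import (
    Association,
    Document,
    Entity,
    Event,
    MKRecord,
    Relation,
    Span,
    StandoffError,
    as_association_table,
    load_document,
    read_standoff,
    segment_sentences,
    write_standoff,
)

RELATION_TEXT = "NPTN is related to Schizophrenia"
RELATION_ANN = (
    "T1\tTarget 0 4\tNPTN\n"
    "T2\tDisease 19 32\tSchizophrenia\n"
    "R1\tTarget-Disorder Arg1:T1 Arg2:T2\n"
)


class TestReadStandoff:
    def test_binary_relation_example(self):
        doc = read_standoff(RELATION_TEXT, RELATION_ANN)
        assert len(doc.relations) == 1
        assert len(doc.associations) == 1
        assoc = doc.associations[0]
        assert assoc.kind == "relation"
        assert doc.entity_map()["T1"].surface == "NPTN"
        assert doc.relations[0].rtype == "Target-Disorder"

    def test_empty_annotation_stream(self):
        doc = read_standoff("Some text.", "")
        assert doc.associations == []

    def test_unresolved_event_reference(self):
        ann = "T1\tProtein 0 4\tNPTN\nE1\tbinding:T1 Theme:T9\n"
        with pytest.raises(StandoffError, match="unresolved reference"):
            read_standoff(RELATION_TEXT, ann)

    def test_surface_mismatch_rejected(self):
        with pytest.raises(StandoffError, match="does not match"):
            read_standoff(RELATION_TEXT, "T1\tTarget 0 4\tXXXX\n")

    def test_span_outside_document(self):
        with pytest.raises(StandoffError, match="outside"):
            read_standoff("ab", "T1\tTarget 0 99\tab\n")

    def test_discontinuous_span_rejected_with_line_number(self):
        with pytest.raises(StandoffError, match="line 1"):
            read_standoff(RELATION_TEXT, "T1\tTarget 0 4;6 8\tNPTN\n")

    def test_participant_cycle_detected(self):
        text = "a b c d"
        ann = (
            "T1\tX 0 1\ta\nT2\tX 2 3\tb\n"
            "E1\tproc:T1 Theme:E2\nE2\tproc:T2 Theme:E1\n"
        )
        with pytest.raises(StandoffError, match="cycle"):
            read_standoff(text, ann)

    def test_hyperdimension_exclusivity_rejected_at_parse(self):
        ann = RELATION_ANN + "A1\tNewKnowledge R1 Yes\nA2\tResearchHypothesis R1 Yes\n"
        with pytest.raises(StandoffError, match="mutual exclusivity"):
            read_standoff(RELATION_TEXT, ann)

    def test_unknown_attribute_warns_and_kept_opaque(self):
        ann = RELATION_ANN + "A1\tShinyNewDim R1 Blue\n"
        with pytest.warns(UserWarning, match="ShinyNewDim"):
            doc = read_standoff(RELATION_TEXT, ann)
        assert doc.associations[0].mk.extras == {"ShinyNewDim": "Blue"}

    def test_mk_attributes_mapped(self, nested_event_doc):
        mk = nested_event_doc.association_map()["E2"].mk
        assert mk.knowledge_type == "Observation"
        assert mk.knowledge_source == "Current"
        assert mk.certainty == "L3"
        assert mk.new_knowledge is True

    def test_event_valued_participants_kept_as_references(self, nested_event_doc):
        e2 = nested_event_doc.event_map()["E2"]
        assert e2.themes == ("E1",)
        assert e2.causes == ("T2",)


class TestMKRecord:
    def test_mutual_exclusivity_invariant(self):
        with pytest.raises(ValueError, match="mutual exclusivity"):
            MKRecord(new_knowledge=True, research_hypothesis=True)

    def test_illegal_dimension_value(self):
        with pytest.raises(ValueError, match="certainty"):
            MKRecord(certainty="L9")


class TestWriteStandoff:
    def test_round_trip_relation(self):
        doc = read_standoff(RELATION_TEXT, RELATION_ANN)
        text, ann = write_standoff(doc)
        doc2 = read_standoff(text, ann)
        assert text == RELATION_TEXT
        assert len(doc2.relations) == 1
        assert write_standoff(doc2) == (text, ann)

    def test_round_trip_preserves_hyperdimension_flag(self):
        ann = RELATION_ANN + "A1\tNewKnowledge R1 Yes\n"
        doc = read_standoff(RELATION_TEXT, ann)
        _, out = write_standoff(doc)
        doc2 = read_standoff(RELATION_TEXT, out)
        assert doc2.associations[0].mk.new_knowledge is True

    def test_round_trip_clue_spans(self):
        ann = RELATION_ANN + "A1\tCertainty R1 L2\n#1\tClueSpan R1 Uncertainty 5 7\n"
        doc = read_standoff(RELATION_TEXT, ann)
        _, out = write_standoff(doc)
        doc2 = read_standoff(RELATION_TEXT, out)
        assert doc2.associations[0].mk.clue_spans == {"Uncertainty": [Span(5, 7)]}

    def test_empty_document_empty_stream(self):
        doc = read_standoff("text.", "")
        assert write_standoff(doc) == ("text.", "")

    def test_round_trip_synthetic_corpus(self, tiny_corpus):
        """Write->read is identity up to id renumbering on generated docs."""
        for doc in tiny_corpus[:8]:
            text, ann = write_standoff(doc)
            doc2 = read_standoff(text, ann, doc_id=doc.id,
                                 sentence_spans=doc.sentence_spans)
            assert len(doc2.associations) == len(doc.associations)
            assert [a.kind for a in doc2.associations] == [a.kind for a in doc.associations]
            got = sorted((a.mk.knowledge_type, a.mk.certainty, a.mk.new_knowledge,
                          a.mk.research_hypothesis) for a in doc2.associations)
            want = sorted((a.mk.knowledge_type, a.mk.certainty, a.mk.new_knowledge,
                           a.mk.research_hypothesis) for a in doc.associations)
            assert got == want
            assert write_standoff(doc2)[1] == ann  # idempotent after one pass


class TestAssociationTable:
    def test_count_is_events_plus_relations(self, tiny_corpus, tiny_relation_corpus):
        for doc in list(tiny_corpus) + list(tiny_relation_corpus):
            assert len(doc.associations) == len(doc.events) + len(doc.relations)

    def test_corpus_scale_counts(self):
        """An event corpus of 6899 events over 150 abstracts and a relation
        corpus of 622 relations over 159 abstracts yield those totals."""

        def doc_with_events(doc_id, n):
            text = "x " * (2 * n)
            entities, events, assocs = [], [], []
            for i in range(n):
                span = Span(4 * i, 4 * i + 1)
                ev = Event(f"E{i + 1}", "binding", span, "x")
                events.append(ev)
                assocs.append(Association("event", ev, 0))
            return Document(doc_id, text, [Span(0, len(text))],
                            entities, events, [], assocs)

        sizes = [46] * 149
        sizes.append(6899 - sum(sizes))
        docs = [doc_with_events(f"d{i:03d}", n) for i, n in enumerate(sizes)]
        assert len(as_association_table(docs)) == 6899

        def doc_with_relations(doc_id, n):
            text = "a b " * n
            ents, rels, assocs = [], [], []
            for i in range(n):
                e1 = Entity(f"T{2 * i + 1}", "Target", Span(4 * i, 4 * i + 1), "a")
                e2 = Entity(f"T{2 * i + 2}", "Disease", Span(4 * i + 2, 4 * i + 3), "b")
                ents += [e1, e2]
                rel = Relation(f"R{i + 1}", "Target-Disorder", e1.id, e2.id)
                rels.append(rel)
                assocs.append(Association("relation", rel, 0))
            return Document(doc_id, text, [Span(0, len(text))], ents, [], rels, assocs)

        sizes = [4] * 145 + [3] * 14  # 159 abstracts, 622 relations
        rel_docs = [doc_with_relations(f"r{i:03d}", n) for i, n in enumerate(sizes)]
        assert len(as_association_table(rel_docs)) == 622

    def test_stable_ordering(self, tiny_corpus):
        table = as_association_table(tiny_corpus)
        assert table == as_association_table(list(reversed(tiny_corpus)))

    def test_empty(self):
        assert as_association_table([]) == []


class TestDialects:
    def test_a1_a2_split_dialect(self, tmp_path):
        (tmp_path / "d.txt").write_text(RELATION_TEXT)
        (tmp_path / "d.a1").write_text(
            "T1\tTarget 0 4\tNPTN\nT2\tDisease 19 32\tSchizophrenia\n"
        )
        (tmp_path / "d.a2").write_text("R1\tTarget-Disorder Arg1:T1 Arg2:T2\n")
        doc = load_document(tmp_path / "d.txt")
        assert len(doc.relations) == 1


def test_sentence_segmentation_tiles_text():
    text = "First one. Second one! Trailing fragment"
    spans = segment_sentences(text)
    assert spans[0].start == 0
    assert spans[-1].end == len(text)
    for a, b in zip(spans, spans[1:]):
        assert a.end == b.start
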