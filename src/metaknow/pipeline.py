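"""End-to-end runs: corpus loading, baseline, supervised CV, agreement.

Every run can write a manifest (inputs, seed, configuration, counts)
sufficient to reproduce its report.  The thin shell interface in
:mod:`metaknow.cli` wraps these functions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .corpus_io import Association, Document, Span, as_association_table, load_document
from .evaluation import cohens_kappa, prf_table
from .features import FeatureConfig, FeatureVector, assemble
from .lexicon import ClueLexicon, default_lexicon
from .linguistic import LinguisticLayer, Token, read_bracketed, read_conllu
from .model import CVResult, cross_validate
from .rules import baseline_hypothesis, baseline_new_knowledge

__all__ = [
    "load_corpus",
    "attach_linguistic",
    "build_instances",
    "run_baseline",
    "run_supervised",
    "run_ablation",
    "run_agreement",
]


def attach_linguistic(doc: Document, conllu_text: str, trees_text: Optional[str] = None) -> None:
    """Attach per-sentence layers, re-aligning token offsets to the document.

    CoNLL-U carries no character offsets; each token surface is located
    left-to-right inside its sentence text.
    """
    parsed = read_conllu(conllu_text)
    trees = read_bracketed(trees_text) if trees_text else [None] * len(parsed)
    if len(parsed) != len(doc.sentence_spans):
        raise ValueError(
            f"{doc.id}: {len(parsed)} linguistic sentences vs "
            f"{len(doc.sentence_spans)} document sentences"
        )
    if trees_text and len(trees) != len(parsed):
        raise ValueError(f"{doc.id}: tree count does not match sentence count")
    for s, (tokens, dep) in enumerate(parsed):
        sent_span = doc.sentence_spans[s]
        sent_text = doc.text[sent_span.start : sent_span.end]
        cursor = 0
        realigned = []
        for tok in tokens:
            found = sent_text.find(tok.surface, cursor)
            if found < 0:
                raise ValueError(
                    f"{doc.id}: token {tok.surface!r} not found in sentence {s}"
                )
            start = sent_span.start + found
            realigned.append(Token(tok.index, Span(start, start + len(tok.surface)),
                                   tok.surface, tok.pos))
            cursor = found + len(tok.surface)
        doc.linguistic[s] = LinguisticLayer(realigned, dep, trees[s])


def load_corpus(directory) -> List[Document]:
    """Load every ``.txt`` + ``.ann`` pair in a directory, attaching
    ``.conllu`` / ``.trees`` siblings when present."""
    docs = []
    for txt in sorted(Path(directory).glob("*.txt")):
        doc = load_document(txt)
        conllu = txt.with_suffix(".conllu")
        if conllu.exists():
            trees = txt.with_suffix(".trees")
            attach_linguistic(doc, conllu.read_text(),
                              trees.read_text() if trees.exists() else None)
        docs.append(doc)
    return docs


_TASK_LABEL = {
    "knowledge_type": lambda mk: mk.knowledge_type,
    "new_knowledge": lambda mk: mk.new_knowledge,
    "research_hypothesis": lambda mk: mk.research_hypothesis,
}


def build_instances(
    docs: Sequence[Document],
    lexicon: Optional[ClueLexicon],
    task: str,
    config: Optional[FeatureConfig] = None,
) -> Tuple[List[FeatureVector], List, List[str]]:
    """Assemble ``(vectors, labels, doc_ids)`` for every labelled association."""
    if lexicon is None:
        lexicon = default_lexicon()
    if config is None:
        config = (FeatureConfig.knowledge_type_default() if task == "knowledge_type"
                  else FeatureConfig.hyperdimension())
    label_of = _TASK_LABEL[task]
    vectors, labels, doc_ids = [], [], []
    by_doc = {}
    for doc in docs:
        for assoc in doc.associations:
            by_doc.setdefault(doc.id, []).append(assoc)
    missing = [doc.id for doc in docs
               if any(a.mk is None or label_of(a.mk) is None for a in doc.associations)]
    if missing:
        raise ValueError(f"missing gold {task} labels in documents: {', '.join(missing)}")
    for doc in docs:
        for assoc in doc.associations:
            vectors.append(assemble(assoc, doc, lexicon, config))
            labels.append(label_of(assoc.mk))
            doc_ids.append(doc.id)
    return vectors, labels, doc_ids


def run_baseline(docs: Sequence[Document]) -> Dict[str, pd.DataFrame]:
    """Apply the rule-based hyperdimension inference to every association
    and score it against the gold hyperdimension labels."""
    assocs = as_association_table(docs)
    if not assocs:
        raise ValueError("empty corpus")
    missing = sorted({a.id for a in assocs if a.mk is None
                      or a.mk.new_knowledge is None or a.mk.research_hypothesis is None})
    if missing:
        raise ValueError(f"missing gold hyperdimension labels on: {', '.join(missing[:10])}")
    gold_nk = [a.mk.new_knowledge for a in assocs]
    gold_rh = [a.mk.research_hypothesis for a in assocs]
    pred_nk = [baseline_new_knowledge(a.mk) for a in assocs]
    pred_rh = [baseline_hypothesis(a.mk) for a in assocs]
    return {
        "new_knowledge": prf_table(gold_nk, pred_nk, classes=[True, False]),
        "research_hypothesis": prf_table(gold_rh, pred_rh, classes=[True, False]),
    }


def run_supervised(
    docs: Sequence[Document],
    task: str = "new_knowledge",
    lexicon: Optional[ClueLexicon] = None,
    learner: str = "random_forest",
    k: int = 10,
    seed: Optional[int] = None,
    config: Optional[FeatureConfig] = None,
    grouped: bool = False,
) -> CVResult:
    """k-fold cross-validation of the supervised classifier on a corpus."""
    vectors, labels, doc_ids = build_instances(docs, lexicon, task, config)
    return cross_validate(
        vectors, labels, task=task, learner=learner, k=k, seed=seed,
        groups=doc_ids if grouped else None,
    )


def run_ablation(
    docs: Sequence[Document],
    task: str = "knowledge_type",
    lexicon: Optional[ClueLexicon] = None,
    k: int = 10,
    seed: Optional[int] = None,
    groups: Sequence[str] = ("sentence", "structural", "participant", "lexical",
                             "constituency", "dependency", "parse_tree"),
) -> Dict[str, pd.DataFrame]:
    """Only-this-feature / all-except-this-feature sweep per group."""
    reports = {}
    for group in groups:
        for mode, cfg in (("only", FeatureConfig.only(group)),
                          ("all_except", FeatureConfig.all_except(group))):
            try:
                result = run_supervised(docs, task, lexicon, k=k, seed=seed, config=cfg)
            except ValueError:
                continue  # a subset may be unable to produce a reliable model
            reports[f"{mode}:{group}"] = result.table()
    full = run_supervised(docs, task, lexicon, k=k, seed=seed,
                          config=FeatureConfig.all_features())
    reports["all"] = full.table()
    return reports


def run_agreement(
    docs_a: Sequence[Document], docs_b: Sequence[Document]
) -> pd.DataFrame:
    """Cohen's kappa per hyperdimension over doubly-annotated associations."""
    map_a = {d.id: d for d in docs_a}
    map_b = {d.id: d for d in docs_b}
    if set(map_a) != set(map_b):
        only_a = sorted(set(map_a) - set(map_b))
        only_b = sorted(set(map_b) - set(map_a))
        raise ValueError(
            f"document id mismatch: only in first {only_a}; only in second {only_b}"
        )
    labels_a = {"new_knowledge": [], "research_hypothesis": []}
    labels_b = {"new_knowledge": [], "research_hypothesis": []}
    for doc_id in sorted(map_a):
        assoc_a = map_a[doc_id].association_map()
        assoc_b = map_b[doc_id].association_map()
        for aid in sorted(set(assoc_a) & set(assoc_b)):
            ma, mb = assoc_a[aid].mk, assoc_b[aid].mk
            if ma is None or mb is None:
                continue
            for dim in labels_a:
                labels_a[dim].append(bool(getattr(ma, dim)))
                labels_b[dim].append(bool(getattr(mb, dim)))
    rows = []
    for dim in ("new_knowledge", "research_hypothesis"):
        res = cohens_kappa(labels_a[dim], labels_b[dim])
        rows.append((dim, res.kappa, res.observed_agreement,
                     res.expected_agreement, res.n_items))
    return pd.DataFrame(rows, columns=["dimension", "kappa", "po", "pe", "n"]).set_index("dimension")


def write_manifest(path, seed, inputs: Dict[str, str], extra: Optional[dict] = None) -> None:
    """Record inputs (with content hashes where files exist), seed and config."""
    manifest = {"seed": seed, "inputs": {}}
    for name, value in inputs.items():
        entry = {"value": str(value)}
        p = Path(str(value))
        if p.is_file():
            entry["sha256"] = hashlib.sha256(p.read_bytes()).hexdigest()
        manifest["inputs"][name] = entry
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
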