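"""Rank-weighted text mining of enriched ontology-term labels.

Labels of ranked enrichment results are tokenized, stopword-filtered, and
assembled into a binary word x term incidence matrix.  A word's
significance is the sum of reciprocal ranks ("orders") of the terms whose
label contains it; the top words feed a word cloud and a Pearson
word-association analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .enrichment import EnrichmentResult

_NON_TOKEN = re.compile(r"[^0-9a-z-]+")


def load_stopwords() -> frozenset[str]:
    """The shipped English stopword list (pinned for reproducibility)."""
    text = resources.files("tfenrich.data").joinpath("stopwords.txt").read_text()
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def clean_tokens(
    label: str,
    stopwords=frozenset(),
    collapse_duplicates: bool = True,
) -> list[str]:
    """Lowercase, strip punctuation, drop stopwords.

    Punctuation (anything outside [a-z0-9-]) becomes whitespace; hyphens
    internal to a token are preserved so compounds like
    "phosphate-containing" stay whole.  Duplicate tokens within one label
    collapse to a single occurrence (switchable).
    """
    text = _NON_TOKEN.sub(" ", label.lower())
    out: list[str] = []
    seen: set[str] = set()
    for tok in text.split():
        tok = tok.strip("-")
        if not tok or tok in stopwords:
            continue
        if collapse_duplicates:
            if tok in seen:
                continue
            seen.add(tok)
        out.append(tok)
    return out


@dataclass
class TermDocumentMatrix:
    """Binary word x document incidence with reciprocal-rank significance.

    ``words`` are sorted by descending significance (ties by ascending
    word); ``incidence[i, j]`` is 1 iff words[i] occurs in document j.
    """

    words: list[str]
    doc_ids: list[str]
    orders: list[int]
    incidence: np.ndarray
    significance: dict[str, float]

    @property
    def n_documents(self) -> int:
        return len(self.doc_ids)

    def document_counts(self) -> dict[str, int]:
        counts = self.incidence.sum(axis=1)
        return {w: int(c) for w, c in zip(self.words, counts)}


def build_tdm(
    results: list[EnrichmentResult],
    stopwords=None,
    collapse_duplicates: bool = True,
) -> TermDocumentMatrix:
    """Term-document matrix over ranked enrichment results.

    significance(word) = sum of 1/order over the documents containing it.
    """
    if stopwords is None:
        stopwords = load_stopwords()
    doc_ids = [r.term for r in results]
    orders = [r.order for r in results]
    if any(o < 1 for o in orders):
        raise ValueError("results must carry 1-based orders")
    tokens_per_doc = [
        clean_tokens(r.label, stopwords, collapse_duplicates=collapse_duplicates)
        for r in results
    ]
    significance: dict[str, float] = {}
    for toks, order in zip(tokens_per_doc, orders):
        for w in set(toks):
            significance[w] = significance.get(w, 0.0) + 1.0 / order
    words = sorted(significance, key=lambda w: (-significance[w], w))
    word_index = {w: i for i, w in enumerate(words)}
    incidence = np.zeros((len(words), len(doc_ids)), dtype=np.uint8)
    for j, toks in enumerate(tokens_per_doc):
        for w in set(toks):
            incidence[word_index[w], j] = 1
    return TermDocumentMatrix(
        words=words,
        doc_ids=doc_ids,
        orders=list(orders),
        incidence=incidence,
        significance=significance,
    )


def top_words(tdm: TermDocumentMatrix, n: int = 100) -> list[tuple[str, float]]:
    """First n (word, significance) pairs in the matrix's sort order."""
    return [(w, tdm.significance[w]) for w in tdm.words[: max(n, 0)]]


@dataclass(frozen=True)
class WordAssociation:
    anchor: str
    word: str
    correlation: float
    anchor_significance: float


def word_correlations(
    tdm: TermDocumentMatrix, k: int = 10, cor_min: float = 0.3
) -> list[WordAssociation]:
    """Pearson associations between each top-k word and every other word.

    Correlations are computed on the binary incidence vectors across
    documents.  Zero-variance vectors yield no associations (never NaN).
    When two top-k anchors are mutually associated both directed pairs
    appear in the output.
    """
    if tdm.n_documents < 2:
        raise ValueError("word correlation requires at least 2 documents")
    anchors = tdm.words[: max(k, 0)]
    x = tdm.incidence.astype(float)
    variances = x.var(axis=1)
    out: list[WordAssociation] = []
    for anchor in anchors:
        i = tdm.words.index(anchor)
        if variances[i] == 0:
            continue
        for j, word in enumerate(tdm.words):
            if j == i or variances[j] == 0:
                continue
            r = float(np.corrcoef(x[i], x[j])[0, 1])
            if r >= cor_min:
                out.append(
                    WordAssociation(
                        anchor=anchor,
                        word=word,
                        correlation=r,
                        anchor_significance=tdm.significance[anchor],
                    )
                )
    return out
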