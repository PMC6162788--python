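"""Word-enrichment analysis of abstract corpora.

Abstracts of publications linked to lncRNAs hit by copy-number alterations
are compared against abstracts of unaffected lncRNAs. Texts are lower-cased,
punctuation-stripped and whitespace-tokenised; stopwords, user-supplied
excluded names (e.g. the lncRNA identifiers themselves) and digit-bearing
tokens are removed. Per-group total token frequencies form the term-document
matrix; comparison-cloud scores are per-word deviations of within-group
relative frequency from the cross-group mean, and per-word enrichment is a
two-sided Fisher's exact test computed from the hypergeometric mass.

Token occurrences are the default counting unit; an abstract-level
(document-presence) contingency is available via ``unit="document"``.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


class TextMineError(ValueError):
    pass


@dataclass(slots=True)
class Corpus:
    label: str
    documents: list[str]

    def __post_init__(self) -> None:
        if not self.documents:
            raise TextMineError(f"corpus {self.label!r} has no documents")


@dataclass(slots=True)
class TermDocumentMatrix:
    """Per-group token totals (``counts``) and document frequencies."""

    counts: pd.DataFrame  # index: word, columns: group labels
    doc_counts: pd.DataFrame
    n_docs: dict[str, int] = field(default_factory=dict)

    @property
    def vocabulary(self) -> list[str]:
        return list(self.counts.index)

    @property
    def groups(self) -> list[str]:
        return list(self.counts.columns)

    def group_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def default_stopwords() -> frozenset[str]:
    text = (
        resources.files("lncfocal").joinpath("data/stopwords_en.txt").read_text()
    )
    return frozenset(w.strip() for w in text.split() if w.strip())


def tokenize(
    text: str,
    stopwords: Iterable[str] = (),
    excluded_names: Iterable[str] = (),
) -> list[str]:
    """Lower-case whitespace tokens after stripping punctuation.

    Tokens containing digits, stopwords and excluded names are removed.
    """
    # normalize filter lists the same way as the text, so entries containing
    # punctuation (e.g. "aren't") match their stripped token pieces
    stop: set[str] = set()
    for w in stopwords:
        stop.update(w.lower().translate(_PUNCT_TABLE).split())
    excluded: set[str] = set()
    for w in excluded_names:
        excluded.update(w.lower().translate(_PUNCT_TABLE).split())
    tokens = text.lower().translate(_PUNCT_TABLE).split()
    return [
        t
        for t in tokens
        if t not in stop
        and t not in excluded
        and not any(ch.isdigit() for ch in t)
    ]


def build_tdm(
    corpora: Sequence[Corpus],
    stopwords: Iterable[str] | None = None,
    excluded_names: Iterable[str] = (),
) -> TermDocumentMatrix:
    """Two-group (or more) term-document matrix from raw corpora."""
    if not corpora:
        raise TextMineError("no corpora supplied")
    stop = default_stopwords() if stopwords is None else frozenset(stopwords)
    counts: dict[str, dict[str, int]] = {}
    doc_counts: dict[str, dict[str, int]] = {}
    n_docs: dict[str, int] = {}
    for corpus in corpora:
        n_docs[corpus.label] = len(corpus.documents)
        for doc in corpus.documents:
            tokens = tokenize(doc, stop, excluded_names)
            for t in tokens:
                counts.setdefault(t, {}).setdefault(corpus.label, 0)
                counts[t][corpus.label] += 1
            for t in set(tokens):
                doc_counts.setdefault(t, {}).setdefault(corpus.label, 0)
                doc_counts[t][corpus.label] += 1
    if not counts:
        raise TextMineError("vocabulary is empty after filtering")
    labels = [c.label for c in corpora]
    cdf = (
        pd.DataFrame.from_dict(counts, orient="index")
        .reindex(columns=labels)
        .fillna(0)
        .astype(int)
        .sort_index()
    )
    ddf = (
        pd.DataFrame.from_dict(doc_counts, orient="index")
        .reindex(columns=labels)
        .fillna(0)
        .astype(int)
        .sort_index()
    )
    return TermDocumentMatrix(counts=cdf, doc_counts=ddf, n_docs=n_docs)


def comparison_scores(tdm: TermDocumentMatrix) -> pd.DataFrame:
    """Comparison-cloud deviation scores.

    For word w and group g, score(w, g) = f(w, g) - mean_g' f(w, g') where f
    is the within-group relative token frequency. Scores sum to zero across
    groups for every word; a positive score assigns the word to the group.
    """
    if len(tdm.groups) < 2:
        raise TextMineError("comparison scores need >= 2 groups")
    freq = tdm.counts / tdm.group_totals()
    return freq.sub(freq.mean(axis=1), axis=0)


def fisher_exact_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p from the hypergeometric mass.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with a standard
    relative tolerance for floating-point ties). Degenerate tables with an
    empty margin give p = 1 with a warning.
    """
    (a, b), (c, d) = np.asarray(table, dtype=np.int64)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        warnings.warn("degenerate 2x2 table (empty margin); p = 1")
        return 1.0
    rv = hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(c1, r1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(1.0, p)


def word_enrichment_test(
    word: str, tdm: TermDocumentMatrix, unit: str = "token"
) -> float:
    """Per-word enrichment p-value between the first two groups.

    ``unit="token"``: 2x2 table of word tokens vs all other tokens per group.
    ``unit="document"``: documents containing the word vs documents not.
    """
    if word not in tdm.counts.index:
        raise KeyError(f"word {word!r} not in vocabulary")
    g1, g2 = tdm.groups[:2]
    if unit == "token":
        a = int(tdm.counts.loc[word, g1])
        c = int(tdm.counts.loc[word, g2])
        totals = tdm.group_totals()
        table = [[a, int(totals[g1]) - a], [c, int(totals[g2]) - c]]
    elif unit == "document":
        a = int(tdm.doc_counts.loc[word, g1])
        c = int(tdm.doc_counts.loc[word, g2])
        table = [[a, tdm.n_docs[g1] - a], [c, tdm.n_docs[g2] - c]]
    else:
        raise ValueError("unit must be 'token' or 'document'")
    return fisher_exact_two_sided(np.asarray(table))


def enrichment_table(
    tdm: TermDocumentMatrix,
    words: Sequence[str] | None = None,
    unit: str = "token",
) -> pd.DataFrame:
    """Scores and enrichment p-values for selected (default: all) words."""
    scores = comparison_scores(tdm)
    words = list(words) if words is not None else list(tdm.counts.index)
    rows = []
    for w in words:
        row = {"word": w}
        for g in tdm.groups:
            row[f"count_{g}"] = int(tdm.counts.loc[w, g])
            row[f"score_{g}"] = float(scores.loc[w, g])
        row["p_value"] = word_enrichment_test(w, tdm, unit=unit)
        rows.append(row)
    return pd.DataFrame(rows)
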