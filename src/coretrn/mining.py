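"""Literature mining: keyword filtering and TF / cell-term co-occurrence.

The mining arm of core-element selection.  Abstracts are plain token
sequences; those mentioning at least one biological-process keyword
(by default "differentiation", "development", "transformation") are kept,
and for every transcription factor the number of retained abstracts in
which the cell-type term (default "monocyte") co-occurs with any of the
TF's names is counted.  Counts are turned into a competition ranking
``rco`` (rank 1 = most co-mentioned TF); TFs never mentioned share the
bottom rank ``n_nonzero + 1``.

Matching is deliberately simple — case-insensitive whole-token comparison
tolerating a plural "s" — because the underlying method is plain
co-occurrence counting, not entity recognition.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd

from ._ranking import competition_rank

__all__ = [
    "Corpus",
    "DEFAULT_KEYWORDS",
    "filter_corpus",
    "count_cooccurrence",
    "rank_cooccurrence",
]

#: Biological-process keywords used to pre-filter abstracts.
DEFAULT_KEYWORDS: tuple[str, ...] = ("differentiation", "development", "transformation")


@dataclass
class Corpus:
    """A list of abstracts, each a sequence of lower-case tokens."""

    abstracts: list[list[str]]
    record_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.record_ids:
            self.record_ids = [f"rec{i}" for i in range(len(self.abstracts))]
        if len(self.record_ids) != len(self.abstracts):
            raise ValueError("record_ids and abstracts must be parallel")
        self.abstracts = [[t.lower() for t in ab] for ab in self.abstracts]

    def __len__(self) -> int:
        return len(self.abstracts)


def _matches(token: str, name: str) -> bool:
    """Whole-token match tolerating a plural 's' ("monocytes" ~ "monocyte")."""
    return token == name or token == name + "s"


def _contains(tokens: Sequence[str], names: Sequence[str]) -> bool:
    return any(_matches(t, n) for t in tokens for n in names)


def filter_corpus(corpus: Corpus, keywords: Sequence[str] = DEFAULT_KEYWORDS) -> Corpus:
    """Retain abstracts containing at least one keyword (order preserved).

    An empty keyword list matches nothing and yields an empty corpus.
    """
    kws = [k.lower() for k in keywords]
    kept = [
        (rid, ab)
        for rid, ab in zip(corpus.record_ids, corpus.abstracts)
        if _contains(ab, kws)
    ]
    return Corpus(abstracts=[ab for _, ab in kept], record_ids=[rid for rid, _ in kept])


def count_cooccurrence(
    corpus: Corpus,
    tf_table: Mapping[str, Sequence[str]],
    cell_term: str = "monocyte",
) -> pd.DataFrame:
    """Count abstracts where ``cell_term`` co-occurs with each TF.

    ``tf_table`` maps a TF symbol to its synonym list (the symbol itself is
    always included as a name).  Each abstract contributes at most one to a
    TF's count regardless of how many times the names appear.

    Returns a DataFrame indexed by symbol with columns ``synonyms`` and
    ``count``, in ``tf_table`` iteration order.
    """
    if not tf_table:
        raise ValueError("tf_table must be non-empty")
    term = cell_term.lower()
    names_per_tf = {
        sym: sorted({sym.lower(), *[s.lower() for s in syns]})
        for sym, syns in tf_table.items()
    }
    counts = dict.fromkeys(tf_table, 0)
    for tokens in corpus.abstracts:
        if not _contains(tokens, [term]):
            continue
        token_set = set(tokens)
        for sym, names in names_per_tf.items():
            if any(n in token_set or n + "s" in token_set for n in names):
                counts[sym] += 1
    return pd.DataFrame(
        {
            "synonyms": ["|".join(tf_table[s]) for s in counts],
            "count": list(counts.values()),
        },
        index=pd.Index(counts.keys(), name="symbol"),
    )


def rank_cooccurrence(table: pd.DataFrame) -> pd.DataFrame:
    """Add competition rank ``rco`` by descending co-occurrence count.

    Zero-count TFs automatically share the rank
    ``(number of TFs with count > 0) + 1``, reproducing the deep shared
    ranks seen when many TFs are never co-mentioned with the cell term.
    """
    out = table.copy()
    out["rco"] = competition_rank(out["count"].to_numpy(), descending=True)
    return out
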