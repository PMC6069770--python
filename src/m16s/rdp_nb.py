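"""RDP-style naive Bayes classifier over 8-mer word presence.

The classifier scores a query sequence s against each genus g by the
joint probability

    P(s | g_i) = prod_j  (m(r_j) + P_j) / (M_i + 1)

taken over the query's distinct words r_j, where M_i is the number of
training sequences of genus i, m(r_j) of those contain word r_j, and

    P_j = (n(r_j) + 0.5) / (N - 1)

is the corpus-wide word prior (n(r_j) sequences of N contain the word).
With equal genus priors the winner is argmax_i P(s | g_i). Scores are
accumulated in log space; presence is counted once per sequence
regardless of word multiplicity.

Notes on the formulation: the prior denominator is (N - 1) as used here
by default; the original RDP publication uses (N + 1), selectable via
``prior_denominator="rdp_original"``. The prior can exceed 1 for words
present in (almost) every sequence — the formula is applied as defined.
Although named for its genus-level role, any taxonomic rank's labels can
be used as classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_WORD_SIZE = 8


def extract_word_set(seq: str, word_size: int = DEFAULT_WORD_SIZE) -> set[str]:
    """Distinct word_size-length substrings of *seq*; windows containing a
    non-ACGT character are skipped."""
    if len(seq) < word_size:
        raise ValueError(f"sequence of length {len(seq)} shorter than word size {word_size}")
    ok = set("ACGT")
    return {
        w
        for i in range(len(seq) - word_size + 1)
        if set(w := seq[i : i + word_size]) <= ok
    }


def word_prior(n_r: int, N: int, denominator: str = "n_minus_1") -> float:
    """Corpus-wide prior for a word seen in *n_r* of *N* training sequences:
    ``(n_r + 0.5) / (N - 1)`` (or ``/(N + 1)`` under the original RDP
    convention)."""
    if denominator not in ("n_minus_1", "rdp_original"):
        raise ValueError("denominator must be 'n_minus_1' or 'rdp_original'")
    if N < 2:
        raise ValueError("need at least 2 training sequences (N - 1 denominator)")
    if not 0 <= n_r <= N:
        raise ValueError("require 0 <= n_r <= N")
    den = (N - 1) if denominator == "n_minus_1" else (N + 1)
    return (n_r + 0.5) / den


@dataclass
class NBModel:
    """Fitted word-presence counts for the naive Bayes classifier."""

    word_size: int
    genera: list[str]
    N: int
    M: np.ndarray  # per-genus training sequence counts, shape (G,)
    word_counts: dict[str, np.ndarray]  # word -> shape (G+1,): per-genus m, last entry n_r
    prior_denominator: str = "n_minus_1"
    _genus_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._genus_index:
            self._genus_index = {g: i for i, g in enumerate(self.genera)}
        if int(self.M.sum()) != self.N:
            raise ValueError("per-genus counts must sum to N")

    @property
    def prior_den(self) -> int:
        return (self.N - 1) if self.prior_denominator == "n_minus_1" else (self.N + 1)


def train_nb(
    seqs: Sequence[str],
    genera: Sequence[str],
    word_size: int = DEFAULT_WORD_SIZE,
    prior_denominator: str = "n_minus_1",
) -> NBModel:
    """Count word presence per genus and corpus-wide over the training set."""
    if len(seqs) != len(genera):
        raise ValueError("seqs and genera must have equal length")
    if len(seqs) < 2:
        raise ValueError("need at least 2 training sequences")
    labels = sorted(set(genera))
    lut = {g: i for i, g in enumerate(labels)}
    G = len(labels)
    M = np.zeros(G, dtype=np.int64)
    word_counts: dict[str, np.ndarray] = {}
    for seq, genus in zip(seqs, genera):
        gi = lut[genus]
        M[gi] += 1
        for w in extract_word_set(seq, word_size):
            row = word_counts.get(w)
            if row is None:
                row = word_counts[w] = np.zeros(G + 1, dtype=np.int64)
            row[gi] += 1
            row[G] += 1
    return NBModel(
        word_size=word_size,
        genera=labels,
        N=len(seqs),
        M=M,
        word_counts=word_counts,
        prior_denominator=prior_denominator,
    )


def _all_log_scores(model: NBModel, words: set[str]) -> np.ndarray:
    G = len(model.genera)
    scores = np.zeros(G)
    log_M1 = np.log(model.M + 1.0)
    zeros = np.zeros(G + 1)
    for w in words:
        row = model.word_counts.get(w, zeros)
        P_j = (row[G] + 0.5) / model.prior_den
        scores += np.log(row[:G] + P_j) - log_M1
    return scores


def genus_log_score(model: NBModel, query_words: set[str], genus: str) -> float:
    """Log P(s | genus) summed over the query's distinct words; an empty
    word set scores 0 (empty product)."""
    if genus not in model._genus_index:
        raise KeyError(f"unknown genus {genus!r}")
    return float(_all_log_scores(model, query_words)[model._genus_index[genus]])


def classify_nb(model: NBModel, seq: str) -> tuple[str, np.ndarray]:
    """Assign *seq* to the genus maximising the joint word probability.

    Returns ``(genus, per_genus_log_scores)``; ties break to the first
    genus in the model's sorted label order (argmax convention).
    """
    words = extract_word_set(seq, model.word_size)
    scores = _all_log_scores(model, words)
    return model.genera[int(np.argmax(scores))], scores


class NaiveBayesClassifier:
    """sklearn-style wrapper operating on raw read sequences."""

    def __init__(self, word_size: int = DEFAULT_WORD_SIZE, prior_denominator: str = "n_minus_1"):
        self.word_size = word_size
        self.prior_denominator = prior_denominator
        self.model_: NBModel | None = None

    def fit(self, seqs: Sequence[str], labels: Sequence[str]) -> "NaiveBayesClassifier":
        self.model_ = train_nb(seqs, labels, self.word_size, self.prior_denominator)
        return self

    def predict(self, seqs: Sequence[str]) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("classifier is not fitted")
        return np.array([classify_nb(self.model_, s)[0] for s in seqs])
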