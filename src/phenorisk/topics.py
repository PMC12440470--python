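"""Stable-topic features from clinical notes.

The unstructured half of the phenotype rests on a two-step topic-modelling
procedure: latent Dirichlet allocation (LDA) is run three times with
independent seeds on the note corpus, and only topics that all three runs
agree on — *stable topics* — are kept as features.  For each stable topic
and note the *pseudo word count* (PWC) is the inferred topic proportion
times the note's word count (generally non-integer), taken as the median
over the three member topics.  A piecewise *presence* function maps PWC to
[0, 1] (0 below 2.0 words, PWC/10 between 2.0 and 10.0, saturating at 1
above 10.0), and a patient's topic feature is the maximum presence over all
their notes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS
from sklearn.metrics.pairwise import cosine_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "tokenize",
    "Corpus",
    "build_corpus",
    "TopicRun",
    "learn_topics",
    "NoteTopicLoads",
    "infer_loads",
    "StableTopic",
    "extract_stable_topics",
    "stable_pwc",
    "PresenceParams",
    "presence",
    "patient_topic_presence",
    "top_terms",
]

_TOKEN_RE = re.compile(r"[^a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase, strip non-alphanumerics, drop short tokens and stopwords."""
    out = []
    for tok in _TOKEN_RE.split(text.lower()):
        if len(tok) < 2 or tok in ENGLISH_STOP_WORDS:
            continue
        out.append(tok)
    return out


@dataclass
class Corpus:
    """Bag-of-words corpus: one row per note over a fixed vocabulary.

    ``word_counts`` is each note's total token count (including tokens that
    fell below the document-frequency floor and are absent from ``vocab``);
    it is the note length used in the PWC definition.
    """

    note_ids: np.ndarray          # (n_notes,) str
    patient_ids: np.ndarray       # (n_notes,) str
    X: sp.csr_matrix              # (n_notes, n_vocab) term counts
    vocab: np.ndarray             # (n_vocab,) str
    word_counts: np.ndarray       # (n_notes,) int

    def __post_init__(self):
        if self.X.shape != (len(self.note_ids), len(self.vocab)):
            raise ValueError("corpus matrix shape does not match ids/vocab")
        if len(self.word_counts) != len(self.note_ids):
            raise ValueError("word_counts length does not match note_ids")

    @property
    def n_notes(self) -> int:
        return len(self.note_ids)

    @property
    def n_vocab(self) -> int:
        return len(self.vocab)

    def subset(self, idx: np.ndarray) -> "Corpus":
        return Corpus(self.note_ids[idx], self.patient_ids[idx],
                      self.X[idx], self.vocab, self.word_counts[idx])


def build_corpus(notes: Iterable, min_df: int = 2) -> Corpus:
    """Vectorize tokenized notes into a bag-of-words corpus.

    ``notes`` is an iterable of objects with ``note_id``, ``patient_id`` and
    ``tokens`` attributes (pre-tokenized), or ``text`` (tokenized here).
    Vocabulary keeps tokens appearing in at least ``min_df`` notes, sorted
    lexicographically for determinism.
    """
    note_ids, patient_ids, token_lists = [], [], []
    for nd in notes:
        toks = getattr(nd, "tokens", None)
        if toks is None:
            toks = tokenize(nd.text)
        note_ids.append(nd.note_id)
        patient_ids.append(nd.patient_id)
        token_lists.append(toks)
    if not note_ids:
        raise ValueError("empty corpus: no notes supplied")
    word_counts = np.array([len(t) for t in token_lists], dtype=np.int64)

    df_count: dict[str, int] = {}
    for toks in token_lists:
        for tok in set(toks):
            df_count[tok] = df_count.get(tok, 0) + 1
    vocab = np.array(sorted(t for t, c in df_count.items() if c >= min_df))
    if len(vocab) == 0:
        raise ValueError("empty vocabulary after document-frequency filtering")
    index = {t: i for i, t in enumerate(vocab)}

    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    for toks in token_lists:
        row: dict[int, int] = {}
        for tok in toks:
            j = index.get(tok)
            if j is not None:
                row[j] = row.get(j, 0) + 1
        indices.extend(row.keys())
        data.extend(row.values())
        indptr.append(len(indices))
    X = sp.csr_matrix(
        (np.array(data, dtype=np.int64), np.array(indices, dtype=np.int32),
         np.array(indptr, dtype=np.int64)),
        shape=(len(note_ids), len(vocab)),
    )
    X.sum_duplicates()
    return Corpus(np.array(note_ids), np.array(patient_ids), X, vocab, word_counts)


@dataclass
class TopicRun:
    """One fitted LDA run: K topic-word distributions plus the fitted model."""

    run_id: str
    K: int
    topic_word: np.ndarray        # (K, n_vocab), rows sum to 1
    seed: int
    vocab: np.ndarray
    model: LatentDirichletAllocation | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if not np.allclose(self.topic_word.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("topic-word rows must sum to 1")


def learn_topics(
    corpus: Corpus,
    K: int,
    seed: int,
    *,
    run_id: str | None = None,
    max_iter: int = 10,
    doc_topic_prior: float | None = None,
    topic_word_prior: float = 0.01,
) -> TopicRun:
    """Fit one LDA run on the corpus (variational EM, deterministic per seed).

    Priors default to a symmetric document prior alpha = 5/K and word prior
    beta = 0.01.
    """
    if corpus.n_notes == 0:
        raise ValueError("cannot learn topics from an empty corpus")
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > corpus.n_vocab:
        raise ValueError(f"K={K} exceeds vocabulary size {corpus.n_vocab}")
    if doc_topic_prior is None:
        # symmetric alpha = 5/K, capped at 1 (the solver requires <= 1;
        # the cap only binds for K < 5)
        doc_topic_prior = min(1.0, 5.0 / K)
    lda = LatentDirichletAllocation(
        n_components=K,
        doc_topic_prior=doc_topic_prior,
        topic_word_prior=topic_word_prior,
        learning_method="batch",
        max_iter=max_iter,
        random_state=seed,
        n_jobs=1,
    )
    lda.fit(corpus.X)
    tw = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return TopicRun(run_id or f"run{seed}", K, tw, seed, corpus.vocab, model=lda)


@dataclass
class NoteTopicLoads:
    """Per-note topic proportions and pseudo word counts for one run.

    ``proportions[i]`` sums to 1; ``pwc = proportions * word_count`` is the
    (generally non-integer) number of words in the note attributable to each
    topic.
    """

    run_id: str
    note_ids: np.ndarray
    patient_ids: np.ndarray
    proportions: np.ndarray       # (n_notes, K)
    word_counts: np.ndarray       # (n_notes,)

    def __post_init__(self):
        sums = self.proportions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("note topic proportions must sum to 1")
        if np.any(self.word_counts <= 0):
            raise ValueError("notes with zero tokens cannot carry topic loads")

    @property
    def pwc(self) -> np.ndarray:
        return self.proportions * self.word_counts[:, None]


def infer_loads(run: TopicRun, corpus: Corpus) -> NoteTopicLoads:
    """Infer per-note topic proportions under a fitted run.

    A note whose tokens are all out-of-vocabulary carries no evidence and
    receives uniform proportions (logged); a note with zero tokens is an
    upstream error.
    """
    if run.model is None:
        raise ValueError("TopicRun carries no fitted model for inference")
    if np.any(corpus.word_counts == 0):
        bad = corpus.note_ids[corpus.word_counts == 0][:5]
        raise ValueError(f"empty notes in corpus (e.g. {list(bad)}): tokenize upstream")
    n_oov = int((np.asarray(corpus.X.sum(axis=1)).ravel() == 0).sum())
    if n_oov:
        logger.info("infer_loads[%s]: %d notes entirely out-of-vocabulary -> uniform proportions",
                    run.run_id, n_oov)
    props = run.model.transform(corpus.X)
    props = props / props.sum(axis=1, keepdims=True)
    return NoteTopicLoads(run.run_id, corpus.note_ids, corpus.patient_ids,
                          props, corpus.word_counts.astype(np.float64))


@dataclass
class StableTopic:
    """A topic recovered consistently by all three runs.

    ``members`` holds one topic index per run; ``word_dist`` is the average
    of the three member distributions (renormalized).
    """

    stable_id: str
    members: tuple[int, int, int]
    word_dist: np.ndarray

    def __post_init__(self):
        if len(self.members) != 3:
            raise ValueError("a stable topic has exactly one member per run")
        if abs(float(self.word_dist.sum()) - 1.0) > 1e-8:
            raise ValueError("stable topic word_dist must sum to 1")


def extract_stable_topics(
    runs: Sequence[TopicRun],
    similarity_threshold: float = 0.8,
) -> list[StableTopic]:
    """Match topics across three runs; keep mutual-best triples.

    A stable topic is a triple (one topic per run) in which every pair is the
    other's best match by cosine similarity between topic-word distributions
    and all three pairwise similarities reach the threshold.  Topics without
    such a triple are dropped; each topic joins at most one stable topic.
    Ties in argmax resolve to the lowest index.
    """
    if len(runs) != 3:
        raise ValueError("stable-topic extraction expects exactly 3 runs")
    v0 = runs[0].topic_word.shape[1]
    if any(r.topic_word.shape[1] != v0 for r in runs):
        raise ValueError("runs have mismatched vocabularies")

    s01 = cosine_similarity(runs[0].topic_word, runs[1].topic_word)
    s02 = cosine_similarity(runs[0].topic_word, runs[2].topic_word)
    s12 = cosine_similarity(runs[1].topic_word, runs[2].topic_word)

    stables: list[StableTopic] = []
    for i in range(runs[0].K):
        j = int(np.argmax(s01[i]))
        k = int(np.argmax(s02[i]))
        # mutual-best in all six directions keeps the triple unambiguous
        if int(np.argmax(s01[:, j])) != i or int(np.argmax(s02[:, k])) != i:
            continue
        if int(np.argmax(s12[j])) != k or int(np.argmax(s12[:, k])) != j:
            continue
        if min(s01[i, j], s02[i, k], s12[j, k]) < similarity_threshold:
            continue
        wd = (runs[0].topic_word[i] + runs[1].topic_word[j] + runs[2].topic_word[k]) / 3.0
        wd = wd / wd.sum()
        stables.append(StableTopic(f"S{len(stables):04d}", (i, j, k), wd))
    logger.info("extract_stable_topics: %d stable topics from K=%d (threshold %.2f)",
                len(stables), runs[0].K, similarity_threshold)
    return stables


def stable_pwc(
    stable_topics: Sequence[StableTopic],
    loads: Sequence[NoteTopicLoads],
) -> np.ndarray:
    """Per-note PWC for each stable topic: median of the 3 member PWCs.

    Returns an (n_notes, n_stable) array aligned with ``loads[0].note_ids``.
    The median of three is invariant to run order.
    """
    if len(loads) != 3:
        raise ValueError("stable PWC needs loads from exactly 3 runs")
    for ld in loads[1:]:
        if not np.array_equal(ld.note_ids, loads[0].note_ids):
            raise ValueError("loads are not aligned on the same notes")
    if not stable_topics:
        return np.zeros((len(loads[0].note_ids), 0))
    pwcs = [ld.pwc for ld in loads]
    cols = []
    for st in stable_topics:
        trio = np.stack([pwcs[r][:, st.members[r]] for r in range(3)], axis=1)
        cols.append(np.median(trio, axis=1))
    return np.stack(cols, axis=1)


@dataclass(frozen=True)
class PresenceParams:
    """Thresholds of the piecewise presence function (in pseudo words)."""

    lower: float = 2.0
    upper: float = 10.0

    def __post_init__(self):
        if not (0 < self.lower < self.upper):
            raise ValueError("presence thresholds must satisfy 0 < lower < upper")


def presence(pwc, params: PresenceParams = PresenceParams()):
    """Degree of topic presence in a note, as a function of its PWC.

    presence = 0 for PWC < lower; PWC/upper for lower <= PWC <= upper;
    1 for PWC > upper (defaults 2.0 and 10.0).  Vectorized; scalar in,
    scalar out.
    """
    arr = np.asarray(pwc, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("PWC must be non-negative")
    out = np.where(arr < params.lower, 0.0,
                   np.where(arr > params.upper, 1.0, arr / params.upper))
    if np.isscalar(pwc) or arr.ndim == 0:
        return float(out)
    return out


def patient_topic_presence(
    stable_pwc_matrix: np.ndarray,
    patient_ids: np.ndarray,
    stable_topics: Sequence[StableTopic],
    params: PresenceParams = PresenceParams(),
) -> pd.DataFrame:
    """Patient-level topic features: max presence over the patient's notes.

    Returns a DataFrame indexed by patient_id with one ``topic:<stable_id>``
    column per stable topic, each entry in [0, 1].
    """
    if stable_pwc_matrix.shape[0] != len(patient_ids):
        raise ValueError("PWC matrix and patient_ids are misaligned")
    if stable_pwc_matrix.shape[0] == 0:
        raise ValueError("patient with zero notes: eligibility violated upstream")
    pres = presence(stable_pwc_matrix, params)
    cols = [f"topic:{st.stable_id}" for st in stable_topics]
    df = pd.DataFrame(pres, columns=cols)
    df["__pid"] = patient_ids
    out = df.groupby("__pid", sort=True).max()
    out.index.name = "patient_id"
    return out


def top_terms(stable_topics: Sequence[StableTopic], vocab: np.ndarray, n: int = 10) -> pd.DataFrame:
    """Top-n terms per stable topic (a readable report of what each topic is)."""
    rows = []
    for st in stable_topics:
        order = np.argsort(st.word_dist)[::-1][:n]
        rows.append({"stable_id": st.stable_id,
                     "terms": " ".join(vocab[order]),
                     "weights": " ".join(f"{st.word_dist[i]:.4f}" for i in order)})
    return pd.DataFrame(rows)
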