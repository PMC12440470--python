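"""End-to-end phenotyping pipeline on a synthetic cohort.

Chains the stages per race stratum: generate cohort -> build the note
corpus -> three LDA runs -> stable-topic extraction -> stable PWCs and
patient presence features -> GEM decomposition and structured binarization
-> feature selection/assembly -> CV-tuned linear SVM -> risk scores and
percentiles for the validation stratum.  Returns everything a validation
study needs, plus planted-truth diagnostics (topic recovery, held-out AUC
against the latent labels) that only a synthetic cohort can provide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.metrics.pairwise import cosine_similarity

from . import features as feat
from . import topics as tp
from .gem import GemGraph, GroupLookup, decompose_gem
from .model import DementiaRiskModel, DementiaRiskResults, SvmSpec
from .synthetic import Cohort, CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StratumResult", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for the stages downstream of cohort generation."""

    K: int = 30                        # topics per LDA run
    n_runs: int = 3
    similarity_threshold: float = 0.8
    learn_fraction: float = 0.25       # notes used for topic learning
    lda_max_iter: int = 10
    min_support: int = 10
    presence: tp.PresenceParams = tp.PresenceParams()
    svm: SvmSpec = SvmSpec()
    seed: int = 0


@dataclass
class StratumResult:
    """Fitted pipeline outputs for one race stratum."""

    stratum: str
    stable_topics: list
    vocab: np.ndarray
    train_matrix: feat.FeatureMatrix
    validation_matrix: feat.FeatureMatrix
    results: DementiaRiskResults
    validation_scores: pd.DataFrame    # patient_id, score, percentile
    topic_recovery: pd.DataFrame       # planted topic -> best stable cosine
    validation_auc: float              # scores vs latent truth

    def summary(self) -> str:
        rec = self.topic_recovery
        frac = float((rec["cosine"] >= 0.9).mean()) if len(rec) else float("nan")
        ns = feat.namespace_counts(self.train_matrix)
        lines = [f"stratum {self.stratum}:",
                 f"  stable topics:        {len(self.stable_topics)}",
                 f"  planted topics with cosine >= 0.9: {frac:.0%}",
                 f"  features by namespace: "
                 + ", ".join(f"{k}={v}" for k, v in ns.items()),
                 f"  chosen C:             {self.results.chosen_C:g}",
                 f"  training AUC:         {self.results.training_auc():.3f}",
                 f"  validation AUC (latent truth): {self.validation_auc:.3f}"]
        return "\n".join(lines)


@dataclass
class PipelineResult:
    cohort: Cohort
    strata: dict[str, StratumResult]

    def summary(self) -> str:
        return "\n".join(s.summary() for s in self.strata.values())


def _topic_recovery(cohort: Cohort, stable_topics, corpus_vocab: np.ndarray) -> pd.DataFrame:
    """Cosine of each planted topic against its best stable topic.

    Planted distributions live on the generator vocabulary; stable topics on
    the corpus vocabulary (a subset ordering), so planted rows are projected
    onto the corpus vocabulary first.
    """
    gen_index = {w: i for i, w in enumerate(cohort.vocab)}
    cols = np.array([gen_index[w] for w in corpus_vocab if w in gen_index])
    keep = np.array([w in gen_index for w in corpus_vocab])
    planted = cohort.topics_true[:, cols]
    rows = []
    if stable_topics:
        stable = np.stack([st.word_dist[keep] for st in stable_topics])
        sims = cosine_similarity(planted, stable)
        for t in range(planted.shape[0]):
            j = int(np.argmax(sims[t]))
            rows.append({"planted_topic": t,
                         "best_stable": stable_topics[j].stable_id,
                         "cosine": float(sims[t, j])})
    else:
        rows = [{"planted_topic": t, "best_stable": None, "cosine": 0.0}
                for t in range(planted.shape[0])]
    return pd.DataFrame(rows)


def run_pipeline(
    cohort_config: CohortConfig | None = None,
    pipe: PipelineConfig = PipelineConfig(),
    cohort: Cohort | None = None,
) -> PipelineResult:
    """Run the full phenotyping pipeline; see module docstring."""
    if cohort is None:
        if cohort_config is None:
            cohort_config = CohortConfig()
        cohort = generate_cohort(cohort_config)
    config = cohort.config
    groups = decompose_gem(GemGraph.from_edges(cohort.gem_spec.edges))
    lookup = GroupLookup(groups)

    strata: dict[str, StratumResult] = {}
    for stratum in config.race_strata:
        pats = cohort.patients[cohort.patients["race_stratum"] == stratum]
        pids = set(pats["patient_id"])
        notes = [n for n in cohort.notes if n.patient_id in pids]
        corpus = tp.build_corpus(notes)

        rng = np.random.default_rng(pipe.seed)
        if pipe.learn_fraction < 1.0:
            n_learn = max(1, int(round(pipe.learn_fraction * corpus.n_notes)))
            learn_idx = np.sort(rng.choice(corpus.n_notes, n_learn, replace=False))
            learn_corpus = corpus.subset(learn_idx)
        else:
            learn_corpus = corpus
        logger.info("[%s] corpus: %d notes (%d for learning), vocab %d",
                    stratum, corpus.n_notes, learn_corpus.n_notes, corpus.n_vocab)

        runs = [tp.learn_topics(learn_corpus, pipe.K, pipe.seed + r,
                                run_id=f"{stratum}-run{r}",
                                max_iter=pipe.lda_max_iter)
                for r in range(pipe.n_runs)]
        stable = tp.extract_stable_topics(runs, pipe.similarity_threshold)
        loads = [tp.infer_loads(run, corpus) for run in runs]
        spwc = tp.stable_pwc(stable, loads)
        presences = tp.patient_topic_presence(spwc, corpus.patient_ids, stable,
                                              pipe.presence)

        events = cohort.events[cohort.events["patient_id"].isin(pids)]
        binary = feat.binarize_structured(events, lookup, pats,
                                          config.lookback_years)

        train_pats = pats[pats["split"] == "train"]
        valid_pats = pats[pats["split"] == "validation"]
        selected = feat.select_features(binary.loc[train_pats["patient_id"].sort_values()],
                                        pipe.min_support)
        age_stats = (float(train_pats["age_at_index"].mean()),
                     float(train_pats["age_at_index"].std()))
        prov = {"stratum": stratum, "n_train": len(train_pats),
                "min_support": pipe.min_support, "age_stats": age_stats}
        fm_train = feat.assemble(train_pats, presences, binary, selected,
                                 age_stats, prov)
        fm_valid = feat.assemble(valid_pats, presences, binary, selected,
                                 age_stats, prov)
        # training selection fixes the columns; align validation exactly
        fm_valid.data = fm_valid.data.reindex(columns=fm_train.feature_names,
                                              fill_value=0.0)

        labels = (train_pats.set_index("patient_id")["label"] == "case").astype(int)
        svm = SvmSpec(**{**pipe.svm.__dict__, "seed": pipe.seed})
        results = DementiaRiskModel.from_feature_matrix(fm_train, labels, svm).fit()
        score_frame = results.score_frame(fm_valid)

        truth = cohort.truth.set_index("patient_id")["latent_truth"]
        y_latent = (truth.reindex(score_frame["patient_id"]) == "possible_probable")
        if y_latent.nunique() == 2:
            v_auc = float(roc_auc_score(y_latent.to_numpy(),
                                        score_frame["score"].to_numpy()))
        else:
            v_auc = float("nan")

        strata[stratum] = StratumResult(
            stratum=stratum,
            stable_topics=stable,
            vocab=corpus.vocab,
            train_matrix=fm_train,
            validation_matrix=fm_valid,
            results=results,
            validation_scores=score_frame,
            topic_recovery=_topic_recovery(cohort, stable, corpus.vocab),
            validation_auc=v_auc,
        )
        logger.info("[%s] %s", stratum, strata[stratum].summary())
    return PipelineResult(cohort, strata)
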