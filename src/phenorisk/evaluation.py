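"""Design-based validation of the risk score.

The validation design verifies dementia status (by chart review, here
simulated from the latent truth) for a subsample of the scored validation
population: a simple random sample (SRS) of the whole frame plus stratified
draws that oversample the upper score percentiles.  Because sampling is
outcome-dependent through the score, every estimate is inverse-probability
weighted (IPW): each reviewed patient counts 1/pi times, where pi is their
inclusion probability under the two-phase design.  Screening
characteristics (prevalence, sensitivity, specificity, PPV, NPV, accuracy)
come from the weighted 2x2 table at percentile cutoffs of the full
validation score distribution; AUC is the area under the weighted empirical
ROC; confidence intervals are percentile bootstrap, resampling within the
sampling strata so the design stays fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingDesign",
    "draw_review_sample",
    "simulate_chart_review",
    "ScreeningEstimates",
    "ipw_estimates",
    "weighted_auc",
    "bootstrap_ci",
    "cohens_kappa",
    "prevalence_by_stratum",
    "screening_table",
]

POSITIVE_LABELS = frozenset({"possible", "probable"})


@dataclass(frozen=True)
class SamplingDesign:
    """Two-phase chart-review sampling design.

    Phase 1: SRS of ``n_srs`` from the full frame.  Phase 2: from the
    remaining frame, ``n_mid`` from the (75, 90] percentile stratum and
    ``n_per_band`` from each 1-percentile band partitioning (90, 100].
    Defaults total 200 + 100 + 10 x 30 = 600 reviewed patients.
    """

    n_srs: int = 200
    mid_stratum: tuple[float, float] = (75.0, 90.0)
    n_mid: int = 100
    band_start: float = 90.0
    band_width: float = 1.0
    n_per_band: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.n_srs < 0 or self.n_mid < 0 or self.n_per_band < 1:
            raise ValueError("sample sizes must be >= 1 (n_srs/n_mid may be 0)")
        n_bands = (100.0 - self.band_start) / self.band_width
        if abs(n_bands - round(n_bands)) > 1e-9:
            raise ValueError("bands must partition (band_start, 100]")
        if not (self.mid_stratum[0] < self.mid_stratum[1] <= self.band_start):
            raise ValueError("mid stratum must precede the upper bands")

    @property
    def bands(self) -> list[tuple[float, float]]:
        n = int(round((100.0 - self.band_start) / self.band_width))
        return [(self.band_start + i * self.band_width,
                 self.band_start + (i + 1) * self.band_width) for i in range(n)]

    @property
    def total(self) -> int:
        return self.n_srs + self.n_mid + self.n_per_band * len(self.bands)


def _stratum_masks(percentile: np.ndarray, design: SamplingDesign) -> dict[str, np.ndarray]:
    masks = {}
    lo, hi = design.mid_stratum
    if design.n_mid > 0:
        masks["mid"] = (percentile > lo) & (percentile <= hi)
    for blo, bhi in design.bands:
        masks[f"band_{blo:g}_{bhi:g}"] = (percentile > blo) & (percentile <= bhi)
    return masks


def draw_review_sample(score_frame: pd.DataFrame, design: SamplingDesign) -> pd.DataFrame:
    """Draw the chart-review sample and attach inclusion probabilities.

    ``score_frame`` must carry patient_id, score and percentile columns for
    the FULL validation stratum.  The SRS is drawn first from the whole
    frame; stratified draws then come from the remaining frame.  Inclusion
    probability follows the two-phase union convention
    ``pi = 1 - (1 - pi_srs) (1 - pi_h)`` with ``pi_srs = n_srs / N`` and
    ``pi_h = n_h / N_h`` (N_h counted on the full frame); patients outside
    every design stratum have ``pi = pi_srs``.

    Returns the reviewed subframe with ``stratum`` (the phase that drew the
    patient) and ``pi`` columns.  Raises if any stratum cannot supply its n.
    """
    frame = score_frame.reset_index(drop=True)
    n = len(frame)
    if design.n_srs > n:
        raise ValueError(f"SRS size {design.n_srs} exceeds frame size {n}")
    rng = np.random.default_rng(design.seed)
    pct = frame["percentile"].to_numpy(dtype=np.float64)
    masks = _stratum_masks(pct, design)

    pi_srs = design.n_srs / n
    pi = np.full(n, pi_srs)
    stratum_n = {"mid": design.n_mid}
    for name in masks:
        if name.startswith("band_"):
            stratum_n[name] = design.n_per_band
    for name, mask in masks.items():
        n_h = int(mask.sum())
        if n_h < stratum_n[name]:
            raise ValueError(f"stratum {name} has {n_h} patients, needs {stratum_n[name]}")
        pi_h = stratum_n[name] / n_h
        pi[mask] = 1.0 - (1.0 - pi_srs) * (1.0 - pi_h)

    srs_idx = rng.choice(n, size=design.n_srs, replace=False)
    taken = np.zeros(n, dtype=bool)
    taken[srs_idx] = True
    chosen = [(srs_idx, "srs")]
    for name, mask in masks.items():
        avail = np.flatnonzero(mask & ~taken)
        need = stratum_n[name]
        if len(avail) < need:
            raise ValueError(f"stratum {name}: only {len(avail)} left after SRS, needs {need}")
        pick = rng.choice(avail, size=need, replace=False)
        taken[pick] = True
        chosen.append((pick, name))

    parts = []
    for idx, name in chosen:
        part = frame.iloc[idx].copy()
        part["stratum"] = name
        part["pi"] = pi[idx]
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    if np.any(out["pi"] <= 0) or np.any(out["pi"] > 1):
        raise AssertionError("inclusion probabilities must lie in (0, 1]")
    return out


def simulate_chart_review(
    reviewed: pd.DataFrame,
    truth: pd.DataFrame,
    reviewer_sensitivity: float = 1.0,
    reviewer_specificity: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Stand-in for the human chart review, driven by the latent truth.

    Latent positives are labelled "possible" or "probable" (equiprobably)
    and missed with probability 1 - sensitivity; latent negatives are
    labelled "none" and falsely flagged "possible" with probability
    1 - specificity.  Adjudication of uncertain reviews is not modelled.
    """
    rng = np.random.default_rng(seed)
    lut = truth.set_index("patient_id")["latent_truth"]
    out = reviewed.copy()
    labels = []
    for pid in out["patient_id"]:
        true_pos = lut.loc[pid] == "possible_probable"
        if true_pos:
            if rng.random() < reviewer_sensitivity:
                labels.append("probable" if rng.random() < 0.5 else "possible")
            else:
                labels.append("none")
        else:
            labels.append("possible" if rng.random() >= reviewer_specificity else "none")
    out["review_label"] = labels
    return out


@dataclass
class ScreeningEstimates:
    """Point estimates of the screening characteristics at one cutoff."""

    cutoff_percentile: float
    cutoff_value: float
    prevalence: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "cutoff_percentile": self.cutoff_percentile,
            "cutoff_value": self.cutoff_value,
            "prevalence": self.prevalence,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "auc": self.auc,
        }


def _positive_mask(reviewed: pd.DataFrame,
                   positive_labels: frozenset = POSITIVE_LABELS) -> np.ndarray:
    return reviewed["review_label"].isin(positive_labels).to_numpy()


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("ipw_estimates: zero weighted margin for %s -> missing", what)
        return float("nan")
    return num / den


def ipw_estimates(
    reviewed: pd.DataFrame,
    full_scores: np.ndarray,
    cutoff_percentile: float,
    positive_labels: frozenset = POSITIVE_LABELS,
) -> ScreeningEstimates:
    """Weighted screening characteristics at one percentile cutoff.

    The cutoff value is the empirical quantile (linear interpolation) of the
    FULL validation stratum's scores; a patient is flagged iff their score is
    strictly above it.  All rates come from the 1/pi-weighted 2x2 table, so
    the Bayes identity between PPV, prevalence, sensitivity and specificity
    holds exactly.  Undefined rates (zero weighted margin) are returned as
    NaN with a log entry.
    """
    if reviewed["pi"].min() <= 0:
        raise ValueError("inclusion probabilities must be positive")
    cutoff_value = float(np.quantile(np.asarray(full_scores, dtype=np.float64),
                                     cutoff_percentile / 100.0))
    w = (1.0 / reviewed["pi"]).to_numpy()
    pos = _positive_mask(reviewed, positive_labels)
    flag = reviewed["score"].to_numpy() > cutoff_value

    tp = float(w[pos & flag].sum())
    fn = float(w[pos & ~flag].sum())
    fp = float(w[~pos & flag].sum())
    tn = float(w[~pos & ~flag].sum())
    total = tp + fn + fp + tn

    return ScreeningEstimates(
        cutoff_percentile=cutoff_percentile,
        cutoff_value=cutoff_value,
        prevalence=_safe_div(tp + fn, total, "prevalence"),
        sensitivity=_safe_div(tp, tp + fn, "sensitivity"),
        specificity=_safe_div(tn, tn + fp, "specificity"),
        ppv=_safe_div(tp, tp + fp, "PPV"),
        npv=_safe_div(tn, tn + fn, "NPV"),
        accuracy=_safe_div(tp + tn, total, "accuracy"),
        auc=weighted_auc(reviewed, positive_labels),
    )


def weighted_auc(reviewed: pd.DataFrame,
                 positive_labels: frozenset = POSITIVE_LABELS) -> float:
    """Area under the weighted empirical ROC curve.

    Equals the weighted pairwise concordance probability: the chance that a
    random weighted positive outscores a random weighted negative, ties
    counting half.  Returns NaN when either class has zero weight.
    """
    scores = reviewed["score"].to_numpy(dtype=np.float64)
    w = (1.0 / reviewed["pi"]).to_numpy(dtype=np.float64)
    pos = _positive_mask(reviewed, positive_labels)
    return _weighted_auc_arrays(scores, pos, w)


def _weighted_auc_arrays(scores: np.ndarray, pos: np.ndarray, w: np.ndarray) -> float:
    w_pos_tot = w[pos].sum()
    w_neg_tot = w[~pos].sum()
    if w_pos_tot == 0 or w_neg_tot == 0:
        logger.warning("weighted_auc: single-class input -> missing")
        return float("nan")
    order = np.argsort(scores, kind="mergesort")
    s, p, ww = scores[order], pos[order], w[order]
    # group tied scores; within a tie, pos-vs-neg pairs count half
    uniq, start = np.unique(s, return_index=True)
    bounds = np.append(start, len(s))
    concordant = 0.0
    cum_neg = 0.0
    for i in range(len(uniq)):
        seg = slice(bounds[i], bounds[i + 1])
        wp = ww[seg][p[seg]].sum()
        wn = ww[seg][~p[seg]].sum()
        concordant += wp * (cum_neg + 0.5 * wn)
        cum_neg += wn
    return float(concordant / (w_pos_tot * w_neg_tot))


def bootstrap_ci(
    statistic: Callable[[pd.DataFrame], float],
    reviewed: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI, resampling within sampling strata.

    Each stratum is resampled with replacement at its own size, keeping the
    verification design fixed across resamples.  Deterministic given seed.
    A statistic that is constant across all resamples yields a zero-width
    interval (warned).
    """
    if B < 100:
        raise ValueError("B must be >= 100 for a percentile interval")
    rng = np.random.default_rng(seed)
    df = reviewed.reset_index(drop=True)
    groups = [np.flatnonzero((df["stratum"] == s).to_numpy())
              for s in sorted(df["stratum"].unique())]
    stats = np.empty(B)
    for b in range(B):
        idx = np.concatenate([g[rng.integers(0, len(g), len(g))] for g in groups])
        stats[b] = statistic(df.take(idx))
    stats = stats[~np.isnan(stats)]
    if len(stats) == 0:
        logger.warning("bootstrap_ci: statistic undefined in every resample")
        return float("nan"), float("nan")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    if lo == hi:
        logger.warning("bootstrap_ci: degenerate statistic -> zero-width interval")
    return float(lo), float(hi)


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> tuple[float, float]:
    """Cohen's kappa for two raters plus its large-sample standard error.

    kappa = (p_o - p_e) / (1 - p_e); SE = sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)).
    Two constant, identical raters (p_e = 1) return kappa = 1 by convention.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need >= 2 paired ratings")
    cats = np.unique(np.concatenate([a, b]))
    n = len(a)
    ai = np.searchsorted(cats, a)
    bi = np.searchsorted(cats, b)
    table = np.zeros((len(cats), len(cats)))
    np.add.at(table, (ai, bi), 1.0)
    p = table / n
    p_o = float(np.trace(p))
    p_e = float(p.sum(axis=1) @ p.sum(axis=0))
    if p_e >= 1.0 - 1e-15:
        logger.info("cohens_kappa: both raters constant and equal -> kappa=1")
        return 1.0, 0.0
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = float(np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2)))
    return float(kappa), se


def prevalence_by_stratum(
    reviewed: pd.DataFrame,
    bands: Sequence[tuple[float, float]] = ((0, 50), (50, 75), (75, 90), (90, 95), (95, 100)),
    positive_labels: frozenset = POSITIVE_LABELS,
) -> pd.DataFrame:
    """Weighted prevalence of verified positives per score-percentile band.

    Bands with no reviewed patients are reported as missing.
    """
    w = (1.0 / reviewed["pi"]).to_numpy()
    pos = _positive_mask(reviewed, positive_labels)
    pct = reviewed["percentile"].to_numpy()
    rows = []
    for lo, hi in bands:
        mask = (pct > lo) & (pct <= hi)
        if not mask.any():
            rows.append({"band_lo": lo, "band_hi": hi, "n_reviewed": 0,
                         "prevalence": float("nan")})
            continue
        rows.append({
            "band_lo": lo, "band_hi": hi, "n_reviewed": int(mask.sum()),
            "prevalence": float(w[mask & pos].sum() / w[mask].sum()),
        })
    return pd.DataFrame(rows)


def screening_table(
    reviewed: pd.DataFrame,
    full_scores: np.ndarray,
    cutoffs: Sequence[float] = (50, 75, 90, 95),
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Screening characteristics with bootstrap CIs at several cutoffs.

    One row per (cutoff, metric) with estimate, lo and hi — the tabular
    deliverable of the validation stage.
    """
    metrics = ("prevalence", "sensitivity", "specificity", "ppv", "npv",
               "accuracy", "auc")
    rows = []
    for cut in cutoffs:
        est = ipw_estimates(reviewed, full_scores, cut)
        for m in metrics:
            lo, hi = bootstrap_ci(
                lambda df, _m=m, _c=cut: getattr(
                    ipw_estimates(df, full_scores, _c), _m),
                reviewed, B=B, seed=seed, level=level)
            rows.append({"cutoff": cut, "metric": m,
                         "estimate": getattr(est, m), "lo": lo, "hi": hi})
    return pd.DataFrame(rows)
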