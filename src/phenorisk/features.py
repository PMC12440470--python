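"""Per-patient feature assembly.

Combines three blocks into one design matrix per race stratum:

* demographics — age in years at the index date (z-scored against the
  training stratum) and sex encoded {0, 1};
* stable-topic presences in [0, 1];
* binary structured indicators — 1 iff the patient had at least one
  qualifying event of that era-spanning ICD group / CPT code / medication /
  note type inside their 3-year lookback window.

Structured candidates are kept only when they appear in at least
``min_support`` training patients (default 10), computed on the training
stratum alone; topic and demographic columns are always retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .gem import GroupLookup
from .synthetic import DAYS_PER_YEAR

logger = logging.getLogger(__name__)

__all__ = [
    "binarize_structured",
    "select_features",
    "assemble",
    "FeatureMatrix",
    "namespace_counts",
]

_NAMESPACES = ("cpt", "demo", "icd_group", "med", "notetype", "topic")


def _feature_name(system: str, code: str, lookup: GroupLookup | None) -> str | None:
    if system in ("ICD9", "ICD10"):
        if lookup is None:
            raise ValueError("ICD events require a GEM group lookup")
        return f"icd_group:{lookup.lookup(system, code)}"
    if system == "CPT":
        return f"cpt:{code}"
    if system == "MED":
        return f"med:{code}"
    if system == "NOTETYPE":
        return f"notetype:{code}"
    return None


def binarize_structured(
    events: pd.DataFrame,
    lookup: GroupLookup,
    patients: pd.DataFrame,
    lookback_years: int = 3,
) -> pd.DataFrame:
    """Binary presence indicators per patient over the lookback window.

    ``events`` has columns patient_id, event_date, system, code; ``patients``
    supplies each patient's index_date.  An event is qualifying iff its date
    lies in [index - lookback, index); events outside the window are ignored
    with a log entry (this is where case index-date dementia codes drop out).
    Indicators record presence, not counts.
    """
    idx = patients.set_index("patient_id")["index_date"]
    idx = pd.to_datetime(idx)
    ev = events.merge(idx.rename("index_date"), left_on="patient_id",
                      right_index=True, how="inner")
    window_days = DAYS_PER_YEAR * lookback_years
    start = ev["index_date"] - pd.to_timedelta(window_days, unit="D")
    in_window = (ev["event_date"] >= start) & (ev["event_date"] < ev["index_date"])
    n_out = int((~in_window).sum())
    if n_out:
        logger.info("binarize_structured: ignoring %d events outside the lookback window", n_out)
    ev = ev[in_window]

    names = [
        _feature_name(s, c, lookup)
        for s, c in zip(ev["system"].to_numpy(), ev["code"].to_numpy())
    ]
    pairs = pd.DataFrame({"patient_id": ev["patient_id"].to_numpy(), "feature": names})
    pairs = pairs.dropna().drop_duplicates()
    wide = pd.crosstab(pairs["patient_id"], pairs["feature"]).astype(np.int8)
    wide = wide.reindex(index=patients["patient_id"].sort_values(), fill_value=0)
    wide.index.name = "patient_id"
    wide.columns.name = None
    return wide.sort_index(axis=1)


def select_features(binary_train: pd.DataFrame, min_support: int = 10) -> list[str]:
    """Structured columns present in >= ``min_support`` training patients.

    Selection is computed on the training stratum only; validation data can
    never change it.  Topic and demographic features are not subject to this
    filter (they are always retained by :func:`assemble`).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    support = (binary_train > 0).sum(axis=0)
    kept = sorted(support.index[support >= min_support])
    logger.info("select_features: kept %d/%d structured features (min_support=%d)",
                len(kept), binary_train.shape[1], min_support)
    return kept


@dataclass
class FeatureMatrix:
    """Design matrix with namespaced, deterministically ordered columns.

    Column namespaces: ``demo:age`` (continuous; z-scored when ``age_stats``
    is set), ``demo:sex`` ({0,1}, 1 = male), ``topic:<id>`` ([0,1]),
    ``icd_group:<id>`` / ``cpt:<code>`` / ``med:<code>`` / ``notetype:<code>``
    ({0,1}).  ``provenance`` records the training stratum whose data fixed
    the structured-column selection and the age scaling.
    """

    data: pd.DataFrame            # index patient_id, columns sorted
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        cols = list(self.data.columns)
        if cols != sorted(cols):
            raise ValueError("feature columns must be sorted by namespace then name")
        bad = [c for c in cols if c.split(":", 1)[0] not in _NAMESPACES]
        if bad:
            raise ValueError(f"unknown feature namespaces: {bad[:5]}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.float64)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()


def assemble(
    patients: pd.DataFrame,
    presences: pd.DataFrame,
    binary: pd.DataFrame,
    selected: Iterable[str],
    age_stats: tuple[float, float] | None = None,
    provenance: Mapping | None = None,
) -> FeatureMatrix:
    """Assemble one row per patient from the three feature blocks.

    ``selected`` fixes the structured columns (from training-stratum
    selection); patients missing a structured column get 0.  ``age_stats``
    is the training (mean, sd) used to z-score age; None leaves age in
    years.  Column order is deterministic (sorted namespace:name).  Every
    patient must have a presence vector (notes are an eligibility
    requirement upstream).
    """
    pats = patients.set_index("patient_id")
    missing = pats.index.difference(presences.index)
    if len(missing):
        raise ValueError(f"patients missing topic presence vectors: {list(missing[:5])}")

    demo = pd.DataFrame(index=pats.index)
    age = pats["age_at_index"].astype(float)
    if age_stats is not None:
        mean, sd = age_stats
        if sd <= 0:
            raise ValueError("age sd must be positive to standardize")
        age = (age - mean) / sd
    demo["demo:age"] = age
    demo["demo:sex"] = (pats["sex"] == "M").astype(float)

    topic = presences.reindex(pats.index)
    struct = binary.reindex(index=pats.index, columns=list(selected), fill_value=0)
    struct = struct.fillna(0).astype(float)

    data = pd.concat([demo, topic.astype(float), struct], axis=1)
    data = data.sort_index(axis=1).sort_index(axis=0)
    zero_cols = data.columns[(data != 0).sum(axis=0) == 0]
    drop = [c for c in zero_cols if not c.startswith(("demo:", "topic:"))]
    if drop:
        # selection should preclude this; guard against degenerate inputs
        logger.warning("assemble: dropping %d all-zero structured columns", len(drop))
        data = data.drop(columns=drop)
    return FeatureMatrix(data, dict(provenance or {}))


def namespace_counts(fm: FeatureMatrix) -> pd.Series:
    """Feature counts per namespace (they sum to the total column count)."""
    ns = pd.Series([c.split(":", 1)[0] for c in fm.feature_names])
    return ns.value_counts().sort_index()
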