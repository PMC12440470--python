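"""Synthetic EHR cohort generator.

Emulates the study-design skeleton of a dementia-phenotyping cohort drawn
from a large health-system data warehouse: per-patient dated clinical notes
whose word content comes from a known topic model, dated structured events
(ICD-9/ICD-10 diagnoses straddling a coding-transition date, procedure
codes, medication fills, note types), demographics, case/control labels
under 3-year lookback eligibility rules, and — for controls — a latent
undiagnosed-dementia truth label that downstream validation tries to
recover.  Cases and latent-positive controls draw their notes from a topic
mixture that upweights designated "signal" topics and carry elevated rates
of designated risk codes; everything else is background.

The generator also fabricates a GEM-style tab-delimited ICD-9<->ICD-10
crosswalk with known connected-component structure, so the code-grouping
stage can be validated against planted truth.

All randomness flows through one ``numpy.random.default_rng(seed)``; the
same config yields byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "CohortConfig",
    "PatientRecord",
    "NoteDoc",
    "CodeEvent",
    "GroupSpec",
    "GemSpec",
    "default_gem_spec",
    "write_gem_file",
    "Cohort",
    "generate_cohort",
    "check_eligibility",
    "write_cohort",
]

DAYS_PER_YEAR = 365  # synthetic calendar: lookback years are 365-day blocks


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Counts are per race stratum.  ``latent_prevalence`` is the fraction of
    controls who carry the dementia signal without a recorded diagnosis
    (the quantity the validation design later estimates).
    """

    n_cases: int = 1000
    n_controls: int = 1000
    n_validation_controls: int = 2000
    race_strata: tuple[str, ...] = ("BA",)
    transition_date: date = date(2015, 10, 1)
    lookback_years: int = 3
    signal_topic_ids: tuple[int, ...] = (0, 1)
    latent_prevalence: float = 0.04
    seed: int = 0

    # note-content model (standard LDA generative process)
    n_topics_true: int = 20
    vocab_size: int = 500
    notes_per_year: float = 8.0
    note_length: tuple[int, int] = (50, 200)
    alpha_background: float = 0.25
    alpha_signal_base: float = 0.02
    signal_boost: float = 1.5
    topic_block_mass: float = 0.8

    # demographics
    male_fraction: float = 0.97
    case_age: tuple[float, float] = (72.4, 4.8)      # mean, sd (years)
    control_age: tuple[float, float] = (69.1, 3.7)
    index_start: date = date(2013, 1, 1)
    index_end: date = date(2018, 9, 12)

    # structured-event model
    n_icd_groups: int = 40
    n_risk_icd_groups: int = 3
    n_cpt: int = 30
    n_risk_cpt: int = 2
    n_med: int = 20
    n_risk_med: int = 2
    n_notetypes: int = 8
    risk_rate_positive: float = 0.6
    risk_rate_negative: float = 0.08
    med_fills_per_window: float = 2.0
    diagnosis_prob_per_visit: float = 0.6

    excluded_meds: tuple[str, ...] = (
        "DONEPEZIL", "GALANTAMINE", "RIVASTIGMINE", "MEMANTINE")
    dementia_icd9: tuple[str, ...] = ("331.0", "290.40")
    dementia_icd10: tuple[str, ...] = ("G30.9", "F03.90")

    def validate(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_validation_controls) <= 0:
            raise ConfigError("all cohort counts must be > 0")
        if not self.race_strata:
            raise ConfigError("at least one race stratum is required")
        if not (0.0 <= self.latent_prevalence <= 1.0):
            raise ConfigError("latent_prevalence must lie in [0, 1]")
        if self.lookback_years < 1:
            raise ConfigError("lookback_years must be >= 1")
        if self.n_topics_true < 2 or self.vocab_size < self.n_topics_true:
            raise ConfigError("need >= 2 true topics and vocab_size >= n_topics_true")
        if any(t < 0 or t >= self.n_topics_true for t in self.signal_topic_ids):
            raise ConfigError("signal_topic_ids out of range")
        if not (0 < self.note_length[0] <= self.note_length[1]):
            raise ConfigError("note_length must be a positive (lo, hi) pair")
        if not (0.0 < self.male_fraction <= 1.0):
            raise ConfigError("male_fraction must lie in (0, 1]")
        if self.index_start >= self.index_end:
            raise ConfigError("index_start must precede index_end")
        if self.n_risk_icd_groups > self.n_icd_groups:
            raise ConfigError("more risk ICD groups than ICD groups")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    race_stratum: str
    sex: str                      # "M" | "F"
    age_at_index: float           # years
    index_date: date
    label: str                    # "case" | "control"
    latent_truth: str | None      # controls only: "none" | "possible_probable"

    def __post_init__(self):
        if self.label == "case":
            if self.age_at_index < 65:
                raise ValueError("cases must be diagnosed after age 65")
            if self.latent_truth is not None:
                raise ValueError("latent_truth is defined only for controls")
        elif self.label == "control":
            if self.latent_truth not in ("none", "possible_probable"):
                raise ValueError("controls need a latent_truth label")
        else:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class NoteDoc:
    note_id: str
    patient_id: str
    note_date: date
    tokens: list[str]

    @property
    def word_count(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class CodeEvent:
    patient_id: str
    event_date: date
    system: str                   # ICD9 | ICD10 | CPT | MED | NOTETYPE
    code: str


@dataclass(frozen=True)
class GroupSpec:
    """One planted crosswalk component: its codes and its connecting edges."""

    icd9: tuple[str, ...]
    icd10: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class GemSpec:
    groups: tuple[GroupSpec, ...]

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [e for g in self.groups for e in g.edges]


def default_gem_spec(config: CohortConfig) -> GemSpec:
    """Fabricate a crosswalk with known component structure.

    Component shapes cycle through 1:1, 2:1, 1:2, 2:2 and 3:2 patterns; the
    first ``n_risk_icd_groups`` components are the "risk" diagnosis groups,
    and a dementia component built from real dementia codes is appended
    (used only to stamp case index events).
    """
    shapes = [(1, 1), (2, 1), (1, 2), (2, 2), (3, 2)]
    groups: list[GroupSpec] = []
    for g in range(config.n_icd_groups):
        n9, n10 = shapes[g % len(shapes)]
        icd9 = tuple(f"{100 + g}.{j}" for j in range(n9))
        icd10 = tuple(f"A{g:03d}.{j}" for j in range(n10))
        # star pattern keeps the component connected
        edges = tuple((icd9[0], c10) for c10 in icd10) + tuple(
            (c9, icd10[0]) for c9 in icd9[1:])
        groups.append(GroupSpec(icd9, icd10, edges))
    d9, d10 = config.dementia_icd9, config.dementia_icd10
    dem_edges = tuple((d9[0], c10) for c10 in d10) + tuple((c9, d10[0]) for c9 in d9[1:])
    groups.append(GroupSpec(d9, d10, dem_edges))
    return GemSpec(tuple(groups))


def write_gem_file(group_spec: GemSpec | Iterable[tuple[str, str]], path) -> None:
    """Write a tab-delimited ``icd9<TAB>icd10`` edge file (CMS GEM layout).

    Duplicate edges are written once (logged).  An empty spec yields an
    empty file.
    """
    edges = group_spec.edges if isinstance(group_spec, GemSpec) else list(group_spec)
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in edges:
            if (a, b) in seen:
                n_dup += 1
                continue
            seen.add((a, b))
            fh.write(f"{a}\t{b}\n")
    if n_dup:
        logger.info("write_gem_file: dropped %d duplicate edges", n_dup)


@dataclass
class Cohort:
    """Everything one synthetic study generates, bundled."""

    config: CohortConfig
    patients: pd.DataFrame        # patient_id, race_stratum, sex, age_at_index,
                                  # index_date, label, split, latent_truth,
                                  # window_starts_before_65
    notes: list[NoteDoc]
    events: pd.DataFrame          # patient_id, event_date (Timestamp), system, code
    truth: pd.DataFrame           # patient_id, split, latent_truth (controls)
    gem_spec: GemSpec
    topics_true: np.ndarray       # (n_topics_true, vocab_size)
    vocab: np.ndarray

    def notes_of(self, patient_id: str) -> list[NoteDoc]:
        return [n for n in self.notes if n.patient_id == patient_id]


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _planted_topics(config: CohortConfig) -> np.ndarray:
    """Block topic-word matrix: each topic concentrates on its own word block."""
    K, V = config.n_topics_true, config.vocab_size
    block = V // K
    topics = np.full((K, V), (1.0 - config.topic_block_mass) / V)
    for t in range(K):
        topics[t, t * block:(t + 1) * block] += config.topic_block_mass / block
    return topics / topics.sum(axis=1, keepdims=True)


def _pool_probs(n: int) -> np.ndarray:
    """Mildly skewed popularity distribution over a code pool."""
    p = 1.0 / (np.arange(n) + 1.5)
    return p / p.sum()


def generate_cohort(config: CohortConfig, verify: bool = False) -> Cohort:
    """Generate a full synthetic cohort under the given study conditions.

    Per stratum: ``n_cases`` cases and ``n_controls`` controls (training
    split) plus ``n_validation_controls`` controls (validation split).  Each
    patient receives >= 2 note-bearing visits in each lookback year by
    construction, so every emitted patient passes :func:`check_eligibility`
    (assertable with ``verify=True``; intended for small cohorts).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    topics_true = _planted_topics(config)
    vocab = np.array([f"w{i:04d}" for i in range(config.vocab_size)])
    gem_spec = default_gem_spec(config)

    risk_groups = gem_spec.groups[:config.n_risk_icd_groups]
    background_groups = gem_spec.groups[config.n_risk_icd_groups:config.n_icd_groups]
    bg_probs = _pool_probs(len(background_groups))

    cpt_pool = [f"CPT{900 + i}" for i in range(config.n_cpt)]
    risk_cpt = cpt_pool[:config.n_risk_cpt]
    bg_cpt = cpt_pool[config.n_risk_cpt:]
    bg_cpt_probs = _pool_probs(len(bg_cpt))

    med_pool = [f"MED{i:03d}" for i in range(config.n_med)]
    risk_med = med_pool[:config.n_risk_med]
    bg_med = med_pool[config.n_risk_med:]
    bg_med_probs = _pool_probs(len(bg_med))

    notetype_pool = [f"NT{i:02d}" for i in range(config.n_notetypes)]
    nt_probs = _pool_probs(len(notetype_pool))

    K = config.n_topics_true
    alpha_neg = np.full(K, config.alpha_background)
    alpha_neg[list(config.signal_topic_ids)] = config.alpha_signal_base
    alpha_pos = alpha_neg.copy()
    alpha_pos[list(config.signal_topic_ids)] += config.signal_boost

    transition = config.transition_date
    index_span = (config.index_end - config.index_start).days
    lo_len, hi_len = config.note_length

    patient_rows: list[dict] = []
    notes: list[NoteDoc] = []
    event_rows: list[tuple[str, date, str, str]] = []
    note_serial = 0

    def era_code(group: GroupSpec, when: date) -> tuple[str, str]:
        if when < transition:
            return "ICD9", group.icd9[int(rng.integers(len(group.icd9)))]
        return "ICD10", group.icd10[int(rng.integers(len(group.icd10)))]

    def emit_patient(pid: str, stratum: str, label: str, split: str,
                     latent: str | None) -> None:
        nonlocal note_serial
        positive = label == "case" or latent == "possible_probable"
        if label == "case":
            age = float(_truncnorm(rng, *config.case_age, 66.0, 84.0, 1)[0])
        elif positive:  # undiagnosed latent positives skew older, like cases
            age = float(_truncnorm(rng, *config.case_age, 65.2, 84.0, 1)[0])
        else:
            age = float(_truncnorm(rng, *config.control_age, 65.2, 84.0, 1)[0])
        sex = "M" if rng.random() < config.male_fraction else "F"
        index = config.index_start + timedelta(days=int(rng.integers(index_span + 1)))
        alpha = alpha_pos if positive else alpha_neg

        visit_dates: list[date] = []
        for y in range(config.lookback_years):
            n_v = max(2, int(rng.poisson(config.notes_per_year)))
            offsets = rng.choice(DAYS_PER_YEAR, size=n_v, replace=False)
            visit_dates.extend(
                index - timedelta(days=int(DAYS_PER_YEAR * y + off + 1))
                for off in sorted(offsets, reverse=True))
        visit_dates.sort()

        for vd in visit_dates:
            # note content: per-note Dirichlet mixture, tokens iid from it
            theta = rng.dirichlet(alpha)
            length = int(rng.integers(lo_len, hi_len + 1))
            word_counts = rng.multinomial(length, theta @ topics_true)
            tok_idx = np.repeat(np.arange(config.vocab_size), word_counts)
            rng.shuffle(tok_idx)
            notes.append(NoteDoc(f"N{note_serial:07d}", pid, vd, list(vocab[tok_idx])))
            note_serial += 1

            event_rows.append((pid, vd, "NOTETYPE",
                               notetype_pool[int(rng.choice(len(notetype_pool), p=nt_probs))]))
            for _ in range(1 + int(rng.random() < 0.4)):
                event_rows.append((pid, vd, "CPT",
                                   bg_cpt[int(rng.choice(len(bg_cpt), p=bg_cpt_probs))]))
            if rng.random() < config.diagnosis_prob_per_visit:
                grp = background_groups[int(rng.choice(len(background_groups), p=bg_probs))]
                system, code = era_code(grp, vd)
                event_rows.append((pid, vd, system, code))

        n_fills = int(rng.poisson(config.med_fills_per_window))
        for _ in range(n_fills):
            vd = visit_dates[int(rng.integers(len(visit_dates)))]
            event_rows.append((pid, vd, "MED",
                               bg_med[int(rng.choice(len(bg_med), p=bg_med_probs))]))

        rate = config.risk_rate_positive if positive else config.risk_rate_negative
        for grp in risk_groups:
            if rng.random() < rate:
                vd = visit_dates[int(rng.integers(len(visit_dates)))]
                system, code = era_code(grp, vd)
                event_rows.append((pid, vd, system, code))
        for code in risk_cpt:
            if rng.random() < rate:
                vd = visit_dates[int(rng.integers(len(visit_dates)))]
                event_rows.append((pid, vd, "CPT", code))
        for code in risk_med:
            if rng.random() < rate:
                vd = visit_dates[int(rng.integers(len(visit_dates)))]
                event_rows.append((pid, vd, "MED", code))

        if label == "case":
            dem_group = gem_spec.groups[-1]
            system, code = era_code(dem_group, index)
            event_rows.append((pid, index, system, code))

        patient_rows.append({
            "patient_id": pid, "race_stratum": stratum, "sex": sex,
            "age_at_index": round(age, 2), "index_date": index,
            "label": label, "split": split,
            "latent_truth": latent if label == "control" else None,
            "window_starts_before_65": (age - config.lookback_years) < 65.0,
        })

    serial = 0
    for stratum in config.race_strata:
        for _ in range(config.n_cases):
            emit_patient(f"{stratum}{serial:06d}", stratum, "case", "train", None)
            serial += 1
        for split, n in (("train", config.n_controls),
                         ("validation", config.n_validation_controls)):
            latents = rng.random(n) < config.latent_prevalence
            for i in range(n):
                emit_patient(f"{stratum}{serial:06d}", stratum, "control", split,
                             "possible_probable" if latents[i] else "none")
                serial += 1

    patients = pd.DataFrame(patient_rows)
    events = pd.DataFrame(event_rows,
                          columns=["patient_id", "event_date", "system", "code"])
    events["event_date"] = pd.to_datetime(events["event_date"])
    ctrl = patients[patients["label"] == "control"]
    truth = ctrl[["patient_id", "split", "latent_truth"]].reset_index(drop=True)

    cohort = Cohort(config, patients, notes, events, truth, gem_spec,
                    topics_true, vocab)
    if verify:
        events_by_pid = {pid: grp for pid, grp in events.groupby("patient_id")}
        notes_by_pid: dict[str, list[NoteDoc]] = {}
        for nd in notes:
            notes_by_pid.setdefault(nd.patient_id, []).append(nd)
        for row in patients.itertuples():
            ok, reason = check_eligibility(
                row, events_by_pid.get(row.patient_id, events.iloc[0:0]),
                notes_by_pid.get(row.patient_id, []), config)
            if not ok:
                raise AssertionError(f"generated patient {row.patient_id} fails "
                                     f"eligibility: {reason}")
    logger.info("generate_cohort: %d patients, %d notes, %d events",
                len(patients), len(notes), len(events))
    return cohort


def _to_date(d) -> date:
    if isinstance(d, pd.Timestamp):
        return d.date()
    if isinstance(d, date):
        return d
    raise ValueError(f"undated or malformed event date: {d!r}")


def check_eligibility(patient, events, notes: Sequence[NoteDoc],
                      config: CohortConfig) -> tuple[bool, str]:
    """Apply the lookback eligibility rules to one patient.

    Cases pass iff their first dementia code falls after age 65 and each of
    the ``lookback_years`` 365-day years before it contains >= 2 distinct
    non-dementia visit dates with notes.  Controls pass iff they have no
    dementia code ever, no excluded medication fill, >= 2 note-bearing visit
    dates in each lookback year before the index visit, and the lookback
    window starts after age 62.

    ``patient`` needs ``index_date``, ``age_at_index`` and ``label``
    attributes; ``events`` is that patient's event table (DataFrame or
    iterable of :class:`CodeEvent`).  Returns ``(passed, reason)``; undated
    events raise ``ValueError``.
    """
    if isinstance(events, pd.DataFrame):
        ev = [(r.event_date, r.system, r.code) for r in events.itertuples()]
    else:
        ev = [(e.event_date, e.system, e.code) for e in events]
    for d, _, _ in ev:
        if d is None or (isinstance(d, float) and np.isnan(d)) or pd.isna(d):
            raise ValueError("undated event in patient record")
    ev = [(_to_date(d), s, c) for d, s, c in ev]
    note_dates = sorted({nd.note_date for nd in notes})
    for nd in notes:
        if nd.note_date is None:
            raise ValueError("undated note in patient record")

    dem9 = {c.replace(".", "").upper() for c in config.dementia_icd9}
    dem10 = {c.replace(".", "").upper() for c in config.dementia_icd10}

    def is_dementia(system: str, code: str) -> bool:
        norm = code.replace(".", "").upper()
        return (system == "ICD9" and norm in dem9) or (system == "ICD10" and norm in dem10)

    dementia_dates = sorted(d for d, s, c in ev if is_dementia(s, c))
    index = _to_date(patient.index_date)
    label = patient.label

    if label == "case":
        if not dementia_dates:
            return False, "no_dementia_code"
        d0 = dementia_dates[0]
        age_at_d0 = patient.age_at_index - (index - d0).days / 365.25
        if age_at_d0 < 65.0:
            return False, "first_dementia_code_before_age_65"
        visit_pool = [d for d in note_dates if d not in set(dementia_dates)]
        anchor = d0
    elif label == "control":
        if dementia_dates:
            return False, "dementia_code_present"
        for d, s, c in ev:
            if s == "MED" and c.upper() in config.excluded_meds:
                return False, "medication_exclusion"
        if patient.age_at_index - config.lookback_years < 62.0:
            return False, "window_starts_before_age_62"
        visit_pool = note_dates
        anchor = index
    else:
        raise ValueError(f"unknown label {label!r}")

    for y in range(config.lookback_years):
        hi = anchor - timedelta(days=DAYS_PER_YEAR * y)
        lo = anchor - timedelta(days=DAYS_PER_YEAR * (y + 1))
        n_visits = sum(1 for d in visit_pool if lo <= d < hi)
        if n_visits < 2:
            return False, f"visit_count:year_{y + 1}"
    return True, "ok"


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort as plain-text artifacts.

    patients.csv, truth.csv, events.csv (ISO-8601 dates), notes.tsv
    (note_id<TAB>text), manifest.csv (note_id, patient_id, date) and
    gem.tsv (the crosswalk edge file).
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    pats = cohort.patients.copy()
    pats["index_date"] = pats["index_date"].astype(str)
    pats.to_csv(os.path.join(outdir, "patients.csv"), index=False)
    cohort.truth.to_csv(os.path.join(outdir, "truth.csv"), index=False)
    ev = cohort.events.copy()
    ev["event_date"] = ev["event_date"].dt.strftime("%Y-%m-%d")
    ev.to_csv(os.path.join(outdir, "events.csv"), index=False)
    with open(os.path.join(outdir, "notes.tsv"), "w", encoding="utf-8") as fh, \
            open(os.path.join(outdir, "manifest.csv"), "w", encoding="utf-8") as mf:
        mf.write("note_id,patient_id,date\n")
        for nd in cohort.notes:
            fh.write(f"{nd.note_id}\t{' '.join(nd.tokens)}\n")
            mf.write(f"{nd.note_id},{nd.patient_id},{nd.note_date.isoformat()}\n")
    write_gem_file(cohort.gem_spec, os.path.join(outdir, "gem.tsv"))
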