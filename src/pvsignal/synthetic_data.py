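"""Synthetic spontaneous-report generator with known ground truth.

The generator emulates the structure of adverse-event report data — per-drug
report cohorts, configurable odds of cardiac-disorder events, sex/age-band
mixtures, one-or-more event terms per case, drug-name synonyms, occasional
duplicate case versions and dual exposures — so every pipeline stage and the
estimator's statistical behaviour can be exercised without external data.

Ground truth is parameterized on the odds scale: a reference product has
baseline odds ``w`` of being a cardiac case and each product's odds are
``w × multiplier``, so the requested multiplier IS the expected reporting
odds ratio of that product against the reference.

:func:`table1_fixture` is a deterministic, non-random companion: it emits a
report set whose per-drug totals reproduce the published case counts for
the four long-acting muscarinic antagonists, enabling end-to-end
reproduction of the published disproportionality estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import yaml

from .report_model import (
    AgeBand, DrugMention, DrugRole, Report, ReportSet, Sex, write_native,
)
from .vocabulary import Vocabulary, demo_vocabulary

__all__ = [
    "CohortSpec",
    "SyntheticParams",
    "generate",
    "table1_fixture",
    "TABLE1_MARGINALS",
]

#: Non-cardiac preferred terms used for non-case reports.
NON_CARDIAC_PTS = (
    "HEADACHE", "NAUSEA", "COUGH", "DYSPNOEA", "DIZZINESS",
    "DRY MOUTH", "FATIGUE", "RASH", "INSOMNIA", "URINARY RETENTION",
)

_DEFAULT_SEX_MIX = {"F": 0.54, "M": 0.34, "NS": 0.12}
_DEFAULT_AGE_MIX = {
    "under18": 0.01, "18to64": 0.28, "65to85": 0.32, "over85": 0.08, "NS": 0.31,
}


@dataclass(frozen=True)
class CohortSpec:
    """Requested cohort size and odds multiplier for one product."""

    size: int
    odds_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("cohort size must be >= 0")
        if self.odds_multiplier <= 0:
            raise ValueError("odds multiplier must be > 0")


@dataclass
class SyntheticParams:
    """Generator parameters; see the module docstring for the odds model."""

    cohorts: dict[str, CohortSpec]
    baseline_odds: float = 0.111  # event probability ~0.1 for multiplier 1
    sex_mixture: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SEX_MIX))
    age_mixture: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_AGE_MIX))
    mean_extra_event_pts: float = 0.3
    synonym_use_prob: float = 0.5
    duplicate_version_prob: float = 0.05
    dual_exposure_prob: float = 0.0
    window_start: date = date(2020, 1, 1)
    window_end: date = date(2023, 9, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("synonym_use_prob", "duplicate_version_prob", "dual_exposure_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.baseline_odds <= 0:
            raise ValueError("baseline_odds must be > 0")
        if self.mean_extra_event_pts < 0:
            raise ValueError("mean_extra_event_pts must be >= 0")

    def event_probability(self, product_id: str) -> float:
        odds = self.baseline_odds * self.cohorts[product_id].odds_multiplier
        return odds / (1.0 + odds)

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "SyntheticParams":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        cohorts = {
            pid: CohortSpec(int(spec["size"]), float(spec.get("odds_multiplier", 1.0)))
            for pid, spec in doc["cohorts"].items()
        }
        kwargs = {}
        for key in ("baseline_odds", "sex_mixture", "age_mixture",
                    "mean_extra_event_pts", "synonym_use_prob",
                    "duplicate_version_prob", "dual_exposure_prob", "seed"):
            if key in doc:
                kwargs[key] = doc[key]
        for key in ("window_start", "window_end"):
            if key in doc:
                kwargs[key] = date.fromisoformat(str(doc[key]))
        if seed is not None:
            kwargs["seed"] = seed
        return cls(cohorts=cohorts, **kwargs)

    def ground_truth(self) -> dict:
        return {
            "seed": self.seed,
            "baseline_odds": self.baseline_odds,
            "odds_multipliers": {p: s.odds_multiplier for p, s in self.cohorts.items()},
            "event_probabilities": {p: self.event_probability(p) for p in self.cohorts},
            "cohort_sizes": {p: s.size for p, s in self.cohorts.items()},
        }


def _choice_from_mixture(rng: np.random.Generator, mixture: dict[str, float],
                         n: int) -> np.ndarray:
    keys = sorted(mixture)
    probs = np.array([mixture[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(np.array(keys, dtype=object), size=n, p=probs)


def _canonical_synonym(vocab: Vocabulary, product_id: str) -> str:
    syns = vocab.drugs.synonyms_of(product_id)
    return product_id if product_id in syns else syns[0]


def generate(
    params: SyntheticParams,
    out_path: str | Path | None = None,
    vocab: Vocabulary | None = None,
) -> ReportSet:
    """Generate a synthetic report set; deterministic given the seed.

    When ``out_path`` is given the reports are also written in the native
    CSV dialect with the ground-truth parameters echoed to a sidecar
    ``<out_path>.meta.json``.
    """
    if sum(s.size for s in params.cohorts.values()) == 0:
        raise ValueError("all cohort sizes are zero: nothing to generate")
    vocab = vocab or demo_vocabulary()
    cardiac_terms = np.array(
        sorted(vocab.group("cardiac_disorders").terms), dtype=object)
    non_cardiac = np.array(NON_CARDIAC_PTS, dtype=object)
    rng = np.random.default_rng(params.seed)
    n_days = (params.window_end - params.window_start).days + 1
    product_ids = sorted(params.cohorts)

    reports: list[Report] = []
    for pid in product_ids:
        spec = params.cohorts[pid]
        if spec.size == 0:
            continue
        n = spec.size
        p_event = params.event_probability(pid)
        is_case = rng.random(n) < p_event
        sexes = _choice_from_mixture(rng, params.sex_mixture, n)
        ages = _choice_from_mixture(rng, params.age_mixture, n)
        day_offsets = rng.integers(0, n_days, size=n)
        use_syn = rng.random(n) < params.synonym_use_prob
        syns = vocab.drugs.synonyms_of(pid)
        syn_idx = rng.integers(0, len(syns), size=n)
        n_extra = rng.poisson(params.mean_extra_event_pts, size=n)
        dup = rng.random(n) < params.duplicate_version_prob
        dual = rng.random(n) < params.dual_exposure_prob
        other_products = [q for q in product_ids if q != pid]
        dual_idx = rng.integers(0, max(len(other_products), 1), size=n)
        # vectorized main-term draws; extra cardiac terms sampled per case
        main_cardiac = rng.integers(0, len(cardiac_terms), size=n)
        main_other = rng.integers(0, len(non_cardiac), size=n)

        canonical = _canonical_synonym(vocab, pid)
        for i in range(n):
            if is_case[i]:
                pts = [cardiac_terms[main_cardiac[i]]]
                k = min(int(n_extra[i]), len(cardiac_terms) - 1)
                if k:
                    pts.extend(rng.choice(cardiac_terms, size=k, replace=False))
            else:
                pts = [non_cardiac[main_other[i]]]
            verbatim = syns[syn_idx[i]] if use_syn[i] else canonical
            drugs = [DrugMention(verbatim, DrugRole.PRIMARY_SUSPECT)]
            if dual[i] and other_products:
                other = other_products[int(dual_idx[i])]
                drugs.append(DrugMention(_canonical_synonym(vocab, other),
                                         DrugRole.SECONDARY_SUSPECT))
            receipt = params.window_start + timedelta(days=int(day_offsets[i]))
            case_id = f"C-{pid}-{i:06d}"
            rep = Report(
                report_id=f"{pid}-{i:06d}",
                case_id=case_id,
                version=1,
                receipt_date=receipt,
                sex=Sex(str(sexes[i])),
                age_band=AgeBand(str(ages[i])),
                drugs=tuple(drugs),
                events=frozenset(str(t) for t in pts),
            )
            if dup[i]:
                earlier = max(receipt - timedelta(days=30), params.window_start)
                reports.append(Report(
                    report_id=f"{pid}-{i:06d}-v0", case_id=case_id, version=0,
                    receipt_date=earlier, sex=rep.sex, age_band=rep.age_band,
                    drugs=rep.drugs, events=rep.events,
                ))
            reports.append(rep)

    rs = ReportSet(reports, provenance=f"synthetic(seed={params.seed})")
    if out_path is not None:
        out_path = Path(out_path)
        write_native(rs, out_path)
        meta = Path(str(out_path) + ".meta.json")
        meta.write_text(json.dumps(params.ground_truth(), indent=2, sort_keys=True))
    return rs


# ---------------------------------------------------------------------------
# deterministic fixture reproducing the published per-drug marginals

#: Per-product marginals from the published cohort table: total adverse-event
#: cases, cardiac-disorder cases, case-level subgroup counts (arrhythmias,
#: cardiac failure, ischemic heart disease), and the sex split of the
#: cardiac cases (F, M, not specified).
TABLE1_MARGINALS: dict[str, dict] = {
    "tiotropium":     {"ae": 12472, "cd": 1238, "subgroups": (373, 211, 417),
                       "sex": (502, 599, 137)},
    "aclidinium":     {"ae": 1254,  "cd": 188,  "subgroups": (52, 24, 131),
                       "sex": (86, 74, 28)},
    "glycopyrronium": {"ae": 1883,  "cd": 376,  "subgroups": (187, 40, 161),
                       "sex": (207, 128, 41)},
    "umeclidinium":   {"ae": 2599,  "cd": 459,  "subgroups": (194, 92, 92),
                       "sex": (145, 254, 60)},
}

_ARR_PT = "ATRIAL FIBRILLATION"
_HF_PT = "CARDIAC FAILURE"
_IHD_PT = "MYOCARDIAL INFARCTION"
_OTHER_CARDIAC_PT = "CARDIOMEGALY"   # broad group only, no subgroup
_NON_CARDIAC_PT = "COUGH"


def _subgroup_events(idx: int, cd: int, arr: int, hf: int, ihd: int) -> frozenset[str]:
    """Event terms for cardiac case ``idx`` of ``cd`` such that case-level
    subgroup counts hit (arr, hf, ihd) exactly.

    Subgroup blocks are laid out consecutively; when arr+hf+ihd exceeds the
    number of cardiac cases the overflow is realized as arrhythmia cases
    that also carry an ischemic term (reports may list several events), and
    when it falls short the remainder get a cardiac term outside all three
    subgroups.
    """
    events: set[str] = set()
    overflow = max(arr + hf + ihd - cd, 0)
    if idx < arr:
        events.add(_ARR_PT)
        if idx < overflow:
            events.add(_IHD_PT)
    elif idx < arr + hf:
        events.add(_HF_PT)
    elif idx < min(arr + hf + ihd, cd):
        events.add(_IHD_PT)
    else:
        events.add(_OTHER_CARDIAC_PT)
    return frozenset(events)


def table1_fixture(out_path: str | Path | None = None,
                   vocab: Vocabulary | None = None) -> ReportSet:
    """Deterministic report set reproducing the published per-drug marginals.

    Per product the fixture emits exactly the published number of
    adverse-event reports, of which exactly the published number are
    cardiac-disorder cases; cardiac cases carry subgroup terms so that
    case-level arrhythmia / cardiac-failure / ischemic-heart-disease counts
    match the published subgroup table, and their sex split matches the
    published cells.  Verbatim drug names cycle through each product's
    synonyms to exercise normalization.  Age bands are not specified.
    """
    vocab = vocab or demo_vocabulary()
    reports: list[Report] = []
    for pid in sorted(TABLE1_MARGINALS):
        m = TABLE1_MARGINALS[pid]
        ae, cd = m["ae"], m["cd"]
        arr, hf, ihd = m["subgroups"]
        f, mm, _ns = m["sex"]
        syns = vocab.drugs.synonyms_of(pid)
        for i in range(ae):
            is_case = i < cd
            if is_case:
                events = _subgroup_events(i, cd, arr, hf, ihd)
                sex = Sex.F if i < f else Sex.M if i < f + mm else Sex.NS
            else:
                events = frozenset({_NON_CARDIAC_PT})
                sex = Sex.NS
            reports.append(Report(
                report_id=f"{pid}-{i:06d}",
                case_id=f"C-{pid}-{i:06d}",
                version=1,
                receipt_date=date(2021, 6, 15),
                sex=sex,
                age_band=AgeBand.NS,
                drugs=(DrugMention(syns[i % len(syns)], DrugRole.PRIMARY_SUSPECT),),
                events=events,
            ))
    rs = ReportSet(reports, provenance="table1_fixture")
    if out_path is not None:
        write_native(rs, out_path)
    return rs
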