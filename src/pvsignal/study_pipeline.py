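"""End-to-end study orchestration.

``run_study`` executes the whole analysis from a config file: load reports,
deduplicate case versions, restrict to the receipt-date window and to
reports exposed to a known product, then produce

* totals — reports examined, event cases, share;
* a per-product cohort table (event cases subdivided by sex and age band);
* a per-product subgroup breakdown (counts and percentages across the
  configured narrow event groups, percentages on the subgroup-sum
  denominator);
* a forest table of reporting-odds-ratio results, one row per configured
  comparison (plus per-stratum rows when stratification is requested).

The run is a pure function of (reports file, vocabulary file, config):
outputs are byte-identical across repeated runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .disprop_stats import (
    ComparatorDesign, DegenerateTableError, RorResult,
    build_contingency, ror, round_half_up, stratified_rors,
)
from .report_model import (
    AgeBand, ReportSet, Sex, deduplicate, filter_window, load_reports,
)
from .vocabulary import Vocabulary, demo_vocabulary, exposure_products, \
    load_vocabulary

logger = logging.getLogger(__name__)

__all__ = [
    "Comparison",
    "StudyConfig",
    "StudyReport",
    "ConfigError",
    "run_study",
    "totals_summary",
    "subgroup_breakdown",
    "DEFAULT_SUBGROUPS",
]

DEFAULT_SUBGROUPS = ["arrhythmias", "cardiac_failure", "ischemic_heart_disease"]


class ConfigError(ValueError):
    """Raised when a study config references unknown products or groups."""


@dataclass
class Comparison:
    """One forest-table contrast: target products vs comparator products
    (or the rest of the database) for one event group."""

    name: str
    target: list[str]
    comparator: list[str] | str = "rest_of_database"
    event_group: str = "cardiac_disorders"

    def design(self, exclusive: bool = True) -> ComparatorDesign:
        comp = None if self.comparator == "rest_of_database" \
            else frozenset(self.comparator)
        return ComparatorDesign(frozenset(self.target), comp, exclusive=exclusive)


@dataclass
class StudyConfig:
    reports_path: str
    window: tuple[date, date]
    vocabulary_path: str | None = None   # None -> bundled demo vocabulary
    reports_format: str = "native"
    event_group: str = "cardiac_disorders"
    subgroup_groups: list[str] = field(default_factory=lambda: list(DEFAULT_SUBGROUPS))
    comparisons: list[Comparison] = field(default_factory=list)
    stratify: list[str] = field(default_factory=list)  # subset of {sex, age_band}
    correction: str = "none"
    exclusive: bool = True
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        window = (date.fromisoformat(str(doc["window"][0])),
                  date.fromisoformat(str(doc["window"][1])))
        comparisons = [
            Comparison(
                name=c["name"], target=list(c["target"]),
                comparator=(c.get("comparator", "rest_of_database")
                            if isinstance(c.get("comparator", "rest_of_database"), str)
                            else list(c["comparator"])),
                event_group=c.get("event_group", doc.get("event_group", "cardiac_disorders")),
            )
            for c in doc.get("comparisons", [])
        ]
        return cls(
            reports_path=doc["reports_path"],
            window=window,
            vocabulary_path=doc.get("vocabulary_path"),
            reports_format=doc.get("reports_format", "native"),
            event_group=doc.get("event_group", "cardiac_disorders"),
            subgroup_groups=list(doc.get("subgroup_groups", DEFAULT_SUBGROUPS)),
            comparisons=comparisons,
            stratify=list(doc.get("stratify", [])),
            correction=doc.get("correction", "none"),
            exclusive=bool(doc.get("exclusive", True)),
            output_dir=doc.get("output_dir"),
        )

    def validate(self, vocab: Vocabulary) -> None:
        """Fail fast on unknown products/groups before any computation."""
        if self.window[0] > self.window[1]:
            raise ConfigError(f"window start {self.window[0]} after end {self.window[1]}")
        known_groups = set(vocab.event_groups)
        for gid in [self.event_group, *self.subgroup_groups]:
            if gid not in known_groups:
                raise ConfigError(f"unknown event group: {gid!r}")
        known_products = set(vocab.drugs.products)
        for comp in self.comparisons:
            refs = list(comp.target)
            if comp.comparator != "rest_of_database":
                refs += list(comp.comparator)
            for pid in refs:
                if pid not in known_products:
                    raise ConfigError(
                        f"comparison {comp.name!r}: unknown product {pid!r}")
            if comp.event_group not in known_groups:
                raise ConfigError(
                    f"comparison {comp.name!r}: unknown event group {comp.event_group!r}")
        if self.stratify and not set(self.stratify) <= {"sex", "age_band"}:
            raise ConfigError(f"unknown strata: {self.stratify}")
        if self.correction not in ("none", "haldane_half"):
            raise ConfigError(f"unknown correction: {self.correction!r}")


@dataclass
class StudyReport:
    totals: pd.DataFrame
    cohorts: pd.DataFrame
    subgroups: pd.DataFrame
    forest: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.totals.to_csv(outdir / "totals.csv", index=False)
        self.cohorts.to_csv(outdir / "cohorts.csv", index=False)
        self.subgroups.to_csv(outdir / "subgroups.csv", index=False)
        self.forest.to_csv(outdir / "forest.csv", index=False)


# ---------------------------------------------------------------------------
# summary operations

def totals_summary(rs: ReportSet, vocab: Vocabulary, group_id: str
                   ) -> tuple[int, int, float]:
    """(reports examined, event cases, share %) for one event group.

    The share is rounded half-up to 1 decimal for display.
    """
    n = len(rs)
    if n == 0:
        raise ValueError("share undefined: no reports")
    terms = vocab.group(group_id).terms
    cases = sum(1 for r in rs if any(pt in terms for pt in r.events))
    return n, cases, round_half_up(100.0 * cases / n, 1)


def subgroup_breakdown(case_counts: Mapping[str, int]
                       ) -> dict[str, tuple[int, float]]:
    """Counts and percentages per subgroup, denominated by the subgroup sum
    (a case contributing to two subgroups is counted in both, so the sum —
    not the number of distinct cases — is the denominator)."""
    total = sum(case_counts.values())
    if total == 0:
        raise ValueError("all subgroup counts are zero: percentages undefined")
    return {k: (v, round_half_up(100.0 * v / total, 1))
            for k, v in case_counts.items()}


# ---------------------------------------------------------------------------
# pipeline

def _forest_row(name: str, comp: Comparison, stratum: str,
                table, result: RorResult | None, reason: str | None) -> dict:
    comp_label = comp.comparator if isinstance(comp.comparator, str) \
        else ";".join(comp.comparator)
    row = {
        "comparison": name, "target": ";".join(comp.target),
        "comparator": comp_label, "event_group": comp.event_group,
        "stratum": stratum,
        "a": table.a, "b": table.b, "c": table.c, "d": table.d,
        "ror": None, "ci_lower": None, "ci_upper": None,
        "n_cases": table.a, "is_signal": None,
        "correction_applied": False, "reason": reason or "",
    }
    if result is not None:
        row.update(ror=result.ror, ci_lower=result.ci_lower,
                   ci_upper=result.ci_upper, n_cases=result.n_cases,
                   is_signal=result.is_signal,
                   correction_applied=result.correction_applied)
    return row


def run_study(cfg: StudyConfig) -> StudyReport:
    """Execute load → dedup → window filter → cohorts → contingency → ROR
    for every configured comparison and assemble all output tables."""
    vocab = load_vocabulary(cfg.vocabulary_path) if cfg.vocabulary_path \
        else demo_vocabulary()
    cfg.validate(vocab)

    rs = load_reports(cfg.reports_path, format=cfg.reports_format)
    n_loaded = len(rs)
    rs = deduplicate(rs)
    n_dedup = len(rs)
    rs = filter_window(rs, *cfg.window)
    n_window = len(rs)
    # restrict to reports exposed to a product known to the dictionary
    exposures = {r.report_id: exposure_products(vocab.drugs, r) for r in rs}
    rs = ReportSet([r for r in rs if exposures[r.report_id]], rs.provenance)
    logger.info("pipeline: %d loaded -> %d after dedup -> %d in window -> "
                "%d exposed", n_loaded, n_dedup, n_window, len(rs))

    n_reports, n_cases, share = totals_summary(rs, vocab, cfg.event_group)
    totals = pd.DataFrame([{
        "event_group": cfg.event_group, "n_reports": n_reports,
        "n_event_cases": n_cases, "share_pct": share,
    }])

    broad_terms = vocab.group(cfg.event_group).terms
    sub_terms = {g: vocab.group(g).terms for g in cfg.subgroup_groups}
    observed_products = sorted({p for ps in exposures.values() for p in ps})

    cohort_rows, subgroup_rows = [], []
    for pid in observed_products:
        cohort = [r for r in rs if pid in exposures[r.report_id]]
        cases = [r for r in cohort if any(pt in broad_terms for pt in r.events)]
        row = {"product": pid, "ae_cases": len(cohort), "event_cases": len(cases)}
        for s in Sex:
            row[f"sex_{s.value}"] = sum(1 for r in cases if r.sex is s)
        for band in AgeBand:
            row[f"age_{band.value}"] = sum(1 for r in cases if r.age_band is band)
        cohort_rows.append(row)

        counts = {g: sum(1 for r in cohort if any(pt in terms for pt in r.events))
                  for g, terms in sub_terms.items()}
        if any(counts.values()):
            for g, (cnt, pct) in subgroup_breakdown(counts).items():
                subgroup_rows.append({"product": pid, "subgroup": g,
                                      "n_cases": cnt, "pct": pct})
    cohorts = pd.DataFrame(cohort_rows)
    subgroups = pd.DataFrame(
        subgroup_rows, columns=["product", "subgroup", "n_cases", "pct"])

    forest_rows = []
    for comp in cfg.comparisons:
        design = comp.design(exclusive=cfg.exclusive)
        table = build_contingency(rs, vocab.drugs, vocab, design, comp.event_group)
        try:
            result = ror(table, correction=cfg.correction)
            reason = None
        except DegenerateTableError as err:
            result, reason = None, str(err)
        forest_rows.append(_forest_row(comp.name, comp, "crude", table, result, reason))
        for strata in cfg.stratify:
            per = stratified_rors(rs, vocab.drugs, vocab, design,
                                  comp.event_group, strata, correction=cfg.correction)
            for level, sres in sorted(per.items()):
                forest_rows.append(_forest_row(
                    comp.name, comp, f"{strata}={level}",
                    sres.table, sres.result, sres.reason))
    forest = pd.DataFrame(forest_rows, columns=[
        "comparison", "target", "comparator", "event_group", "stratum",
        "a", "b", "c", "d", "ror", "ci_lower", "ci_upper", "n_cases",
        "is_signal", "correction_applied", "reason"])

    report = StudyReport(totals, cohorts, subgroups, forest)
    if cfg.output_dir:
        report.write(cfg.output_dir)
    return report
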