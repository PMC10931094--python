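"""Orchestration of the four hotspot-survival comparison strategies.

For every called hotspot X within one cancer type, its carriers are
compared against four universes:

* ``X_vs_All``   — every other patient with clinical data in the cohort;
* ``X_vs_Gene``  — patients mutated in the same gene but not at X;
* ``X_vs_Spots`` — patients carrying any *other* called hotspot of the
  gene (and not X);
* ``X_vs_Y``     — carriers of one specific other hotspot Y of the gene,
  with dual carriers excluded, each unordered pair tested once.

Group assignment gives carriers precedence, so the two groups of every
comparison are disjoint.  Tests 2-4 require at least ``min_patients`` on
*both* sides; comparisons below the threshold are skipped and logged.
Each performed comparison is scored three ways: the empirical two-sided
p-value from the conditional permutation null of the log-rank statistic
(the screen's calling statistic), the classical chi-square log-rank
p-value, and the Cox hazard ratio with its Wald p-value.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .hotspots import Hotspot, call_hotspots, gene_mutated_patients, pool_positions
from .maf_io import MutationRecord, SurvivalRecord
from .survnull import (
    KMCurve,
    NullDistribution,
    SurvivalSample,
    asymptotic_p,
    cox_fit,
    empirical_p,
    exact_null,
    km_estimate,
    logrank_statistic,
)
from .tmb_filter import compute_tmb, flag_hypermutated, remove_hypermutated

logger = logging.getLogger(__name__)

TESTS = ("X_vs_All", "X_vs_Gene", "X_vs_Spots", "X_vs_Y")


@dataclass(slots=True)
class ScreenConfig:
    """Screen-wide knobs; the RNG seed is mandatory for reproducibility."""

    seed: int
    alpha: float = 0.05
    min_patients: int = 4
    enum_limit: int = 100_000
    n_perm_per_stratum: int = 10_000
    remove_hypermutated: bool = True
    scaled_mad: bool = False
    tmb_cap: float = 500.0
    top_fraction: float = 0.10
    mad_multiplier: float = 4.0
    collect_exports: bool = False


@dataclass(slots=True)
class ScreenRow:
    """One hotspot-comparison result (Table-style schema)."""

    test: str
    cancer_type: str
    gene: str
    position_x: int
    position_y: int | None
    n_with: int
    n_without: int
    events_with: int
    events_without: int
    p_valorate: float
    p_logrank: float
    p_cox: float | None
    hr: float | str | None
    significant: bool

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "cancer_type": self.cancer_type,
            "gene": self.gene,
            "position_x": self.position_x,
            "position_y": self.position_y,
            "n_with": self.n_with,
            "n_without": self.n_without,
            "events_with": self.events_with,
            "events_without": self.events_without,
            "p_valorate": self.p_valorate,
            "p_logrank": self.p_logrank,
            "p_cox": self.p_cox,
            "hr": self.hr,
            "significant": self.significant,
        }


@dataclass
class ScreenResult:
    """All rows plus per-cancer summary counts and optional curve data."""

    rows: list[ScreenRow]
    summaries: list[dict]
    km_curves: dict[str, dict[str, KMCurve]] = field(default_factory=dict)
    null_dists: dict[str, NullDistribution] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "test", "cancer_type", "gene", "position_x", "position_y",
            "n_with", "n_without", "events_with", "events_without",
            "p_valorate", "p_logrank", "p_cox", "hr", "significant",
        ]
        return pd.DataFrame([r.to_dict() for r in self.rows], columns=cols)


# ---------------------------------------------------------------------------
# group construction
# ---------------------------------------------------------------------------


def _sample_from_sets(
    minority: set[str], comparison: set[str], surv_map: Mapping[str, SurvivalRecord]
) -> SurvivalSample:
    ids = sorted(minority) + sorted(comparison)
    times = np.array([surv_map[p].time_days for p in ids])
    events = np.array([surv_map[p].event for p in ids])
    group = np.zeros(len(ids), dtype=bool)
    group[: len(minority)] = True
    return SurvivalSample(times=times, events=events, group=group)


def groups_x_vs_all(
    hotspot: Hotspot, surv_map: Mapping[str, SurvivalRecord]
) -> SurvivalSample:
    """Carriers vs every other patient with clinical data."""
    minority = set(hotspot.carriers)
    comparison = set(surv_map) - minority
    return _sample_from_sets(minority, comparison, surv_map)


def groups_x_vs_gene(
    hotspot: Hotspot,
    gene_patients: set[str],
    surv_map: Mapping[str, SurvivalRecord],
    min_patients: int = 4,
) -> SurvivalSample | None:
    """Carriers vs gene-mutated non-carriers; ``None`` when the comparison
    side falls below the patient threshold."""
    minority = set(hotspot.carriers)
    comparison = (gene_patients & set(surv_map)) - minority
    if len(comparison) < min_patients:
        logger.info("skip X_vs_Gene for %s: comparison group has %d patients",
                    hotspot.label, len(comparison))
        return None
    return _sample_from_sets(minority, comparison, surv_map)


def groups_x_vs_spots(
    hotspot: Hotspot,
    other_hotspots: Iterable[Hotspot],
    surv_map: Mapping[str, SurvivalRecord],
    min_patients: int = 4,
) -> SurvivalSample | None:
    """Carriers vs carriers of any other called hotspot of the gene.

    A patient carrying X and another hotspot counts as an X carrier
    (carrier precedence keeps the groups disjoint).
    """
    minority = set(hotspot.carriers)
    comparison: set[str] = set()
    for other in other_hotspots:
        if other.aa_position == hotspot.aa_position and other.transcript_id == hotspot.transcript_id:
            continue
        comparison |= set(other.carriers)
    comparison = (comparison & set(surv_map)) - minority
    if len(comparison) < min_patients:
        logger.info("skip X_vs_Spots for %s: comparison group has %d patients",
                    hotspot.label, len(comparison))
        return None
    return _sample_from_sets(minority, comparison, surv_map)


def groups_x_vs_y(
    hotspot_x: Hotspot,
    hotspot_y: Hotspot,
    surv_map: Mapping[str, SurvivalRecord],
    min_patients: int = 4,
) -> SurvivalSample | None:
    """X-only carriers vs Y-only carriers; dual carriers are excluded."""
    both = set(hotspot_x.carriers) & set(hotspot_y.carriers)
    minority = (set(hotspot_x.carriers) - both) & set(surv_map)
    comparison = (set(hotspot_y.carriers) - both) & set(surv_map)
    if len(minority) < min_patients or len(comparison) < min_patients:
        logger.info("skip X_vs_Y for %s vs %s: groups %d/%d",
                    hotspot_x.label, hotspot_y.label, len(minority), len(comparison))
        return None
    return _sample_from_sets(minority, comparison, surv_map)


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------


def _comparison_seed(base_seed: int, *parts: object) -> int:
    """Deterministic per-comparison RNG seed derived from the screen seed
    and the comparison identity (stable across runs and platforms)."""
    tag = ":".join(str(p) for p in parts)
    return (base_seed * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1)


def _comparison_id(cancer: str, test: str, hotspot: Hotspot, position_y: int | None) -> str:
    stem = f"{cancer}_{hotspot.gene}_{hotspot.aa_position}"
    if position_y is not None:
        stem += f"_vs_{position_y}"
    return f"{stem}_{test}"


def _evaluate(
    sample: SurvivalSample,
    test: str,
    cancer: str,
    hotspot: Hotspot,
    position_y: int | None,
    config: ScreenConfig,
    result: ScreenResult,
) -> ScreenRow:
    L, V = logrank_statistic(sample)
    seed = _comparison_seed(config.seed, cancer, test, hotspot.gene, hotspot.transcript_id,
                            hotspot.aa_position, position_y)
    null = exact_null(
        sample, seed=seed, enum_limit=config.enum_limit,
        n_perm_per_stratum=config.n_perm_per_stratum,
    )
    p_val = empirical_p(null, L)
    cox = cox_fit(sample)
    hr: float | str | None = cox.hr if cox.degenerate == "none" else cox.hr_label
    row = ScreenRow(
        test=test,
        cancer_type=cancer,
        gene=hotspot.gene,
        position_x=hotspot.aa_position,
        position_y=position_y,
        n_with=sample.n1,
        n_without=sample.n - sample.n1,
        events_with=int(sample.events[sample.group].sum()),
        events_without=int(sample.events[~sample.group].sum()),
        p_valorate=p_val,
        p_logrank=asymptotic_p(L, V),
        p_cox=cox.p_cox,
        hr=hr,
        significant=p_val <= config.alpha,
    )
    if config.collect_exports:
        cid = _comparison_id(cancer, test, hotspot, position_y)
        result.km_curves[cid] = {
            "with": km_estimate(sample.times[sample.group], sample.events[sample.group]),
            "without": km_estimate(sample.times[~sample.group], sample.events[~sample.group]),
        }
        result.null_dists[cid] = null
    return row


def screen_cohort(
    mutations: list[MutationRecord],
    survival: list[SurvivalRecord],
    cancer_type: str,
    config: ScreenConfig,
    result: ScreenResult | None = None,
) -> ScreenResult:
    """Run all four tests over one cancer-type cohort."""
    if result is None:
        result = ScreenResult(rows=[], summaries=[])
    surv_map = {r.patient_id: r for r in survival}
    if len(surv_map) < config.min_patients:
        logger.warning("cohort %s skipped: only %d patients with clinical data",
                       cancer_type, len(surv_map))
        result.summaries.append({"cancer_type": cancer_type, "skipped": True})
        return result

    flagged: set[str] = set()
    if config.remove_hypermutated and mutations:
        profile = compute_tmb(mutations, scaled_mad=config.scaled_mad)
        if len(profile.counts) >= 2:
            flagged = flag_hypermutated(
                profile, tmb_cap=config.tmb_cap,
                top_fraction=config.top_fraction, mad_multiplier=config.mad_multiplier,
            )
    muts = remove_hypermutated(mutations, flagged)

    pooled = pool_positions(muts, survival)
    hotspots = call_hotspots(pooled, min_patients=config.min_patients, cancer_type=cancer_type)
    by_gene: dict[str, list[Hotspot]] = {}
    for h in hotspots:
        by_gene.setdefault(h.gene, []).append(h)
    clinical_ids = set(surv_map)
    gene_patients = {g: gene_mutated_patients(muts, g, clinical_ids) for g in by_gene}

    counts = {t: {"comparisons": 0, "significant": 0} for t in TESTS}

    def run(sample: SurvivalSample | None, test: str, h: Hotspot, pos_y: int | None) -> None:
        if sample is None:
            return
        row = _evaluate(sample, test, cancer_type, h, pos_y, config, result)
        result.rows.append(row)
        counts[test]["comparisons"] += 1
        counts[test]["significant"] += int(row.significant)

    for h in hotspots:
        run(groups_x_vs_all(h, surv_map), "X_vs_All", h, None)
        run(groups_x_vs_gene(h, gene_patients[h.gene], surv_map, config.min_patients),
            "X_vs_Gene", h, None)
        siblings = by_gene[h.gene]
        if len(siblings) >= 2:
            run(groups_x_vs_spots(h, siblings, surv_map, config.min_patients),
                "X_vs_Spots", h, None)
    for gene, siblings in by_gene.items():
        for i in range(len(siblings)):
            for j in range(i + 1, len(siblings)):
                x, y = siblings[i], siblings[j]
                run(groups_x_vs_y(x, y, surv_map, config.min_patients),
                    "X_vs_Y", x, y.aa_position)

    result.summaries.append(
        {
            "cancer_type": cancer_type,
            "patients": len(surv_map),
            "hypermutated_removed": len(flagged),
            "potential_hotspots": len(hotspots),
            "tests": counts,
        }
    )
    return result


def run_screen(
    cohorts: Mapping[str, tuple[list[MutationRecord], list[SurvivalRecord]]],
    config: ScreenConfig,
) -> ScreenResult:
    """Screen several cancer-type cohorts independently.

    ``cohorts`` maps cancer-type label to (mutations, survival records).
    Re-running with the same seed reproduces every empirical p-value
    exactly.
    """
    result = ScreenResult(rows=[], summaries=[])
    for cancer_type in sorted(cohorts):
        mutations, survival = cohorts[cancer_type]
        screen_cohort(mutations, survival, cancer_type, config, result)
    return result


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_results(result: ScreenResult, out_dir) -> list[Path]:
    """Write per-test and merged result tables, the summary JSON, and any
    collected KM / null-distribution data.  Deterministic file naming and
    row order, so re-export of identical inputs is byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    df = result.to_frame().sort_values(
        ["cancer_type", "test", "gene", "position_x", "position_y"],
        na_position="first", kind="stable",
    )
    for test in TESTS:
        sub = df[df["test"] == test]
        if test != "X_vs_Y":
            sub = sub.drop(columns=["position_y"])
        path = out / f"results_{test}.tsv"
        sub.to_csv(path, sep="\t", index=False)
        written.append(path)
    merged = out / "results_all_tests.tsv"
    df.to_csv(merged, sep="\t", index=False)
    written.append(merged)

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(result.summaries, indent=2, sort_keys=True))
    written.append(summary_path)

    if result.km_curves or result.null_dists:
        curve_dir = out / "curves"
        curve_dir.mkdir(exist_ok=True)
        for cid in sorted(result.km_curves):
            for side, curve in result.km_curves[cid].items():
                path = curve_dir / f"{cid}_km_{side}.tsv"
                curve.to_frame().to_csv(path, sep="\t", index=False)
                written.append(path)
        for cid in sorted(result.null_dists):
            path = curve_dir / f"{cid}_null.tsv"
            result.null_dists[cid].to_frame().to_csv(path, sep="\t", index=False)
            written.append(path)
    return written


def summary_table(result: ScreenResult) -> pd.DataFrame:
    """Per-cancer summary in the shape of a results-overview table:
    potential hotspots and significant counts per test."""
    rows = []
    for s in result.summaries:
        if s.get("skipped"):
            continue
        row = {
            "cancer_type": s["cancer_type"],
            "potential_hotspots": s["potential_hotspots"],
        }
        for t in TESTS:
            row[f"{t}_comparisons"] = s["tests"][t]["comparisons"]
            row[f"{t}_significant"] = s["tests"][t]["significant"]
        rows.append(row)
    return pd.DataFrame(rows)
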