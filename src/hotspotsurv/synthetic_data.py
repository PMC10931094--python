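"""Synthetic cohorts with known ground truth.

Generates MAF-style mutation tables and clinical TSVs that exercise every
stage of the screen without any external download: per-gene background
mutation rates, planted recurrent amino-acid positions with chosen carrier
counts and hazard ratios, exponential overall survival with independent
exponential plus administrative censoring, and an optional fraction of
hypermutated samples.

Two background mechanisms coexist, mirroring real exome data.  The modeled
genes (the ones hotspots are planted in) receive sparse per-patient
background mutations governed by a per-gene probability, so random
positional recurrence stays rare, as it is in a real exome.  The
per-sample mutation *burden* — what the hypermutation filter sees — is
emitted separately as Poisson-distributed SNV counts scattered across a
large pool of background genes with a huge joint position space, so TMB is
realistic without flooding the modeled genes with recurrent positions.
Hypermutated patients draw their burden (everywhere, including the modeled
genes) at the elevated rate, which is exactly the mechanism that biases
hotspot calling when such samples are not removed.

Survival is exponential with a proportional-hazards effect for planted
carriers, so the Cox model's estimand has a known truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .survnull import SurvivalSample

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True, slots=True)
class GeneSpec:
    """A modeled gene: background mutation probability per patient and the
    length of its protein in amino acids."""

    name: str
    mutation_prob: float = 0.10
    n_positions: int = 800


@dataclass(frozen=True, slots=True)
class PlantedHotspot:
    """A planted recurrent position: who carries it and its hazard ratio."""

    gene: str
    position: int
    n_carriers: int
    hazard_ratio: float = 1.0


@dataclass(slots=True)
class CohortSpec:
    """Ground-truth parameters for one synthetic cancer-type cohort.

    Defaults describe a mid-sized TCGA-like cohort: 400 patients, median
    survival on the order of 700 days (baseline hazard 1/1000 per day),
    independent censoring at roughly 1/3 of patients, a 10-year
    administrative cutoff, and a background burden of ~50 SNVs per exome.
    Hypermutated samples, when requested, carry ~1000 SNVs.
    """

    n_patients: int = 400
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    censoring_rate: float = 1.0 / 2000.0  # censorings per day
    admin_censor_days: float = 3650.0
    genes: tuple[GeneSpec, ...] = (
        GeneSpec("GENE1", 0.15, 1000),
        GeneSpec("GENE2", 0.10, 800),
        GeneSpec("GENE3", 0.05, 600),
    )
    planted_hotspots: tuple[PlantedHotspot, ...] = ()
    hyper_fraction: float = 0.0
    hyper_tmb: float = 1000.0
    background_tmb: float = 50.0
    indel_mean: float = 1.0  # in-frame/frameshift events per patient in modeled genes
    silent_fraction: float = 0.2
    n_background_genes: int = 200
    background_gene_positions: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        for rate in (self.baseline_hazard, self.censoring_rate):
            if rate <= 0:
                raise ValueError("hazard and censoring rates must be positive")
        gene_names = {g.name for g in self.genes}
        seen: set[tuple[str, int]] = set()
        for h in self.planted_hotspots:
            if h.gene not in gene_names:
                raise ValueError(f"planted hotspot in unknown gene {h.gene!r}")
            if h.n_carriers > self.n_patients:
                raise ValueError("more carriers than patients")
            if h.hazard_ratio <= 0:
                raise ValueError("hazard_ratio must be positive")
            if (h.gene, h.position) in seen:
                raise ValueError("planted positions must be distinct within a gene")
            seen.add((h.gene, h.position))
        if not 0 <= self.hyper_fraction < 1:
            raise ValueError("hyper_fraction must be in [0, 1)")


def _patient_ids(n: int) -> list[str]:
    # 12-character TCGA-style patient stems; sample = stem + "-01A"
    return [f"TCGA-SY-{i:04d}" for i in range(n)]


def _transcript_of(gene_index: int) -> str:
    return f"ENST{10_000 + gene_index:08d}"


def _hgvsp_missense(rng: np.random.Generator, pos: int) -> str:
    a, b = rng.choice(list(_AA), size=2)
    return f"p.{a}{pos}{b}"


def _hgvsp_silent(rng: np.random.Generator, pos: int) -> str:
    a = rng.choice(list(_AA))
    return f"p.{a}{pos}="


def _hgvsp_frameshift(rng: np.random.Generator, pos: int) -> str:
    a, b = rng.choice(list(_AA), size=2)
    return f"p.{a}{pos}{b}fs*{int(rng.integers(2, 30))}"


def _hgvsp_rangedel(rng: np.random.Generator, pos: int, max_pos: int) -> str:
    a, b = rng.choice(list(_AA), size=2)
    end = min(pos + int(rng.integers(1, 6)), max_pos)
    return f"p.{a}{pos}_{b}{end}del"


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (MAF-style table, clinical table, truth record).

    Fully reproducible from ``spec.seed``.  The truth record lists the
    planted carriers, their hazard ratios, and the hypermutated samples.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    patients = _patient_ids(n)
    samples = [p + "-01A" for p in patients]

    n_hyper = int(round(spec.hyper_fraction * n))
    hyper_idx = rng.choice(n, size=n_hyper, replace=False) if n_hyper else np.array([], dtype=int)
    is_hyper = np.zeros(n, dtype=bool)
    is_hyper[hyper_idx] = True

    # planted carriers, drawn without replacement per hotspot
    carriers: dict[PlantedHotspot, np.ndarray] = {}
    log_hr = np.zeros(n)
    for h in spec.planted_hotspots:
        idx = rng.choice(n, size=h.n_carriers, replace=False)
        carriers[h] = np.sort(idx)
        log_hr[idx] += np.log(h.hazard_ratio)

    # exponential survival under proportional hazards, with independent
    # exponential censoring and an administrative cutoff
    rate = spec.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.exponential(1.0 / spec.censoring_rate, size=n)
    follow_up = np.minimum(t_censor, spec.admin_censor_days)
    observed = np.minimum(t_event, follow_up)
    event = t_event <= follow_up
    days = np.round(observed).astype(int)  # registries record whole days

    clinical = pd.DataFrame(
        {
            "case_submitter_id": patients,
            "vital_status": np.where(event, "Dead", "Alive"),
            "days_to_death": np.where(event, days.astype(str), "'--"),
            "days_to_last_follow_up": np.where(event, "'--", days.astype(str)),
        }
    )

    rows: list[tuple[str, str, str, str, str, str]] = []

    def emit(sample: str, gene: str, transcript: str, kind: str, pos: int, max_pos: int) -> None:
        if kind == "missense":
            rows.append((gene, transcript, _hgvsp_missense(rng, pos), "SNP", "Missense_Mutation", sample))
        elif kind == "silent":
            rows.append((gene, transcript, _hgvsp_silent(rng, pos), "SNP", "Silent", sample))
        elif kind == "frameshift":
            rows.append((gene, transcript, _hgvsp_frameshift(rng, pos), "DEL", "Frame_Shift_Del", sample))
        else:  # in-frame range deletion
            rows.append((gene, transcript, _hgvsp_rangedel(rng, pos, max_pos), "DEL", "In_Frame_Del", sample))

    burden_scale = spec.hyper_tmb / spec.background_tmb

    # background mutations in the modeled genes (sparse, per-gene probability)
    for gi, gene in enumerate(spec.genes):
        transcript = _transcript_of(gi)
        prob = np.minimum(1.0, gene.mutation_prob * np.where(is_hyper, burden_scale, 1.0))
        mutated = rng.random(n) < prob
        for i in np.flatnonzero(mutated):
            n_calls = 1 + rng.poisson(0.2)
            for _ in range(n_calls):
                pos = int(rng.integers(1, gene.n_positions + 1))
                kind = "silent" if rng.random() < spec.silent_fraction else "missense"
                emit(samples[i], gene.name, transcript, kind, pos, gene.n_positions)
        # occasional indels so the parser's full grammar is exercised
        n_indels = rng.poisson(spec.indel_mean * gene.mutation_prob, size=n)
        for i in np.flatnonzero(n_indels):
            for _ in range(int(n_indels[i])):
                pos = int(rng.integers(1, gene.n_positions + 1))
                kind = "frameshift" if rng.random() < 0.5 else "rangedel"
                emit(samples[i], gene.name, transcript, kind, pos, gene.n_positions)

    # planted hotspot carriers (missense SNVs at the planted position)
    for h, idx in carriers.items():
        gi = next(i for i, g in enumerate(spec.genes) if g.name == h.gene)
        for i in idx:
            emit(samples[i], h.gene, _transcript_of(gi), "missense", h.position,
                 spec.genes[gi].n_positions)

    # exome-wide burden: SNVs over a large pool of background genes; this is
    # what the TMB filter measures
    tmb_mean = np.where(is_hyper, spec.hyper_tmb, spec.background_tmb)
    n_snv = rng.poisson(tmb_mean)
    for i in range(n):
        if n_snv[i] == 0:
            continue
        gidx = rng.integers(0, spec.n_background_genes, size=n_snv[i])
        positions = rng.integers(1, spec.background_gene_positions + 1, size=n_snv[i])
        silent = rng.random(n_snv[i]) < spec.silent_fraction
        for g, pos, sil in zip(gidx, positions, silent):
            gene_name = f"BG{g:03d}"
            transcript = f"ENST{900_000 + g:08d}"
            emit(samples[i], gene_name, transcript, "silent" if sil else "missense",
                 int(pos), spec.background_gene_positions)

    maf = pd.DataFrame(
        rows,
        columns=[
            "Hugo_Symbol",
            "Transcript_ID",
            "HGVSp_Short",
            "Variant_Type",
            "Variant_Classification",
            "Tumor_Sample_Barcode",
        ],
    )

    truth = {
        "seed": spec.seed,
        "n_patients": n,
        "planted_hotspots": [
            {
                "gene": h.gene,
                "position": h.position,
                "hazard_ratio": h.hazard_ratio,
                "carriers": [patients[i] for i in carriers[h]],
            }
            for h in spec.planted_hotspots
        ],
        "hypermutated_samples": sorted(samples[i] for i in hyper_idx),
    }
    return maf, clinical, truth


def generate_null_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Same generator with every planted hazard ratio forced to 1, so
    carriers share the non-carriers' survival law exactly."""
    null_spec = dataclasses.replace(
        spec,
        planted_hotspots=tuple(
            dataclasses.replace(h, hazard_ratio=1.0) for h in spec.planted_hotspots
        ),
    )
    return generate_cohort(null_spec)


def write_cohort(maf: pd.DataFrame, clinical: pd.DataFrame, truth: dict, out_dir) -> None:
    """Write the three artifacts (maf.tsv, clinical.tsv, truth.json)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    maf.to_csv(out / "maf.tsv", sep="\t", index=False)
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))


def figure1_toy() -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Deterministic 54-patient walkthrough cohort.

    One gene, 34 mutated patients, four recurrent positions (carrier counts
    10, 5, 4 and 3 — the toy's hotspot threshold is 3), twelve singleton
    positions, and twenty unmutated patients.  Used throughout the
    documentation to illustrate the four comparison universes.
    """
    patients = [f"TCGA-FG-{i:04d}" for i in range(54)]
    samples = [p + "-01A" for p in patients]
    gene, transcript = "GENEX", "ENST00099001"
    hotspot_plan = [(100, range(0, 10)), (200, range(10, 15)), (300, range(15, 19)), (400, range(19, 22))]
    rows = []
    aa = _AA
    for pos, rng_ in hotspot_plan:
        for i in rng_:
            rows.append((gene, transcript, f"p.{aa[i % 20]}{pos}{aa[(i + 3) % 20]}", "SNP",
                         "Missense_Mutation", samples[i]))
    for j, i in enumerate(range(22, 34)):  # singleton positions, one per patient
        pos = 500 + 7 * j
        rows.append((gene, transcript, f"p.{aa[j % 20]}{pos}{aa[(j + 5) % 20]}", "SNP",
                     "Missense_Mutation", samples[i]))
    maf = pd.DataFrame(
        rows,
        columns=["Hugo_Symbol", "Transcript_ID", "HGVSp_Short", "Variant_Type",
                 "Variant_Classification", "Tumor_Sample_Barcode"],
    )
    # deterministic survival: carriers of the big hotspot die early, the
    # rest follow a slowly decaying pattern with alternating censoring
    times, status = [], []
    for i in range(54):
        if i < 10:
            times.append(120 + 60 * i)
            status.append(True)
        else:
            times.append(400 + 55 * (i - 10))
            status.append(i % 2 == 0)
    clinical = pd.DataFrame(
        {
            "case_submitter_id": patients,
            "vital_status": ["Dead" if s else "Alive" for s in status],
            "days_to_death": [str(t) if s else "'--" for t, s in zip(times, status)],
            "days_to_last_follow_up": ["'--" if s else str(t) for t, s in zip(times, status)],
        }
    )
    truth = {
        "n_patients": 54,
        "n_gene_mutated": 34,
        "hotspot_threshold": 3,
        "hotspots": {pos: [patients[i] for i in idx] for pos, idx in hotspot_plan},
    }
    return maf, clinical, truth


def simulate_survival_sample(
    rng: np.random.Generator,
    n: int,
    n1: int,
    hazard: float = 1.0 / 1000.0,
    censoring_fraction: float = 0.3,
    hazard_ratio: float = 1.0,
) -> SurvivalSample:
    """Draw a two-group exponential survival sample directly.

    The first ``n1`` patients form the minority group with hazard
    ``hazard * hazard_ratio``; independent exponential censoring is tuned
    so that, at ``hazard_ratio`` 1, the expected censored fraction equals
    ``censoring_fraction``.  Times are continuous (no rounding), which
    keeps simulated null statistics free of tie artifacts.
    """
    if not 0 < n1 < n:
        raise ValueError("need 0 < n1 < n")
    if not 0 <= censoring_fraction < 1:
        raise ValueError("censoring_fraction must be in [0, 1)")
    group = np.zeros(n, dtype=bool)
    group[:n1] = True
    rates = np.where(group, hazard * hazard_ratio, hazard)
    t_event = rng.exponential(1.0 / rates)
    if censoring_fraction > 0:
        c_rate = hazard * censoring_fraction / (1.0 - censoring_fraction)
        t_censor = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_censor = np.full(n, np.inf)
    times = np.minimum(t_event, t_censor)
    events = t_event <= t_censor
    return SurvivalSample(times=times, events=events, group=group)
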