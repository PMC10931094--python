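"""Readers and normalizers for MAF-style mutation tables and clinical survival tables.

Somatic mutation calls arrive as MAF-dialect TSV files (one row per variant
per tumor sample, ``#``-prefixed comment lines, column names following the
GDC convention).  Overall-survival observations arrive as clinical TSV
files with a vital status and the two follow-up day counters.  This module
reads both into light-weight record types, derives patient identity from
the sample barcode, and parses compact HGVS protein-change strings
(``HGVSp_Short``, e.g. ``p.L858R``) into amino-acid positions.

Rows lacking a protein-change annotation are dropped at read time; silent
(synonymous) mutations are deliberately retained, since positional
recurrence of synonymous changes can still be functional.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Strings treated as missing values in GDC-style TSV files.
NA_TOKENS = frozenset(
    {
        "",
        ".",
        "-",
        "--",
        "'--",
        "NA",
        "N/A",
        "NaN",
        "nan",
        "None",
        "[Not Available]",
        "[Not Applicable]",
        "[Not Evaluated]",
        "[Unknown]",
        "[Discrepancy]",
    }
)

#: Recognized variant-type categories; anything else maps to ``"other"``.
VARIANT_TYPES = frozenset({"SNP", "DNP", "TNP", "INS", "DEL"})

_MAF_ALIASES: Mapping[str, Sequence[str]] = {
    "sample_id": ("Tumor_Sample_Barcode", "sample_id"),
    "gene": ("Hugo_Symbol", "Gene_Symbol", "gene"),
    "transcript_id": ("Transcript_ID", "Annotation_Transcript", "transcript_id"),
    "hgvsp_short": ("HGVSp_Short", "hgvsp_short"),
    "variant_type": ("Variant_Type", "variant_type"),
    "variant_classification": ("Variant_Classification", "variant_classification"),
}

_CLINICAL_ALIASES: Mapping[str, Sequence[str]] = {
    "patient_id": ("case_submitter_id", "bcr_patient_barcode", "patient_id", "Patient_ID"),
    "vital_status": ("vital_status", "Vital_Status"),
    "days_to_death": ("days_to_death", "Days_to_death"),
    "days_to_last_follow_up": (
        "days_to_last_follow_up",
        "days_to_last_followup",
        "last_contact_days_to",
    ),
}

_DEAD_TOKENS = frozenset({"dead", "deceased"})
_ALIVE_TOKENS = frozenset({"alive", "living", "not reported"})

_FIRST_INT = re.compile(r"(\d+)")


@dataclass(slots=True)
class MutationRecord:
    """One somatic mutation call, normalized.

    ``aa_position`` is the first amino-acid position parsed from
    ``hgvsp_short`` (``None`` when the string carries no position, e.g.
    ``p.=``).  ``patient_id`` is derived deterministically from the sample
    barcode.
    """

    sample_id: str
    patient_id: str
    gene: str
    transcript_id: str
    hgvsp_short: str
    variant_type: str
    variant_classification: str
    aa_position: int | None


@dataclass(slots=True)
class SurvivalRecord:
    """One patient's overall-survival observation (time in days)."""

    patient_id: str
    time_days: float
    event: bool


def parse_hgvsp(hgvsp: str) -> int | None:
    """Return the first integer amino-acid position in an HGVS-short string.

    Missense ``p.L858R`` -> 858; range deletions ``p.E746_A750del`` -> 746
    (the start of the event); frameshifts ``p.G96Wfs*12`` -> 96; synonymous
    ``p.L123=`` -> 123.  Strings without positional digits (``p.=``) return
    ``None``; the function never raises and never returns a value < 1.
    """
    if not hgvsp:
        return None
    m = _FIRST_INT.search(hgvsp)
    if m is None:
        return None
    pos = int(m.group(1))
    if pos < 1:
        logger.debug("non-positive amino-acid position in %r ignored", hgvsp)
        return None
    return pos


def patient_of_sample(sample_id: str) -> str:
    """Derive the patient identifier from a tumor sample barcode.

    TCGA barcodes encode the patient in the first 12 characters
    (``TCGA-AB-1234-01A-...`` -> ``TCGA-AB-1234``).  Identifiers already at
    or below 12 characters pass through unchanged, so the function is
    idempotent.
    """
    if not sample_id:
        raise ValueError("empty sample barcode")
    return sample_id[:12]


def sample_type_code(sample_id: str) -> str | None:
    """Extract the 2-character TCGA sample-type code (e.g. ``01`` = primary
    tumor, ``06`` = metastatic), or ``None`` when the barcode does not carry
    one."""
    if len(sample_id) >= 15 and sample_id[12] == "-":
        code = sample_id[13:15]
        if code.isdigit():
            return code
    return None


def _resolve_columns(
    columns: Iterable[str],
    aliases: Mapping[str, Sequence[str]],
    required: Sequence[str],
    column_map: Mapping[str, str] | None = None,
) -> dict[str, str]:
    present = {c: c for c in columns}
    resolved: dict[str, str] = {}
    for logical, candidates in aliases.items():
        if column_map and logical in column_map:
            candidates = (column_map[logical],)
        for cand in candidates:
            if cand in present:
                resolved[logical] = cand
                break
    missing = [name for name in required if name not in resolved]
    if missing:
        raise ValueError(
            "missing required column(s): "
            + ", ".join(f"{m} (expected one of {list(aliases[m])})" for m in missing)
        )
    return resolved


def _clean(value: object) -> str:
    s = str(value).strip()
    return "" if s in NA_TOKENS else s


def mutations_from_frame(
    df: pd.DataFrame,
    sample_type_whitelist: Iterable[str] | None = ("01",),
    column_map: Mapping[str, str] | None = None,
) -> list[MutationRecord]:
    """Normalize a MAF-style DataFrame into :class:`MutationRecord` lists.

    Rows with an empty/NA ``HGVSp_Short`` are dropped.  When
    ``sample_type_whitelist`` is given, rows whose barcode carries a
    parseable sample-type code outside the whitelist are dropped; barcodes
    without a recognizable code are kept.
    """
    cols = _resolve_columns(
        df.columns,
        _MAF_ALIASES,
        required=["sample_id", "gene", "transcript_id", "hgvsp_short", "variant_type"],
        column_map=column_map,
    )
    whitelist = frozenset(sample_type_whitelist) if sample_type_whitelist is not None else None
    has_cls = "variant_classification" in cols

    records: list[MutationRecord] = []
    n_dropped_hgvsp = 0
    n_dropped_type = 0
    for row in df.itertuples(index=False):
        data = dict(zip(df.columns, row))
        hgvsp = _clean(data[cols["hgvsp_short"]])
        if not hgvsp:
            n_dropped_hgvsp += 1
            continue
        sample = _clean(data[cols["sample_id"]])
        if whitelist is not None:
            code = sample_type_code(sample)
            if code is not None and code not in whitelist:
                n_dropped_type += 1
                continue
        vtype = _clean(data[cols["variant_type"]]).upper()
        if vtype not in VARIANT_TYPES:
            vtype = "other"
        records.append(
            MutationRecord(
                sample_id=sample,
                patient_id=patient_of_sample(sample),
                gene=_clean(data[cols["gene"]]),
                transcript_id=_clean(data[cols["transcript_id"]]),
                hgvsp_short=hgvsp,
                variant_type=vtype,
                variant_classification=_clean(data[cols["variant_classification"]]) if has_cls else "",
                aa_position=parse_hgvsp(hgvsp),
            )
        )
    if n_dropped_hgvsp:
        logger.info("dropped %d rows lacking HGVSp_Short", n_dropped_hgvsp)
    if n_dropped_type:
        logger.info("dropped %d rows by sample-type whitelist", n_dropped_type)
    return records


def read_maf(
    path,
    sample_type_whitelist: Iterable[str] | None = ("01",),
    column_map: Mapping[str, str] | None = None,
) -> list[MutationRecord]:
    """Read a MAF-dialect TSV file into normalized mutation records.

    ``#``-prefixed lines are treated as comments.  A missing required
    column raises :class:`ValueError` naming the column.  Silent mutations
    are retained; rows without a protein-change annotation are dropped.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return mutations_from_frame(df, sample_type_whitelist, column_map)


def survival_from_frame(
    df: pd.DataFrame, column_map: Mapping[str, str] | None = None
) -> list[SurvivalRecord]:
    """Normalize a clinical DataFrame into one survival record per patient.

    ``time_days`` is ``days_to_death`` for deceased patients and
    ``days_to_last_follow_up`` otherwise; ``event`` marks observed death.
    Patients with a missing or negative time are dropped (logged).  Unknown
    vital-status strings are treated as censored (logged), not dropped.
    The first usable record per patient wins.
    """
    cols = _resolve_columns(
        df.columns,
        _CLINICAL_ALIASES,
        required=["patient_id", "vital_status", "days_to_death", "days_to_last_follow_up"],
        column_map=column_map,
    )
    records: dict[str, SurvivalRecord] = {}
    n_dropped = 0
    unknown_status: set[str] = set()
    for row in df.itertuples(index=False):
        data = dict(zip(df.columns, row))
        pid = _clean(data[cols["patient_id"]])
        if not pid or pid in records:
            continue
        status = _clean(data[cols["vital_status"]]).lower()
        if status in _DEAD_TOKENS:
            event = True
        elif status in _ALIVE_TOKENS:
            event = False
        else:
            event = False
            unknown_status.add(status)
        raw = data[cols["days_to_death"]] if event else data[cols["days_to_last_follow_up"]]
        raw = _clean(raw)
        try:
            time_days = float(raw) if raw else None
        except ValueError:
            time_days = None
        if time_days is None or time_days < 0:
            n_dropped += 1
            continue
        records[pid] = SurvivalRecord(patient_id=pid, time_days=time_days, event=event)
    if unknown_status:
        logger.warning("unknown vital-status value(s) treated as censored: %s", sorted(unknown_status))
    if n_dropped:
        logger.info("dropped %d clinical rows with missing/negative time", n_dropped)
    return list(records.values())


def read_clinical(path, column_map: Mapping[str, str] | None = None) -> list[SurvivalRecord]:
    """Read a clinical TSV file into normalized survival records."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return survival_from_frame(df, column_map)


def mutations_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    """Serialize mutation records back to a TSV-ready DataFrame."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "patient_id": r.patient_id,
                "gene": r.gene,
                "transcript_id": r.transcript_id,
                "hgvsp_short": r.hgvsp_short,
                "variant_type": r.variant_type,
                "variant_classification": r.variant_classification,
                "aa_position": r.aa_position,
            }
            for r in records
        ]
    )


def survival_to_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    """Serialize survival records to a TSV-ready DataFrame."""
    return pd.DataFrame(
        [
            {"patient_id": r.patient_id, "time_days": r.time_days, "event": r.event}
            for r in records
        ]
    )
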