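"""Tumor mutation burden and hypermutated-sample flagging.

TMB is the count of single-nucleotide variants per tumor sample.
Hypermutated samples distort positional recurrence (they scatter calls over
many positions and can fabricate apparent hotspots), so the screen excludes
them by the union of two rules:

* Rule A — TMB exceeds 500 mutations AND ranks in the top 10% of the cohort
  (nearest-rank 90th percentile, ties at the threshold included);
* Rule B — TMB exceeds the cohort median plus four times the median
  absolute deviation (MAD, unscaled by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .maf_io import MutationRecord

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class TMBProfile:
    """Per-sample SNV counts with the cohort's robust summary statistics."""

    counts: dict[str, int]
    median: float
    mad: float
    q90: float

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], scaled_mad: bool = False) -> "TMBProfile":
        if not counts:
            raise ValueError("cannot profile an empty cohort")
        values = np.asarray(sorted(counts.values()), dtype=float)
        median = float(np.median(values))
        mad = float(np.median(np.abs(values - median)))
        if scaled_mad:
            mad *= 1.4826  # normal-consistency constant, optional
        q90 = float(np.quantile(values, 0.9, method="inverted_cdf"))
        return cls(counts=dict(counts), median=median, mad=mad, q90=q90)


def compute_tmb(
    mutations: Iterable[MutationRecord],
    all_samples: Iterable[str] | None = None,
    scaled_mad: bool = False,
) -> TMBProfile:
    """Count SNVs per sample.

    Every sample appearing in ``mutations`` (and any extra id in
    ``all_samples``) gets a count, zero when it carries no SNV.  Raises on
    an empty cohort.
    """
    counts: dict[str, int] = {s: 0 for s in (all_samples or ())}
    for m in mutations:
        counts.setdefault(m.sample_id, 0)
        if m.variant_type == "SNP":
            counts[m.sample_id] += 1
    return TMBProfile.from_counts(counts, scaled_mad=scaled_mad)


def flag_hypermutated(
    profile: TMBProfile,
    tmb_cap: float = 500.0,
    top_fraction: float = 0.10,
    mad_multiplier: float = 4.0,
) -> set[str]:
    """Return the sample ids flagged hypermutated (Rule A union Rule B).

    Deterministic and invariant to sample ordering.  ``top_fraction`` sets
    the Rule A rank threshold (default: top 10%, i.e. TMB at or above the
    nearest-rank 90th percentile).
    """
    if len(profile.counts) < 2:
        raise ValueError("hypermutation flagging needs at least 2 samples")
    values = np.asarray(sorted(profile.counts.values()), dtype=float)
    q = float(np.quantile(values, 1.0 - top_fraction, method="inverted_cdf"))
    rule_b_threshold = profile.median + mad_multiplier * profile.mad
    flagged = {
        s
        for s, tmb in profile.counts.items()
        if (tmb > tmb_cap and tmb >= q) or tmb > rule_b_threshold
    }
    if flagged:
        logger.info(
            "flagged %d/%d samples hypermutated (ruleA: >%g & >=%g, ruleB: >%g)",
            len(flagged),
            len(profile.counts),
            tmb_cap,
            q,
            rule_b_threshold,
        )
    return flagged


def hypermutation_report(
    profile: TMBProfile,
    tmb_cap: float = 500.0,
    top_fraction: float = 0.10,
    mad_multiplier: float = 4.0,
) -> pd.DataFrame:
    """Per-sample TSV-ready report with the two rule verdicts."""
    values = np.asarray(sorted(profile.counts.values()), dtype=float)
    q = float(np.quantile(values, 1.0 - top_fraction, method="inverted_cdf"))
    thr_b = profile.median + mad_multiplier * profile.mad
    rows = []
    for sample in sorted(profile.counts):
        tmb = profile.counts[sample]
        rule_a = tmb > tmb_cap and tmb >= q
        rule_b = tmb > thr_b
        rows.append(
            {
                "sample_id": sample,
                "tmb": tmb,
                "rule_a": rule_a,
                "rule_b": rule_b,
                "flagged": rule_a or rule_b,
            }
        )
    return pd.DataFrame(rows)


def remove_hypermutated(
    mutations: Iterable[MutationRecord], flagged: Iterable[str]
) -> list[MutationRecord]:
    """Drop every mutation record from a flagged sample.

    The screen first runs *with* hypermutated samples to demonstrate the
    recurrence bias, then without them; hence a plain toggleable filter.
    """
    flagged = set(flagged)
    return [m for m in mutations if m.sample_id not in flagged]
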