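"""Pooling of mutations by amino-acid position and hotspot calling.

A hotspot is an amino-acid position of one transcript carrying mutations in
at least ``min_patients`` patients *with clinical data* within a single
cancer type (default threshold 4).  Pooling is positional: missense,
synonymous, frameshift and in-frame indel events all contribute to the
position where they start, so an exon-19-deletion cluster and a point
substitution at the same residue count together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .maf_io import MutationRecord, SurvivalRecord

PoolKey = tuple[str, str, int]  # (gene, transcript_id, aa_position)


@dataclass(frozen=True, slots=True)
class Hotspot:
    """A recurrent amino-acid position with its carrier patient set."""

    cancer_type: str
    gene: str
    transcript_id: str
    aa_position: int
    carriers: frozenset[str]

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)

    @property
    def label(self) -> str:
        """Display name in gene-position form, e.g. ``IDH1-132``."""
        return f"{self.gene}-{self.aa_position}"


def pool_positions(
    mutations: Iterable[MutationRecord],
    survival: Iterable[SurvivalRecord],
) -> dict[PoolKey, set[str]]:
    """Pool mutations by (gene, transcript, position) into carrier sets.

    A patient counts at most once per position no matter how many samples
    or calls support it; patients without a survival record are excluded,
    since they cannot enter any comparison.
    """
    clinical = {r.patient_id for r in survival}
    pooled: dict[PoolKey, set[str]] = {}
    for m in mutations:
        if m.aa_position is None or m.patient_id not in clinical:
            continue
        pooled.setdefault((m.gene, m.transcript_id, m.aa_position), set()).add(m.patient_id)
    return pooled


def call_hotspots(
    pooled: Mapping[PoolKey, set[str]],
    min_patients: int = 4,
    cancer_type: str = "",
) -> list[Hotspot]:
    """Return positions with at least ``min_patients`` carriers, sorted by
    (gene, transcript, position).  Deterministic."""
    if min_patients < 2:
        raise ValueError("min_patients must be >= 2")
    out = [
        Hotspot(
            cancer_type=cancer_type,
            gene=gene,
            transcript_id=transcript,
            aa_position=pos,
            carriers=frozenset(carriers),
        )
        for (gene, transcript, pos), carriers in pooled.items()
        if len(carriers) >= min_patients
    ]
    out.sort(key=lambda h: (h.gene, h.transcript_id, h.aa_position))
    return out


def gene_mutated_patients(
    mutations: Iterable[MutationRecord],
    gene: str,
    clinical_patients: set[str] | None = None,
) -> set[str]:
    """All patients with at least one retained mutation record in ``gene``
    (any position, parsed or not), optionally restricted to patients with
    clinical data."""
    patients = {m.patient_id for m in mutations if m.gene == gene}
    if clinical_patients is not None:
        patients &= clinical_patients
    return patients


def hotspots_to_frame(hotspots: Iterable[Hotspot]) -> pd.DataFrame:
    """TSV-ready export of called hotspots."""
    return pd.DataFrame(
        [
            {
                "cancer_type": h.cancer_type,
                "gene": h.gene,
                "transcript_id": h.transcript_id,
                "aa_position": h.aa_position,
                "n_carriers": h.n_carriers,
                "carriers": ",".join(sorted(h.carriers)),
            }
            for h in hotspots
        ]
    )
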