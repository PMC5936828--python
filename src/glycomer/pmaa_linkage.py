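"""GC-MS PMAA linkage assignment and linkage-abundance ratios.

Partially methylated alditol acetates (PMAAs) carry acetyl groups at the
positions that were glycosidically linked (or ring-involved) in the intact
glycan; their electron-impact signature ions, together with GC retention
time, identify the linkage category of each monosaccharide.  Fragmentation
chemistry is not simulated here — the ten-row reference table of the study
system is an authoritative lookup, matched by Jaccard similarity of
signature-ion sets with retention time as tie-breaker.  Terminal mannose and
terminal galactose share an identical ion set ({102,118,129,145,161,205})
and are separable only by retention time (9.92 vs 10.15 min).  Terminal
fucose is absent from the reference table (undetected in the source data)
and therefore unassignable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from glycomer.glycan_model import GlycanError

__all__ = [
    "PMAARecord",
    "REFERENCE_TABLE",
    "assign_linkage",
    "assign_records",
    "gal_ratio",
    "read_records_csv",
    "write_assignments_csv",
]


@dataclass(frozen=True)
class PMAARecord:
    """One GC-MS peak: retention time, EI signature ions, optional abundance."""

    retention_time: float  # minutes
    signature_ions: frozenset
    abundance: Optional[float] = None
    assigned_linkage: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.signature_ions:
            raise GlycanError("PMAA record needs a non-empty signature-ion set")
        if self.retention_time <= 0:
            raise GlycanError("retention time must be positive")


# (retention time / min, signature ions, linkage assignment)
REFERENCE_TABLE: list[tuple[float, frozenset, str]] = [
    (9.51, frozenset({101, 118, 143, 203}), "4-linked fucose"),
    (9.92, frozenset({102, 118, 129, 145, 161, 205}), "terminal mannose"),
    (10.15, frozenset({102, 118, 129, 145, 161, 205}), "terminal galactose"),
    (10.96, frozenset({129, 130, 161, 190}), "2-linked mannose"),
    (11.18, frozenset({113, 118, 131, 173, 233}), "4-linked galactose"),
    (11.29, frozenset({118, 129, 161, 234, 277}), "3-linked mannose"),
    (11.42, frozenset({102, 118, 129, 162, 189}), "6-linked mannose"),
    (12.55, frozenset({118, 129, 189, 234}), "3,6-linked mannose"),
    (14.25, frozenset({117, 159, 233}), "4-linked N-acetylglucosamine"),
    (15.48, frozenset({117, 159, 261}), "4,6-linked N-acetylglucosamine"),
]


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def assign_linkage(
    record: PMAARecord,
    table: Optional[Sequence[tuple[float, frozenset, str]]] = None,
    score_cutoff: float = 0.8,
    rt_window: float = 0.3,
) -> PMAARecord:
    """Best-matching linkage for one PMAA record.

    The reference row maximizing Jaccard similarity of the ion sets wins;
    ties (identical ion sets, e.g. terminal Man vs terminal Gal) are broken
    by nearest retention time.  Below ``score_cutoff`` the record stays
    unassigned.  ``rt_window`` bounds how far a tie-broken retention time
    may sit from the reference row; a tie with no row inside the window
    stays unassigned.
    """
    rows = REFERENCE_TABLE if table is None else list(table)
    scored = [
        (_jaccard(record.signature_ions, ions), abs(record.retention_time - rt), label)
        for rt, ions, label in rows
    ]
    best_score = max(s for s, _, _ in scored)
    if best_score < score_cutoff:
        return PMAARecord(
            record.retention_time, record.signature_ions, record.abundance, None, best_score
        )
    contenders = [(drt, label) for s, drt, label in scored if s == best_score]
    contenders.sort()
    drt, label = contenders[0]
    if len(contenders) > 1 and drt > rt_window:
        label = None  # ambiguous ion set and retention time discriminates nothing
    return PMAARecord(
        record.retention_time, record.signature_ions, record.abundance, label, best_score
    )


def assign_records(
    records: Sequence[PMAARecord], **kwargs
) -> list[PMAARecord]:
    return [assign_linkage(r, **kwargs) for r in records]


def gal_ratio(records: Sequence[PMAARecord]) -> float:
    """Terminal-Gal : 4-linked-Gal abundance ratio, normalized as 1:x.

    Returns x. Both categories must be present with abundances.
    """
    terminal = sum(
        r.abundance
        for r in records
        if r.assigned_linkage == "terminal galactose" and r.abundance is not None
    )
    fourlinked = sum(
        r.abundance
        for r in records
        if r.assigned_linkage == "4-linked galactose" and r.abundance is not None
    )
    if terminal == 0 or fourlinked == 0:
        raise GlycanError(
            "terminal-to-4-linked galactose ratio undefined: both categories "
            "must be present with non-zero abundance"
        )
    return fourlinked / terminal


# --- CSV I/O: rt_min, ions (semicolon-separated), abundance ----------------

def read_records_csv(path: str | Path) -> list[PMAARecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        ions = frozenset(int(x) for x in str(row["ions"]).split(";") if x.strip())
        abundance = float(row["abundance"]) if "abundance" in df.columns else None
        records.append(PMAARecord(float(row["rt_min"]), ions, abundance))
    return records


def write_assignments_csv(records: Sequence[PMAARecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "rt_min": [r.retention_time for r in records],
            "ions": [";".join(str(i) for i in sorted(r.signature_ions)) for r in records],
            "abundance": [r.abundance for r in records],
            "assigned_linkage": [r.assigned_linkage or "unassigned" for r in records],
            "score": [r.score for r in records],
        }
    ).to_csv(path, index=False)
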