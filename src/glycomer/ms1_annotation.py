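"""MS1 composition assignment, glycan-class calling, and methyl-ladder profiling.

Peak lists are centroided (m/z, intensity) tables; the annotation is a
bounded exhaustive enumeration of (Hex, HexNAc, dHex, Me) compositions whose
theoretical sodiated mass falls within tolerance of the observed peak.
Glycan classes follow the series structure of an invertebrate N-glycome:
paucimannose (HexNAc2, Hex <= 4), high-mannose (HexNAc2, Hex >= 5), the
core-galactofucosylated F1HnN2 series (HexNAc2 + one dHex), and a
complex/hybrid candidate bucket (HexNAc >= 3).

Methylation of 2-AB-labeled glycans appears as ladders of peaks spaced by
14.0157 Da above the unmethylated base composition; ladder profiling sums
intensity per methyl count and reports the predominant methylation state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from glycomer.glycan_model import CH2, Composition, GlycanError, composition_mass

__all__ = [
    "PeakList",
    "CompositionAssignment",
    "LadderProfile",
    "enumerate_compositions",
    "classify_glycan",
    "detect_methyl_ladders",
    "annotate_peaklist",
]

DEFAULT_BOUNDS = {"Hex": 12, "HexNAc": 6, "dHex": 2, "Me": 8}
SEARCH_BUDGET = 2_000_000  # max enumerated tuples before raising


@dataclass
class PeakList:
    """Centroided peak list with acquisition metadata.

    ``peaks`` is a DataFrame with columns ``mz`` (Da, ascending, > 0) and
    ``intensity`` (>= 0). ``ms_level`` 2 requires ``parent_mz``.
    """

    peaks: pd.DataFrame
    ms_level: int = 1
    parent_mz: Optional[float] = None
    derivatization: str = "permethylated"
    adduct: str = "Na"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.peaks, columns=["mz", "intensity"]).astype(float)
        if len(df):
            if (df["mz"] <= 0).any():
                raise ValueError("peak m/z values must be strictly positive")
            if (df["intensity"] < 0).any():
                raise ValueError("peak intensities must be non-negative")
            df = df.sort_values("mz", kind="mergesort").reset_index(drop=True)
        self.peaks = df
        if self.ms_level == 2 and self.parent_mz is None:
            raise ValueError("MS/MS peak list requires parent_mz")

    @property
    def mz(self) -> np.ndarray:
        return self.peaks["mz"].to_numpy()

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks["intensity"].to_numpy()

    def base_peak_intensity(self) -> float:
        return float(self.peaks["intensity"].max()) if len(self.peaks) else 0.0

    def __len__(self) -> int:
        return len(self.peaks)

    # --- I/O: headered CSV with metadata in '#' comment lines -------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "msLevel": self.ms_level,
            "derivatization": self.derivatization,
            "adduct": self.adduct,
        }
        if self.parent_mz is not None:
            meta["parentMz"] = self.parent_mz
        with open(path, "w") as fh:
            for key, value in meta.items():
                fh.write(f"# {key}={value}\n")
            self.peaks.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PeakList":
        meta: dict = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").strip().partition("=")
                meta[key] = value
                body_start = i + 1
            else:
                break
        from io import StringIO

        sep = "\t" if "\t" in lines[body_start] else ","
        df = pd.read_csv(StringIO("".join(lines[body_start:])), sep=sep)
        if not {"mz", "intensity"} <= set(df.columns):
            raise ValueError(f"{path}: peak list needs 'mz' and 'intensity' columns")
        return cls(
            df[["mz", "intensity"]],
            ms_level=int(meta.get("msLevel", 1)),
            parent_mz=float(meta["parentMz"]) if "parentMz" in meta else None,
            derivatization=meta.get("derivatization", "permethylated"),
            adduct=meta.get("adduct", "Na"),
        )


@dataclass(frozen=True)
class CompositionAssignment:
    peak_mz: float
    composition: Composition
    theoretical_mz: float
    glycan_class: str

    @property
    def delta(self) -> float:
        """Observed minus theoretical m/z (Da)."""
        return self.peak_mz - self.theoretical_mz


def classify_glycan(comp: Composition) -> str:
    """Total classification of a composition into one N-glycan class.

    The paucimannose/high-mannose boundary sits between Hex4 and Hex5 of the
    HexNAc2 backbone, matching the observed series membership of the study
    glycome (967.5/1171.6/1375.7 paucimannose vs 1579.8+ high mannose).
    """
    if comp.nHexNAc >= 3:
        return "complex/hybrid-candidate"
    if comp.nHexNAc == 2 and comp.ndHex == 0 and comp.nHex <= 4:
        return "paucimannose"
    if comp.nHexNAc == 2 and comp.ndHex == 0 and comp.nHex >= 5:
        return "high-mannose"
    if comp.nHexNAc == 2 and comp.ndHex == 1:
        return "F1HnN2"
    return "unassigned"


def enumerate_compositions(
    mz: float,
    derivatization: str = "permethylated",
    tolerance: float = 0.1,
    bounds: Optional[dict] = None,
) -> list[CompositionAssignment]:
    """All bounded compositions whose theoretical [M+Na]+ m/z matches ``mz``.

    Exhaustive integer enumeration over (nHex, nHexNAc, ndHex, nMe) within
    ``bounds``; the methyl dimension is searched only for native and 2-AB
    derivatizations (permethylation makes natural methyls mass-invisible).
    Results are sorted by |delta|, then fewest residues, then fewest methyls.
    """
    if mz <= 0:
        raise GlycanError("mz must be positive")
    if tolerance <= 0:
        raise GlycanError("tolerance must be positive")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    me_max = b["Me"] if derivatization in ("native", "twoAB") else 0
    n_tuples = (b["Hex"] + 1) * (b["HexNAc"] + 1) * (b["dHex"] + 1) * (me_max + 1)
    if n_tuples > SEARCH_BUDGET:
        raise GlycanError(
            f"enumeration budget exceeded ({n_tuples} > {SEARCH_BUDGET} tuples); "
            "tighten bounds"
        )
    out = []
    for nhex in range(b["Hex"] + 1):
        for nhexnac in range(b["HexNAc"] + 1):
            for ndhex in range(b["dHex"] + 1):
                for nme in range(me_max + 1):
                    comp = Composition(nhex, nhexnac, ndhex, nme, derivatization)
                    theo = composition_mass(comp)
                    if abs(mz - theo) <= tolerance:
                        out.append(
                            CompositionAssignment(mz, comp, theo, classify_glycan(comp))
                        )
    out.sort(
        key=lambda a: (
            abs(a.delta),
            a.composition.total_residues(),
            a.composition.nMe,
        )
    )
    return out


def _match_peak(
    peaks: PeakList, target_mz: float, tolerance: float
) -> Optional[int]:
    """Index of the nearest peak within tolerance; ties go to lower m/z."""
    mz = peaks.mz
    if len(mz) == 0:
        return None
    dist = np.abs(mz - target_mz)
    best = float(dist.min())
    if best > tolerance:
        return None
    # ties toward lower m/z: first index attaining the minimum (mz ascending)
    return int(np.flatnonzero(dist == best)[0])


@dataclass
class LadderProfile:
    """Methylation ladder of one base composition: intensity per methyl count."""

    base: Composition
    intensity_by_me: dict[int, float]
    warnings: list[str] = field(default_factory=list)

    @property
    def predominant_state(self) -> Optional[int]:
        if not self.intensity_by_me or all(
            v == 0 for v in self.intensity_by_me.values()
        ):
            return None
        return max(sorted(self.intensity_by_me), key=lambda k: self.intensity_by_me[k])


def detect_methyl_ladders(
    peaks: PeakList,
    base_comps: Sequence[Composition],
    max_me: int = 8,
    tolerance: float = 0.1,
) -> list[LadderProfile]:
    """Profile 14-Da methylation ladders of 2-AB MS1 spectra.

    For each base composition, peaks at theoretical m/z + k*14.0157
    (k = 0..max_me) are matched within tolerance.  A peak claimed by
    ladders of more than one base composition has its intensity split
    equally among the claimants (with a warning) so that total intensity is
    conserved, never double-counted.
    """
    if peaks.derivatization != "twoAB":
        raise GlycanError("methyl-ladder profiling expects 2-AB-labeled MS1 data")
    claims: dict[int, list[tuple[int, int]]] = {}  # peak idx -> [(base idx, k)]
    for bi, base in enumerate(base_comps):
        base0 = Composition(
            base.nHex, base.nHexNAc, base.ndHex, 0, peaks.derivatization
        )
        theo0 = composition_mass(base0)
        for k in range(max_me + 1):
            idx = _match_peak(peaks, theo0 + k * CH2, tolerance)
            if idx is not None:
                claims.setdefault(idx, []).append((bi, k))
    profiles = [
        LadderProfile(base, {k: 0.0 for k in range(max_me + 1)})
        for base in base_comps
    ]
    for idx, claimants in claims.items():
        share = float(peaks.intensity[idx]) / len(claimants)
        if len(claimants) > 1:
            bases = ", ".join(base_comps[bi].label() for bi, _ in claimants)
            msg = (
                f"peak {peaks.mz[idx]:.4f} claimed by {len(claimants)} ladders "
                f"({bases}); intensity split equally"
            )
            for bi, _ in claimants:
                profiles[bi].warnings.append(msg)
        for bi, k in claimants:
            profiles[bi].intensity_by_me[k] += share
    return profiles


def annotate_peaklist(
    peaks: PeakList,
    tolerance: float = 0.1,
    bounds: Optional[dict] = None,
    min_relative_intensity: float = 0.0,
) -> pd.DataFrame:
    """Assign the best composition to every MS1 peak.

    Returns a DataFrame (one row per peak) with the top-ranked candidate, or
    class ``unassigned`` when no composition matches within tolerance.
    """
    base = peaks.base_peak_intensity()
    rows = []
    for mz, inten in zip(peaks.mz, peaks.intensity):
        if base > 0 and inten < min_relative_intensity * base:
            continue
        cands = enumerate_compositions(mz, peaks.derivatization, tolerance, bounds)
        if cands:
            top = cands[0]
            rows.append(
                {
                    "mz": mz,
                    "intensity": inten,
                    "composition": top.composition.label(),
                    "theoretical_mz": round(top.theoretical_mz, 4),
                    "delta": round(top.delta, 4),
                    "glycan_class": top.glycan_class,
                    "n_candidates": len(cands),
                }
            )
        else:
            rows.append(
                {
                    "mz": mz,
                    "intensity": inten,
                    "composition": "",
                    "theoretical_mz": np.nan,
                    "delta": np.nan,
                    "glycan_class": "unassigned",
                    "n_candidates": 0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mz",
            "intensity",
            "composition",
            "theoretical_mz",
            "delta",
            "glycan_class",
            "n_candidates",
        ],
    )


def summary_json(assignments: pd.DataFrame) -> str:
    """JSON summary: per-class peak counts and total intensity."""
    if len(assignments) == 0:
        return json.dumps({"n_peaks": 0, "classes": {}}, sort_keys=True)
    grouped = assignments.groupby("glycan_class")["intensity"].agg(["count", "sum"])
    classes = {
        cls: {"n_peaks": int(row["count"]), "total_intensity": float(row["sum"])}
        for cls, row in grouped.iterrows()
    }
    return json.dumps(
        {"n_peaks": int(len(assignments)), "classes": classes}, sort_keys=True
    )
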