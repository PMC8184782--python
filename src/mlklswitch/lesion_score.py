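"""Grid-based Histological multivariate Lesion Score (HLS).

A digitised skin section is overlaid with a grid of equal square fields of
view (FOV) and each FOV receives one severity score:

    0  regular epidermis, no changes to any stratum
    1  epidermal thickening in any stratum
    2  epidermal erosion (partial loss, stratum basale intact)
    3  ulcer — loss of epidermis including the stratum basale
    4  ulceration with dermal/hypodermal fibrosis

The specimen score is HLS = Σ_s s · (% of FOVs scored s), ranging from 0
(fully regular epidermis) to 400 (100 % deep ulceration).  Proportions are
kept as exact rationals internally, which makes the mixture identity
HLS(G1 ∪ G2) = (n1·HLS1 + n2·HLS2)/(n1 + n2) exact rather than approximate.

Group comparisons use the exact two-sided Mann–Whitney test on per-specimen
HLS values.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .inference import RankTestResult, mann_whitney_exact

__all__ = [
    "SEVERITY_SCORES",
    "FovGrid",
    "LesionScoreResult",
    "compute_hls",
    "fov_geometry",
    "compare_hls_groups",
    "pool_sections",
    "read_fov_csv",
    "results_to_dataframe",
]

SEVERITY_SCORES = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class FovGrid:
    """Per-specimen grid: one severity score per field of view."""

    specimen_id: str
    scores: tuple[int, ...]
    genotype: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        scores = tuple(int(s) for s in self.scores)
        if not scores:
            raise ValueError(f"specimen {self.specimen_id}: grid has no FOVs")
        for i, s in enumerate(scores):
            if s not in SEVERITY_SCORES:
                raise ValueError(
                    f"specimen {self.specimen_id}: FOV {i} has score {s}, "
                    "outside the 0-4 severity scale"
                )
        object.__setattr__(self, "scores", scores)

    @property
    def n_fov(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class LesionScoreResult:
    """Severity-class proportions (percent) and the specimen HLS."""

    specimen_id: str
    proportions: dict[int, Fraction]  # percent per class, exact; sums to 100
    hls_exact: Fraction
    genotype: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        if sum(self.proportions.values()) != 100:
            raise ValueError("class proportions must sum to 100%")
        if not 0 <= self.hls_exact <= 400:
            raise ValueError("HLS outside [0, 400]")

    @property
    def hls(self) -> float:
        return float(self.hls_exact)

    def proportions_percent(self) -> dict[int, float]:
        return {s: float(p) for s, p in self.proportions.items()}


def compute_hls(grid: FovGrid) -> LesionScoreResult:
    """HLS of one specimen: Σ_s s · (percent of FOVs in severity class s)."""
    n = grid.n_fov
    counts = Counter(grid.scores)
    proportions = {s: Fraction(100 * counts.get(s, 0), n) for s in SEVERITY_SCORES}
    hls = sum((s * p for s, p in proportions.items()), start=Fraction(0))
    return LesionScoreResult(grid.specimen_id, proportions, hls,
                             grid.genotype, grid.treatment)


def fov_geometry(area_mm2: float) -> tuple[float, float]:
    """Side and perimeter (µm) of a square FOV of the given area (mm²).

    The published grid uses 0.04 mm² FOVs, i.e. 200 µm sides and an 800 µm
    perimeter.
    """
    if area_mm2 <= 0:
        raise ValueError("FOV area must be positive")
    side_um = 1000.0 * area_mm2 ** 0.5
    return side_um, 4.0 * side_um


def pool_sections(grids: Sequence[FovGrid], specimen_id: str | None = None) -> FovGrid:
    """Pool FOVs of several sections of the same animal into one grid.

    When two sections per mouse are scored, proportions are taken over the
    pooled FOVs; per-section results can still be computed from the inputs.
    """
    if not grids:
        raise ValueError("no sections to pool")
    sid = specimen_id or grids[0].specimen_id
    scores: list[int] = []
    for g in grids:
        scores.extend(g.scores)
    return FovGrid(sid, tuple(scores), grids[0].genotype, grids[0].treatment)


def compare_hls_groups(
    results_a: Iterable[LesionScoreResult | float],
    results_b: Iterable[LesionScoreResult | float],
) -> RankTestResult:
    """Exact two-sided Mann–Whitney test on per-specimen HLS values."""

    def _values(results) -> list[float]:
        return [r.hls if isinstance(r, LesionScoreResult) else float(r) for r in results]

    a, b = _values(results_a), _values(results_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 specimens")
    return mann_whitney_exact(a, b)


# --- CSV I/O ---------------------------------------------------------------

def read_fov_csv(path: str | Path, pool_by_specimen: bool = True) -> list[FovGrid]:
    """Read per-FOV scores from a tidy CSV.

    Required columns: specimen_id, score.  Optional: genotype, treatment,
    section, fov_index.  With ``pool_by_specimen`` (default) FOVs from all
    sections of one specimen are pooled into a single grid.
    """
    df = pd.read_csv(path)
    required = {"specimen_id", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: FOV table needs columns {sorted(required)}")
    group_cols = ["specimen_id"] if pool_by_specimen else \
        ["specimen_id"] + (["section"] if "section" in df.columns else [])
    sort_cols = ["specimen_id"] + (["section"] if "section" in df.columns else [])
    if "fov_index" in df.columns:
        sort_cols.append("fov_index")
    df = df.sort_values(sort_cols, kind="stable")
    grids = []
    for key, sub in df.groupby(group_cols, sort=True):
        sid = key[0] if isinstance(key, tuple) else key
        grids.append(FovGrid(
            specimen_id=str(sid),
            scores=tuple(int(s) for s in sub["score"]),
            genotype=str(sub["genotype"].iloc[0]) if "genotype" in sub else "",
            treatment=str(sub["treatment"].iloc[0]) if "treatment" in sub else "",
        ))
    return grids


def results_to_dataframe(results: Iterable[LesionScoreResult]) -> pd.DataFrame:
    """Per-specimen proportions and HLS as a flat table."""
    rows = []
    for r in results:
        row = {"specimen_id": r.specimen_id, "genotype": r.genotype,
               "treatment": r.treatment, "hls": r.hls}
        for s in SEVERITY_SCORES:
            row[f"pct_score_{s}"] = float(r.proportions[s])
        rows.append(row)
    return pd.DataFrame(rows)
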