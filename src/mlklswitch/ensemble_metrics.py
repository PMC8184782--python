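"""Ensemble-level quantities of the MLKL switch simulations.

Turns a :class:`~mlklswitch.trajectory_io.TrajectoryEnsemble` into the
figure-level observables: per-frame angle series (activation-loop helix vs
adjacent helix; 4HB domain vs pseudokinase domain), K219::Q343 hydrogen-bond
occupancy, pooled histograms over all replicates, per-time replicate
mean/SD envelopes, per-replicate grand means (the exchangeable units of the
permutation test) and relative-RMSF summaries.

Histograms pool all frames of all independent replicates of one construct
before binning; replicate identity is kept everywhere else so that
statistics can treat replicates — not frames — as independent observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    HBondCriteria,
    hbond_present,
    helix_axis,
    inter_axis_angle,
    principal_axis,
    relative_rmsf,
)
from .trajectory_io import (
    ConformationFrame,
    DomainAnnotation,
    TrajectoryEnsemble,
    select_atom_indices,
)

__all__ = [
    "MetricSeries",
    "EnsembleHistogram",
    "ReplicateSummary",
    "OccupancyResult",
    "angle_series",
    "hbond_occupancy",
    "pooled_histogram",
    "replicate_summary",
    "reference_metric",
    "rmsf_summary",
    "series_to_dataframe",
    "histogram_to_dataframe",
]

ANGLE_MODES = ("helix_helix", "domain_domain")


@dataclass
class MetricSeries:
    """Per-frame scalar metric, one list per replicate."""

    metric_name: str
    construct: str
    values: list[np.ndarray]   # one array of per-frame values per replicate
    time_ps: list[np.ndarray]  # matching time stamps

    def __post_init__(self) -> None:
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        self.time_ps = [np.asarray(t, dtype=float) for t in self.time_ps]
        if len(self.values) != len(self.time_ps):
            raise ValueError("values and time_ps must have one entry per replicate")
        for r, (v, t) in enumerate(zip(self.values, self.time_ps)):
            if v.shape != t.shape:
                raise ValueError(f"replicate {r}: value/time length mismatch")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"replicate {r}: non-finite metric values")

    @property
    def n_replicates(self) -> int:
        return len(self.values)

    def pooled(self) -> np.ndarray:
        """All frames of all replicates, concatenated."""
        return np.concatenate(self.values)

    def grand_means(self) -> np.ndarray:
        """Time-average of each replicate — one exchangeable value per replicate."""
        return np.array([v.mean() for v in self.values])


@dataclass
class EnsembleHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_total: int
    normalised: bool = False

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if not self.normalised and int(self.counts.sum()) != self.n_total:
            raise ValueError("histogram counts do not sum to n_total")

    def density(self) -> np.ndarray:
        widths = np.diff(self.bin_edges)
        return self.counts / (self.n_total * widths)


@dataclass
class ReplicateSummary:
    """Across-replicate mean and sample SD at each time point, plus grand means."""

    time_ps: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    grand_means: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sd < 0):
            raise ValueError("SD must be non-negative")


@dataclass
class OccupancyResult:
    """Hydrogen-bond occupancy, pooled and per replicate."""

    pooled: float
    per_replicate: np.ndarray
    series: MetricSeries

    def __post_init__(self) -> None:
        if not 0.0 <= self.pooled <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


def _selection(ensemble: TrajectoryEnsemble, annotation: DomainAnnotation,
               residue_range: tuple[int, int], atom_name: str = "CA") -> np.ndarray:
    table = ensemble.replicates[0][0].table
    idx = select_atom_indices(table, residue_range, atom_name, annotation.chain_id)
    if idx.size == 0:
        raise ValueError(
            f"empty selection: residues {residue_range[0]}-{residue_range[1]} "
            f"atom {atom_name} chain {annotation.chain_id}"
        )
    return idx


def _domain_axes_reference(reference: ConformationFrame, idx_a: np.ndarray,
                           idx_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return (principal_axis(reference.coords[idx_a]),
            principal_axis(reference.coords[idx_b]))


def angle_series(
    ensemble: TrajectoryEnsemble,
    annotation: DomainAnnotation,
    mode: str,
    reference_frame: ConformationFrame | None = None,
) -> MetricSeries:
    """Per-frame inter-axis angle series for one construct.

    mode="helix_helix"
        Angle between the activation-loop helix axis and the adjacent helix
        axis (both Cα principal axes oriented N→C).
    mode="domain_domain"
        Angle between the first principal axes of the 4HB and pseudokinase
        Cα sets, each sign-fixed against the corresponding axis of the
        reference frame (the crystal structure when available; the first
        frame of the first replicate otherwise).
    """
    if mode not in ANGLE_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {ANGLE_MODES}")

    if mode == "helix_helix":
        idx_a = _selection(ensemble, annotation, annotation.loop_helix_range)
        idx_b = _selection(ensemble, annotation, annotation.adjacent_helix_range)
        ref_axes = None
        name = "loop_helix_angle"
    else:
        idx_a = _selection(ensemble, annotation, annotation.fourhb_range)
        idx_b = _selection(ensemble, annotation, annotation.pseudokinase_range)
        if reference_frame is None:
            reference_frame = ensemble.replicates[0][0]
        ref_axes = _domain_axes_reference(reference_frame, idx_a, idx_b)
        name = "interdomain_angle"

    values, times = [], []
    for rep in ensemble.replicates:
        vals = np.empty(len(rep))
        for k, frame in enumerate(rep):
            if mode == "helix_helix":
                ax_a = helix_axis(frame.coords[idx_a])
                ax_b = helix_axis(frame.coords[idx_b])
            else:
                ax_a = principal_axis(frame.coords[idx_a], reference_axis=ref_axes[0])
                ax_b = principal_axis(frame.coords[idx_b], reference_axis=ref_axes[1])
            vals[k] = inter_axis_angle(ax_a, ax_b)
        values.append(vals)
        times.append(np.array([f.time_ps for f in rep]))
    return MetricSeries(name, ensemble.construct, values, times)


def reference_metric(
    reference_frame: ConformationFrame,
    annotation: DomainAnnotation,
    mode: str,
) -> float:
    """The same angle computed on a single (crystal) structure.

    Plotted as the dashed vertical reference line on the pooled histograms.
    """
    if mode not in ANGLE_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {ANGLE_MODES}")
    if mode == "helix_helix":
        ranges = (annotation.loop_helix_range, annotation.adjacent_helix_range)
    else:
        ranges = (annotation.fourhb_range, annotation.pseudokinase_range)
    axes = []
    for rng in ranges:
        idx = select_atom_indices(reference_frame.table, rng, "CA", annotation.chain_id)
        if idx.size < 4:
            raise ValueError(f"reference structure lacks Cα atoms in {rng[0]}-{rng[1]}")
        axes.append(helix_axis(reference_frame.coords[idx]))
    return inter_axis_angle(axes[0], axes[1])


def hbond_occupancy(
    ensemble: TrajectoryEnsemble,
    annotation: DomainAnnotation,
    criteria: HBondCriteria = HBondCriteria(),
) -> OccupancyResult:
    """Fraction of frames in which the K219::Q343 hydrogen bond is formed.

    The pooled fraction (true frames / all frames over all replicates) is the
    primary estimate; per-replicate fractions are returned alongside for
    replicate-level statistics.
    """
    values, times = [], []
    for rep in ensemble.replicates:
        flags = np.array([
            float(hbond_present(frame, annotation.hbond_donor,
                                annotation.hbond_acceptor, criteria))
            for frame in rep
        ])
        values.append(flags)
        times.append(np.array([f.time_ps for f in rep]))
    series = MetricSeries("hbond_indicator", ensemble.construct, values, times)
    per_rep = np.array([v.mean() for v in values])
    pooled = float(series.pooled().mean())
    return OccupancyResult(pooled, per_rep, series)


def pooled_histogram(series: MetricSeries, bin_width: float = 2.0) -> EnsembleHistogram:
    """Histogram of all frames of all replicates, on bin-width-aligned edges.

    Edges start at ``floor(min / width) * width`` so that identical data give
    identical bins regardless of replicate ordering; the final edge closes the
    last bin (right-inclusive, numpy convention), so counts always conserve
    the total frame number.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    pooled = series.pooled()
    if pooled.size == 0:
        raise ValueError("empty metric series")
    lo = np.floor(pooled.min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((pooled.max() - lo) / bin_width)))
    if lo + n_bins * bin_width <= pooled.max():
        n_bins += 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(pooled, bins=edges)
    return EnsembleHistogram(edges, counts.astype(int), int(pooled.size))


def replicate_summary(series: MetricSeries) -> ReplicateSummary:
    """Across-replicate mean ± sample SD at every time point.

    This is the shaded-envelope view of a metric trace: the line is the mean
    over independent replicates, the band the n−1 SD.  Requires ≥2 replicates
    of equal length.
    """
    if series.n_replicates < 2:
        raise ValueError("replicate summary needs at least 2 replicates")
    lengths = {len(v) for v in series.values}
    if len(lengths) != 1:
        raise ValueError("ragged replicate lengths; trim to a common length first")
    stack = np.vstack(series.values)  # (n_rep, n_frames)
    times = series.time_ps[0]
    for t in series.time_ps[1:]:
        if not np.array_equal(t, times):
            raise ValueError("replicates disagree on time stamps")
    return ReplicateSummary(
        time_ps=times,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=1),
        grand_means=series.grand_means(),
    )


def rmsf_summary(
    ensemble: TrajectoryEnsemble,
    annotation: DomainAnnotation,
    two_pass: bool = False,
) -> MetricSeries:
    """Mean relative RMSF of the 4HB domain, one value per replicate.

    Each replicate's frames are superposed on the pseudokinase Cα set and the
    4HB Cα fluctuations measured; the per-replicate mean RMSF values feed the
    replicate-mean permutation test.
    """
    fit_idx = _selection(ensemble, annotation, annotation.pseudokinase_range)
    measure_idx = _selection(ensemble, annotation, annotation.fourhb_range)
    values, times = [], []
    for rep in ensemble.replicates:
        coords = np.stack([f.coords for f in rep])
        _, mean_rmsf = relative_rmsf(coords, fit_idx, measure_idx, two_pass=two_pass)
        values.append(np.array([mean_rmsf]))
        times.append(np.array([0.0]))
    return MetricSeries("rmsf_summary", ensemble.construct, values, times)


# --- tidy-table output -----------------------------------------------------

def series_to_dataframe(series: MetricSeries) -> pd.DataFrame:
    """Tidy long table: construct, replicate, time_ps, metric, value."""
    rows = []
    for r, (vals, times) in enumerate(zip(series.values, series.time_ps)):
        rows.append(pd.DataFrame({
            "construct": series.construct,
            "replicate": r,
            "time_ps": times,
            "metric": series.metric_name,
            "value": vals,
        }))
    return pd.concat(rows, ignore_index=True)


def histogram_to_dataframe(hist: EnsembleHistogram) -> pd.DataFrame:
    return pd.DataFrame({
        "bin_lo": hist.bin_edges[:-1],
        "bin_hi": hist.bin_edges[1:],
        "count": hist.counts,
    })
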