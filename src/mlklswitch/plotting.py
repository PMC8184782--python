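"""Best-effort plots of ensemble metrics (requires matplotlib)."""

from __future__ import annotations

from .ensemble_metrics import EnsembleHistogram, ReplicateSummary


def plot_pooled_histogram(hist: EnsembleHistogram, reference: float | None = None,
                          mean: float | None = None, ax=None, **kwargs):
    """Pooled-ensemble histogram with optional crystal (dashed) and mean lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centres = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    widths = hist.bin_edges[1:] - hist.bin_edges[:-1]
    ax.bar(centres, hist.density(), width=widths, align="center",
           edgecolor="none", **kwargs)
    if reference is not None:
        ax.axvline(reference, color="black", linestyle="--", label="crystal")
    if mean is not None:
        ax.axvline(mean, color="C3", linestyle="-", label="ensemble mean")
    ax.set_ylabel("density")
    return ax


def plot_replicate_envelope(summary: ReplicateSummary, ax=None, **kwargs):
    """Across-replicate mean trace with a ±SD shaded envelope."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(summary.time_ps, summary.mean, **kwargs)
    ax.fill_between(summary.time_ps, summary.mean - summary.sd,
                    summary.mean + summary.sd, alpha=0.3)
    ax.set_xlabel("time (ps)")
    return ax
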