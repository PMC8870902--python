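"""Aggregate per-stack cavity statistics into reporting quantities.

The headline quantity is the average cavity depth (mean ± sample SD, µm)
per experimental condition (cell type, day, gel type), alongside the same
statistics for prominence and the maximum depth reached. Aggregation
across replicate stacks is reported both pooled (all peaks together) and
as per-stack means, explicitly labelled, since the two differ when stacks
contribute unequal peak counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GelpenError
from .topography import PeakSet

#: Stable column order of the condition-comparison table.
SUMMARY_COLUMNS = (
    "cell_type",
    "day",
    "gel_type",
    "aggregation",
    "n_peaks",
    "mean_depth_um",
    "sd_depth_um",
    "mean_prominence_um",
    "sd_prominence_um",
    "max_depth_um",
)


@dataclass(frozen=True)
class MigrationSummary:
    """Summary statistics of one condition's cavities.

    Statistics are ``None`` (absent, not zero) when they are undefined:
    all of them for an empty peak set, the SDs for a single peak
    (sample SD uses the n-1 denominator).
    """

    n_peaks: int
    mean_depth_um: float | None = None
    sd_depth_um: float | None = None
    mean_prominence_um: float | None = None
    sd_prominence_um: float | None = None
    max_depth_um: float | None = None
    cell_type: str = ""
    day: str = ""
    gel_type: str = ""
    aggregation: str = "pooled"

    @property
    def labels(self) -> tuple[str, str, str, str]:
        return (self.cell_type, self.day, self.gel_type, self.aggregation)


def _mean_sd(values: np.ndarray) -> tuple[float | None, float | None]:
    vals = values[np.isfinite(values)]
    if vals.size == 0:
        return None, None
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else None
    return mean, sd


def summarize_peaks(peaks: PeakSet, labels: dict[str, str] | None = None) -> MigrationSummary:
    """Mean and sample SD of depth and prominence over a peak set."""
    labels = labels or {}
    depths = peaks.depths_um
    proms = peaks.prominences_um
    mean_d, sd_d = _mean_sd(depths)
    mean_p, sd_p = _mean_sd(proms)
    return MigrationSummary(
        n_peaks=len(peaks),
        mean_depth_um=mean_d,
        sd_depth_um=sd_d,
        mean_prominence_um=mean_p,
        sd_prominence_um=sd_p,
        max_depth_um=float(depths.max()) if depths.size else None,
        cell_type=str(labels.get("cell_type", "")),
        day=str(labels.get("day", "")),
        gel_type=str(labels.get("gel_type", "")),
        aggregation=str(labels.get("aggregation", "pooled")),
    )


def pooled_summary(
    peak_sets: Sequence[PeakSet], labels: dict[str, str] | None = None
) -> MigrationSummary:
    """Pool the peaks of replicate stacks and summarize them together."""
    labels = dict(labels or {})
    labels.setdefault("aggregation", "pooled")
    depths = np.concatenate([ps.depths_um for ps in peak_sets]) if peak_sets else np.array([])
    proms = np.concatenate([ps.prominences_um for ps in peak_sets]) if peak_sets else np.array([])
    mean_d, sd_d = _mean_sd(depths)
    mean_p, sd_p = _mean_sd(proms)
    return MigrationSummary(
        n_peaks=int(depths.size),
        mean_depth_um=mean_d,
        sd_depth_um=sd_d,
        mean_prominence_um=mean_p,
        sd_prominence_um=sd_p,
        max_depth_um=float(depths.max()) if depths.size else None,
        cell_type=str(labels.get("cell_type", "")),
        day=str(labels.get("day", "")),
        gel_type=str(labels.get("gel_type", "")),
        aggregation=str(labels["aggregation"]),
    )


def per_stack_summary(
    peak_sets: Sequence[PeakSet], labels: dict[str, str] | None = None
) -> MigrationSummary:
    """Average the per-stack mean depths (each stack weighted equally)."""
    labels = dict(labels or {})
    labels["aggregation"] = "per_stack_mean"
    stack_means_d = [s.mean_depth_um for ps in peak_sets if (s := summarize_peaks(ps)).n_peaks > 0]
    stack_means_p = [summarize_peaks(ps).mean_prominence_um for ps in peak_sets if len(ps) > 0]
    depths_all = np.concatenate([ps.depths_um for ps in peak_sets]) if peak_sets else np.array([])
    mean_d, sd_d = _mean_sd(np.array(stack_means_d, dtype=float))
    mean_p, sd_p = _mean_sd(np.array([m for m in stack_means_p if m is not None], dtype=float))
    return MigrationSummary(
        n_peaks=int(depths_all.size),
        mean_depth_um=mean_d,
        sd_depth_um=sd_d,
        mean_prominence_um=mean_p,
        sd_prominence_um=sd_p,
        max_depth_um=float(depths_all.max()) if depths_all.size else None,
        cell_type=str(labels.get("cell_type", "")),
        day=str(labels.get("day", "")),
        gel_type=str(labels.get("gel_type", "")),
        aggregation="per_stack_mean",
    )


def compare_conditions(summaries: Sequence[MigrationSummary]) -> pd.DataFrame:
    """Long-format table, one row per condition; no hypothesis testing."""
    if len(summaries) < 1:
        raise GelpenError("compare_conditions needs at least one summary")
    seen = set()
    for s in summaries:
        if s.labels in seen:
            raise GelpenError(f"duplicate condition label set: {s.labels}")
        seen.add(s.labels)
    rows = [
        {
            "cell_type": s.cell_type,
            "day": s.day,
            "gel_type": s.gel_type,
            "aggregation": s.aggregation,
            "n_peaks": s.n_peaks,
            "mean_depth_um": s.mean_depth_um,
            "sd_depth_um": s.sd_depth_um,
            "mean_prominence_um": s.mean_prominence_um,
            "sd_prominence_um": s.sd_prominence_um,
            "max_depth_um": s.max_depth_um,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def plot_peak_histograms(peaks: PeakSet, path: str | Path, bin_um: float = 5.0) -> Path:
    """Depth and prominence histograms of one peak set, saved as an image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    for ax, vals, title in (
        (axes[0], peaks.depths_um, "cavity depth (µm)"),
        (axes[1], peaks.prominences_um, "prominence (µm)"),
    ):
        if vals.size:
            hi = np.ceil(vals.max() / bin_um) * bin_um
            ax.hist(vals, bins=np.arange(0, hi + bin_um, bin_um), color="#4c72b0")
        ax.set_xlabel(title)
        ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
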