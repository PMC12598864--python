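"""Running-average convergence analysis of per-configuration energies.

Cluster-continuum solvation free energies are averaged over an ensemble of
explicit-solvent cluster configurations.  This module tracks the running
mean and standard error of such an ordered energy stream and locates the
configuration count after which the running mean stays inside a tolerance
band around the final value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .thermochem import Quantity

__all__ = [
    "EnergyStream",
    "ConvergenceSummary",
    "running_stats",
    "detect_convergence",
    "NOT_CONVERGED",
]

#: Sentinel returned when no prefix satisfies the tolerance band.
NOT_CONVERGED = -1


@dataclass(frozen=True)
class EnergyStream:
    """Ordered per-configuration energies (kcal/mol).

    ``truth`` optionally records the known population mean for synthetic
    streams, so recovery can be checked downstream.
    """

    values: np.ndarray
    label: str = ""
    truth: float | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("stream must be a nonempty 1-D array")
        if not np.all(np.isfinite(vals)):
            raise ValueError("stream contains non-finite values")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class ConvergenceSummary:
    """Running mean/SE sequences and the detected convergence point.

    ``running_se[0]`` is NaN (a single configuration has no dispersion).
    ``convergence_index`` is 1-based: the smallest number of configurations
    after which the running mean never leaves the tolerance band around the
    final mean, or :data:`NOT_CONVERGED`.
    """

    running_mean: np.ndarray
    running_se: np.ndarray
    final: Quantity
    convergence_index: int
    tolerance: float
    label: str = ""

    @property
    def n(self) -> int:
        return int(self.running_mean.size)


def _running_mean_se(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = values.size
    k = np.arange(1, n + 1, dtype=float)
    csum = np.cumsum(values)
    means = csum / k
    csq = np.cumsum(values**2)
    # unbiased variance of the first k values, guarded for k = 1
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (csq - k * means**2) / (k - 1)
    var = np.clip(var, 0.0, None)
    se = np.sqrt(var / k)
    se[0] = np.nan
    return means, se


def running_stats(
    stream: EnergyStream, tolerance: float | None = None
) -> ConvergenceSummary:
    """Prefix means and standard errors, plus the convergence index.

    ``tolerance`` defaults to the final standard error of the mean (one
    SE band); pass an explicit value in kcal/mol to override.
    """
    values = stream.values
    means, se = _running_mean_se(values)
    n = values.size
    final_se = float(se[-1]) if n > 1 else 0.0
    final = Quantity(float(means[-1]), final_se, "kcal/mol")
    if tolerance is None:
        tolerance = final_se if n > 1 else 0.0
    summary = ConvergenceSummary(
        running_mean=means,
        running_se=se,
        final=final,
        convergence_index=0,
        tolerance=float(tolerance),
        label=stream.label,
    )
    idx = detect_convergence(summary, tolerance) if tolerance > 0 else (
        1 if np.allclose(values, values[0]) else NOT_CONVERGED
    )
    object.__setattr__(summary, "convergence_index", idx)
    return summary


def detect_convergence(summary: ConvergenceSummary, tolerance: float) -> int:
    """Smallest 1-based k with |mean_j - mean_n| <= tolerance for all j >= k.

    Returns :data:`NOT_CONVERGED` if even the final prefix mean is outside
    the band (cannot happen for positive tolerance, since mean_n is its own
    reference, so the result is always <= n there).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    means = summary.running_mean
    final = means[-1]
    inside = np.abs(means - final) <= tolerance
    # last index where the mean is outside the band
    outside = np.nonzero(~inside)[0]
    if outside.size == 0:
        return 1
    k = int(outside[-1]) + 2  # first index after the last excursion, 1-based
    return k if k <= means.size else NOT_CONVERGED


def plot_running_mean(
    summary: ConvergenceSummary,
    path: str,
    reference: float | None = None,
) -> None:
    """Write a running-mean convergence figure (PNG/SVG by extension).

    Shows the running mean with a +-1 SE band, the tolerance band around
    the final mean, and an optional horizontal reference line.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = np.arange(1, summary.n + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(k, summary.running_mean, lw=1.2, label="running mean")
    se = summary.running_se
    ax.fill_between(
        k, summary.running_mean - se, summary.running_mean + se,
        alpha=0.25, linewidth=0, label="±1 SE",
    )
    final = summary.final.value
    ax.axhline(final, ls="--", lw=0.8, color="k")
    ax.axhspan(
        final - summary.tolerance, final + summary.tolerance,
        alpha=0.12, color="grey", label="tolerance band",
    )
    if reference is not None:
        ax.axhline(reference, ls=":", lw=1.0, color="C3", label="reference")
    if summary.convergence_index != NOT_CONVERGED:
        ax.axvline(summary.convergence_index, ls=":", lw=0.8, color="C2")
    ax.set_xlabel("configurations")
    ax.set_ylabel("energy (kcal/mol)")
    if summary.label:
        ax.set_title(summary.label)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
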