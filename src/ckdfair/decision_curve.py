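"""Decision-curve analysis: net benefit of model-guided intervention.

Net benefit at an intervention threshold ``p_t`` is
``TP/N - (FP/N) * p_t / (1 - p_t)`` -- true-positive-equivalent gain per
patient after penalizing false positives by the odds at which a patient (or
clinician) would accept intervention.  Model curves are compared against the
default strategies of treating everyone
(``prevalence - (1 - prevalence) * p_t / (1 - p_t)``, which crosses zero
exactly at ``p_t = prevalence``) and treating no one (always zero).  The
flagging convention is boundary-inclusive (``score >= p_t``), shared with
the classification metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fairness_eval import ConfusionCounts, confusion_at_threshold

__all__ = [
    "DecisionCurvePoint",
    "net_benefit",
    "reference_strategies",
    "decision_curve",
    "default_grid",
]


def default_grid(start: float = 0.05, stop: float = 0.50, step: float = 0.01):
    """Threshold grid 5%..50% in 1% steps (endpoint inclusive)."""
    n = int(round((stop - start) / step))
    return np.round(start + step * np.arange(n + 1), 10)


@dataclass
class DecisionCurvePoint:
    """Net benefit of the model and reference strategies at one threshold."""

    threshold: float
    net_benefit: float
    treat_all: float
    treat_none: float = 0.0


def net_benefit(counts: ConfusionCounts, p_t: float) -> float:
    """Net benefit ``TP/N - (FP/N) * p_t/(1-p_t)`` (may be negative)."""
    if not 0.0 < p_t < 1.0:
        raise ValueError("threshold must be strictly inside (0, 1)")
    if abs(counts.threshold - p_t) > 1e-12:
        raise ValueError(
            f"counts were taken at threshold {counts.threshold}, not {p_t}"
        )
    n = counts.n
    return float(counts.tp / n - (counts.fp / n) * (p_t / (1.0 - p_t)))


def reference_strategies(prevalence: float, p_t: float):
    """Net benefit of treat-all and treat-none at one threshold.

    Treat-all flags everyone: TP/N = prevalence and FP/N = 1 - prevalence.
    Treat-none is identically zero.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be strictly inside (0, 1)")
    if not 0.0 < p_t < 1.0:
        raise ValueError("threshold must be strictly inside (0, 1)")
    treat_all = prevalence - (1.0 - prevalence) * (p_t / (1.0 - p_t))
    return float(treat_all), 0.0


def decision_curve(scores, labels, grid=None):
    """Net-benefit curve of a model across a threshold grid.

    Out-of-fold scores only.  Returns one :class:`DecisionCurvePoint` per
    threshold; deterministic.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    y = np.asarray(labels, dtype=float).ravel()
    prevalence = float(y.mean())
    points = []
    for p_t in grid:
        p_t = float(p_t)
        counts = confusion_at_threshold(scores, labels, p_t)
        treat_all, treat_none = reference_strategies(prevalence, p_t)
        points.append(DecisionCurvePoint(
            threshold=p_t,
            net_benefit=net_benefit(counts, p_t),
            treat_all=treat_all,
            treat_none=treat_none,
        ))
    return points


def curve_frame(points) -> pd.DataFrame:
    """Tidy frame (threshold, net_benefit, treat_all, treat_none)."""
    return pd.DataFrame([
        {
            "threshold": p.threshold,
            "net_benefit": p.net_benefit,
            "treat_all": p.treat_all,
            "treat_none": p.treat_none,
        }
        for p in points
    ])
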