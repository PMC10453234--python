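"""Risk-level classification, distribution summaries, and report export.

A composite risk above the warning threshold (default 1.0) means at least
one indicator's weighted contribution pushed the sample past a regulatory
exceedance, so samples are color-coded high (> threshold), medium (between
half the threshold and the threshold, boundaries inclusive toward the more
cautious interior category), and low (< half the threshold).
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "RiskLevelAssignment",
    "RiskSummary",
    "classify_risk",
    "classify_risks",
    "summarize_risks",
    "export_report",
]

LEVELS = ("low", "medium", "high")
_LEVEL_COLORS = {"low": "#2ca02c", "medium": "#ffbf00", "high": "#d62728"}


@dataclass(frozen=True)
class RiskLevelAssignment:
    sample: str
    risk: float
    level: str
    warning_threshold: float


@dataclass(frozen=True)
class RiskSummary:
    """Five-number-style summary plus the per-level sample proportions."""

    n: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    proportions: dict[str, float]
    warning_threshold: float


def classify_risk(risk: float, threshold: float = 1.0) -> str:
    """Level of one risk value: low / medium / high.

    Boundary ties go to the interior (more cautious) category: exactly
    threshold/2 is medium, exactly threshold is medium.
    """
    if threshold <= 0:
        raise ValueError(f"warning threshold must be positive, got {threshold}")
    if risk < 0:
        raise ValueError(f"risk values are non-negative, got {risk}")
    if risk > threshold:
        return "high"
    if risk >= threshold / 2.0:
        return "medium"
    return "low"


def classify_risks(
    risks: Sequence[float],
    samples: Sequence[str] | None = None,
    threshold: float = 1.0,
) -> list[RiskLevelAssignment]:
    risks = np.asarray(risks, dtype=float)
    if samples is None:
        samples = [str(i + 1) for i in range(risks.size)]
    if len(samples) != risks.size:
        raise ValueError("sample ids and risks must align")
    return [
        RiskLevelAssignment(str(s), float(r), classify_risk(float(r), threshold), threshold)
        for s, r in zip(samples, risks)
    ]


def summarize_risks(risks: Sequence[float], threshold: float = 1.0) -> RiskSummary:
    """Quartiles (inclusive linear interpolation) and per-level proportions."""
    risks = np.asarray(risks, dtype=float)
    if risks.size == 0:
        raise ValueError("cannot summarize an empty risk vector")
    q1, median, q3 = np.quantile(risks, [0.25, 0.5, 0.75], method="linear")
    levels = [classify_risk(float(r), threshold) for r in risks]
    proportions = {lvl: levels.count(lvl) / risks.size for lvl in LEVELS}
    return RiskSummary(
        n=int(risks.size),
        minimum=float(risks.min()),
        q1=float(q1),
        median=float(median),
        q3=float(q3),
        maximum=float(risks.max()),
        proportions=proportions,
        warning_threshold=float(threshold),
    )


def _assignments_frame(assignments: Sequence[RiskLevelAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [a.sample for a in assignments],
            "risk": [a.risk for a in assignments],
            "level": [a.level for a in assignments],
            "warning_threshold": [a.warning_threshold for a in assignments],
        }
    )


def export_report(
    assignments: Sequence[RiskLevelAssignment],
    summary: RiskSummary,
    destination: str,
    *,
    plots: bool = False,
    hazard: np.ndarray | None = None,
    indicator_names: Sequence[str] | None = None,
) -> dict[str, str]:
    """Write per-sample assignments (CSV), the summary (JSON) and optional plots.

    Output is byte-stable: fixed row order and float formatting, sorted JSON
    keys.  ``hazard`` (indicators x samples) enables the parallel-coordinate
    hazard-composition plot.  Returns {artifact name: path}.
    """
    if not assignments:
        raise ValueError("no assignments to export")
    os.makedirs(destination, exist_ok=True)
    paths: dict[str, str] = {}

    csv_path = os.path.join(destination, "risk_assignments.csv")
    _assignments_frame(assignments).to_csv(csv_path, index=False, float_format="%.6f")
    paths["assignments"] = csv_path

    json_path = os.path.join(destination, "risk_summary.json")
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(asdict(summary), fh, indent=2, sort_keys=True)
    paths["summary"] = json_path

    if plots:
        paths.update(
            _export_plots(assignments, summary, destination, hazard, indicator_names)
        )
    return paths


def _export_plots(
    assignments: Sequence[RiskLevelAssignment],
    summary: RiskSummary,
    destination: str,
    hazard: np.ndarray | None,
    indicator_names: Sequence[str] | None,
) -> dict[str, str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths: dict[str, str] = {}
    risks = np.array([a.risk for a in assignments])
    colors = [_LEVEL_COLORS[a.level] for a in assignments]
    threshold = summary.warning_threshold

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].scatter(np.arange(risks.size), risks, c=colors, s=18)
    axes[0].axhline(threshold, color=_LEVEL_COLORS["high"], ls="--", lw=1)
    axes[0].axhline(threshold / 2, color=_LEVEL_COLORS["medium"], ls="--", lw=1)
    axes[0].set_xlabel("sample")
    axes[0].set_ylabel("composite risk")
    axes[0].set_title("predicted risk per sample")
    props = summary.proportions
    axes[1].bar(list(props), [props[k] for k in props],
                color=[_LEVEL_COLORS[k] for k in props])
    axes[1].set_ylabel("proportion of samples")
    axes[1].set_title("risk-level composition")
    fig.tight_layout()
    scatter_path = os.path.join(destination, "risk_levels.png")
    fig.savefig(scatter_path, dpi=120)
    plt.close(fig)
    paths["risk_plot"] = scatter_path

    if hazard is not None:
        hazard = np.asarray(hazard, dtype=float)
        names = (list(indicator_names) if indicator_names is not None
                 else [f"i{j + 1}" for j in range(hazard.shape[0])])
        fig, ax = plt.subplots(figsize=(10, 4))
        xs = np.arange(hazard.shape[0])
        for k in range(hazard.shape[1]):
            ax.plot(xs, hazard[:, k], color=colors[k], alpha=0.35, lw=0.8)
        ax.set_xticks(xs, names, rotation=30, ha="right")
        ax.set_ylabel("hazard quotient")
        ax.set_title("per-indicator risk composition")
        fig.tight_layout()
        parallel_path = os.path.join(destination, "hazard_composition.png")
        fig.savefig(parallel_path, dpi=120)
        plt.close(fig)
        paths["hazard_plot"] = parallel_path
    return paths
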