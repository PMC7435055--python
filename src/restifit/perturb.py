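"""Treatment-vs-control percent-change analysis and chord edge lists.

For every drug group the percent change of each fitted model parameter
relative to the control group mean is computed; the strongest positive
(activation) and strongest negative (inhibition) effects are reduced to
edge lists ready for chord-diagram rendering — one view per drug, one
view per parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import PARAM_NAMES

__all__ = [
    "PerturbationEdge",
    "percent_change_table",
    "max_effects_per_drug",
    "max_effects_per_parameter",
    "export_chord_edges",
    "edges_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerturbationEdge:
    """One chord-plot arrow: a drug's strongest effect on a parameter."""

    drug: str
    parameter: str
    percent_change: float
    direction: str  # "activation" (+) or "inhibition" (−)

    def __post_init__(self) -> None:
        expected = "activation" if self.percent_change > 0 else "inhibition"
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with "
                f"percent_change {self.percent_change:+g}"
            )


def percent_change_table(
    cohort: pd.DataFrame,
    control_label: str = "control",
    parameters: tuple[str, ...] = PARAM_NAMES,
    aggregator: str = "mean",
) -> pd.DataFrame:
    """Drug × parameter matrix of percent change vs the control group.

    %Δ(d, p) = 100 · (agg_d(p) − agg_ctrl(p)) / agg_ctrl(p), with the
    aggregator (mean by default) taken over per-organoid fitted values;
    missing values are excluded pairwise.  A control aggregate of zero
    leaves that parameter's column undefined (NaN).
    """
    if control_label not in set(cohort["treatment"]):
        raise ValueError(f"control group {control_label!r} not present")
    params = [p for p in parameters if p in cohort.columns]
    grouped = cohort.groupby("treatment")[params].agg(aggregator)
    ctrl = grouped.loc[control_label]
    drugs = grouped.drop(index=control_label)
    denom = ctrl.where(ctrl != 0)
    if denom.isna().any():
        logger.warning(
            "control mean is zero for %s; reported as missing",
            list(denom.index[denom.isna()]),
        )
    return 100.0 * (drugs - ctrl) / denom


def _edge(drug: str, parameter: str, pct: float) -> PerturbationEdge:
    return PerturbationEdge(
        drug=drug,
        parameter=parameter,
        percent_change=float(pct),
        direction="activation" if pct > 0 else "inhibition",
    )


def max_effects_per_drug(matrix: pd.DataFrame) -> list[PerturbationEdge]:
    """Per drug: the most-activated and most-inhibited parameter.

    At most two edges per drug; a drug with no positive (or no negative)
    percent change contributes a single edge.  Ties resolve to the first
    parameter in column order.
    """
    if matrix.empty:
        raise ValueError("empty percent-change matrix")
    edges = []
    for drug, row in matrix.iterrows():
        row = row.dropna()
        pos = row[row > 0]
        neg = row[row < 0]
        if len(pos):
            edges.append(_edge(drug, pos.idxmax(), pos.max()))
        if len(neg):
            edges.append(_edge(drug, neg.idxmin(), neg.min()))
    return edges


def max_effects_per_parameter(matrix: pd.DataFrame) -> list[PerturbationEdge]:
    """Per parameter: the strongest enhancing and strongest inhibiting drug.

    Parameters that every drug moves in the same direction yield a
    single edge (e.g. when all treatments delay the actin peak).
    """
    if matrix.empty:
        raise ValueError("empty percent-change matrix")
    edges = []
    for parameter in matrix.columns:
        col = matrix[parameter].dropna()
        pos = col[col > 0]
        neg = col[col < 0]
        if len(pos):
            edges.append(_edge(pos.idxmax(), parameter, pos.max()))
        if len(neg):
            edges.append(_edge(neg.idxmin(), parameter, neg.min()))
    return edges


def edges_to_frame(edges: list[PerturbationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source": e.drug,
                "target": e.parameter,
                "percent_change": e.percent_change,
                "direction": e.direction,
            }
            for e in edges
        ],
        columns=["source", "target", "percent_change", "direction"],
    )


def export_chord_edges(edges: list[PerturbationEdge], path: str | Path) -> Path:
    """Write the edge list as CSV (source, target, percent_change, direction)."""
    path = Path(path)
    edges_to_frame(edges).to_csv(path, index=False)
    return path
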