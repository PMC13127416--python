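"""Incremental comparisons: stepwise ICERs with dominance handling, and NMB.

Strategies are compared on the cost-effectiveness plane.  A strategy costing
at least as much as another while delivering no more QALYs is *strictly
dominated*.  Among the remainder, sorted by cost, a strategy whose removal
restores a non-decreasing sequence of pairwise ICERs is *extended dominated*
(it is beaten by a blend of its neighbours).  Surviving strategies form the
cost-effectiveness frontier and carry incremental cost, effectiveness and
ICER relative to the previous frontier strategy.

Net monetary benefit converts effectiveness to dollars at a willingness-to-pay
threshold: ``NMB = QALY * WTP - cost``; at a given WTP the strategy with the
highest NMB is cost-effective.

A cheaper-and-more-effective comparison is labelled ``dominant`` rather than
reported as a negative ICER; the raw ratio is kept separately for users who
want the signed number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from adtcea.markov_engine import StrategyResult

__all__ = ["CEARow", "CEATable", "nmb", "icer_frontier", "incremental"]

ON_FRONTIER = "on_frontier"
STRICTLY_DOMINATED = "strictly_dominated"
EXTENDED_DOMINATED = "extended_dominated"


def nmb(result: StrategyResult, wtp: float) -> float:
    """Net monetary benefit ``qaly * wtp - cost`` in USD."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return result.qaly * wtp - result.cost


@dataclass
class CEARow:
    """One strategy's line in the incremental comparison table.

    ``icer`` holds the raw ratio (may be negative for a dominant comparison,
    None when undefined); ``icer_label`` holds the presentation value:
    "dominant", "dominated", a number, or "" for the reference row.
    """

    strategy_name: str
    cost: float
    qaly: float
    nmb: float
    dominance_status: str
    incremental_cost: float | None = None
    incremental_qaly: float | None = None
    icer: float | None = None
    icer_label: str = ""
    note: str = ""


@dataclass
class CEATable:
    """Rows sorted by ascending cost, plus the WTP used for the NMB column."""

    rows: list[CEARow]
    wtp: float

    def row(self, strategy_name: str) -> CEARow:
        for r in self.rows:
            if r.strategy_name == strategy_name:
                return r
        raise KeyError(f"no row for strategy {strategy_name!r}")

    @property
    def frontier(self) -> list[CEARow]:
        return [r for r in self.rows if r.dominance_status == ON_FRONTIER]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": r.strategy_name,
                    "cost": r.cost,
                    "qaly": r.qaly,
                    "nmb": r.nmb,
                    "dominance_status": r.dominance_status,
                    "incremental_cost": r.incremental_cost,
                    "incremental_qaly": r.incremental_qaly,
                    "icer": r.icer,
                    "icer_label": r.icer_label,
                    "note": r.note,
                }
                for r in self.rows
            ]
        )


def incremental(a: StrategyResult, b: StrategyResult, wtp: float) -> dict:
    """Pairwise comparison of strategy ``a`` minus reference ``b``.

    Returns incremental cost, incremental QALYs, the raw ICER (None when the
    effectiveness difference is zero), the incremental NMB, and a label:
    "dominant" (a cheaper and more effective), "dominated" (a costlier and
    less effective), or "icer" otherwise.
    """
    d_cost = a.cost - b.cost
    d_qaly = a.qaly - b.qaly
    icer = d_cost / d_qaly if d_qaly != 0 else None
    if d_cost <= 0 and d_qaly >= 0 and (d_cost < 0 or d_qaly > 0):
        label = "dominant"
    elif d_cost >= 0 and d_qaly <= 0 and (d_cost > 0 or d_qaly < 0):
        label = "dominated"
    else:
        label = "icer"
    return {
        "incremental_cost": d_cost,
        "incremental_qaly": d_qaly,
        "icer": icer,
        "incremental_nmb": nmb(a, wtp) - nmb(b, wtp),
        "label": label,
    }


def icer_frontier(results: list[StrategyResult], wtp: float) -> CEATable:
    """Stepwise comparison of strategies with dominance classification.

    Rows come back sorted by ascending cost.  Frontier rows (after removing
    strictly and extended dominated strategies) carry incremental columns
    relative to the previous frontier strategy; dominated rows carry the raw
    ratio against the nearest cheaper frontier strategy and the label
    "dominated".  Exact (cost, qaly) duplicates keep the first by input order;
    the rest are marked strictly dominated with an "equivalent" note.
    """
    if not results:
        raise ValueError("icer_frontier requires at least one strategy")
    n = len(results)
    status: dict[int, str] = {}
    notes: dict[int, str] = {}

    for i in range(n):
        ri = results[i]
        for j in range(n):
            if i == j:
                continue
            rj = results[j]
            if rj.cost == ri.cost and rj.qaly == ri.qaly:
                if j < i:
                    status[i] = STRICTLY_DOMINATED
                    notes[i] = f"equivalent to {rj.strategy_name}"
                continue
            if rj.cost <= ri.cost and rj.qaly >= ri.qaly:
                status[i] = STRICTLY_DOMINATED

    order = sorted(range(n), key=lambda i: (results[i].cost, -results[i].qaly, i))
    candidates = [i for i in order if i not in status]

    # extended dominance: enforce a non-decreasing ICER sequence along the
    # cost-sorted candidates by popping interior points that break it
    def _icer(a: int, b: int) -> float:
        return (results[a].cost - results[b].cost) / (results[a].qaly - results[b].qaly)

    stack: list[int] = []
    for i in candidates:
        while len(stack) >= 2 and _icer(i, stack[-1]) < _icer(stack[-1], stack[-2]):
            status[stack.pop()] = EXTENDED_DOMINATED
        stack.append(i)
    frontier = stack

    rows: list[CEARow] = []
    prev_frontier: int | None = None
    frontier_set = set(frontier)
    for i in order:
        res = results[i]
        row = CEARow(
            strategy_name=res.strategy_name,
            cost=res.cost,
            qaly=res.qaly,
            nmb=nmb(res, wtp),
            dominance_status=status.get(i, ON_FRONTIER),
            note=notes.get(i, ""),
        )
        if i in frontier_set:
            if prev_frontier is not None:
                comp = incremental(res, results[prev_frontier], wtp)
                row.incremental_cost = comp["incremental_cost"]
                row.incremental_qaly = comp["incremental_qaly"]
                row.icer = comp["icer"]
                row.icer_label = (
                    comp["label"] if comp["label"] != "icer" else f"{comp['icer']:.0f}"
                )
            elif any(j != i and j not in frontier_set for j in range(n)):
                # cheapest frontier strategy beating everything else outright
                row.icer_label = "dominant" if len(frontier) == 1 else ""
            prev_frontier = i
        else:
            row.icer_label = "dominated"
            cheaper = [j for j in frontier if results[j].cost <= res.cost]
            if cheaper:
                comp = incremental(res, results[cheaper[-1]], wtp)
                row.incremental_cost = comp["incremental_cost"]
                row.incremental_qaly = comp["incremental_qaly"]
                row.icer = comp["icer"]
        rows.append(row)
    return CEATable(rows=rows, wtp=wtp)
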