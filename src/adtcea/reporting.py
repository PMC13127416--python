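"""Report assembly: stamped CSV outputs, run manifests, optional plots.

Every tabular output starts with a ``#``-prefixed header line carrying the
package version (and seed where randomness is involved), so published numbers
are traceable to a run; the package's readers skip those lines.  Money is
rounded to whole dollars and QALYs to two decimals only in the formatted
console table — CSV outputs keep full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from adtcea.cea_stats import CEATable
from adtcea.sensitivity import TornadoEntry

__all__ = [
    "RunManifest",
    "write_table",
    "read_table",
    "tornado_frame",
    "ceac_frame",
    "format_cea_table",
    "plot_tornado",
    "plot_ceac",
]


def _version() -> str:
    from adtcea import __version__

    return __version__


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a CSV with a traceability header line (version, optional seed)."""
    path = Path(path)
    header = f"# adtcea {_version()}"
    if seed is not None:
        header += f" seed={seed}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (header lines skipped)."""
    return pd.read_csv(path, comment="#")


@dataclass
class RunManifest:
    """What a CLI run did: inputs, seeds, version, and the files it wrote."""

    spec_path: str
    command: str
    seeds: dict = field(default_factory=dict)
    version: str = field(default_factory=_version)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "param_path": e.param_path,
                "low_value": e.low_value,
                "high_value": e.high_value,
                "inmb_at_low": e.inmb_at_low,
                "inmb_at_high": e.inmb_at_high,
                "spread": e.spread,
            }
            for e in entries
        ]
    )


def ceac_frame(curve: list[tuple[float, float]]) -> pd.DataFrame:
    return pd.DataFrame(curve, columns=["wtp", "probability_cost_effective"])


def format_cea_table(table: CEATable) -> str:
    """Console rendering with presentation rounding (whole USD, 2-dp QALYs)."""
    lines = [
        f"{'Strategy':<14} {'Cost ($)':>10} {'QALY':>6} {'Inc. cost':>10} "
        f"{'Inc. QALY':>9} {'ICER':>12} {'NMB ($)':>10}  Status"
    ]
    for r in table.rows:
        inc_c = f"{r.incremental_cost:,.0f}" if r.incremental_cost is not None else "—"
        inc_q = f"{r.incremental_qaly:.2f}" if r.incremental_qaly is not None else "—"
        icer = r.icer_label or "—"
        lines.append(
            f"{r.strategy_name:<14} {r.cost:>10,.0f} {r.qaly:>6.2f} {inc_c:>10} "
            f"{inc_q:>9} {icer:>12} {r.nmb:>10,.0f}  {r.dominance_status}"
        )
    lines.append(f"(NMB at WTP ${table.wtp:,.0f}/QALY)")
    return "\n".join(lines)


def plot_tornado(entries: list[TornadoEntry], path: str | Path, base_inmb: float | None = None) -> None:
    """Horizontal-bar tornado with a reference line at incremental NMB 0."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = sorted(entries, key=lambda e: e.spread)
    labels = [e.param_path for e in entries]
    lows = [min(e.inmb_at_low, e.inmb_at_high) for e in entries]
    widths = [e.spread for e in entries]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(entries) + 1.5))
    ax.barh(labels, widths, left=lows, color="#4878a8")
    ax.axvline(0.0, color="gray", lw=1)
    if base_inmb is not None:
        ax.axvline(base_inmb, color="black", lw=1, ls="--")
    ax.set_xlabel("Incremental net monetary benefit ($)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: list[tuple[float, float]], path: str | Path, label: str = "") -> None:
    """Cost-effectiveness acceptability curve over the WTP grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wtp, prob = zip(*curve)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(wtp, prob, marker="o", label=label or None)
    ax.set_xlabel("Willingness-to-pay ($/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    if label:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
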