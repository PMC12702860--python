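"""Rendering of result tables (CSV + JSON) with run provenance.

Tables mirror the published layout: payer costs by care setting, clinical
results per 100 infants, hospital costs by FOF achievement, and subgroup
costs by GAB group.  Full-precision values are written; totals are the exact
``math.fsum`` of the rendered category values, so re-summing a rendered table
reproduces its total bit-exactly.  Monetary rounding happens only at display.
Every artifact embeds the parameter-set hash, the seed, and the package
version.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from . import __version__
from .costing import BudgetImpact, CostBreakdown
from .parameters import ParameterSet


class ReportError(RuntimeError):
    pass


def _meta(ps: ParameterSet, seed: int | None) -> dict:
    return {
        "package_version": __version__,
        "parameter_hash": ps.content_hash(),
        "parameter_label": ps.label,
        "seed": seed,
    }


def cost_table(
    b_intervention: CostBreakdown,
    b_comparator: CostBreakdown,
    impact: BudgetImpact,
    ui: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Category x {intervention, comparator, difference} table plus a total row.

    The total row is the fsum of the category rows actually rendered.
    """
    if tuple(b_intervention.categories) != tuple(b_comparator.categories) or tuple(
        b_intervention.categories
    ) != tuple(impact.categories):
        raise ReportError("inconsistent category sets across inputs")
    rows = []
    for cat in b_intervention.categories:
        row = {
            "category": cat,
            b_intervention.arm.value: b_intervention.categories[cat],
            b_comparator.arm.value: b_comparator.categories[cat],
            "difference": impact.categories[cat],
        }
        if ui and cat in ui:
            row["ui_lower"], row["ui_upper"] = ui[cat]
        rows.append(row)
    df = pd.DataFrame(rows)
    total = {
        "category": "Total costs",
        b_intervention.arm.value: math.fsum(df[b_intervention.arm.value]),
        b_comparator.arm.value: math.fsum(df[b_comparator.arm.value]),
        "difference": math.fsum(df["difference"]),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def outcomes_table(outcomes: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Clinical/resource results per arm with differences (per 100 infants)."""
    arms = [k for k in outcomes if k != "difference"]
    rows = []
    for key in outcomes[arms[0]]:
        row = {"outcome": key}
        for arm in arms:
            row[arm] = outcomes[arm][key]
        row["difference"] = outcomes["difference"][key]
        rows.append(row)
    return pd.DataFrame(rows)


def render_tables(
    tables: dict[str, pd.DataFrame],
    outdir: str | Path,
    ps: ParameterSet,
    seed: int | None = None,
    fmt: str = "both",
    overwrite: bool = False,
) -> list[Path]:
    """Write each named table as CSV and/or JSON with embedded provenance.

    CSV files carry the provenance as leading ``#`` comment lines; JSON files
    carry a ``meta`` object next to the full-precision records.  The two
    renderings share the same DataFrame, so their numbers are identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = _meta(ps, seed)
    written: list[Path] = []
    for name, df in tables.items():
        if fmt in ("csv", "both"):
            path = outdir / f"{name}.csv"
            _check_overwrite(path, overwrite)
            header = "".join(f"# {k}={v}\n" for k, v in meta.items())
            path.write_text(header + df.to_csv(index=False, float_format=None))
            written.append(path)
        if fmt in ("json", "both"):
            path = outdir / f"{name}.json"
            _check_overwrite(path, overwrite)
            payload = {"meta": meta, "records": df.to_dict(orient="records")}
            path.write_text(json.dumps(payload, indent=2, default=float))
            written.append(path)
    return written


def _check_overwrite(path: Path, overwrite: bool) -> None:
    if path.exists() and not overwrite:
        raise ReportError(f"refusing to overwrite existing {path} (pass overwrite/--force)")


def read_rendered_csv(path: str | Path) -> pd.DataFrame:
    """Read back a rendered CSV, skipping provenance comment lines."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def format_money(value: float) -> str:
    """Display rounding: dollars for tables (used by the CLI, not storage)."""
    return f"-${abs(value):,.0f}" if value < 0 else f"${value:,.0f}"


def plot_tornado(entries, path: str | Path) -> None:
    """Horizontal tornado diagram of one-way sensitivity results."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = sorted(entries, key=lambda e: e.spread)
    names = [e.parameter for e in entries]
    base = entries[0].base_result if entries else 0.0
    fig, ax = plt.subplots(figsize=(7, 0.45 * max(len(entries), 4) + 1.2))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.low_result, e.high_result))
        ax.barh(i, hi - lo, left=lo, color="#4878a8", height=0.6)
    ax.axvline(base, color="k", lw=1)
    ax.set_yticks(range(len(entries)), names)
    ax.set_xlabel("total cost difference (intervention - comparator), USD")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_threshold(curve, path: str | Path) -> None:
    """Probability of cost saving vs. per-patient device cost."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.device_cost_grid, 100.0 * curve.prob_cost_saving, marker="o")
    ax.set_xlabel("device cost per patient, USD")
    ax.set_ylabel("probability of cost saving, %")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
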