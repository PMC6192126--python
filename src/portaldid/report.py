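"""Rendering of effect tables, trajectory plots, and capacity arithmetic."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .prep import quarter_label


def format_p(p: float, floor: float = 0.001) -> str:
    """Format a p-value to 3 decimals with a display floor, e.g. '<0.001'."""
    if not np.isfinite(p):
        return "--"
    if p < floor:
        return f"<{floor:.3f}".rstrip("0").rstrip(".") if floor != 0.001 else "<0.001"
    return f"{p:.3f}"


def format_effect(rr: float, ci_low: float, ci_high: float, p: float) -> str:
    """Render one estimate block: '1.330 (1.271, 1.389) <0.001'."""
    if not np.isfinite(rr):
        return "--"
    return f"{rr:.3f} ({ci_low:.3f}, {ci_high:.3f}) {format_p(p)}"


def wasted_appointment_slots(
    noshows_per_patient_year: tuple[float, float] = (0.14, 0.20),
    panel_size: int = 1300,
) -> tuple[int, int]:
    """Annual appointment slots lost to no-shows for one provider panel.

    With an annual per-patient no-show count between the two bounds and a
    typical primary-care panel, the wasted slots are bound x panel size.
    """
    low, high = noshows_per_patient_year
    if low < 0 or high < low:
        raise ValueError("no-show bounds must satisfy 0 <= low <= high")
    return round(low * panel_size), round(high * panel_size)


def render_effect_report(
    arrived: pd.DataFrame,
    noshow: pd.DataFrame | None = None,
    cancel: pd.DataFrame | None = None,
    max_lag: int = 10,
) -> str:
    """One row per quarter post adoption with up to three estimate blocks.

    Columns mirror the published layout: arrived-visit rate ratio, no-show
    Omega, cancellation Omega; estimates to 3 decimals with 95% CIs and
    floored p-values.  Missing lags (zero-support dummies) render as '--'
    with a footnote.
    """
    def block(table: pd.DataFrame | None, k: int, rr_col: str) -> str:
        if table is None or k not in set(table["lag"]):
            return "--"
        row = table.loc[table["lag"] == k].iloc[0]
        return format_effect(row[rr_col], row["ci_low"], row["ci_high"], row["p"])

    header = (
        f"{'Lag':>3} {'Quarter':>7} | {'OFV arrived RR (95% CI) p':^34} | "
        f"{'No-show Omega (95% CI) p':^34} | {'Cancellation Omega (95% CI) p':^34}"
    )
    lines = [header, "-" * len(header)]
    missing = False
    for k in range(max_lag + 1):
        a = block(arrived, k, "rr")
        ns = block(noshow, k, "omega")
        ca = block(cancel, k, "omega")
        missing = missing or "--" in (a, ns, ca)
        lines.append(f"{k:>3} {'+' + str(k) + 'q':>7} | {a:^34} | {ns:^34} | {ca:^34}")
    if noshow is None and cancel is None:
        lines.append("note: arrived-visit model only; no-show/cancellation tests not run")
    elif missing:
        lines.append("note: '--' marks lags without support (dummy dropped) or not run")
    return "\n".join(lines)


def plot_rr_trajectories(
    tables: dict[str, pd.DataFrame], path: str | Path, value_cols: dict[str, str] | None = None
) -> Path:
    """Plot lag-k rate-ratio trajectories with CI bands to ``path`` (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    value_cols = value_cols or {}
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, table in tables.items():
        col = value_cols.get(label, "rr" if "rr" in table.columns else "omega")
        ax.errorbar(
            table["lag"], table[col],
            yerr=[table[col] - table["ci_low"], table["ci_high"] - table[col]],
            marker="o", capsize=3, label=label,
        )
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("quarters post portal adoption (lag k)")
    ax.set_ylabel("rate ratio users / non-users")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def effect_table_with_labels(table: pd.DataFrame) -> pd.DataFrame:
    """Attach calendar-quarter labels (Y13Q3..) for lags that are valid quarters."""
    out = table.copy()
    out["quarter_post_adoption"] = out["lag"]
    out["example_quarter"] = [
        quarter_label(k) if 0 <= k <= 11 else "" for k in out["lag"]
    ]
    return out
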