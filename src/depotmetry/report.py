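"""Figures and summary statistics from morphometry tables and event logs.

Everything here is regenerable from the morphometry CSV and the events
JSON alone; no pipeline state is needed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import FormatError
from .morpho import AggregateIoD, DepotMorphometry, aggregate_iod


def table_to_records(df: pd.DataFrame) -> list[DepotMorphometry]:
    """Rebuild morphometry records from a table written by session_io."""
    records = []
    for _, row in df.iterrows():
        flags = [f for f in str(row.get("flags", "") or "").split(";") if f]
        rec = DepotMorphometry(
            frame_index=int(row["frame_index"]),
            time_min=float(row["time_min"]),
            flags=flags,
        )
        if pd.notna(row["iod"]):
            rec.volume_mm3 = float(row["volume_mm3"])
            rec.surface_mm2 = float(row["surface_mm2"])
            rec.r_compact_mm = float(row["r_compact_mm"])
            rec.s_compact_mm2 = float(row["s_compact_mm2"])
            rec.iod = float(row["iod"])
        records.append(rec)
    return records


def plot_iod_curve(agg: AggregateIoD, path: str | Path) -> None:
    """Mean +/- SD IoD curve over the session."""
    fig, ax = plt.subplots(figsize=(6, 4))
    t = agg.time_min
    ok = ~np.isnan(agg.mean_iod)
    ax.plot(t[ok], agg.mean_iod[ok], "o-", color="tab:green", ms=3,
            label=f"mean IoD ({agg.group}, N={int(agg.n_assays.max())})")
    sd_ok = ok & ~np.isnan(agg.sd_iod)
    if sd_ok.any():
        ax.fill_between(t[sd_ok],
                        agg.mean_iod[sd_ok] - agg.sd_iod[sd_ok],
                        agg.mean_iod[sd_ok] + agg.sd_iod[sd_ok],
                        alpha=0.25, color="tab:green", label="+/- 1 SD")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("Index of Dispersion")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_final_boxplots(groups: dict[str, Sequence[float]],
                        path: str | Path) -> None:
    """Boxplots of final-time IoD values, one box per group."""
    names = [g for g, v in groups.items() if len(v)]
    data = [list(groups[g]) for g in names]
    if not names:
        raise FormatError("no group has final IoD values")
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(names), 4))
    ax.boxplot(data, tick_labels=names, whis=(0, 100))
    ax.set_ylabel("IoD at session end")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def build_report(
    assay_tables: Sequence[pd.DataFrame],
    out_dir: str | Path,
    group_labels: Optional[Sequence[str]] = None,
    events: Optional[dict] = None,
) -> dict:
    """Aggregate one or more assays, write figures + a stats JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assays = [table_to_records(df) for df in assay_tables]
    if group_labels is None:
        group_labels = ["all"] * len(assays)

    stats: dict = {"groups": {}}
    by_group: dict[str, list] = {}
    for a, g in zip(assays, group_labels):
        by_group.setdefault(g, []).append(a)

    all_agg = aggregate_iod(assays, group="all")
    plot_iod_curve(all_agg, out_dir / "iod_mean_sd.png")
    stats["all"] = {
        "mean_of_sds": all_agg.mean_of_sds,
        "final_boxplot": all_agg.final_boxplot,
        "final_iods": all_agg.final_iods,
        "n_assays": len(assays),
    }

    finals = {}
    for g, members in by_group.items():
        agg = aggregate_iod(members, group=g)
        stats["groups"][g] = {
            "mean_of_sds": agg.mean_of_sds,
            "final_boxplot": agg.final_boxplot,
            "n_assays": len(members),
        }
        finals[g] = agg.final_iods
    if any(len(v) for v in finals.values()):
        plot_final_boxplots(finals, out_dir / "iod_final_boxplot.png")

    if events is not None:
        stats["pressure_events"] = events

    with open(out_dir / "report_stats.json", "w") as fh:
        json.dump(stats, fh, indent=2)
    return stats
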