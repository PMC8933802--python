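"""Price–workload signaling analysis and session summaries.

The mechanism under study treats a ward's posted price as a signal of its
hidden workload.  If the signal works, prices set when the ward's own
workload is high should be systematically higher.  ``extract_pairs`` rebuilds
(workload-at-pricing, price) pairs purely from the event log — workload is
the ward's value at the moment prices were posted, i.e. at day start before
that day's arrivals — and ``association`` quantifies the relationship with
both Pearson r (linear) and Spearman rho (monotone), since the signaling
claim is qualitative and need not be linear.  Degenerate groups (no price
variance, no workload variance, or too few points) are flagged and reported
as NaN rather than fabricated.

No hypothesis tests are attached by default; ``association`` optionally
returns p-values for users who want them.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .market import EventLog, SessionResult

__all__ = [
    "extract_pairs",
    "association",
    "summarize_session",
    "plot_price_workload",
]

_GROUPINGS = {
    "pooled": [],
    "ward": ["ward"],
    "pattern": ["illness", "severity"],
    "ward_pattern": ["ward", "illness", "severity"],
}


def extract_pairs(log: EventLog) -> pd.DataFrame:
    """One row per (day, ward, illness, severity): the posted price and the
    ward's workload at pricing time, reconstructed solely from the log."""
    rows = []
    for ev in log.of_kind("price_set"):
        p = ev.payload
        for illness, severity, price in p["prices"]:
            rows.append(
                {
                    "day": ev.day,
                    "ward": p["ward"],
                    "illness": illness,
                    "severity": severity,
                    "workload_at_pricing": p["workload"],
                    "price": price,
                }
            )
    if not rows:
        import warnings

        warnings.warn("event log contains no price_set events; empty pair table")
        return pd.DataFrame(
            columns=["day", "ward", "illness", "severity", "workload_at_pricing", "price"]
        )
    return pd.DataFrame(rows)


def _one_association(g: pd.DataFrame, min_points: int, with_p: bool) -> dict:
    n = len(g)
    out = {
        "n": n,
        "pearson_r": np.nan,
        "spearman_rho": np.nan,
        "degenerate": "none",
    }
    if with_p:
        out["pearson_p"] = np.nan
        out["spearman_p"] = np.nan
    if n < min_points:
        out["degenerate"] = "too_few_points"
        return out
    w = g["workload_at_pricing"].to_numpy(float)
    p = g["price"].to_numpy(float)
    if np.ptp(p) == 0:
        out["degenerate"] = "zero_price_variance"
        return out
    if np.ptp(w) == 0:
        out["degenerate"] = "zero_workload_variance"
        return out
    pr = stats.pearsonr(w, p)
    sr = stats.spearmanr(w, p)
    out["pearson_r"] = float(pr.statistic)
    out["spearman_rho"] = float(sr.statistic)
    if with_p:
        out["pearson_p"] = float(pr.pvalue)
        out["spearman_p"] = float(sr.pvalue)
    return out


def association(
    pairs: pd.DataFrame,
    grouping: str = "ward_pattern",
    min_points: int = 3,
    with_p_values: bool = False,
) -> pd.DataFrame:
    """Pearson and Spearman association per group of price–workload pairs.

    ``grouping`` is one of 'pooled', 'ward', 'pattern', 'ward_pattern'.
    Groups whose coefficients are undefined carry a ``degenerate`` flag in
    {'too_few_points', 'zero_price_variance', 'zero_workload_variance'} and
    NaN coefficients.
    """
    if grouping not in _GROUPINGS:
        raise ValueError(f"grouping must be one of {sorted(_GROUPINGS)}")
    keys = _GROUPINGS[grouping]
    if not keys:
        row = _one_association(pairs, min_points, with_p_values)
        return pd.DataFrame([row])
    rows = []
    for key_vals, g in pairs.groupby(keys, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        row = dict(zip(keys, key_vals))
        row.update(_one_association(g, min_points, with_p_values))
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_session(result: SessionResult) -> dict[str, pd.DataFrame]:
    """Per-ward and hospital-level summary tables for one session.

    Ward table: final balance, mean/max workload over day-start snapshots,
    mean occupancy, and the fraction of the ward's admissions whose illness
    matched its specialty.  Hospital table: total admissions, rejections, and
    the empirical mean length of stay over completed stays.
    """
    cfg = result.config
    snaps = result.snapshots
    admissions = result.log.of_kind("admission")
    ward_rows = []
    for w in cfg.wards:
        ws = snaps[snaps["ward"] == w.id] if len(snaps) else snaps
        own = [e for e in admissions if e.payload["ward"] == w.id]
        matched = sum(1 for e in own if e.payload["illness"] == w.specialty)
        ward_rows.append(
            {
                "ward": w.id,
                "specialty": w.specialty,
                "final_balance": result.ledger.ward_balances.get(w.id, 0.0),
                "mean_workload": ws["workload"].mean() if len(ws) else 0.0,
                "max_workload": ws["workload"].max() if len(ws) else 0.0,
                "mean_occupancy": ws["occupancy"].mean() if len(ws) else 0.0,
                "n_admissions": len(own),
                "specialty_match_fraction": matched / len(own) if own else float("nan"),
            }
        )
    completed = [
        p.discharge_day - p.admit_day
        for p in result.state.patients.values()
        if p.discharge_day is not None
    ]
    hospital = pd.DataFrame(
        [
            {
                "n_arrivals": len(result.log.of_kind("arrival")),
                "n_admissions": len(admissions),
                "rejections": result.rejections,
                "completed_stays": len(completed),
                "mean_los_days": float(np.mean(completed)) if completed else 0.0,
                "total_tokens_issued": result.ledger.hospital_issuance,
            }
        ]
    )
    return {"wards": pd.DataFrame(ward_rows), "hospital": hospital}


def plot_price_workload(
    pairs: pd.DataFrame,
    severities: Optional[Sequence[str]] = None,
    path: Optional[str] = None,
):
    """Scatter of price against day, one panel per (illness, severity),
    points shaded darker at higher workload-at-pricing (the heavier the ward,
    the darker the dot).  Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    illnesses = sorted(pairs["illness"].unique())
    sev_order = list(severities) if severities else sorted(pairs["severity"].unique())
    fig, axes = plt.subplots(
        len(sev_order),
        len(illnesses),
        figsize=(3.2 * len(illnesses), 2.6 * len(sev_order)),
        squeeze=False,
        sharex=True,
    )
    wmax = pairs["workload_at_pricing"].max() or 1.0
    for i, sev in enumerate(sev_order):
        for j, ill in enumerate(illnesses):
            ax = axes[i][j]
            g = pairs[(pairs["illness"] == ill) & (pairs["severity"] == sev)]
            shade = 0.85 - 0.75 * (g["workload_at_pricing"] / wmax)
            ax.scatter(g["day"], g["price"], c=shade, cmap="gray", vmin=0, vmax=1, s=18)
            if i == 0:
                ax.set_title(ill, fontsize=9)
            if j == 0:
                ax.set_ylabel(f"{sev}\nprice (tokens)", fontsize=8)
            if i == len(sev_order) - 1:
                ax.set_xlabel("day")
    fig.suptitle("Posted price by day (darker = higher ward workload at pricing)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=130)
    return fig
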