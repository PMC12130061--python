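"""Per-bend reduction, case-relative normalization and group statistics.

Per-slice near-wall ROI means are averaged over the slices of each bend
(sectional means), normalized per case by the case-wide maximum — so a
large vessel and a small one become comparable — and grouped into the
aneurysm-hosting bend (A-bend) versus the remaining bends (O-bend).
Group differences use the Welch t-test (unequal variances and group
sizes: one A-bend per case versus roughly two O-bends per case).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .landmarks import BranchSection

__all__ = [
    "GroupComparison",
    "sectional_means",
    "normalize_case",
    "welch_t",
    "welch_t_summary",
    "cohort_table",
    "box_summary",
    "plot_boxes",
    "VELOCITY_QUANTITIES",
    "CURVATURE_QUANTITIES",
]

DEFAULT_ALPHA = 0.05

VELOCITY_QUANTITIES = ["n_vec", "n_ax", "n_cir", "n_rad"]
CURVATURE_QUANTITIES = ["nKappa", "nKappaMax"]

_RAW_TO_NORM = {
    "mean_v": "n_vec",
    "mean_v_ax": "n_ax",
    "mean_v_cir": "n_cir",
    "mean_v_rad": "n_rad",
}


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample comparison of one normalized quantity."""

    quantity: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p: float
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


# --------------------------------------------------------------------------
# sectional means and normalization
# --------------------------------------------------------------------------

def sectional_means(
    slice_df: pd.DataFrame,
    bends: list[BranchSection],
    case_id: str = "case",
) -> pd.DataFrame:
    """Average per-slice ROI rows over the member slices of each bend.

    ``slice_df`` has one row per (slice, side) with columns ``slice_pos``
    (position in the analyzed slice list), ``side``, the four velocity
    means, ``count``, and per-slice ``kappa`` / ``abs_tau``.  Rows with
    ``count == 0`` (empty sectors) are dropped.  Each output row is one
    (bend, side) with unweighted means over its slices; ``peak_kappa``
    is the max slice curvature within the bend.  Bends without any
    usable slice are excluded.
    """
    rows = []
    usable = slice_df[slice_df["count"] > 0]
    for b in bends:
        member = usable[usable["slice_pos"].isin(b.slice_indices)]
        if member.empty:
            continue
        for side, g in member.groupby("side"):
            rows.append({
                "case": case_id,
                "bend": b.index,
                "side": side,
                "is_aneurysmal": b.is_aneurysmal,
                "mean_v": g["mean_v"].mean(),
                "mean_v_ax": g["mean_v_ax"].mean(),
                "mean_v_cir": g["mean_v_cir"].mean(),
                "mean_v_rad": g["mean_v_rad"].mean(),
                "mean_kappa": g["kappa"].mean(),
                "peak_kappa": g["kappa"].max(),
                "mean_abs_tau": g["abs_tau"].mean(),
                "n_slices": len(g),
            })
    return pd.DataFrame(rows)


def normalize_case(
    bend_df: pd.DataFrame,
    kappa_centerline_max: float,
    velocity_max: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Case-relative normalization of sectional means.

    Each velocity quantity is divided by its maximum over all
    (bend, side) rows of the case, so exactly one entry per quantity
    reaches 1.0; passing ``velocity_max`` (e.g. maxima over all slices
    instead of bend means) overrides the base.  Curvature quantities are
    divided by the maximum curvature along the whole analyzed
    centerline (``kappa_centerline_max``).
    """
    if bend_df["bend"].nunique() < 2:
        raise ValueError("case-relative normalization needs at least 2 bends")
    if not kappa_centerline_max > 0:
        raise ValueError("centerline curvature maximum must be positive")
    out = bend_df.copy()
    for raw, norm in _RAW_TO_NORM.items():
        base = velocity_max[norm] if velocity_max is not None else out[raw].max()
        if not base > 0:
            raise ValueError(f"zero normalization base for {norm}")
        out[norm] = out[raw] / base
    out["nKappa"] = out["mean_kappa"] / kappa_centerline_max
    out["nKappaMax"] = out["peak_kappa"] / kappa_centerline_max
    return out


# --------------------------------------------------------------------------
# Welch t-test
# --------------------------------------------------------------------------

def welch_t_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    quantity: str = "",
    alpha: float = DEFAULT_ALPHA,
) -> GroupComparison:
    """Welch t-test from group summary statistics.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom and a two-sided p from the
    Student-t distribution.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    se2 = va + vb
    if se2 == 0.0:
        if mean_a == mean_b:
            t_stat, df, p = 0.0, float(n_a + n_b - 2), 1.0
        else:
            raise ValueError("zero pooled standard error with unequal means")
    else:
        t_stat = (mean_a - mean_b) / np.sqrt(se2)
        df = se2**2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
        p = 2.0 * scipy.stats.t.sf(abs(t_stat), df)
    return GroupComparison(quantity, mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                           float(t_stat), float(df), float(p), alpha)


def welch_t(sample_a, sample_b, quantity: str = "", alpha: float = DEFAULT_ALPHA) -> GroupComparison:
    """Welch t-test from raw samples."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    return welch_t_summary(
        float(a.mean()), float(a.std(ddof=1)), len(a),
        float(b.mean()), float(b.std(ddof=1)), len(b),
        quantity=quantity, alpha=alpha)


# --------------------------------------------------------------------------
# cohort table and box summaries
# --------------------------------------------------------------------------

def box_summary(values: np.ndarray, label: str, quantity: str) -> dict:
    """Five-number box-plot summary with 1.5*IQR whiskers."""
    v = np.asarray(values, float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr].min()
    hi = v[v <= q3 + 1.5 * iqr].max()
    return {"quantity": quantity, "group": label, "n": len(v),
            "whisker_lo": float(lo), "q1": float(q1), "median": float(med),
            "q3": float(q3), "whisker_hi": float(hi), "mean": float(v.mean())}


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def cohort_table(
    norm_df: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    holm: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group comparisons and box summaries across the cohort.

    Velocity quantities are compared on the A-side sector only — the
    side where the aneurysm sits — between A-bend and O-bend rows.
    Curvature quantities are compared per bend (A-bend vs O-bend).
    Returns ``(table, boxes)``; the table reports raw p-values, with an
    optional Holm-adjusted column (off by default).
    """
    if norm_df["case"].nunique() < 2:
        raise ValueError("cohort statistics need at least 2 cases")
    comps: list[GroupComparison] = []
    boxes: list[dict] = []

    a_side = norm_df[norm_df["side"] == "A-side"]
    for q in VELOCITY_QUANTITIES:
        ga = a_side.loc[a_side["is_aneurysmal"], q].to_numpy()
        gb = a_side.loc[~a_side["is_aneurysmal"], q].to_numpy()
        if len(ga) < 2 or len(gb) < 2:
            continue
        comps.append(welch_t(ga, gb, quantity=q, alpha=alpha))
        boxes.append(box_summary(ga, "A-bend", q))
        boxes.append(box_summary(gb, "O-bend", q))

    per_bend = norm_df.drop_duplicates(subset=["case", "bend"])
    for q in CURVATURE_QUANTITIES:
        ga = per_bend.loc[per_bend["is_aneurysmal"], q].to_numpy()
        gb = per_bend.loc[~per_bend["is_aneurysmal"], q].to_numpy()
        if len(ga) < 2 or len(gb) < 2:
            continue
        comps.append(welch_t(ga, gb, quantity=q, alpha=alpha))
        boxes.append(box_summary(ga, "A-bend", q))
        boxes.append(box_summary(gb, "O-bend", q))

    table = pd.DataFrame([{
        "quantity": c.quantity,
        "mean_A": c.mean_a, "sd_A": c.sd_a, "n_A": c.n_a,
        "mean_O": c.mean_b, "sd_O": c.sd_b, "n_O": c.n_b,
        "t": c.t, "df": c.df, "p": c.p, "significant": c.significant,
    } for c in comps])
    if holm and not table.empty:
        table["p_holm"] = _holm(table["p"].to_numpy())
    return table, pd.DataFrame(boxes)


def plot_boxes(norm_df: pd.DataFrame, path: str, quantities=None) -> None:
    """Box plots of normalized quantities by A-bend/O-bend group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    quantities = quantities or VELOCITY_QUANTITIES
    a_side = norm_df[norm_df["side"] == "A-side"]
    fig, axes = plt.subplots(1, len(quantities), figsize=(3 * len(quantities), 4),
                             sharey=True)
    for ax, q in zip(np.atleast_1d(axes), quantities):
        ga = a_side.loc[a_side["is_aneurysmal"], q]
        gb = a_side.loc[~a_side["is_aneurysmal"], q]
        ax.boxplot([ga, gb], tick_labels=["A-bend", "O-bend"], showmeans=True)
        ax.set_title(q)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
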