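"""End-to-end case and cohort analysis.

``analyze_case`` runs the full chain on one case: Frenet frames,
perpendicular slices, velocity interpolation and decomposition,
near-wall A-side/O-side averaging, bend landmarking, sectional means
and case-relative normalization.  ``run_cohort`` maps it over a list of
cases and produces the group-comparison table; ``replicate_power_study``
repeats cohorts across seeds to measure detection rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cohort as chrt
from . import landmarks as lm
from . import sections as sec
from .centerline import frenet
from .synthetic import SyntheticCase, make_population

__all__ = ["analyze_case", "run_cohort", "replicate_power_study"]

#: desk-scale analysis defaults (see docs/methods.md for the rationale)
ANALYSIS_DEFAULTS = {
    "n_rho": 8,
    "n_theta": 24,
    "slice_stride": 4,
    "k": 4,
    "power": 2.0,
    "sector_deg": sec.DEFAULT_SECTOR_DEG,
    "wall_fraction": sec.DEFAULT_WALL_FRACTION,
    "min_prominence": lm.DEFAULT_MIN_PROMINENCE,
    "min_separation": lm.DEFAULT_MIN_SEPARATION_MM,
}


def analyze_case(case: SyntheticCase, **overrides) -> dict:
    """Run the full per-case analysis; returns intermediate tables.

    Returns a dict with ``slice_df`` (per-slice, per-side ROI rows),
    ``bend_df`` (sectional means), ``norm_df`` (case-normalized),
    ``bends``, ``orientation`` and the frame set.
    """
    p = dict(ANALYSIS_DEFAULTS)
    p.update(overrides)
    c = case.centerline
    fr = frenet(c)

    slices = sec.make_slices(c, fr, n_rho=p["n_rho"], n_theta=p["n_theta"],
                             stride=p["slice_stride"])
    if not slices:
        raise ValueError(f"{case.case_id}: no valid slices")
    sec.sample_velocity(slices, case.field_points, case.field_velocities,
                        k=p["k"], power=p["power"])
    sec.decompose(slices)

    neck = [s for s in slices
            if case.neck_start_abscissa <= s.abscissa <= case.neck_end_abscissa]
    if not neck:  # neck narrower than the slice stride: use the nearest slice
        mid = 0.5 * (case.neck_start_abscissa + case.neck_end_abscissa)
        neck = [min(slices, key=lambda s: abs(s.abscissa - mid))]
    orientation = sec.classify_orientation(case.aneurysm_direction, neck)

    rows = []
    for pos, s in enumerate(slices):
        theta_c = sec.aneurysm_theta(case.aneurysm_direction, s)
        roi_a, roi_o = sec.roi_average(s, theta_c, sector_deg=p["sector_deg"],
                                       wall_fraction=p["wall_fraction"])
        kappa_i = float(fr.kappa[s.index])
        tau_i = float(abs(fr.tau[s.index])) if np.isfinite(fr.tau[s.index]) else 0.0
        for roi in (roi_a, roi_o):
            rows.append({
                "slice_pos": pos, "abscissa": s.abscissa, "side": roi.side,
                "mean_v": roi.mean_v, "mean_v_ax": roi.mean_v_ax,
                "mean_v_cir": roi.mean_v_cir, "mean_v_rad": roi.mean_v_rad,
                "count": roi.count, "kappa": kappa_i, "abs_tau": tau_i,
            })
    slice_df = pd.DataFrame(rows)

    bends = lm.landmark(fr, min_prominence=p["min_prominence"],
                        min_separation=p["min_separation"])
    lm.assign_slices(bends, np.array([s.abscissa for s in slices]))
    lm.mark_aneurysmal(bends, case.neck_start_abscissa, case.neck_end_abscissa)

    bend_df = chrt.sectional_means(slice_df, bends, case_id=case.case_id)
    kappa_max = float(np.max(fr.kappa[fr.valid]))
    norm_df = chrt.normalize_case(bend_df, kappa_centerline_max=kappa_max)
    return {"slice_df": slice_df, "bend_df": bend_df, "norm_df": norm_df,
            "bends": bends, "orientation": orientation, "frames": fr}


def run_cohort(cases: list[SyntheticCase], alpha: float = chrt.DEFAULT_ALPHA,
               holm: bool = False, **analysis_overrides):
    """Analyze every case and build the cohort comparison table.

    Returns ``(norm_df, table, boxes)``: the pooled normalized per-bend
    rows, the Welch comparison table and the box-plot summaries.  Cases
    failing analysis (e.g. landmarking finds no bend) are skipped with a
    warning entry in the returned table's attrs.
    """
    frames, skipped = [], []
    for case in cases:
        try:
            frames.append(analyze_case(case, **analysis_overrides)["norm_df"])
        except ValueError as exc:  # degenerate case: log and continue
            skipped.append((case.case_id, str(exc)))
    if not frames:
        raise ValueError("no case could be analyzed")
    norm_df = pd.concat(frames, ignore_index=True)
    table, boxes = chrt.cohort_table(norm_df, alpha=alpha, holm=holm)
    table.attrs["skipped_cases"] = skipped
    return norm_df, table, boxes


def replicate_power_study(
    n_replicates: int,
    n_cases: int,
    seed: int = 0,
    effect: float | None = None,
    alpha: float = chrt.DEFAULT_ALPHA,
    population_overrides: dict | None = None,
    **analysis_overrides,
) -> pd.DataFrame:
    """p-values of the cohort comparisons across seeded replicate cohorts.

    One row per replicate with the Welch p of each quantity; used to
    measure how often the pipeline flags curvature-coupled secondary
    flow (n_cir, n_rad) versus curvature-independent axial flow (n_ax)
    as significant at the chosen effect size.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31 - 1)
    pop_kw = population_overrides or {}
    rows = []
    for rep, s in enumerate(seeds):
        cases = make_population(n_cases, effect=effect, seed=int(s), **pop_kw)
        _, table, _ = run_cohort(cases, alpha=alpha, **analysis_overrides)
        row = {"replicate": rep, "seed": int(s)}
        for _, r in table.iterrows():
            row[f"p_{r['quantity']}"] = r["p"]
            row[f"mean_A_{r['quantity']}"] = r["mean_A"]
            row[f"sd_A_{r['quantity']}"] = r["sd_A"]
            row[f"mean_O_{r['quantity']}"] = r["mean_O"]
            row[f"sd_O_{r['quantity']}"] = r["sd_O"]
        rows.append(row)
    return pd.DataFrame(rows)
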