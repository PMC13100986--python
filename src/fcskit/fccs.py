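"""Dual-color cross-correlation (FCCS) analysis and oligomeric-state calls.

The headline statistic is the cross-correlation ratio: the fitted
cross-correlation amplitude divided by an autocorrelation amplitude,
in percent. For two labels on non-interacting molecules the ratio sits at
an instrument baseline (set by crosstalk and volume mismatch); co-diffusing
dual-labeled complexes raise it toward 100%. A cohort of per-cell ratios is
classified monomeric or oligomeric by a one-sided elevation test against a
baseline cohort measured on co-expressed free fluorophores.

Amplitudes are taken from fitted N (triplet- and noise-corrected), never
from the raw first-lag G value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlate import CorrelationCurve, bin_photons, estimate_errors
from .models import FitOptions, FitResult, ObservationVolume, fit_correlation
from .simulate import PhotonStream

DENOMINATOR_CONVENTIONS = ("green_auto", "red_auto", "min_amplitude")

#: significance tiers: ns p >= 0.10; trend (#) 0.05 <= p < 0.10;
#: * p < 0.05; ** p < 0.01; *** p < 0.001
def tier_from_p(p: float) -> str:
    if not np.isfinite(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "#"
    return "ns"


_TIER_RANK = {"ns": 0, "#": 1, "*": 2, "**": 3, "***": 4}


@dataclass
class FCCSMeasurement:
    """One dual-color acquisition: three curves and their fits."""

    G_green: CorrelationCurve
    G_red: CorrelationCurve
    G_cross: CorrelationCurve
    fit_green: Optional[FitResult] = None
    fit_red: Optional[FitResult] = None
    fit_cross: Optional[FitResult] = None
    fit_green_anomalous: Optional[FitResult] = None
    cell_id: str = ""
    condition: str = ""
    timepoint: str = ""


@dataclass
class FCCSResult:
    """Cross-correlation ratio and bound fractions for one measurement."""

    ratio_percent: float
    denominator_convention: str
    bound_fraction_green: float      # G_cross(0) / G_red(0)
    bound_fraction_red: float        # G_cross(0) / G_green(0)
    ratio_sd: float = np.nan
    valid: bool = True
    amplitudes: dict = field(default_factory=dict)


@dataclass
class StateCall:
    """Monomeric/oligomeric classification with its supporting test."""

    label: str                       # monomeric | oligomeric | indeterminate
    baseline_percent: float
    p_value: float
    tier: str
    sample_mean: float = np.nan
    diffusion_coefficient: Optional[float] = None   # corroborating only
    note: str = ""


@dataclass
class GroupComparison:
    """Two-group Welch comparison in the tables' mean +/- SD convention."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    p: float
    tier: str
    paired: bool = False


def analyze_measurement(stream: PhotonStream, volume: ObservationVolume,
                        n_segments: int = 10, m_channels: int = 16,
                        options: Optional[FitOptions] = None,
                        anomalous_green: bool = False,
                        **metadata) -> FCCSMeasurement:
    """Correlate and fit a two-channel stream into an FCCSMeasurement."""
    trace = bin_photons(stream, stream.bin_width
                        if stream.mode == "binned" else 1e-6)
    g = trace.channel(0)
    r = trace.channel(1)
    curves = {
        "green": estimate_errors(g, g, n_segments, m_channels, (0, 0)),
        "red": estimate_errors(r, r, n_segments, m_channels, (1, 1)),
        "cross": estimate_errors(g, r, n_segments, m_channels, (0, 1)),
    }
    opts = options or FitOptions()
    fits = {k: fit_correlation(c, "free3d", volume, opts)
            for k, c in curves.items()}
    fit_anom = None
    if anomalous_green:
        fit_anom = fit_correlation(curves["green"], "anomalous", volume, opts)
    return FCCSMeasurement(
        G_green=curves["green"], G_red=curves["red"], G_cross=curves["cross"],
        fit_green=fits["green"], fit_red=fits["red"], fit_cross=fits["cross"],
        fit_green_anomalous=fit_anom, **metadata)


def fccs_ratio(m: FCCSMeasurement, convention: str = "min_amplitude"
               ) -> FCCSResult:
    """Cross-correlation ratio (%) from the three fitted amplitudes.

    Amplitudes are the fitted diffusion amplitudes 1/N. Bound fractions are
    bf_green = A_cross/A_red and bf_red = A_cross/A_green; the
    ``min_amplitude`` convention (default) divides by the smaller auto
    amplitude, i.e. reports the larger bound fraction — the convention is
    always recorded in the result. Uncertainty is first-order propagation
    from the fit standard errors. Any unconverged fit yields an
    indeterminate (invalid) result.
    """
    if convention not in DENOMINATOR_CONVENTIONS:
        raise ValueError(f"convention must be one of "
                         f"{DENOMINATOR_CONVENTIONS}")
    fits = (m.fit_green, m.fit_red, m.fit_cross)
    if any(f is None for f in fits):
        raise ValueError("measurement must carry three fits "
                         "(see analyze_measurement)")
    if not all(f.converged for f in fits):
        return FCCSResult(np.nan, convention, np.nan, np.nan, valid=False)
    a_g, a_r, a_x = (f.amplitude for f in fits)
    bf_green = a_x / a_r if a_r > 0 else np.nan
    bf_red = a_x / a_g if a_g > 0 else np.nan
    denom = {"green_auto": a_g, "red_auto": a_r,
             "min_amplitude": min(a_g, a_r)}[convention]
    ratio = 100.0 * a_x / denom if denom > 0 else np.nan

    def rel_var(f: FitResult) -> float:
        e = f.stderr.get("N", np.nan)
        n = f.params["N"]
        return (e / n) ** 2 if np.isfinite(e) and np.isfinite(n) and n > 0 \
            else 0.0

    denom_fit = {"green_auto": m.fit_green, "red_auto": m.fit_red,
                 "min_amplitude": m.fit_green if a_g <= a_r else m.fit_red}[
                     convention]
    sd = ratio * math.sqrt(rel_var(m.fit_cross) + rel_var(denom_fit)) \
        if np.isfinite(ratio) and a_x > 0 else np.nan
    return FCCSResult(
        ratio_percent=float(ratio), denominator_convention=convention,
        bound_fraction_green=float(bf_green), bound_fraction_red=float(bf_red),
        ratio_sd=float(sd) if np.isfinite(sd) else np.nan,
        amplitudes={"green": a_g, "red": a_r, "cross": a_x})


def _as_ratio_array(x) -> np.ndarray:
    if isinstance(x, FCCSResult):
        x = [x]
    if len(x) and isinstance(x[0], FCCSResult):
        x = [r.ratio_percent for r in x if r.valid]
    return np.asarray(x, dtype=float)


def classify_state(ratios, baseline, d_fit: Optional[FitResult] = None,
                   alpha_level: float = 0.05) -> StateCall:
    """Classify a ratio cohort as monomeric or oligomeric vs a baseline.

    ``ratios`` and ``baseline`` are per-cell cross-correlation ratios (%)
    (FCCSResult sequences accepted); the baseline cohort comes from
    co-expressed free fluorophores. A one-sided Welch test for elevation
    above the baseline is applied: oligomeric requires significance of at
    least * (p < alpha_level); a sample at or below baseline is monomeric
    by construction (the test is one-sided). Fewer than 3 baseline (or
    sample) cells is indeterminate. A diffusion-coefficient fit may be
    attached as corroborating evidence; it never decides the label.
    """
    sample = _as_ratio_array(ratios)
    base = _as_ratio_array(baseline)
    d_val = d_fit.D if d_fit is not None and d_fit.converged else None
    if base.size < 3 or sample.size < 3:
        return StateCall("indeterminate", float(np.mean(base)) if base.size
                         else np.nan, np.nan, "ns",
                         sample_mean=float(np.mean(sample)) if sample.size
                         else np.nan,
                         diffusion_coefficient=d_val,
                         note="need >= 3 cells in sample and baseline")
    t, p = stats.ttest_ind(sample, base, equal_var=False,
                           alternative="greater")
    p = float(p)
    tier = tier_from_p(p)
    label = "oligomeric" if (_TIER_RANK[tier] >= _TIER_RANK["*"]
                             and p < alpha_level) else "monomeric"
    return StateCall(label=label, baseline_percent=float(base.mean()),
                     p_value=p, tier=tier, sample_mean=float(sample.mean()),
                     diffusion_coefficient=d_val)


def classify_state_from_stats(mean: float, sd: float, n: int,
                              baseline_mean: float, baseline_sd: float,
                              baseline_n: int,
                              alpha_level: float = 0.05) -> StateCall:
    """classify_state from summary statistics (mean +/- SD, n) per cohort."""
    if baseline_n < 3 or n < 3:
        return StateCall("indeterminate", baseline_mean, np.nan, "ns",
                         sample_mean=mean, note="need n >= 3 per cohort")
    t, p2 = stats.ttest_ind_from_stats(mean, sd, n, baseline_mean,
                                       baseline_sd, baseline_n,
                                       equal_var=False)
    p = float(p2) / 2.0 if t > 0 else 1.0 - float(p2) / 2.0
    tier = tier_from_p(p)
    label = "oligomeric" if p < alpha_level else "monomeric"
    return StateCall(label=label, baseline_percent=baseline_mean,
                     p_value=p, tier=tier, sample_mean=mean)


def compare_groups(a, b, paired: bool = False) -> GroupComparison:
    """Two-tailed Welch t-test between two value samples, tier-mapped.

    Zero variance in both groups with equal means yields t = 0, p = 1, ns.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal n")
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    if not np.isfinite(t):            # degenerate: no variance anywhere
        t, p = 0.0, 1.0
    return GroupComparison(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=int(b.size),
        t=float(t), p=float(p), tier=tier_from_p(float(p)), paired=paired)


#: row labels of the condition summary, in table order
SUMMARY_ROWS = (
    "diffusion coefficient (um^2/s) (free 3D diffusion fitting)",
    "eGFP concentration (nM)",
    "mApple concentration (nM)",
    "transport coefficient (um^2/s) (anomalous fitting)",
    "FCCS ratio (%)",
)


def summarize_condition(measurements: Sequence[FCCSMeasurement],
                        condition: str = "",
                        n_experiments: Optional[int] = None,
                        convention: str = "min_amplitude") -> pd.DataFrame:
    """Per-condition summary table (mean +/- SD rows, N/n bookkeeping).

    Rows: free-fit diffusion coefficient of the green label, the two
    channel concentrations, the anomalous-fit transport coefficient with
    its exponent, and the FCCS ratio. The header convention records N
    (independent experiments) and n (cells analyzed).
    """
    if len(measurements) == 0:
        raise ValueError("need at least one measurement")
    d_free, c_g, c_r, d_anom, alphas, ratios = [], [], [], [], [], []
    for m in measurements:
        if m.fit_green is not None and m.fit_green.converged:
            d_free.append(m.fit_green.D)
            c_g.append(m.fit_green.concentration_nM)
        if m.fit_red is not None and m.fit_red.converged:
            c_r.append(m.fit_red.concentration_nM)
        fa = m.fit_green_anomalous
        if fa is not None and fa.converged:
            d_anom.append(fa.D)
            alphas.append(fa.params["alpha"])
        r = fccs_ratio(m, convention)
        if r.valid:
            ratios.append(r.ratio_percent)

    def ms(vals):
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            return (np.nan, np.nan, 0)
        return (float(v.mean()),
                float(v.std(ddof=1)) if v.size > 1 else 0.0, int(v.size))

    rows = {
        SUMMARY_ROWS[0]: ms(d_free),
        SUMMARY_ROWS[1]: ms(c_g),
        SUMMARY_ROWS[2]: ms(c_r),
        SUMMARY_ROWS[3]: ms(d_anom),
        SUMMARY_ROWS[4]: ms(ratios),
    }
    am, asd, _ = ms(alphas)
    df = pd.DataFrame(
        {"mean": {k: v[0] for k, v in rows.items()},
         "sd": {k: v[1] for k, v in rows.items()},
         "n_cells": {k: v[2] for k, v in rows.items()}})
    df.index.name = "quantity"
    df.attrs["condition"] = condition
    df.attrs["N_experiments"] = n_experiments
    df.attrs["n_cells"] = len(measurements)
    df.attrs["alpha_mean"] = am
    df.attrs["alpha_sd"] = asd
    df.attrs["convention"] = convention
    return df


def format_condition_table(df: pd.DataFrame) -> str:
    """Render a condition summary as the tables' text convention."""
    cond = df.attrs.get("condition", "")
    n_exp = df.attrs.get("N_experiments")
    n_cells = df.attrs.get("n_cells")
    header = cond or "condition"
    if n_exp is not None:
        header += f" (N = {n_exp}, n = {n_cells})"
    else:
        header += f" (n = {n_cells})"
    lines = [header]
    for row in SUMMARY_ROWS:
        mean, sd = df.loc[row, "mean"], df.loc[row, "sd"]
        cell = f"{mean:.1f} ± {sd:.1f}"
        if row == SUMMARY_ROWS[3] and np.isfinite(
                df.attrs.get("alpha_mean", np.nan)):
            cell += (f" (alpha = {df.attrs['alpha_mean']:.2f} ± "
                     f"{df.attrs['alpha_sd']:.2f})")
        lines.append(f"{row}\t{cell}")
    return "\n".join(lines)
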