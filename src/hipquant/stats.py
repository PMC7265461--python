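"""Relative-quantification statistics for normalized peptide tables.

Fold changes are ratios of arithmetic mean intensities between conditions
(reported as log2).  Significance of an increase is an unpaired two-sided
Student's t test on the replicate intensities.  Because a treatment can
shift the whole repertoire (e.g. a global rise in surface MHC), enrichment
*above* the global trend is tested after mean centering: treated intensities
are divided by the arithmetic mean fold change over all peptides before the
t test.  Centering is skipped when the mean log2 fold change already lies
within +-0.07 of zero, where it would only add noise.

The spread of replicate quantification is summarised two ways: per-peptide
coefficients of variation (median CV), and a Gaussian fitted to the pooled
histogram of log2(x / mu) ratios, whose 3-sigma span converts to the fold
change containing 99.7%% of replicate variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

#: skip mean centering when |mean log2 FC| is at or below this
CENTERING_EXEMPTION_LOG2 = 0.07
SIGNIFICANCE_ALPHA = 0.05


@dataclass
class DistributionSummary:
    """Replicate-variation summary for one intensity matrix."""

    cv_percent: pd.Series
    median_cv: float
    sigma_log2_fit: float        # Gaussian fitted to binned log2(x/mu)
    sigma_log2_direct: float     # plain SD of the pooled ratios
    fc_bound_3sd: float          # 2**(3 * sigma_log2_fit)


def fold_changes(
    values: pd.DataFrame,
    condition_map: dict[str, str],
    treated: str,
    control: str,
) -> pd.DataFrame:
    """Per-peptide log2 fold change of mean(treated) over mean(control).

    Operates on complete cases across both groups; peptides with a zero
    control mean are excluded.  Returns a frame with the group means, the
    ratio-scale FC and its log2.
    """
    cols_t = [c for c, v in condition_map.items() if v == treated]
    cols_c = [c for c, v in condition_map.items() if v == control]
    if not cols_t or not cols_c:
        raise ValueError(f"conditions {treated!r}/{control!r} not in map")
    sub = values[cols_t + cols_c].dropna()
    mean_t = sub[cols_t].mean(axis=1)
    mean_c = sub[cols_c].mean(axis=1)
    ok = mean_c > 0
    if (~ok).any():
        ok_idx = ok[ok].index
        sub, mean_t, mean_c = sub.loc[ok_idx], mean_t[ok_idx], mean_c[ok_idx]
    fc = mean_t / mean_c
    return pd.DataFrame({
        "mean_treated": mean_t, "mean_control": mean_c,
        "fc": fc, "log2_fc": np.log2(fc)})


def t_test(treated: np.ndarray, control: np.ndarray,
           equal_var: bool = True) -> float:
    """Two-sided p of an unpaired two-sample t test.

    Degenerate case (zero variance in both groups): p = 1 for equal means,
    p = 0 for unequal means.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("need >= 2 values per group")
    if treated.std(ddof=1) == 0 and control.std(ddof=1) == 0:
        return 1.0 if treated.mean() == control.mean() else 0.0
    res = sps.ttest_ind(treated, control, equal_var=equal_var)
    return float(res.pvalue)


def compare_conditions(
    values: pd.DataFrame,
    condition_map: dict[str, str],
    treated: str,
    control: str,
    equal_var: bool = True,
    center: str = "auto",
    mean_kind: str = "arithmetic",
) -> pd.DataFrame:
    """Full two-condition comparison: FC, raw p, mean-adjusted p, flags.

    ``center`` is ``auto`` (skip when |mean log2 FC| <= 0.07), ``on`` or
    ``off``.  ``mean_kind`` picks how the global mean fold change is taken
    over peptides (``arithmetic`` over ratios, or ``geometric``).

    Flags: ``significantly_increased`` (p_raw <= 0.05 and FC > 1) and
    ``significantly_enriched`` (p_mean_adjusted <= 0.05 and centered FC > 1).
    """
    if center not in ("auto", "on", "off"):
        raise ValueError(f"center must be auto|on|off, got {center!r}")
    cols_t = [c for c, v in condition_map.items() if v == treated]
    cols_c = [c for c, v in condition_map.items() if v == control]
    fc = fold_changes(values, condition_map, treated, control)
    if fc.empty:
        raise ValueError("empty comparison: no complete-case peptides")
    sub = values.loc[fc.index]

    p_raw = np.array([
        t_test(row[cols_t].to_numpy(), row[cols_c].to_numpy(),
               equal_var=equal_var)
        for _, row in sub.iterrows()])

    if mean_kind == "arithmetic":
        m = float(fc["fc"].mean())
    elif mean_kind == "geometric":
        m = float(2 ** fc["log2_fc"].mean())
    else:
        raise ValueError(f"unknown mean_kind {mean_kind!r}")

    do_center = {"on": True, "off": False}.get(
        center, abs(np.log2(m)) > CENTERING_EXEMPTION_LOG2)
    if do_center:
        centered = sub.copy()
        centered[cols_t] = centered[cols_t] / m
        p_adj = np.array([
            t_test(row[cols_t].to_numpy(), row[cols_c].to_numpy(),
                   equal_var=equal_var)
            for _, row in centered.iterrows()])
        fc_centered = fc["fc"] / m
    else:
        p_adj = p_raw.copy()
        fc_centered = fc["fc"]

    out = fc.copy()
    out["p_raw"] = p_raw
    out["p_mean_adjusted"] = p_adj
    out["mean_fc_global"] = m
    out["centered"] = do_center
    out["significantly_increased"] = (
        (out["p_raw"] <= SIGNIFICANCE_ALPHA) & (out["fc"] > 1.0))
    out["significantly_enriched"] = (
        (out["p_mean_adjusted"] <= SIGNIFICANCE_ALPHA) & (fc_centered > 1.0))
    return out


def cv_summary(values: pd.DataFrame, replicates: list[str]) -> DistributionSummary:
    """Per-peptide CV (%) across replicate columns plus pooled ratio fit."""
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicate columns")
    sub = values[replicates].dropna()
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    cv = 100.0 * sd / mean
    sigma_fit, sigma_direct, bound = _ratio_distribution(sub, mean)
    return DistributionSummary(
        cv_percent=cv, median_cv=float(cv.median()),
        sigma_log2_fit=sigma_fit, sigma_log2_direct=sigma_direct,
        fc_bound_3sd=bound)


def _ratio_distribution(sub: pd.DataFrame, mu: pd.Series):
    ratios = np.log2(sub.div(mu, axis=0).to_numpy(dtype=float)).ravel()
    ratios = ratios[np.isfinite(ratios)]
    if len(ratios) == 0 or np.ptp(ratios) == 0:
        return 0.0, 0.0, 1.0
    sigma_direct = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    # histogram fit needs enough pooled ratios; small tables use the SD
    sigma_fit = fc_distribution_bound(ratios)[0] if len(ratios) >= 30 \
        else sigma_direct
    return sigma_fit, sigma_direct, float(2 ** (3 * sigma_fit))


def fc_distribution_bound(log2_ratios: np.ndarray) -> tuple[float, float]:
    """Gaussian histogram fit of pooled log2(x/mu); returns (sigma, 2**(3 sigma)).

    Binned with the Freedman-Diaconis rule and fitted by least squares on
    the counts.  Degenerate input (all ratios equal) gives sigma = 0,
    bound = 1.
    """
    x = np.asarray(log2_ratios, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("no finite ratios")
    if np.ptp(x) == 0:
        return 0.0, 1.0
    if len(x) < 30:
        raise ValueError("need >= 30 ratios for a distribution fit")
    counts, edges = np.histogram(x, bins="fd")
    centers = (edges[:-1] + edges[1:]) / 2.0

    def gauss(t, a, mu, sigma):
        return a * np.exp(-((t - mu) ** 2) / (2.0 * sigma ** 2))

    a0 = float(counts.max())
    mu0 = float(centers[np.argmax(counts)])
    s0 = float(np.std(x, ddof=1))
    try:
        popt, _ = optimize.curve_fit(
            gauss, centers, counts, p0=[a0, mu0, s0], maxfev=5000)
        sigma = abs(float(popt[2]))
    except RuntimeError:
        sigma = s0
    return sigma, float(2 ** (3 * sigma))


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (optional layer; peptide tests default to raw p)."""
    p = np.asarray(pvalues, dtype=float)
    return sps.false_discovery_control(p, method="bh")
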