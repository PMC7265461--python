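"""Internal-standard normalization and dynamic-range-suppression estimation.

Correction hipMHCs are spiked into every sample at the same amount before
immunoprecipitation, so they experience the same losses as the endogenous
peptides; any ratio between their observed intensities across
samples/channels measures differential loss and loading.  The correction
factor is the multiplier that puts every sample back in the reference
sample's frame:

* TMT: per retained standard PSM, ratio r_c = I(c) / I(reference); the factor
  for channel c is 1 / median(r_c) over all retained correction-standard PSMs
  (pooled across standards, charge states and fractions).
* Label-free: per standard h, ratio of per-sample summed AUC to the
  reference sample's AUC; the factor is 1 / mean over standards.

Standard PSMs whose mean reporter intensity falls outside ten-fold of the
interquartile range of endogenous PSM intensities are dropped before the
TMT median — extreme spike levels drift away from the endogenous response
regime.

A titrated standard (increasing spikes across channels) estimates
dynamic-range suppression: the expected fold between the extreme spiked
amounts divided by the observed intensity fold.  Suppression > 1 means
measured fold changes understate true abundance differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .psm_io import HipMHCSpec, PSMRecord
from .qc_aggregate import PeptideQuantTable

logger = logging.getLogger("hipquant")


@dataclass
class CorrectionFactors:
    """Per-sample/channel multiplicative normalization factors."""

    method: str                     # "lf_mean" | "tmt_median"
    reference_id: str
    factors: dict[str, float]
    standards_used: list[str] = field(default_factory=list)
    n_standard_psms: int = 0
    condition_scoped: bool = False

    def __post_init__(self) -> None:
        ref = self.factors.get(self.reference_id)
        if ref is None or abs(ref - 1.0) > 1e-12:
            raise ValueError("factor(reference) must equal 1 exactly")
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("all correction factors must be > 0")


@dataclass
class SuppressionEstimate:
    """Expected vs observed fold of a titrated standard, plus linear fits."""

    spec_id: str
    expected_fold: float
    observed_fold: float
    suppression: float
    fit_r2_raw: float
    fit_r2_adjusted: float
    slope_adjusted: float = float("nan")


def abundance_window_filter(
    standard_psms: list[PSMRecord],
    endogenous_psms: list[PSMRecord],
    fold_window: float = 10.0,
) -> list[PSMRecord]:
    """Keep standard PSMs within ``fold_window`` of the endogenous IQR.

    Per-PSM mean reporter intensity is computed for every endogenous PSM;
    with [Q1, Q3] its interquartile range (linear-interpolation quantiles),
    standard PSMs are retained iff their mean reporter intensity lies in
    [Q1 / fold_window, Q3 * fold_window], bounds inclusive.
    """
    if not endogenous_psms:
        raise ValueError("endogenous PSM set is empty; no abundance window")
    means = np.array([r.mean_reporter() for r in endogenous_psms])
    q1, q3 = np.percentile(means, [25, 75])  # linear interpolation (type 7)
    lo, hi = q1 / fold_window, q3 * fold_window
    kept = [r for r in standard_psms if lo <= r.mean_reporter() <= hi]
    dropped = len(standard_psms) - len(kept)
    if dropped:
        logger.info("abundance window [%g, %g]: dropped %d standard PSM(s)",
                    lo, hi, dropped)
    if standard_psms and not kept:
        raise ValueError(
            f"all standard PSMs fall outside the endogenous abundance window "
            f"[{lo:g}, {hi:g}]; adjust the spike level")
    return kept


def compute_tmt_correction(
    standard_psms: list[PSMRecord],
    reference: str,
    channels: list[str] | None = None,
    standards_used: list[str] | None = None,
) -> CorrectionFactors:
    """Median-of-ratios correction factors from pooled TMT standard PSMs."""
    if channels is None:
        channels = sorted({c for r in standard_psms for c in (r.reporter or {})})
    ratios: dict[str, list[float]] = {c: [] for c in channels if c != reference}
    n_used = 0
    for r in standard_psms:
        rep = r.reporter or {}
        ref_val = rep.get(reference, 0.0)
        if ref_val <= 0:
            logger.warning("standard PSM scan %s: zero/missing reference "
                           "intensity, excluded", r.scan)
            continue
        n_used += 1
        for c in ratios:
            if c in rep:
                ratios[c].append(rep[c] / ref_val)
    if n_used == 0:
        raise ValueError("no standard PSM with positive reference intensity")
    factors = {reference: 1.0}
    for c, rs in ratios.items():
        if not rs:
            raise ValueError(f"channel {c}: no standard ratios available")
        factors[c] = 1.0 / float(np.median(rs))
    return CorrectionFactors(
        method="tmt_median", reference_id=reference, factors=factors,
        standards_used=standards_used or [], n_standard_psms=n_used)


def compute_lf_correction(
    standard_aucs: dict[str, dict[str, float]],
    reference: str,
    samples: list[str] | None = None,
) -> CorrectionFactors:
    """Mean-of-ratios correction from per-standard per-sample summed AUC.

    ``standard_aucs`` maps standard id -> {sample_id: summed AUC}.  Every
    standard must be quantified in the reference sample; a standard missing
    in some other sample is excluded from that sample's mean.
    """
    for sid, per_sample in standard_aucs.items():
        if per_sample.get(reference, 0.0) <= 0:
            raise ValueError(
                f"correction standard {sid} not quantified in reference "
                f"sample {reference}")
    if samples is None:
        samples = sorted({s for v in standard_aucs.values() for s in v})
    factors = {reference: 1.0}
    for s in samples:
        if s == reference:
            continue
        rs = []
        for sid, per_sample in standard_aucs.items():
            if s in per_sample and per_sample[s] > 0:
                rs.append(per_sample[s] / per_sample[reference])
            else:
                logger.warning("standard %s missing in sample %s; excluded "
                               "from its mean", sid, s)
        if not rs:
            raise ValueError(f"no correction standard quantified in sample {s}")
        factors[s] = 1.0 / float(np.mean(rs))
    return CorrectionFactors(
        method="lf_mean", reference_id=reference, factors=factors,
        standards_used=sorted(standard_aucs), n_standard_psms=len(standard_aucs))


def apply_correction(
    table: PeptideQuantTable, factors: CorrectionFactors,
) -> PeptideQuantTable:
    """Multiply each column of the raw matrix by its factor (raw retained)."""
    missing = [c for c in table.raw.columns if c not in factors.factors]
    if missing:
        raise KeyError(f"no correction factor for column(s) {missing}")
    adjusted = table.raw.mul(
        [factors.factors[c] for c in table.raw.columns], axis=1)
    table.adjusted = adjusted
    return table


def correction_trigger(
    table: PeptideQuantTable,
    condition_map: dict[str, str],
    cond_a: str,
    cond_b: str,
    threshold_log2: float = 1.0,
) -> tuple[bool, float]:
    """Whether per-condition correction is warranted (mean FC beyond 2x).

    Returns ``(trigger, mean_log2_fc)`` where the mean fold change compares
    per-peptide mean intensities of ``cond_a`` vs ``cond_b`` over complete
    cases.  A global shift beyond the threshold means a single set of factors
    would absorb biology into normalization.
    """
    cols_a = [c for c, v in condition_map.items() if v == cond_a]
    cols_b = [c for c, v in condition_map.items() if v == cond_b]
    sub = table.values[cols_a + cols_b].dropna()
    fc = sub[cols_a].mean(axis=1) / sub[cols_b].mean(axis=1)
    mean_log2 = float(np.log2(fc.mean()))
    return abs(mean_log2) > threshold_log2, mean_log2


def per_condition_correction(
    standard_psms: list[PSMRecord],
    condition_map: dict[str, str],
    reference_per_condition: dict[str, str],
) -> list[CorrectionFactors]:
    """Independent median-of-ratios factors within each condition group."""
    conditions = sorted(set(condition_map.values()))
    if len(conditions) < 2:
        raise ValueError("need >= 2 condition groups")
    out = []
    for cond in conditions:
        chans = [c for c, v in condition_map.items() if v == cond]
        if not chans:
            raise ValueError(f"condition {cond}: no channels")
        ref = reference_per_condition[cond]
        if ref not in chans:
            raise ValueError(f"reference {ref} not in condition {cond}")
        scoped = []
        for r in standard_psms:
            rep = {c: v for c, v in (r.reporter or {}).items() if c in chans}
            if rep:
                scoped.append(PSMRecord(
                    sequence=r.sequence, modifications=r.modifications,
                    charge=r.charge, ion_score=r.ion_score,
                    search_rank=r.search_rank, sample_id=r.sample_id,
                    fraction_id=r.fraction_id, rt_sec=r.rt_sec, scan=r.scan,
                    reporter=rep))
        cf = compute_tmt_correction(scoped, ref, channels=chans)
        cf.condition_scoped = True
        out.append(cf)
    return out


def estimate_suppression(
    spec: HipMHCSpec,
    raw_intensity: dict[str, float],
    adjusted_intensity: dict[str, float],
) -> SuppressionEstimate:
    """Dynamic-range suppression of a titrated standard.

    ``raw_intensity`` / ``adjusted_intensity`` map sample/channel to the
    standard's summed intensity before/after correction.  Suppression is the
    expected fold between the extreme spiked amounts divided by the observed
    adjusted-intensity fold; OLS of intensity on fmol yields r² for both.
    """
    pts = [(fmol, ch) for ch, fmol in spec.amounts_fmol.items()
           if ch in adjusted_intensity]
    if len({f for f, _ in pts}) < 2:
        raise ValueError("need >= 2 distinct spiked amounts observed")
    fmol_min, ch_min = min(pts)
    fmol_max, ch_max = max(pts)
    if adjusted_intensity[ch_min] <= 0:
        raise ValueError("intensity at the minimum spike must be > 0")
    expected = fmol_max / fmol_min
    observed = adjusted_intensity[ch_max] / adjusted_intensity[ch_min]
    if observed <= 0:
        raise ValueError("observed fold must be > 0")

    def r2(values: dict[str, float]) -> tuple[float, float]:
        x = np.array([f for f, ch in pts if ch in values])
        y = np.array([values[ch] for f, ch in pts if ch in values])
        if len(x) < 2 or np.ptp(x) == 0:
            return float("nan"), float("nan")
        res = sps.linregress(x, y)
        return float(res.rvalue ** 2), float(res.slope)

    r2_raw, _ = r2(raw_intensity)
    r2_adj, slope_adj = r2(adjusted_intensity)
    return SuppressionEstimate(
        spec_id=spec.spec_id,
        expected_fold=expected,
        observed_fold=observed,
        suppression=expected / observed,
        fit_r2_raw=r2_raw,
        fit_r2_adjusted=r2_adj,
        slope_adjusted=slope_adj)
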