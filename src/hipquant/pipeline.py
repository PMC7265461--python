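"""End-to-end orchestration: read -> filter -> aggregate -> normalize -> stats.

These helpers wire the stage modules together in the fixed order the method
runs, and are what the CLI calls.  Every run directory receives exactly one
JSON manifest (tool version, config hash, input hashes, seeds, per-stage
record counts) so results are traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .absquant import (CalibrationCurve, CopiesPerCellResult,
                       build_calibration_curve, fit_gaussian_profile,
                       quantify_target)
from .norm import (CorrectionFactors, abundance_window_filter,
                   apply_correction, compute_lf_correction,
                   compute_tmt_correction, correction_trigger,
                   estimate_suppression, per_condition_correction)
from .psm_io import ExperimentConfig, HipMHCSpec, PSMRecord, match_standards
from .qc_aggregate import (FilterPolicy, PeptideQuantTable,
                           aggregate_to_peptides, filter_psms)

logger = logging.getLogger("hipquant")


@dataclass
class RunManifest:
    version: str = __version__
    config_hash: str = ""
    input_hashes: dict[str, str] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    started: float = field(default_factory=time.time)
    stage_counts: dict[str, int] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(self.__dict__, indent=1, default=str))
        return path


def hash_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class NormalizedExperiment:
    """Everything the normalization stage produces."""

    table: PeptideQuantTable
    factors: CorrectionFactors | list[CorrectionFactors]
    standards: dict[str, list[PSMRecord]]
    rejection_tally: dict[str, int]
    layout: ExperimentConfig


def normalize_experiment(
    records: list[PSMRecord],
    specs: list[HipMHCSpec],
    layout: ExperimentConfig,
    policy: FilterPolicy | None = None,
    per_condition: str = "auto",
    manifest: RunManifest | None = None,
) -> NormalizedExperiment:
    """Filter PSMs, aggregate, derive and apply hipMHC correction factors.

    ``per_condition``: ``off`` always computes one global factor set; ``on``
    forces condition-scoped factors; ``auto`` switches to condition-scoped
    factors when the global mean fold change between the first two
    conditions exceeds 2x (beyond that the standards' ratios absorb the
    biology, so each condition gets its own reference frame).
    """
    if policy is None:
        policy = FilterPolicy(mode=layout.mode)
    kept, tally = filter_psms(records, policy)
    standards, endogenous = match_standards(kept, specs)
    std_seqs = {s.sequence for s in specs}
    table = aggregate_to_peptides(kept, standard_sequences=std_seqs)

    correction_psms = [r for s in specs if s.role == "correction"
                       for r in standards[s.spec_id]]
    used = [s.spec_id for s in specs if s.role == "correction"]
    if layout.mode == "tmt":
        retained = abundance_window_filter(correction_psms, endogenous) \
            if endogenous else correction_psms
        factors: CorrectionFactors | list[CorrectionFactors] = \
            compute_tmt_correction(retained, layout.reference_id,
                                   channels=layout.channel_labels,
                                   standards_used=used)
    else:
        aucs = {}
        for s in specs:
            if s.role != "correction":
                continue
            per_sample: dict[str, float] = {}
            for r in standards[s.spec_id]:
                per_sample[r.sample_id] = per_sample.get(r.sample_id, 0.0) \
                    + (r.auc or 0.0)
            aucs[s.spec_id] = per_sample
        factors = compute_lf_correction(aucs, layout.reference_id,
                                        samples=layout.channel_labels)

    conditions = sorted(set(layout.condition_map.values()))
    if layout.mode == "tmt" and per_condition != "off" and len(conditions) >= 2:
        trigger, mean_fc = correction_trigger(
            table, layout.condition_map, conditions[0], conditions[1])
        if per_condition == "on" or (per_condition == "auto" and trigger):
            logger.info("per-condition correction engaged "
                        "(mean log2 FC %.2f)", mean_fc)
            retained = abundance_window_filter(correction_psms, endogenous) \
                if endogenous else correction_psms
            refs = {}
            for cond in conditions:
                chans = [c for c, v in layout.condition_map.items()
                         if v == cond]
                refs[cond] = layout.reference_id \
                    if layout.reference_id in chans else chans[0]
            scoped = per_condition_correction(
                retained, layout.condition_map, refs)
            merged = {}
            for cf in scoped:
                merged.update(cf.factors)
            factors = CorrectionFactors(
                method="tmt_median",
                reference_id=scoped[0].reference_id,
                factors=merged,
                standards_used=used,
                n_standard_psms=sum(cf.n_standard_psms for cf in scoped),
                condition_scoped=True)

    apply_correction(table,
                     factors if isinstance(factors, CorrectionFactors)
                     else factors[0])
    if manifest is not None:
        manifest.stage_counts.update({
            "psms_in": len(records), "psms_kept": len(kept),
            "standard_psms": sum(len(v) for v in standards.values()),
            "peptides": len(table.raw)})
    return NormalizedExperiment(
        table=table, factors=factors, standards=standards,
        rejection_tally=dict(tally), layout=layout)


def suppression_from_experiment(
    norm: NormalizedExperiment, specs: list[HipMHCSpec],
):
    """Suppression estimates for every titration standard in the run."""
    out = []
    for spec in specs:
        if spec.role != "titration":
            continue
        key = None
        for k in norm.table.raw.index:
            if k[0] == spec.sequence and "Leu+7" in k[1]:
                key = k
                break
        if key is None:
            logger.warning("titration standard %s not quantified", spec.spec_id)
            continue
        raw = norm.table.raw.loc[key].dropna().to_dict()
        adj = norm.table.adjusted.loc[key].dropna().to_dict()
        out.append(estimate_suppression(spec, raw, adj))
    return out


def quantify_targeted_run(
    scans: pd.DataFrame,
    target: str,
    calibrant_fmol: list[float],
    n_cells: float,
    norm_profiles: list[str] | None = None,
    reference: str | None = None,
) -> tuple[CopiesPerCellResult, CalibrationCurve, CorrectionFactors]:
    """Full absolute-quantification loop on a scan-level reporter table.

    Expects profiles ``<target>_heavy`` (one calibrant amount per channel)
    and ``<target>_light`` (endogenous in every channel/replicate), plus
    normalization-standard profiles spiked equally across channels.  Apex
    intensities come from per-channel Gaussian fits; normalization-standard
    apex ratios give the correction factors (median-of-ratios, as in
    multiplexed runs); the adjusted calibrant apexes form the standard
    curve; light-channel apexes back-calculate to fmol and copies per cell.
    """
    channels = [c[len("reporter_"):] for c in scans.columns
                if c.startswith("reporter_")]
    if reference is None:
        reference = channels[0]
    if norm_profiles is None:
        norm_profiles = sorted(
            p for p in scans["profile_id"].unique()
            if p not in (f"{target}_heavy", f"{target}_light"))

    def apexes(profile: str) -> dict[str, float]:
        sub = scans[scans["profile_id"] == profile]
        if sub.empty:
            raise ValueError(f"profile {profile!r} absent from run")
        out = {}
        for c in channels:
            pts = list(zip(sub["rt_sec"], sub[f"reporter_{c}"]))
            out[c] = fit_gaussian_profile(pts).apex
        return out

    # correction factors from the equal-spike standards' apex ratios
    std_psms = []
    for i, prof in enumerate(norm_profiles):
        std_psms.append(PSMRecord(
            sequence=prof.split("_")[0], modifications=[("Leu+7", 1)],
            scan=i, sample_id="targeted", reporter=apexes(prof)))
    factors = compute_tmt_correction(std_psms, reference, channels=channels,
                                     standards_used=norm_profiles)

    heavy = apexes(f"{target}_heavy")
    light = apexes(f"{target}_light")
    adj_heavy = [heavy[c] * factors.factors[c] for c in channels]
    adj_light = [light[c] * factors.factors[c] for c in channels]
    curve = build_calibration_curve(f"{target}[calibrant]",
                                    list(calibrant_fmol), adj_heavy)
    result = quantify_target(target, curve, adj_light, n_cells)
    return result, curve, factors
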