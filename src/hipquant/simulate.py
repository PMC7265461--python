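"""Synthetic PSM tables and targeted runs with known ground truth.

The generator emulates the study designs this package analyses: multiplexed
(6-plex) or label-free replicate experiments of ~1e7 cells with internal
hipMHC standards, and targeted absolute-quantification runs with an
embedded calibrant series.  Its core premise mirrors the method's: spiked
standards pass through the same per-sample loss factor k_s as endogenous
peptides, so the correction recoverable from standards is exactly 1/k_s.

Signal model per peptide p and sample/channel s::

    I(p, s) = base_p * k_s * effect(p, s)^(1/gamma) * 2^N(0, sigma_log2)

* ``base_p`` — lognormal base abundance (log2 ~ Normal(17, 2)).
* ``k_s`` — multiplicative sample loss/loading factor.
* ``effect`` — condition fold change for endogenous peptides, or relative
  spiked amount for titrated standards.
* ``gamma`` — dynamic-range suppression: observed fold = true fold^(1/gamma),
  a power-law compression of the fold scale (gamma = 1 means none).
* ``sigma_log2`` — lognormal reporter/AUC noise, applied per PSM per channel.

Each peptide yields Poisson-many PSMs (zero means the peptide goes
unobserved — the missingness real tables show); standards get a fixed PSM
count so normalization is always estimable.  Everything is driven by one
integer seed and is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .psm_io import (AMIDATION, HEAVY_LEU, ExperimentConfig, HipMHCSpec,
                     PSMRecord)

#: study-style 6-plex layout
DEFAULT_CHANNELS = ["TMT126", "TMT127", "TMT128", "TMT129", "TMT130", "TMT131"]
#: correction standards spiked equally; titration standard spiked increasing
DEFAULT_CORRECTION_FMOL = 30.0
DEFAULT_TITRATION_FMOL = [30.0, 60.0, 100.0, 150.0, 200.0, 300.0]
#: instrument response, intensity counts per fmol of standard
RESPONSE_PER_FMOL = 2000.0

AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def default_standards(channels: list[str]) -> list[HipMHCSpec]:
    """Two equal-spike correction standards plus one titrated standard."""
    titr = {c: DEFAULT_TITRATION_FMOL[i % len(DEFAULT_TITRATION_FMOL)]
            for i, c in enumerate(channels)}
    return [
        HipMHCSpec("ALNEQIARL", [9], "correction",
                   {c: DEFAULT_CORRECTION_FMOL for c in channels}),
        HipMHCSpec("SLEEPIGHL", [9], "correction",
                   {c: DEFAULT_CORRECTION_FMOL for c in channels}),
        HipMHCSpec("SVVESVKFL", [8], "titration", titr),
    ]


@dataclass
class SimulationConfig:
    """Knobs of the replicate-experiment generator (defaults = study design)."""

    seed: int = 0
    mode: str = "tmt"
    n_peptides: int = 2000
    channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    condition_map: dict[str, str] | None = None   # default: all "replicate"
    reference: str = "TMT126"
    loss_factors: dict[str, float] | None = None  # default: all 1.0
    gamma: float = 1.0
    sigma_log2: float = 0.2
    psm_rate: float = 2.0            # Poisson mean PSMs per endogenous peptide
    standard_psms: int = 10          # PSMs per standard (fixed)
    effect_log2fc: dict[str, float] | None = None  # condition -> global log2 FC
    spike_effects: dict[int, float] | None = None  # peptide idx -> log2 FC
    treated_condition: str | None = None
    standards: list[HipMHCSpec] | None = None
    n_cells: float = 1e7

    def __post_init__(self) -> None:
        if self.mode not in ("lf", "tmt"):
            raise ValueError(f"mode must be lf or tmt, got {self.mode!r}")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.sigma_log2 < 0:
            raise ValueError("sigma_log2 must be >= 0")
        if self.condition_map is None:
            self.condition_map = {c: "replicate" for c in self.channels}
        if self.loss_factors is None:
            self.loss_factors = {c: 1.0 for c in self.channels}
        if any(k <= 0 for k in self.loss_factors.values()):
            raise ValueError("loss factors must be > 0")
        if self.standards is None:
            self.standards = default_standards(self.channels)


@dataclass
class GroundTruth:
    """What the generator actually put in, serialised beside every dataset."""

    seed: int
    loss_factors: dict[str, float]
    gamma: float
    sigma_log2: float
    true_log2_fc: dict[str, float]          # peptide sequence -> log2 FC
    standard_fmol: dict[str, dict[str, float]]
    endogenous_fmol: float | None = None
    n_cells: float | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _random_sequences(rng: np.random.Generator, n: int,
                      forbidden: set[str]) -> list[str]:
    out: list[str] = []
    seen = set(forbidden)
    while len(out) < n:
        length = int(rng.integers(8, 12))
        seq = "".join(rng.choice(AMINO, size=length))
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def generate_replicate_experiment(
    config: SimulationConfig,
) -> tuple[list[PSMRecord], GroundTruth, ExperimentConfig]:
    """Simulate one multiplexed (or LF) replicate experiment.

    Returns the PSM records, the ground truth, and the matching experiment
    layout.  Standards are injected through the same loss/noise path as
    endogenous peptides.
    """
    rng = np.random.default_rng(config.seed)
    channels = config.channels
    k = np.array([config.loss_factors[c] for c in channels])
    noise_sd = config.sigma_log2

    std_seqs = {s.sequence for s in config.standards}
    sequences = _random_sequences(rng, config.n_peptides, std_seqs)
    base = 2.0 ** rng.normal(17.0, 2.0, size=config.n_peptides)

    fc_log2 = np.zeros(config.n_peptides)
    treated = config.treated_condition
    if config.effect_log2fc and treated:
        fc_log2 += config.effect_log2fc.get(treated, 0.0)
    if config.spike_effects:
        for idx, lfc in config.spike_effects.items():
            fc_log2[idx] += lfc
    observed_fold = (2.0 ** fc_log2) ** (1.0 / config.gamma)

    is_treated = np.array([
        config.condition_map[c] == treated if treated else False
        for c in channels])

    records: list[PSMRecord] = []
    scan = 0

    def emit(seq: str, signal_per_channel: np.ndarray, n_psms: int,
             mods: list[tuple[str, int]], score_loc: float = 60.0) -> None:
        nonlocal scan
        if n_psms == 0:
            return
        for _ in range(n_psms):
            scan += 1
            # each PSM is an independent full-scale measurement of the
            # precursor; per-peptide totals are the sum over its PSMs
            noise = 2.0 ** rng.normal(0.0, noise_sd, size=len(channels)) \
                if noise_sd > 0 else np.ones(len(channels))
            psm_int = signal_per_channel * noise
            common = dict(
                sequence=seq, modifications=mods,
                charge=int(rng.integers(2, 4)),
                ion_score=float(np.round(rng.normal(score_loc, 10.0), 2)),
                percolator_q=float(np.round(rng.uniform(0.0, 0.04), 4)),
                isolation_interference_pct=float(
                    np.round(rng.uniform(0.0, 25.0), 1)),
                search_rank=1, fraction_id="f1",
                rt_sec=float(np.round(rng.uniform(300.0, 6000.0), 1)),
                scan=scan)
            if config.mode == "tmt":
                records.append(PSMRecord(
                    **common, sample_id="plex1",
                    reporter={c: float(v)
                              for c, v in zip(channels, psm_int)}))
            else:
                for c, v in zip(channels, psm_int):
                    records.append(PSMRecord(
                        **{**common, "sample_id": c}, auc=float(v)))

    for i, seq in enumerate(sequences):
        signal = base[i] * k * np.where(is_treated, observed_fold[i], 1.0)
        emit(seq, signal, int(rng.poisson(config.psm_rate)), mods=[])

    standard_fmol: dict[str, dict[str, float]] = {}
    for spec in config.standards:
        amounts = np.array([spec.amounts_fmol[c] for c in channels])
        standard_fmol[spec.spec_id] = dict(zip(channels, map(float, amounts)))
        a_ref = amounts.min()
        # titrated spikes feel the same fold compression as real changes
        signal = RESPONSE_PER_FMOL * a_ref * \
            (amounts / a_ref) ** (1.0 / config.gamma) * k
        mods = [(HEAVY_LEU, spec.heavy_positions[0]), (AMIDATION, 0)]
        emit(spec.sequence, signal, config.standard_psms, mods=mods,
             score_loc=80.0)

    truth = GroundTruth(
        seed=config.seed,
        loss_factors=dict(config.loss_factors),
        gamma=config.gamma,
        sigma_log2=config.sigma_log2,
        true_log2_fc={s: float(f) for s, f in zip(sequences, fc_log2)
                      if f != 0.0},
        standard_fmol=standard_fmol,
        n_cells=config.n_cells)
    layout = ExperimentConfig(
        mode=config.mode,
        channel_labels=list(channels),
        reference_id=config.reference if config.mode == "tmt"
        else channels[0],
        condition_map=dict(config.condition_map),
        n_cells=config.n_cells)
    return records, truth, layout


def generate_null_comparison(
    config: SimulationConfig | None = None,
    n_true_effects: int = 0,
    effect_log2fc: float = 2.0,
    seed: int = 0,
) -> tuple[list[PSMRecord], GroundTruth, ExperimentConfig]:
    """Two-condition experiment with no effect (plus optional spike-ins).

    Three channels per condition on the default 6-plex; used to calibrate
    type-I error of the differential statistics.
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    cmap = {c: ("treated" if i >= len(config.channels) // 2 else "control")
            for i, c in enumerate(config.channels)}
    config.condition_map = cmap
    config.treated_condition = "treated"
    if n_true_effects > 0:
        rng = np.random.default_rng(config.seed + 1)
        idx = rng.choice(config.n_peptides, size=n_true_effects, replace=False)
        config.spike_effects = {int(i): effect_log2fc for i in idx}
    return generate_replicate_experiment(config)


# ---------------------------------------------------------------------------
# targeted runs

@dataclass
class TargetedRunConfig:
    """Design of a targeted absolute-quantification run.

    Channels are biological replicates; the heavy calibrant is spiked at a
    different amount into each (the embedded standard curve), the light
    endogenous peptide is present at ``endogenous_fmol`` in every replicate,
    and normalization standards are spiked equally.
    """

    seed: int = 0
    target: str = "KQVSDLISV"
    calibrant_fmol: list[float] = field(default_factory=lambda: [0.3, 1.0, 3.0])
    endogenous_fmol: float = 0.81
    channels: list[str] = field(
        default_factory=lambda: ["TMT126", "TMT127", "TMT128"])
    loss_factors: dict[str, float] | None = None
    gamma: float = 1.0
    sigma_log2: float = 0.0
    rt_center: float = 2400.0
    rt_sigma: float = 8.0
    scan_interval: float = 2.0
    n_cells: float = 1e7
    norm_standard_fmol: float = 30.0

    def __post_init__(self) -> None:
        if len(self.calibrant_fmol) != len(self.channels):
            raise ValueError("one calibrant amount per channel required")
        if self.loss_factors is None:
            self.loss_factors = {c: 1.0 for c in self.channels}
        lo, hi = min(self.calibrant_fmol), max(self.calibrant_fmol)
        if not (lo <= self.endogenous_fmol <= hi):
            import warnings
            warnings.warn("calibrant amounts do not bracket the endogenous "
                          "level; extrapolation ahead", stacklevel=2)


def generate_targeted_run(
    config: TargetedRunConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate scan-level reporter traces for a targeted run.

    Output is a long table: profile_id, scan, rt_sec, reporter_<channel>...
    Profiles: ``<target>_heavy`` (calibrant series), ``<target>_light``
    (endogenous), and two normalization standards.  Amplitudes pass through
    per-channel loss and fold-scale suppression exactly like the replicate
    generator.
    """
    rng = np.random.default_rng(config.seed)
    chans = config.channels
    k = np.array([config.loss_factors[c] for c in chans])
    rts = np.arange(config.rt_center - 4 * config.rt_sigma,
                    config.rt_center + 4 * config.rt_sigma + 1e-9,
                    config.scan_interval)

    a_min = min(min(config.calibrant_fmol), config.endogenous_fmol,
                config.norm_standard_fmol)

    def amplitude(fmol_per_channel: np.ndarray) -> np.ndarray:
        rel = fmol_per_channel / a_min
        return RESPONSE_PER_FMOL * a_min * rel ** (1.0 / config.gamma) * k

    profiles = {
        f"{config.target}_heavy": amplitude(np.array(config.calibrant_fmol)),
        f"{config.target}_light": amplitude(
            np.full(len(chans), config.endogenous_fmol)),
        "ALNEQIARL_heavy": amplitude(
            np.full(len(chans), config.norm_standard_fmol)),
        "SLEEPIGHL_heavy": amplitude(
            np.full(len(chans), config.norm_standard_fmol)),
    }

    rows = []
    scan0 = 10000
    for pid, amps in profiles.items():
        mu = config.rt_center + rng.normal(0.0, 2.0) \
            if config.sigma_log2 > 0 else config.rt_center
        for j, t in enumerate(rts):
            shape = np.exp(-((t - mu) ** 2) / (2 * config.rt_sigma ** 2))
            noise = 2.0 ** rng.normal(0.0, config.sigma_log2, len(chans)) \
                if config.sigma_log2 > 0 else np.ones(len(chans))
            vals = amps * shape * noise
            row = {"profile_id": pid, "scan": scan0 + j,
                   "rt_sec": float(t)}
            row.update({f"reporter_{c}": float(v)
                        for c, v in zip(chans, vals)})
            rows.append(row)
        scan0 += 1000
    truth = GroundTruth(
        seed=config.seed,
        loss_factors=dict(config.loss_factors),
        gamma=config.gamma,
        sigma_log2=config.sigma_log2,
        true_log2_fc={},
        standard_fmol={
            f"{config.target}[calibrant]": dict(
                zip(chans, map(float, config.calibrant_fmol)))},
        endogenous_fmol=config.endogenous_fmol,
        n_cells=config.n_cells)
    return pd.DataFrame(rows), truth
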