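"""Post-search PSM filtering and aggregation to a per-peptide matrix.

Filters follow immunopeptidomics practice for MHC class I peptides: search
engine rank 1, isolation interference <= 30%, length 8-15 residues, ion
score >= 20 for label-free runs or >= 15 plus percolator q <= 0.05 for
TMT-labeled runs.  All thresholds are inclusive and overridable.

Surviving PSM intensities for each unique peptide (sequence + modification
state) are summed per sample/channel across fractions; unobserved cells stay
missing (NaN), never zero.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psm_io import PSMRecord

#: default ion-score thresholds by quantification mode
DEFAULT_MIN_ION_SCORE = {"lf": 20.0, "tmt": 15.0}


@dataclass
class FilterPolicy:
    """Inclusive post-search acceptance thresholds for PSMs."""

    mode: str
    min_ion_score: float | None = None
    max_isolation_interference: float = 30.0
    max_percolator_q: float = 0.05   # applied in TMT mode only
    length_range: tuple[int, int] = (8, 15)
    require_rank1: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("lf", "tmt"):
            raise ValueError(f"mode must be lf or tmt, got {self.mode!r}")
        if self.min_ion_score is None:
            self.min_ion_score = DEFAULT_MIN_ION_SCORE[self.mode]
        lo, hi = self.length_range
        if lo > hi or lo < 1:
            raise ValueError(f"bad length_range {self.length_range}")
        if self.min_ion_score < 0 or self.max_isolation_interference < 0:
            raise ValueError("thresholds must be non-negative")


def filter_psms(
    records: list[PSMRecord], policy: FilterPolicy,
) -> tuple[list[PSMRecord], Counter]:
    """Apply the policy; return survivors and a rejection tally by rule.

    A record is rejected by every rule it fails (the tally counts rule hits),
    and the ``total_rejected`` key counts rejected records, so individual
    rule counts can exceed it only when records fail several rules.
    """
    kept: list[PSMRecord] = []
    tally: Counter = Counter()
    lo, hi = policy.length_range
    for r in records:
        if r.mode != policy.mode:
            raise ValueError(
                f"record quant type {r.mode} does not match policy mode "
                f"{policy.mode}")
        failures = []
        if policy.require_rank1 and r.search_rank != 1:
            failures.append("search_rank")
        if not (lo <= len(r.sequence) <= hi):
            failures.append("length")
        if r.ion_score < policy.min_ion_score:
            failures.append("ion_score")
        if (r.isolation_interference_pct is not None
                and r.isolation_interference_pct
                > policy.max_isolation_interference):
            failures.append("isolation_interference")
        if policy.mode == "tmt" and r.percolator_q is not None \
                and r.percolator_q > policy.max_percolator_q:
            failures.append("percolator_q")
        if failures:
            tally.update(failures)
            tally["total_rejected"] += 1
        else:
            kept.append(r)
    return kept, tally


@dataclass
class PeptideQuantTable:
    """Per-peptide x per-sample/channel intensity matrix.

    ``raw`` holds summed PSM intensities; ``adjusted`` is filled by
    normalization (``adjusted = raw * factor`` column-wise) and is None until
    then.  ``n_psms`` records provenance.  Missing observations are NaN.
    """

    raw: pd.DataFrame
    n_psms: pd.DataFrame
    adjusted: pd.DataFrame | None = None
    merged_amidation_for: frozenset[str] = field(default_factory=frozenset)

    @property
    def values(self) -> pd.DataFrame:
        """Adjusted intensities if normalization has run, else raw."""
        return self.raw if self.adjusted is None else self.adjusted

    def total_intensity(self) -> float:
        return float(np.nansum(self.raw.to_numpy(dtype=float)))


def aggregate_to_peptides(
    records: list[PSMRecord],
    standard_sequences: set[str] | frozenset[str] = frozenset(),
) -> PeptideQuantTable:
    """Sum PSM intensities per unique peptide per sample/channel.

    In TMT mode columns are reporter channels; in LF mode columns are sample
    ids and the summed quantity is precursor AUC.  PSMs of the same peptide
    in different fractions of the same sample are summed together.
    Amidation variants are merged for sequences in ``standard_sequences``.
    """
    cells: dict[tuple[str, str], dict[str, float]] = {}
    counts: dict[tuple[str, str], Counter] = {}
    for r in records:
        key = r.peptide_key(merge_amidation=r.sequence in standard_sequences)
        row = cells.setdefault(key, {})
        cnt = counts.setdefault(key, Counter())
        if r.mode == "lf":
            row[r.sample_id] = row.get(r.sample_id, 0.0) + (r.auc or 0.0)
            cnt[r.sample_id] += 1
        else:
            for ch, v in (r.reporter or {}).items():
                row[ch] = row.get(ch, 0.0) + v
            cnt.update({ch: 1 for ch in (r.reporter or {})})

    index = pd.MultiIndex.from_tuples(
        sorted(cells) or [], names=["sequence", "modifications"])
    raw = pd.DataFrame(
        [cells[k] for k in sorted(cells)], index=index, dtype=float)
    raw = raw.reindex(sorted(raw.columns), axis=1)
    npsm = pd.DataFrame(
        [counts[k] for k in sorted(cells)], index=index).fillna(0).astype(int)
    npsm = npsm.reindex(raw.columns, axis=1, fill_value=0)
    return PeptideQuantTable(
        raw=raw, n_psms=npsm,
        merged_amidation_for=frozenset(standard_sequences))


def completeness_mask(table: PeptideQuantTable, samples: list[str]) -> pd.DataFrame:
    """Rows of the table quantified (non-missing) in every listed sample."""
    unknown = [s for s in samples if s not in table.raw.columns]
    if unknown:
        raise KeyError(f"unknown sample id(s) {unknown}")
    sub = table.values[samples]
    return sub[sub.notna().all(axis=1)]
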