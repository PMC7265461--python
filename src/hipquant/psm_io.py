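"""Reading and writing PSM-level quantification tables and experiment configs.

The canonical on-disk format is a long/wide hybrid TSV: one row per
peptide-spectrum match (PSM), with identification metadata in fixed columns
and quantification either as a single ``auc`` column (label-free mode) or as
one ``reporter_<label>`` column per isobaric channel (TMT mode).  A column
alias map absorbs the most common search-engine export dialects.

Internal standards (hipMHCs — heavy-isotope-coded peptide-MHC complexes
spiked into lysate before immunoprecipitation) are declared in a YAML config
together with the experiment layout (channels, reference, conditions, cell
counts).  Standard PSMs are recognised post-search by their heavy-leucine
modification annotation, never by recomputing masses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("hipquant")

HEAVY_LEU = "Leu+7"
AMIDATION = "C-term amide"
REPORTER_PREFIX = "reporter_"

#: accepted spellings for mandatory columns (lower-cased before lookup)
COLUMN_ALIASES: dict[str, str] = {
    "sequence": "sequence",
    "peptide": "sequence",
    "annotated sequence": "sequence",
    "modifications": "modifications",
    "mods": "modifications",
    "charge": "charge",
    "z": "charge",
    "ion_score": "ion_score",
    "ions score": "ion_score",
    "percolator_q": "percolator_q",
    "percolator q-value": "percolator_q",
    "isolation_interference_pct": "isolation_interference_pct",
    "isolation interference [%]": "isolation_interference_pct",
    "search_rank": "search_rank",
    "rank": "search_rank",
    "sample_id": "sample_id",
    "fraction_id": "fraction_id",
    "rt_sec": "rt_sec",
    "scan": "scan",
    "auc": "auc",
    "precursor abundance": "auc",
}

MANDATORY = ["sequence", "modifications", "charge", "ion_score", "search_rank",
             "sample_id", "fraction_id", "rt_sec", "scan"]


class SchemaError(ValueError):
    """A PSM table or config file violates the documented schema."""


@dataclass
class PSMRecord:
    """One peptide-spectrum match with its quantification payload.

    Exactly one of ``auc`` (label-free) or ``reporter`` (TMT) is set.
    ``modifications`` is a list of ``(name, position)`` pairs; position is
    1-based in the peptide, 0 marks a terminal modification.
    """

    sequence: str
    modifications: list[tuple[str, int]] = field(default_factory=list)
    charge: int = 2
    ion_score: float = 0.0
    percolator_q: float | None = None
    isolation_interference_pct: float | None = None
    search_rank: int = 1
    sample_id: str = ""
    fraction_id: str = ""
    rt_sec: float = 0.0
    scan: int = 0
    auc: float | None = None
    reporter: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("PSM sequence must be non-empty")
        if (self.auc is None) == (self.reporter is None):
            raise ValueError(
                "exactly one of auc (LF) or reporter (TMT) must be present")

    @property
    def mode(self) -> str:
        return "lf" if self.auc is not None else "tmt"

    def is_heavy(self, positions: Iterable[int] | None = None) -> bool:
        """True if the PSM carries the +7 heavy-leucine label.

        With ``positions`` given, the label must sit at one of them.
        """
        heavy_at = {p for (n, p) in self.modifications if n == HEAVY_LEU}
        if not heavy_at:
            return False
        if positions is None:
            return True
        return bool(heavy_at & set(positions))

    def has_amidation(self) -> bool:
        return any(n == AMIDATION for n, _ in self.modifications)

    def mean_reporter(self) -> float:
        if not self.reporter:
            raise ValueError("record has no reporter intensities")
        vals = list(self.reporter.values())
        return sum(vals) / len(vals)

    def peptide_key(self, merge_amidation: bool = False) -> tuple[str, str]:
        """Unique-peptide identity: (sequence, canonical modification string).

        Phosphopeptides and other modified forms stay distinct from the
        unmodified sequence.  ``merge_amidation=True`` drops the C-terminal
        amide from the key — used for synthetic standards, whose amidated and
        free-carboxyl forms are the same standard.
        """
        mods = sorted(self.modifications)
        if merge_amidation:
            mods = [m for m in mods if m[0] != AMIDATION]
        return self.sequence, ";".join(f"{n}@{p}" for n, p in mods)


@dataclass
class HipMHCSpec:
    """An internal-standard peptide: sequence, heavy label positions, role.

    Roles: ``correction`` (equal spike in every sample — defines the
    normalization), ``titration`` (increasing spikes — probes dynamic-range
    suppression), ``calibrant`` (multipoint embedded standard curve for
    absolute quantification).
    """

    sequence: str
    heavy_positions: list[int]
    role: str
    amounts_fmol: dict[str, float]

    ROLES = ("correction", "titration", "calibrant")

    def __post_init__(self) -> None:
        if self.role not in self.ROLES:
            raise SchemaError(f"unknown hipMHC role {self.role!r}")
        if not self.heavy_positions:
            raise SchemaError(f"{self.sequence}: heavy_positions empty")
        amounts = list(self.amounts_fmol.values())
        if any(a <= 0 for a in amounts):
            raise SchemaError(f"{self.sequence}: spiked amounts must be > 0")
        if self.role == "correction":
            if len(set(amounts)) != 1:
                raise SchemaError(
                    f"correction standard {self.sequence} has unequal "
                    f"amounts {sorted(set(amounts))}")
        else:
            if len(set(amounts)) < 2:
                raise SchemaError(
                    f"{self.role} standard {self.sequence} needs >= 2 "
                    f"distinct amounts")

    @property
    def spec_id(self) -> str:
        return f"{self.sequence}[{self.role}]"


@dataclass
class ExperimentConfig:
    """Experiment layout: quant mode, channels, reference, conditions, cells."""

    mode: str
    channel_labels: list[str]
    reference_id: str
    condition_map: dict[str, str]
    n_cells: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("lf", "tmt"):
            raise SchemaError(f"mode must be lf or tmt, got {self.mode!r}")
        if self.reference_id not in self.channel_labels:
            raise SchemaError(
                f"reference {self.reference_id!r} not among channels")
        missing = set(self.channel_labels) - set(self.condition_map)
        if missing:
            raise SchemaError(f"condition_map misses channels {sorted(missing)}")


# ---------------------------------------------------------------------------
# table IO

def _parse_mods(cell: str) -> list[tuple[str, int]]:
    if not cell or pd.isna(cell) or cell == "-":
        return []
    out = []
    for tok in str(cell).split(";"):
        tok = tok.strip()
        if not tok:
            continue
        if "@" in tok:
            name, pos = tok.rsplit("@", 1)
            out.append((name.strip(), int(pos)))
        else:
            out.append((tok, 0))
    return out


def _format_mods(mods: Sequence[tuple[str, int]]) -> str:
    return ";".join(f"{n}@{p}" for n, p in mods)


def read_psm_table(path: str | Path, mode: str) -> list[PSMRecord]:
    """Read a delimited PSM table into records.

    Unknown columns are ignored; malformed numeric cells are reported with
    their row numbers; a reporter cell of NA leaves that channel absent from
    the record's reporter map.
    """
    if mode not in ("lf", "tmt"):
        raise ValueError(f"mode must be lf or tmt, got {mode!r}")
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        warnings.warn(f"{path}: empty PSM table", stacklevel=2)
        return []
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in COLUMN_ALIASES:
            rename[col] = COLUMN_ALIASES[key]
    df = df.rename(columns=rename)

    for col in MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    reporter_cols = [c for c in df.columns if c.startswith(REPORTER_PREFIX)]
    if mode == "tmt" and not reporter_cols:
        raise SchemaError(f"{path}: TMT mode but no {REPORTER_PREFIX}* columns")
    if mode == "lf" and "auc" not in df.columns:
        raise SchemaError(f"{path}: LF mode but no 'auc' column")

    def num(row_i: int, col: str, cell, cast=float):
        if cell is None or (isinstance(cell, float) and pd.isna(cell)) or \
                str(cell).strip() in ("", "NA", "NaN", "nan"):
            return None
        try:
            return cast(float(cell))
        except (TypeError, ValueError):
            raise SchemaError(
                f"{path}: row {row_i + 2}: malformed numeric cell "
                f"{cell!r} in column {col!r}") from None

    records: list[PSMRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = dict(zip(df.columns, row))
        kw = dict(
            sequence=str(d["sequence"]).strip().upper(),
            modifications=_parse_mods(d.get("modifications", "")),
            charge=num(i, "charge", d["charge"], int) or 2,
            ion_score=num(i, "ion_score", d["ion_score"]) or 0.0,
            percolator_q=num(i, "percolator_q", d.get("percolator_q")),
            isolation_interference_pct=num(
                i, "isolation_interference_pct",
                d.get("isolation_interference_pct")),
            search_rank=num(i, "search_rank", d["search_rank"], int) or 1,
            sample_id=str(d["sample_id"]),
            fraction_id=str(d["fraction_id"]),
            rt_sec=num(i, "rt_sec", d["rt_sec"]) or 0.0,
            scan=num(i, "scan", d["scan"], int) or 0,
        )
        if mode == "lf":
            kw["auc"] = num(i, "auc", d["auc"]) or 0.0
        else:
            rep = {}
            for c in reporter_cols:
                v = num(i, c, d[c])
                if v is None:
                    logger.debug("row %d: channel %s NA, dropped", i + 2, c)
                else:
                    rep[c[len(REPORTER_PREFIX):]] = v
            kw["reporter"] = rep
        records.append(PSMRecord(**kw))
    return records


def write_psm_table(records: Sequence[PSMRecord], path: str | Path,
                    channel_labels: Sequence[str] | None = None) -> None:
    """Write records to TSV in the canonical schema (round-trips with read)."""
    path = Path(path)
    if not records:
        pd.DataFrame(columns=MANDATORY).to_csv(path, sep="\t", index=False)
        return
    mode = records[0].mode
    if channel_labels is None and mode == "tmt":
        channel_labels = sorted({c for r in records for c in (r.reporter or {})})
    rows = []
    for r in records:
        d = {
            "sequence": r.sequence,
            "modifications": _format_mods(r.modifications),
            "charge": r.charge,
            "ion_score": r.ion_score,
            "percolator_q": "" if r.percolator_q is None else r.percolator_q,
            "isolation_interference_pct": ""
                if r.isolation_interference_pct is None
                else r.isolation_interference_pct,
            "search_rank": r.search_rank,
            "sample_id": r.sample_id,
            "fraction_id": r.fraction_id,
            "rt_sec": r.rt_sec,
            "scan": r.scan,
        }
        if mode == "lf":
            d["auc"] = r.auc
        else:
            for c in channel_labels:
                d[REPORTER_PREFIX + c] = (r.reporter or {}).get(c, "")
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# config IO

def load_hipmhc_config(path: str | Path) -> tuple[list[HipMHCSpec], ExperimentConfig]:
    """Load standards + experiment layout from a YAML config.

    Expected layout::

        mode: tmt
        channels: [TMT126, TMT127, ...]
        reference: TMT126
        conditions: {TMT126: dmso, ...}
        n_cells: 1.0e7
        standards:
          - sequence: ALNEQIARL
            heavy_positions: [9]
            role: correction
            amounts_fmol: 30            # scalar = same in every channel
          - sequence: SVVESVKFL
            heavy_positions: [9]
            role: titration
            amounts_fmol: {TMT126: 30, TMT127: 60, ...}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    for key in ("mode", "channels", "reference", "conditions", "standards"):
        if key not in doc:
            raise SchemaError(f"{path}: missing config key {key!r}")
    channels = [str(c) for c in doc["channels"]]
    config = ExperimentConfig(
        mode=str(doc["mode"]),
        channel_labels=channels,
        reference_id=str(doc["reference"]),
        condition_map={str(k): str(v) for k, v in doc["conditions"].items()},
        n_cells=float(doc["n_cells"]) if doc.get("n_cells") else None,
    )
    specs = []
    for entry in doc["standards"]:
        amounts = entry["amounts_fmol"]
        if not isinstance(amounts, dict):
            amounts = {c: float(amounts) for c in channels}
        else:
            amounts = {str(k): float(v) for k, v in amounts.items()}
        specs.append(HipMHCSpec(
            sequence=str(entry["sequence"]).upper(),
            heavy_positions=[int(p) for p in entry["heavy_positions"]],
            role=str(entry["role"]),
            amounts_fmol=amounts,
        ))
    return specs, config


def match_standards(
    records: Sequence[PSMRecord], specs: Sequence[HipMHCSpec],
) -> tuple[dict[str, list[PSMRecord]], list[PSMRecord]]:
    """Partition PSMs into standards (by spec id) and endogenous.

    A PSM belongs to a standard iff its sequence matches the spec and it
    carries the heavy-leucine label at a declared position.  C-terminal
    amidation does not split a standard (amidated and free-carboxyl forms of
    a synthetic peptide are the same standard).  Light versions of standard
    sequences stay endogenous.
    """
    by_seq = {s.sequence: s for s in specs}
    standards: dict[str, list[PSMRecord]] = {s.spec_id: [] for s in specs}
    endogenous: list[PSMRecord] = []
    for r in records:
        spec = by_seq.get(r.sequence)
        if spec is not None and r.is_heavy(spec.heavy_positions):
            standards[spec.spec_id].append(r)
        else:
            endogenous.append(r)
    n_std = sum(len(v) for v in standards.values())
    if n_std == 0:
        logger.warning("no standard PSMs matched any spec")
    return standards, endogenous
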