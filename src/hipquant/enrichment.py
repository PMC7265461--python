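"""Pre-ranked gene-set enrichment on peptide-derived protein scores.

Peptide fold changes are collapsed to one score per source protein (the
maximum log2 FC when testing positive enrichment, the minimum when testing
depletion), rank-ordered descending, and tested against gene sets with the
weighted running-sum statistic: walking down the ranked list, hitting a set
member increments the sum by |score|^w normalised by the summed hit weights,
missing decrements by 1/(N - N_hits); the enrichment score (ES) is the
signed maximum deviation from zero.  Weight w = 1 by default.

The null is gene-label permutation (scores stay with ranks, labels are
shuffled), fully seeded.  The nominal p is the same-sign tail fraction, the
NES divides ES by the mean same-sign null ES, and q-values are
Benjamini-Hochberg across the tested sets.  The conventional reporting
filter is nominal p <= 0.05 and q <= 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .stats import benjamini_hochberg

MIN_GENE_SIZE_PEPTIDE = 8    # minimum overlap for peptide-derived lists
MIN_GENE_SIZE_EXPRESSION = 15


@dataclass
class RankedGeneList:
    """Descending (gene, score) ranking; one entry per gene."""

    genes: list[str]
    scores: np.ndarray
    collapse_rule: str = "max"

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    n_overlap: int
    n_permutations: int
    seed: int | None
    testable: bool = True
    notes: list[str] = field(default_factory=list)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: set name, description, then member genes per line."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_rnk(ranked: RankedGeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g, s in zip(ranked.genes, ranked.scores):
            fh.write(f"{g}\t{s:.6g}\n")


def read_rnk(path: str | Path) -> RankedGeneList:
    genes, scores = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        g, s = line.split("\t")
        genes.append(g)
        scores.append(float(s))
    order = sorted(range(len(genes)),
                   key=lambda i: (-scores[i], genes[i]))
    return RankedGeneList(
        genes=[genes[i] for i in order],
        scores=np.array([scores[i] for i in order]))


def collapse_to_proteins(
    peptide_scores: dict[str, float],
    peptide_to_gene: dict[str, str],
    direction: str = "positive",
) -> RankedGeneList:
    """One score per gene: max peptide log2 FC (positive) or min (negative).

    Unmapped peptides are dropped.  Ties in the ranking are broken by gene
    name for determinism.
    """
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be positive|negative, {direction!r}")
    if not peptide_to_gene:
        raise ValueError("empty peptide-to-gene map")
    pick = max if direction == "positive" else min
    per_gene: dict[str, float] = {}
    for pep, score in peptide_scores.items():
        gene = peptide_to_gene.get(pep)
        if gene is None:
            continue
        per_gene[gene] = pick(per_gene.get(gene, score), score)
    items = sorted(per_gene.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedGeneList(
        genes=[g for g, _ in items],
        scores=np.array([s for _, s in items]),
        collapse_rule="max" if direction == "positive" else "min")


def enrichment_score(
    ranked: RankedGeneList,
    gene_set: set[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted running-sum ES of ``gene_set`` in the ranked list.

    Returns (ES, running-sum profile).  ES is the running sum's value at its
    maximum absolute deviation (sign preserved).
    """
    hits = np.array([g in gene_set for g in ranked.genes])
    n = len(ranked.genes)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("empty intersection between list and set")
    if n_hits == n:
        raise ValueError("gene set covers the whole list: ES degenerate")
    w = np.abs(ranked.scores) ** weight
    hit_w = np.where(hits, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all hit scores are zero: fall back to unweighted increments
        hit_w = hits.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~hits) / float(n - n_hits)
    running = np.cumsum(steps)
    es = _signed_extreme(running)
    return es, running


def _signed_extreme(running: np.ndarray, tie_tol: float = 1e-9) -> float:
    """Signed maximum deviation; a near-tie resolves to the positive side."""
    hi, lo = float(running.max()), float(running.min())
    return hi if hi >= -lo - tie_tol else lo


def _overlap(ranked: RankedGeneList, gene_set: set[str]) -> int:
    return sum(g in gene_set for g in ranked.genes)


def permutation_null(
    ranked: RankedGeneList,
    gene_sets: dict[str, set[str]],
    n_permutations: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
    min_size: int = MIN_GENE_SIZE_PEPTIDE,
) -> list[EnrichmentResult]:
    """Gene-label permutation test for each set, with NES and BH q-values.

    For each permutation, set-membership labels are reassigned to random
    ranks (scores stay put).  Nominal p is the fraction of same-sign null ES
    at least as extreme as the observed (never reported below
    1/n_permutations); NES = ES / mean |same-sign null ES|.
    """
    if n_permutations < 100:
        raise ValueError("need >= 100 permutations")
    rng = np.random.default_rng(seed)
    n = len(ranked.genes)
    results: list[EnrichmentResult] = []
    for name in sorted(gene_sets):
        members = gene_sets[name]
        k = _overlap(ranked, members)
        if k < min_size or k == 0 or k >= n:
            results.append(EnrichmentResult(
                set_name=name, es=float("nan"), nes=float("nan"),
                p_nominal=float("nan"), fdr_q=float("nan"), n_overlap=k,
                n_permutations=0, seed=seed, testable=False,
                notes=[f"overlap {k} outside testable range "
                       f"[{min_size}, {n - 1}]"]))
            continue
        es, _ = enrichment_score(ranked, members, weight)
        in_set_template = np.zeros(n, dtype=bool)
        in_set_template[:k] = True
        null = np.empty(n_permutations)
        w = np.abs(ranked.scores) ** weight
        for i in range(n_permutations):
            perm = rng.permutation(n)
            hits = np.zeros(n, dtype=bool)
            hits[perm[:k]] = True
            hit_w = np.where(hits, w, 0.0)
            total = hit_w.sum()
            if total == 0:
                hit_w = hits.astype(float)
                total = float(k)
            steps = hit_w / total - (~hits) / float(n - k)
            null[i] = _signed_extreme(np.cumsum(steps))
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same_sign) == 0:
            p = 1.0 / n_permutations
            nes = float("nan")
        else:
            extreme = np.sum(np.abs(same_sign) >= abs(es))
            p = max(float(extreme) / len(same_sign), 1.0 / n_permutations)
            denom = float(np.mean(np.abs(same_sign)))
            nes = es / denom if denom > 0 else float("nan")
        results.append(EnrichmentResult(
            set_name=name, es=es, nes=nes, p_nominal=p, fdr_q=float("nan"),
            n_overlap=k, n_permutations=n_permutations, seed=seed))
    testable = [r for r in results if r.testable]
    if testable:
        qs = benjamini_hochberg(np.array([r.p_nominal for r in testable]))
        for r, q in zip(testable, qs):
            r.fdr_q = float(q)
    return results


def filter_significant(
    results: list[EnrichmentResult],
    max_p: float = 0.05,
    max_q: float = 0.25,
) -> list[EnrichmentResult]:
    """Conventional reporting filter: nominal p <= 0.05 and FDR q <= 0.25."""
    return [r for r in results
            if r.testable and r.p_nominal <= max_p and r.fdr_q <= max_q]
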