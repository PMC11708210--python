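"""Monte Carlo GO-term enrichment of unique-region gene content.

The question: do the genes whose promoters (or transcripts) intersect
the unique regions over-represent particular GO terms? The null model
keeps the URs' lengths but forgets their locations: each interval is
re-placed uniformly at random across the genome (a chromosome chosen
with probability proportional to its number of valid start positions,
then a start uniformly), the shuffled set is annotated again, and genes
per term are re-counted. The raw p-value of a term is the add-one
estimate

    p_raw = (1 + #{iterations with null count >= observed}) / (1 + N)

which is never exactly zero — with 10^6 iterations the floor is just
above 1e-6. Only terms with at least ``min_genes`` genes genome-wide are
tested; p-values are Bonferroni-corrected by multiplication with the
number of tested terms, and terms with corrected p <= alpha (0.01 by
default) are called enriched. The enrichment ratio is the observed gene
count over the mean null count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomeannot import _build_trees, _feature_intervals
from .regions import GenomicInterval, URSet

__all__ = [
    "TermCounts",
    "EnrichmentResult",
    "count_genes_per_term",
    "shuffle_intervals",
    "mc_enrichment",
    "enrichment_ratio",
    "smallest_corrected_p",
    "write_enrichment",
]

DEFAULT_ITERATIONS = 10_000
DEFAULT_MIN_GENES = 10
DEFAULT_ALPHA = 0.01
DEFAULT_NAMESPACE = "biological_process"

_NAMESPACE_ALIASES = {
    "biological_process": "Process",
    "molecular_function": "Function",
    "cellular_component": "Component",
    "Process": "Process",
    "Function": "Function",
    "Component": "Component",
}


@dataclass
class TermCounts:
    """Distinct-gene counts per GO term for one gene set."""

    counts: dict  # go_id -> int
    total_genes: int

    def __getitem__(self, go_id: str) -> int:
        return self.counts.get(go_id, 0)


def count_genes_per_term(genes, table: pd.DataFrame) -> TermCounts:
    """Count how many distinct input genes are annotated to each GO term."""
    gene_set = set(genes)
    sub = table[table["gene_id"].isin(gene_set)]
    counts = sub.groupby("go_id")["gene_id"].nunique().to_dict()
    return TermCounts(counts=counts, total_genes=len(gene_set))


class PlacementError(ValueError):
    pass


def _placement_tables(chrom_lengths: dict):
    names = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in names], dtype=np.int64)
    return names, lengths


def _place(length: int, names, lengths, rng) -> GenomicInterval:
    valid = np.maximum(lengths - length + 1, 0)
    total = int(valid.sum())
    if total == 0:
        raise PlacementError(f"no chromosome can hold an interval of {length} bp")
    r = int(rng.integers(total))
    cum = np.cumsum(valid)
    ci = int(np.searchsorted(cum, r, side="right"))
    start = r - (int(cum[ci - 1]) if ci else 0)
    return GenomicInterval(names[ci], start, start + length)


def shuffle_intervals(urs, chrom_lengths: dict, seed=None) -> URSet:
    """Re-place every interval uniformly at random, preserving lengths.

    Uniform over all (chromosome, start) placements of each interval's
    length, i.e. a chromosome is hit with probability proportional to
    its number of valid starts. Placed intervals may overlap each other.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names, lengths = _placement_tables(chrom_lengths)
    intervals = [_place(iv.end - iv.start, names, lengths, rng) for iv in urs]
    prov = dict(getattr(urs, "provenance", {}))
    prov["shuffled"] = True
    return URSet(intervals=intervals, provenance=prov)


@dataclass
class EnrichmentResult:
    """Per-term enrichment table plus the metadata of the test run."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def enriched_terms(self) -> list:
        return sorted(self.table.loc[self.table["enriched"], "go_id"])


def enrichment_ratio(observed: float, null_mean: float) -> float:
    """Observed count over mean null count; NaN when the null mean is 0."""
    if null_mean == 0:
        return float("nan")
    return observed / null_mean


def smallest_corrected_p(iterations: int, number_of_tests: int) -> float:
    """Floor of the Bonferroni-corrected add-one Monte Carlo p-value."""
    return min(1.0, number_of_tests / (iterations + 1))


def mc_enrichment(
    urs,
    models,
    table: pd.DataFrame,
    chrom_lengths: dict,
    mode: str = "promoter",
    iterations: int = DEFAULT_ITERATIONS,
    min_genes: int = DEFAULT_MIN_GENES,
    alpha: float = DEFAULT_ALPHA,
    seed=None,
    namespace: str = DEFAULT_NAMESPACE,
) -> EnrichmentResult:
    """The interval-shuffling Monte Carlo test for GO-term enrichment.

    ``table`` is a gene2go table (columns ``gene_id, go_id, go_term,
    category``); the test runs within a single GO namespace. The
    ``min_genes`` filter is applied genome-wide, i.e. to the number of
    genes annotated to the term in the whole table, and the number of
    tests used for the Bonferroni correction is the number of terms
    passing it.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    category = _NAMESPACE_ALIASES.get(namespace)
    if category is None:
        raise ValueError(f"unknown GO namespace {namespace!r}")
    rng = np.random.default_rng(seed)
    sub = table[table["category"] == category]
    genome_counts = sub.groupby("go_id")["gene_id"].nunique()
    tested = sorted(genome_counts.index[genome_counts >= min_genes])
    meta = {
        "mode": mode,
        "iterations": iterations,
        "min_genes": min_genes,
        "min_genes_scope": "genome-wide",
        "alpha": alpha,
        "seed": seed,
        "namespace": namespace,
        "number_of_tests": len(tested),
        "n_intervals": len(list(urs)),
    }
    if not tested:
        import warnings

        warnings.warn("no GO term passes the min_genes filter; empty result")
        return EnrichmentResult(
            table=pd.DataFrame(
                columns=[
                    "go_id",
                    "go_term",
                    "category",
                    "observed_count",
                    "null_mean",
                    "enrichment_ratio",
                    "p_raw",
                    "p_bonferroni",
                    "enriched",
                ]
            ),
            metadata=meta,
        )
    term_index = {t: i for i, t in enumerate(tested)}
    tested_set = set(tested)
    gene_terms: dict = {}
    for gene_id, go_id in sub[["gene_id", "go_id"]].itertuples(index=False):
        if go_id in tested_set:
            gene_terms.setdefault(gene_id, []).append(term_index[go_id])

    trees = _build_trees(_feature_intervals(models, mode, chrom_lengths))

    def annotate_counts(intervals) -> np.ndarray:
        genes: set = set()
        for iv in intervals:
            tree = trees.get(iv.chromosome)
            if tree is not None:
                for hit in tree.overlap(iv.start, iv.end):
                    genes.add(hit.data)
        counts = np.zeros(len(tested), dtype=np.int64)
        for g in genes:
            for ti in gene_terms.get(g, ()):
                counts[ti] += 1
        return counts

    observed = annotate_counts(urs)

    names, lengths = _placement_tables(chrom_lengths)
    ge = np.zeros(len(tested), dtype=np.int64)
    null_sum = np.zeros(len(tested), dtype=np.float64)
    interval_lengths = [iv.end - iv.start for iv in urs]
    for _ in range(iterations):
        shuffled = [_place(l, names, lengths, rng) for l in interval_lengths]
        counts = annotate_counts(shuffled)
        ge += counts >= observed
        null_sum += counts

    p_raw = (1.0 + ge) / (1.0 + iterations)
    p_bonf = np.minimum(1.0, p_raw * len(tested))
    null_mean = null_sum / iterations
    ratios = np.array(
        [enrichment_ratio(o, m) for o, m in zip(observed.astype(float), null_mean)]
    )
    first = sub.drop_duplicates("go_id").set_index("go_id")
    out = pd.DataFrame(
        {
            "go_id": tested,
            "go_term": [first.loc[t, "go_term"] for t in tested],
            "category": category,
            "observed_count": observed,
            "null_mean": null_mean,
            "enrichment_ratio": ratios,
            "p_raw": p_raw,
            "p_bonferroni": p_bonf,
            "enriched": p_bonf <= alpha,
        }
    )
    return EnrichmentResult(table=out, metadata=meta)


def write_enrichment(result: EnrichmentResult, path) -> None:
    with open(path, "w") as fh:
        for k, v in result.metadata.items():
            fh.write(f"# {k}={v}\n")
        result.table.to_csv(fh, sep="\t", index=False, na_rep="NA")
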