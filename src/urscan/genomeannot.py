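"""Gene models, strand-aware promoters, and UR annotation.

Parses NCBI-dialect GFF3 into light-weight gene models, derives 2 kb
promoters upstream of each transcription start site (strand-aware,
truncated at chromosome edges), and intersects unique regions with
promoters or transcript spans to produce gene lists. URs touching
neither promoters nor transcripts are *anonymous*: candidate locations
of missing genes.

Coordinates are converted from GFF3's 1-based inclusive convention to
0-based half-open on parsing; an overlap means >= 1 shared bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils
from intervaltree import IntervalTree

from .regions import GenomicInterval, URSet
from .seqindex import InputFormatError

__all__ = [
    "GeneModel",
    "PromoterSet",
    "parse_gff3",
    "sequence_regions",
    "promoters",
    "annotate",
    "anonymous_regions",
]

DEFAULT_UPSTREAM = 2_000

# NCBI GFF3 transcript-level feature types linked to genes by Parent
_TRANSCRIPT_TYPES = {
    "mRNA",
    "transcript",
    "lnc_RNA",
    "ncRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "miRNA",
    "primary_transcript",
}


@dataclass
class GeneModel:
    """A gene with its transcript spans (0-based half-open) and proteins.

    ``tss`` of a transcript is the strand-appropriate 5' end of its
    span: ``start`` on the + strand, ``end`` on the - strand.
    """

    gene_id: str
    chromosome: str
    strand: str
    transcripts: list = field(default_factory=list)  # list[(start, end)]
    protein_ids: list = field(default_factory=list)

    def tss_positions(self) -> list:
        if self.strand == "+":
            return sorted({s for s, _ in self.transcripts})
        return sorted({e for _, e in self.transcripts})


@dataclass
class PromoterSet:
    """Per-gene promoter intervals, one per distinct TSS."""

    promoters: list  # list[(gene_id, GenomicInterval)]

    def __iter__(self):
        return iter(self.promoters)

    def __len__(self) -> int:
        return len(self.promoters)

    def intervals(self) -> list:
        return [iv for _, iv in self.promoters]


def _prescan(path) -> None:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise InputFormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated GFF3 columns"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError:
                raise InputFormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None


def sequence_regions(path) -> dict:
    """Chromosome lengths from ``##sequence-region`` pragmas (may be empty)."""
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    out[parts[1]] = int(parts[3])
            elif not line.startswith("#"):
                break
    return out


def _gene_identity(feature) -> str:
    # NCBI dialect: prefer the Dbxref GeneID, fall back to the ID attribute
    for xref in feature.attributes.get("Dbxref", []):
        if xref.startswith("GeneID:"):
            return xref.split(":", 1)[1]
    return feature.id


def parse_gff3(path) -> list:
    """One :class:`GeneModel` per ``gene`` feature, transcripts linked by Parent.

    Protein IDs are collected from CDS children (``protein_id``
    attribute, deduplicated). Transcript features whose Parent is not a
    known gene are skipped with a warning.
    """
    _prescan(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: dict = {}
    gene_feature_ids = set()
    for gene in db.features_of_type("gene"):
        gene_feature_ids.add(gene.id)
        models[gene.id] = GeneModel(
            gene_id=_gene_identity(gene),
            chromosome=gene.seqid,
            strand=gene.strand,
        )
    for ftype in sorted(_TRANSCRIPT_TYPES):
        for tr in db.features_of_type(ftype):
            parents = tr.attributes.get("Parent", [])
            parent = next((p for p in parents if p in gene_feature_ids), None)
            if parent is None:
                warnings.warn(
                    f"{path}: transcript {tr.id!r} has no known gene parent; skipped"
                )
                continue
            model = models[parent]
            model.transcripts.append((tr.start - 1, tr.end))
            for cds in db.children(tr, featuretype="CDS"):
                for pid in cds.attributes.get("protein_id", []):
                    if pid not in model.protein_ids:
                        model.protein_ids.append(pid)
    return list(models.values())


def promoters(
    models: list, chrom_lengths: dict | None = None, upstream: int = DEFAULT_UPSTREAM
) -> PromoterSet:
    """2 kb (by default) intervals immediately upstream of each TSS.

    On the + strand the promoter of a transcript spanning ``[s, e)`` is
    ``[max(0, s - upstream), s)``; on the - strand it is
    ``[e, min(L, e + upstream))``. Promoters are truncated, not dropped,
    at chromosome edges; a TSS at position 0 on the + strand yields an
    empty interval which is dropped. One promoter per distinct TSS.
    """
    out: list = []
    for model in models:
        L = None if chrom_lengths is None else chrom_lengths.get(model.chromosome)
        for tss in model.tss_positions():
            if model.strand == "+":
                start, end = max(0, tss - upstream), tss
            else:
                start, end = tss, tss + upstream
                if L is not None:
                    end = min(L, end)
            if end > start:
                out.append((model.gene_id, GenomicInterval(model.chromosome, start, end)))
    return PromoterSet(promoters=out)


def _feature_intervals(models: list, mode: str, chrom_lengths: dict | None):
    if mode == "promoter":
        return [(g, iv) for g, iv in promoters(models, chrom_lengths)]
    if mode == "transcript":
        return [
            (m.gene_id, GenomicInterval(m.chromosome, s, e))
            for m in models
            for s, e in m.transcripts
        ]
    raise ValueError(f"mode must be 'promoter' or 'transcript', got {mode!r}")


def _build_trees(pairs) -> dict:
    trees: dict = {}
    for gene_id, iv in pairs:
        trees.setdefault(iv.chromosome, IntervalTree()).addi(iv.start, iv.end, gene_id)
    return trees


def annotate(
    intervals,
    models: list,
    mode: str = "promoter",
    chrom_lengths: dict | None = None,
    known_chromosomes=None,
) -> list:
    """Genes whose promoters (or transcript spans) overlap any interval.

    Overlap means >= 1 shared bp under half-open semantics: an interval
    abutting a promoter does not report the gene. Each gene is reported
    once; the result is sorted. If ``known_chromosomes`` is given,
    intervals on chromosomes outside it raise a ``ValueError`` listing
    the unmatched names.
    """
    if known_chromosomes is not None:
        bad = sorted({iv.chromosome for iv in intervals} - set(known_chromosomes))
        if bad:
            raise ValueError(f"intervals reference unknown chromosomes: {', '.join(bad)}")
    trees = _build_trees(_feature_intervals(models, mode, chrom_lengths))
    hits: set = set()
    for iv in intervals:
        tree = trees.get(iv.chromosome)
        if tree is not None:
            for hit in tree.overlap(iv.start, iv.end):
                hits.add(hit.data)
    return sorted(hits)


def anonymous_regions(
    urs: URSet, models: list, chrom_lengths: dict | None = None, by_length: bool = False
) -> URSet:
    """URs intersecting neither any promoter nor any transcript span.

    With ``by_length=True`` the result is sorted by length descending
    (the longest anonymous UR is the natural headline per genome);
    otherwise genomic order is kept.
    """
    trees = _build_trees(
        _feature_intervals(models, "promoter", chrom_lengths)
        + _feature_intervals(models, "transcript", chrom_lengths)
    )
    keep = []
    for iv in urs:
        tree = trees.get(iv.chromosome)
        if tree is None or not tree.overlap(iv.start, iv.end):
            keep.append(iv)
    if by_length:
        keep.sort(key=lambda iv: iv.length, reverse=True)
    prov = dict(urs.provenance)
    prov["subset"] = "anonymous"
    return URSet(intervals=keep, provenance=prov)


def write_gene_list(genes: list, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
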