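"""Sequence simulation: repeat planting, divergence decay, and fixtures.

Two jobs live here. First, the sensitivity experiment: how diverged can
two copies of a repeat be before the sliding-window complexity no longer
sees them? Two copies of a 3.7 kb repeat are planted in a 25 kb random
background, mutated at a grid of per-site substitution rates, and the
percentage of repeat nucleotides falling in windows classified as
non-unique is recorded per rate; the *breakpoint* is the first grid rate
at which that percentage drops below 50%.

Second, :func:`make_fixture` emits a complete synthetic input set —
genome FASTA with planted repeat-dense and repeat-free blocks, NCBI-ish
GFF3 gene models whose promoters tie designated GO terms to the
repeat-free blocks, a protein-to-GO table, a miniature ontology, and a
truth table — so the whole pipeline can be exercised end to end without
downloading anything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .complexity import WindowConfig, calibrate_null, classify_unique, profile_genome
from .regions import GenomicInterval, merge_intervals
from .seqindex import SequenceRecord, build_index, random_residues

__all__ = [
    "MutationSpec",
    "DecayExperimentSpec",
    "DecayCurve",
    "random_sequence",
    "mutate",
    "plant_repeats",
    "detection_decay",
    "make_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(
    length: int, composition=None, seed=None, name: str = "random"
) -> SequenceRecord:
    """An i.i.d. random chromosome; a fixed seed gives identical output."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return SequenceRecord(name, random_residues(length, composition, rng))


@dataclass(frozen=True)
class MutationSpec:
    """Per-site substitution probability; each hit site takes one of the
    3 alternative bases uniformly. No indels; ``N`` sites are untouched."""

    rate: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("rate must be in [0, 1]")


def mutate(seq: SequenceRecord, spec: MutationSpec, rng=None) -> SequenceRecord:
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    raw = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8).copy()
    hit = (rng.random(len(raw)) < spec.rate) & (raw != ord("N"))
    idx = np.flatnonzero(hit)
    if len(idx):
        # base code 0..3, shifted by 1..3 mod 4 -> always a different base
        code = np.searchsorted(_BASES, raw[idx])
        new = (code + rng.integers(1, 4, size=len(idx))) % 4
        raw[idx] = _BASES[new]
    return SequenceRecord(seq.id, raw.tobytes().decode("ascii"))


@dataclass(frozen=True)
class DecayExperimentSpec:
    """Geometry of the repeat-divergence experiment.

    Defaults mirror the reference setup: 2 copies of a 3.7 kb repeat on
    a 25 kb random background, scanned with 1 kb windows; rates on a
    grid from 0 to 0.6 in steps of 0.05, 20 replicates per rate.
    """

    background_length: int = 25_000
    repeat_length: int = 3_700
    copies: int = 2
    window: int = 1_000
    rate_grid: tuple = tuple(np.round(np.arange(0, 0.6001, 0.05), 2))
    replicates: int = 20
    seed: int | None = None
    mutation_regime: str = "per_copy"  # 'per_copy' | 'one_copy'
    null_replicates: int = 20

    def __post_init__(self) -> None:
        if self.copies < 2:
            raise ValueError("copies must be >= 2")
        if self.copies * self.repeat_length >= self.background_length:
            raise ValueError("repeats do not fit in the background")
        if self.mutation_regime not in ("one_copy", "per_copy"):
            raise ValueError("mutation_regime must be 'one_copy' or 'per_copy'")
        if list(self.rate_grid) != sorted(self.rate_grid) or not self.rate_grid:
            raise ValueError("rate_grid must be non-empty and increasing")

    @property
    def composite_length(self) -> int:
        return self.background_length + self.copies * self.repeat_length


@dataclass
class DecayCurve:
    """Mean/SD of the detected repeat fraction per rate, and the 50% break."""

    table: pd.DataFrame  # rate, mean_detected_pct, sd, n
    breakpoint: float | None

    def write(self, path) -> None:
        with open(path, "w") as fh:
            if self.breakpoint is not None:
                fh.write(f"# breakpoint_rate={self.breakpoint}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def plant_repeats(
    spec: DecayExperimentSpec, rng=None
) -> tuple[SequenceRecord, list]:
    """Insert ``copies`` identical random repeat copies into a random background.

    Returns the composite sequence and the exact copy coordinates. The
    copies are inserted at random positions of the background, so they
    never overlap (at worst they abut).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    bg = random_residues(spec.background_length, None, rng)
    unit = random_residues(spec.repeat_length, None, rng)
    offsets = np.sort(rng.integers(0, spec.background_length + 1, size=spec.copies))
    parts = []
    intervals = []
    prev = 0
    for k, off in enumerate(offsets):
        parts.append(bg[prev:off])
        pos = off + k * spec.repeat_length
        intervals.append(GenomicInterval("sim", pos, pos + spec.repeat_length))
        parts.append(unit)
        prev = off
    parts.append(bg[prev:])
    return SequenceRecord("sim", "".join(parts)), intervals


def _covered_length(intervals, targets) -> int:
    total = 0
    for t in targets:
        for iv in intervals:
            lo, hi = max(iv.start, t.start), min(iv.end, t.end)
            if hi > lo:
                total += hi - lo
    return total


def detection_decay(spec: DecayExperimentSpec, alpha: float = 0.05) -> DecayCurve:
    """Run the divergence-decay experiment over the rate grid.

    Per rate and replicate: plant fresh copies, mutate them (under
    ``spec.mutation_regime``: ``per_copy``, the default, mutates every
    copy independently at the grid rate, so the grid rate is each copy's
    divergence from the shared ancestor; ``one_copy`` mutates all copies
    but the first, making the grid rate the copy-to-copy divergence for
    two copies), index the
    composite, classify windows at ``alpha``, and record the percentage
    of copy nucleotides lying inside non-unique windows. The null model
    is calibrated once — it depends only on the composite length,
    composition and window geometry, which are shared by all replicates.
    """
    ss = np.random.SeedSequence(spec.seed)
    null_seed, exp_seed = (int(s) % 2**31 for s in ss.generate_state(2))
    cfg = WindowConfig(spec.window)
    null = calibrate_null(
        spec.composite_length,
        np.full(4, 0.25),
        cfg,
        replicates=spec.null_replicates,
        seed=null_seed,
    )
    rng = np.random.default_rng(exp_seed)
    rows = []
    for rate in spec.rate_grid:
        detected = []
        for _ in range(spec.replicates):
            seq, copies = plant_repeats(spec, rng)
            mspec = MutationSpec(rate=float(rate))
            raw = list(seq.residues)
            to_mutate = copies[1:] if spec.mutation_regime == "one_copy" else copies
            for iv in to_mutate:
                sub = SequenceRecord("c", seq.residues[iv.start : iv.end])
                raw[iv.start : iv.end] = mutate(sub, mspec, rng).residues
            composite = SequenceRecord(seq.id, "".join(raw))
            index = build_index([composite])
            profile = profile_genome(index, cfg, null)
            classified = classify_unique(profile, null, alpha)
            nonuniq = classified[~classified["unique"]]
            windows = [
                GenomicInterval(r.chromosome, int(r.start), int(r.end))
                for r in nonuniq.itertuples()
            ]
            cov = _covered_length(merge_intervals(windows), copies)
            detected.append(100.0 * cov / (spec.copies * spec.repeat_length))
        detected = np.asarray(detected)
        rows.append(
            {
                "rate": float(rate),
                "mean_detected_pct": float(detected.mean()),
                "sd": float(detected.std(ddof=1)) if len(detected) > 1 else 0.0,
                "n": len(detected),
            }
        )
    table = pd.DataFrame(rows)
    below = table[table["mean_detected_pct"] < 50.0]
    breakpoint = float(below["rate"].iloc[0]) if len(below) else None
    return DecayCurve(table=table, breakpoint=breakpoint)


# ---------------------------------------------------------------------------
# End-to-end synthetic fixture
# ---------------------------------------------------------------------------

_OBO_TERMS = [
    # (go_id, name, namespace, parents)
    ("GO:0000001", "synthetic biological process root", "biological_process", []),
    ("GO:0000010", "synthetic pattern specification process", "biological_process", ["GO:0000001"]),
    ("GO:0000011", "synthetic embryo development", "biological_process", ["GO:0000010"]),
    ("GO:0000020", "synthetic metabolic process", "biological_process", ["GO:0000001"]),
    ("GO:0000030", "synthetic catalytic activity", "molecular_function", []),
]


@dataclass
class FixturePaths:
    directory: Path
    fasta: Path
    gff3: Path
    pro2go: Path
    obo: Path
    truth: Path


def make_fixture(
    outdir,
    seed: int | None = None,
    unique_blocks: int = 6,
    repeat_blocks: int = 6,
    block_length: int = 25_000,
    genes_per_block: int = 4,
    repeat_unit: int = 400,
    plant_signal: bool = True,
) -> FixturePaths:
    """Write a synthetic genome + annotation with known ground truth.

    The single chromosome alternates repeat-dense blocks (tandem copies
    of one repeat unit, complexity near 0) with repeat-free blocks
    (i.i.d. random, complexity near 1). "Developmental-like" genes
    (terms GO:0000010/GO:0000011) sit in the repeat-free blocks when
    ``plant_signal`` is true, control genes (GO:0000020) in the
    repeat-dense blocks — so the repeat-free blocks are the planted URs
    and the developmental-like terms the planted enrichment. With
    ``plant_signal`` false, genes of both kinds are interleaved across
    blocks of both types, so no term is preferentially unique.

    All files are synthetic stand-ins generated from the seed; the truth
    table (JSON) records planted URs and planted enriched terms.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_blocks = unique_blocks + repeat_blocks
    chrom = "chrS"
    unit = random_residues(repeat_unit, None, rng)
    reps_per_block = -(-block_length // repeat_unit)  # ceil: tile then clip
    blocks = []
    block_kind = []
    for b in range(n_blocks):
        if b % 2 == 0 and (b // 2) < repeat_blocks:
            blocks.append((unit * reps_per_block)[:block_length])
            block_kind.append("repeat")
        else:
            blocks.append(random_residues(block_length, None, rng))
            block_kind.append("unique")
    # if counts are uneven, fix the tail assignment
    while block_kind.count("unique") > unique_blocks:
        i = len(block_kind) - 1 - block_kind[::-1].index("unique")
        blocks[i] = (unit * reps_per_block)[:block_length]
        block_kind[i] = "repeat"
    genome = SequenceRecord(chrom, "".join(blocks))

    genes = []  # (gene_id, protein_id, start, end, strand, kind)
    gi = 0
    for b, kind in enumerate(block_kind):
        base = b * block_length
        for j in range(genes_per_block):
            start = base + 5_000 + j * 4_500
            end = start + 2_000
            if plant_signal:
                g_kind = "dev" if kind == "unique" else "ctl"
            else:
                g_kind = "dev" if (gi % 2 == 0) else "ctl"
            gi += 1
            genes.append((f"{100000 + gi}", f"P{gi:04d}", start, end, "+", g_kind))

    fasta = outdir / "genome.fasta"
    with open(fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.residues[i : i + 70] + "\n")

    gff3 = outdir / "annotation.gff3"
    with open(gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {chrom} 1 {genome.length}\n")
        for gene_id, pid, s, e, strand, _ in genes:
            g1, e1 = s + 1, e  # GFF3 is 1-based inclusive
            fh.write(
                f"{chrom}\tsynthetic\tgene\t{g1}\t{e1}\t.\t{strand}\t.\t"
                f"ID=gene-{gene_id};Dbxref=GeneID:{gene_id}\n"
            )
            fh.write(
                f"{chrom}\tsynthetic\tmRNA\t{g1}\t{e1}\t.\t{strand}\t.\t"
                f"ID=rna-{gene_id};Parent=gene-{gene_id}\n"
            )
            fh.write(
                f"{chrom}\tsynthetic\tCDS\t{g1}\t{e1}\t.\t{strand}\t0\t"
                f"ID=cds-{gene_id};Parent=rna-{gene_id};protein_id={pid}\n"
            )

    pro2go = outdir / "pro2go.tsv"
    with open(pro2go, "w") as fh:
        fh.write("# protein\tGO terms (synthetic)\n")
        for _, pid, *_rest, kind in [(g[0], g[1], g[5]) for g in genes]:
            gos = (
                "GO:0000010,GO:0000011,GO:0000030"
                if kind == "dev"
                else "GO:0000020,GO:0000030"
            )
            fh.write(f"{pid}\t{gos}\n")

    obo = outdir / "go.obo"
    with open(obo, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for go_id, name, ns, ps in _OBO_TERMS:
            fh.write(f"\n[Term]\nid: {go_id}\nname: {name}\nnamespace: {ns}\n")
            for p in ps:
                fh.write(f"is_a: {p}\n")

    truth = outdir / "truth.json"
    planted_urs = [
        [chrom, b * block_length, (b + 1) * block_length]
        for b, kind in enumerate(block_kind)
        if kind == "unique"
    ]
    with open(truth, "w") as fh:
        json.dump(
            {
                "planted_urs": planted_urs if plant_signal else [],
                "unique_blocks": planted_urs,
                "enriched_terms": ["GO:0000010", "GO:0000011"] if plant_signal else [],
                "control_terms": ["GO:0000020"],
                "chromosome_length": genome.length,
                "seed": seed,
                "plant_signal": plant_signal,
            },
            fh,
            indent=1,
        )
    return FixturePaths(outdir, fasta, gff3, pro2go, obo, truth)
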