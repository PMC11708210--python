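# Methods

## Model

A genome is read as a set of chromosomes over {A,C,G,T,N}. For position
*i* the matching statistic MS[i] is the length of the longest prefix of
the suffix at *i* that occurs at least once at a *different* position of
the forward strand or anywhere in the reverse-complemented genome.
Matching is exact; N matches nothing, including another N, so assembly
gaps cannot create artifactual repeats, and no match crosses a
chromosome or strand boundary.

The index concatenates all chromosomes and their reverse complements,
separated by sentinels; every N and every sentinel is encoded as its own
unique integer symbol, which enforces the non-matching rules by
construction. The suffix array is built by numpy prefix doubling
(O(n log n) with vectorised sorts), the LCP array by Kasai's algorithm
(numba-compiled), and MS[i] is the larger of the two LCP entries
adjacent to suffix *i* in suffix-array order. A quadratic brute-force
scanner over both strands serves as the independent oracle in the test
suite (genomes ≤ 200 bp).

Each chromosome is greedily factorized from position 0: the factor at
*p* has length max(MS[p], 1) and the next factor starts immediately
after it. The length-1 floor makes the tiling total and guarantees
termination. The observed count *m*<sub>o</sub> of a window is the
number of precomputed factors overlapping it by ≥ 1 bp — a single parse
per chromosome, shared by all (overlapping) windows, which keeps
*m*<sub>o</sub> well-defined across strides. Whether a reference
factor-counting implementation counts per factor or per occurrence pair
is not documented anywhere we could rely on; the greedy-factor reading
is this package's definition and everything downstream is calibrated
against it, so the choice cancels in Cm.

The match complexity of a window is Cm = (m<sub>o</sub> − 1) /
(m<sub>e</sub> − 1). The −1 pins a perfect repeat (one factor spanning
the window) at exactly 0 and makes random sequence average 1.

## Null calibration

m<sub>e</sub> and the null distribution of Cm are estimated by Monte
Carlo rather than a closed form: `calibrate_null` draws i.i.d. random
sequences matched to the genome in total length and global (non-N) base
composition — one null per genome, not per chromosome — indexes each
exactly as a real genome, and collects every window's factor count.
m<sub>e</sub> is the mean count (an error is raised if m<sub>e</sub> ≤ 1,
which signals a window too short to carry information at that genome
length); the null Cm sample is the standardised counts. Default 20
replicates. The calibration is seeded and fully reproducible; the null
model serialises to a key-value sidecar carrying all metadata plus the
sample itself.

A window is **unique** iff its Cm is at or above the empirical
α-quantile (linear interpolation, ties inclusive) of the null — a
one-sided lower test in which low Cm means repeat-like. Default
α = 0.05; on pure random sequence the fraction of windows rejected
tracks α, which the suite checks. Note the direction: a *larger* α is a
*stricter* uniqueness call. Windows more than 50% N get a missing Cm
and are never unique. Window geometry: length W, stride W/10 by default
(the stride is not prescribed by the underlying method; every
experiment here states its own), last window flush with the chromosome
end.

Unique regions (URs) are maximal runs of unique windows, merged over
overlaps and book-ended joins, filtered to ≥ 10 kb by default
(inclusive bound, configurable).

## Annotation

GFF3 (NCBI dialect) is parsed with gffutils; gene identity is the
Dbxref `GeneID` where present, the feature ID otherwise; any
transcript-level child (mRNA, ncRNA, …) links by `Parent`, so
non-coding genes get promoters too. Promoters are the 2 kb immediately
upstream of each distinct TSS, strand-aware, truncated (not dropped) at
chromosome edges. Intersection of URs with promoters or full transcript
spans (introns and UTRs included) uses ≥ 1 bp of overlap under 0-based
half-open coordinates — the most permissive reading of "intersect", and
stated so it is testable. URs touching neither promoters nor
transcripts are *anonymous*.

gene→GO tables are built as an inner join of gene→protein (from CDS
`protein_id` attributes), protein→GO (input TSV, comma-separated GO
lists per protein), and the ontology (go-basic OBO via obonet; is_a and
part_of edges; obsolete terms excluded; acyclicity enforced). Output is
the 8-column NCBI gene2go dialect with `-` placeholders in the four
unused columns. Optional propagation annotates every gene to the
ancestor closure of its terms; it is **off** by default because the
counting convention of reference tools is unstated, and the enrichment
output records which mode produced it.

## Enrichment test

Per GO term, the observed statistic is the number of distinct genes
annotated to the term among the genes whose promoters (or transcripts)
intersect the URs. The null re-places each UR uniformly at random:
chromosome chosen with probability proportional to its number of valid
start positions for that interval's length, then a start uniformly;
placed intervals may overlap each other and may land on N runs (no
collision or gap avoidance; an N-exclusion flag is not provided because
the shuffle model deliberately matches the plain uniform-placement
null). Lengths are preserved exactly.

p_raw = (1 + #{iterations with null count ≥ observed}) / (1 + N) — the
add-one estimator, never exactly 0; with 10⁶ iterations and 2,953
tests the corrected floor is 2953/1000001 ≈ 0.0030. Only terms with at
least `min_genes` (default 10) genes **genome-wide** are tested — the
filter is applied to the whole gene2go table, not the observed UR gene
set, and the scope is recorded in the output metadata so the two
readings can be compared. Bonferroni correction multiplies by the
number of tested terms, capped at 1; corrected p ≤ 0.01 (default) is
called enriched. Tests run within one GO namespace at a time (default
biological_process). Desk default 10⁴ iterations. The enrichment ratio
is observed over mean null count (missing when the null mean is 0).

## Simulation and fixtures

The mutation model is substitutions only (no indel model is defined for
the reference simulator, so none is implemented): each site is hit
independently with the given probability and takes one of the three
alternative bases uniformly; N is untouched.

The divergence-decay experiment plants 2 identical copies of a random
3.7 kb repeat unit at random non-overlapping positions of a 25 kb
i.i.d. background (composite 32.4 kb), mutates **each copy
independently** at the grid rate — so the grid rate is each copy's
divergence from their common ancestor — scans with 1 kb windows
(stride 100), classifies at α = 0.05, and records the percentage of
copy nucleotides inside non-unique windows; 20 replicates per rate on a
0–0.6 grid in steps of 0.05. The breakpoint is the first grid rate
whose mean detected fraction falls below 50%; under these defaults it
sits at 0.2 substitutions/site. A `one_copy` regime (only one copy
mutated, making the grid rate the copy-to-copy divergence) is provided
for sensitivity analysis and shifts the breakpoint to ~0.35. The
background is left unmutated: substituting i.i.d. random sequence
yields i.i.d. random sequence. One null model is calibrated and shared
across all rates and replicates, since it depends only on the composite
length, composition, and window geometry, which are identical
throughout.

The synthetic fixture emulates the one property the method measures —
presence/absence of long exact self-homology — by alternating 25 kb
blocks of tandem repeats with 25 kb blocks of i.i.d. random sequence,
and ties GO terms to block types through gene placement. What it does
*not* emulate: real base composition and GC heterogeneity, degenerate
repeat families at intermediate divergence, alternative transcripts,
and realistic GO topology. Passing the end-to-end tests therefore shows
the machinery is correct and calibrated under the stated null, not that
real genomes will separate as cleanly.

## Numerical and design notes

- Coordinates are 0-based half-open internally; GFF3's 1-based
  inclusive convention is converted at the parser boundary only.
- Determinism: every stochastic routine takes a seed (or numpy
  Generator); the pipeline derives per-stage seeds from one global seed
  via `SeedSequence`, and identical seeds give byte-identical outputs.
- Empirical quantiles use numpy's linear interpolation; the uniqueness
  threshold is inclusive (Cm equal to the threshold → unique).
- Degenerate inputs: all-N genomes are rejected; chromosomes shorter
  than the window yield no windows (not an error); empty regions yield
  empty factorizations; a gene with no transcript contributes no
  promoter; an interval longer than every chromosome cannot be shuffled
  and raises a placement error naming the length.
- Problem sizes in the shipped experiments (1 Mb × 21 sequences for the
  normalization check; 260 composite sequences of 32.4 kb for the decay
  curve; a 300 kb fixture genome) were chosen as the smallest scales at
  which the quantities of interest are stable against Monte Carlo
  noise.

## Known limitations

- The suffix array is rebuilt per run; there is no persisted index, so
  multi-gigabase genomes are out of reach of this implementation (the
  windowed analysis itself is linear and would carry over).
- The null is genome-global: locally GC-rich or GC-poor regions are
  compared against the global composition, which can bias Cm in either
  direction; a GC-stratified null is deliberately out of scope.
- Matching is exact, so repeats diverged beyond ~0.2 substitutions/site
  are invisible by design — that insensitivity is quantified, not
  corrected.
- The enrichment null shuffles intervals independently (they may
  overlap), which is slightly liberal for very high UR densities; at
  realistic UR fractions the effect is negligible and the calibration
  test bounds it.
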