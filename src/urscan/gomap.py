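"""Building the gene -> GO map by joining three tables.

NCBI distributes a ``gene2go`` file for only a handful of organisms, so
for an arbitrary genome the map is reconstructed by joining:

* ``gene2pro`` — gene ID -> protein ID, extracted from the GFF3;
* ``pro2go``   — protein ID -> GO IDs, from homology annotation of the
  proteome (consumed here as a TSV in the eggNOG annotations-column
  convention: protein, comma-separated GO IDs);
* ``go2term``  — GO ID -> term name and category, from the go-basic
  ontology (OBO).

The result is written in the 8-column NCBI gene2go dialect, of which
four columns carry information (GeneID, GO_ID, GO_term, Category);
unused columns hold ``-``. Annotations can optionally be propagated to
all ``is_a``/``part_of`` ancestors; propagation is off by default and
the choice is recorded by downstream consumers.
"""

from __future__ import annotations

import warnings

import networkx as nx
import obonet
import pandas as pd

from .seqindex import InputFormatError

__all__ = [
    "GoDag",
    "parse_obo",
    "extract_gene2pro",
    "read_pro2go",
    "build_gene2go",
    "propagate",
    "read_gene2go",
    "write_gene2go",
]

GENE2GO_COLUMNS = [
    "tax_id",
    "GeneID",
    "GO_ID",
    "Evidence",
    "Qualifier",
    "GO_term",
    "PubMed",
    "Category",
]

# GO namespace -> the Category word used by the NCBI gene2go dialect
NAMESPACE_TO_CATEGORY = {
    "biological_process": "Process",
    "molecular_function": "Function",
    "cellular_component": "Component",
}


class GoDag:
    """Gene Ontology terms with their ``is_a``/``part_of`` parent links."""

    def __init__(self, terms: dict, parents: dict):
        self.terms = terms  # go_id -> (name, namespace)
        self._parents = parents  # go_id -> set of parent go_ids

    def __contains__(self, go_id: str) -> bool:
        return go_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def name(self, go_id: str) -> str:
        return self.terms[go_id][0]

    def namespace(self, go_id: str) -> str:
        return self.terms[go_id][1]

    def category(self, go_id: str) -> str:
        return NAMESPACE_TO_CATEGORY[self.namespace(go_id)]

    def parents(self, go_id: str) -> set:
        return set(self._parents.get(go_id, ()))

    def ancestors(self, go_id: str) -> set:
        """Transitive closure over ``is_a`` and ``part_of`` (excl. the term)."""
        seen: set = set()
        stack = list(self.parents(go_id))
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.parents(t))
        return seen


def parse_obo(path) -> GoDag:
    """Load a go-basic OBO file; obsolete terms are excluded.

    Terms without a namespace are skipped with a warning; a cycle over
    ``is_a``/``part_of`` raises :class:`~urscan.seqindex.InputFormatError`.
    """
    graph = obonet.read_obo(str(path))
    terms: dict = {}
    for go_id, data in graph.nodes(data=True):
        ns = data.get("namespace")
        if ns is None:
            warnings.warn(f"GO term {go_id} has no namespace; skipped")
            continue
        terms[go_id] = (data.get("name", go_id), ns)
    parents: dict = {}
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for child, parent, key in graph.edges(keys=True):
        if key not in ("is_a", "part_of"):
            continue
        if child in terms and parent in terms:
            parents.setdefault(child, set()).add(parent)
            g.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(g):
        raise InputFormatError(f"{path}: cycle detected over is_a/part_of relations")
    return GoDag(terms=terms, parents=parents)


def extract_gene2pro(models: list) -> pd.DataFrame:
    """The gene ID -> protein ID table from parsed gene models."""
    rows = [
        (m.gene_id, pid)
        for m in models
        for pid in m.protein_ids
    ]
    return (
        pd.DataFrame(rows, columns=["gene_id", "protein_id"])
        .drop_duplicates()
        .reset_index(drop=True)
    )


def read_pro2go(path) -> pd.DataFrame:
    """Protein -> GO TSV: column 1 protein ID, column 2 comma-separated GO IDs."""
    rows: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InputFormatError(f"{path}: line {lineno}: expected 2 columns")
            gos = fields[1].strip()
            if gos in ("", "-"):
                continue
            for go_id in gos.split(","):
                go_id = go_id.strip()
                if go_id:
                    rows.append((fields[0], go_id))
    return (
        pd.DataFrame(rows, columns=["protein_id", "go_id"])
        .drop_duplicates()
        .reset_index(drop=True)
    )


def build_gene2go(
    gene2pro: pd.DataFrame, pro2go: pd.DataFrame, dag: GoDag
) -> pd.DataFrame:
    """Inner join gene2pro |><| pro2go |><| go2term; duplicates collapsed.

    GO IDs absent from the ontology are dropped with a warning. The
    result has columns ``gene_id, go_id, go_term, category``.
    """
    joined = gene2pro.merge(pro2go, on="protein_id", how="inner")
    unknown = sorted(set(joined["go_id"]) - set(dag.terms))
    if unknown:
        warnings.warn(
            f"{len(unknown)} GO ID(s) absent from the ontology dropped "
            f"(e.g. {unknown[0]})"
        )
        joined = joined[~joined["go_id"].isin(unknown)]
    if joined.empty:
        warnings.warn("gene2go join produced no rows")
        return pd.DataFrame(columns=["gene_id", "go_id", "go_term", "category"])
    out = joined[["gene_id", "go_id"]].drop_duplicates()
    out = out.assign(
        go_term=out["go_id"].map(dag.name),
        category=out["go_id"].map(dag.category),
    )
    return out.sort_values(["gene_id", "go_id"]).reset_index(drop=True)


def propagate(table: pd.DataFrame, dag: GoDag) -> pd.DataFrame:
    """Annotate each gene to every ancestor of its GO terms (idempotent)."""
    rows = []
    for gene_id, go_id in table[["gene_id", "go_id"]].itertuples(index=False):
        for anc in dag.ancestors(go_id):
            rows.append((gene_id, anc))
    if rows:
        extra = pd.DataFrame(rows, columns=["gene_id", "go_id"]).drop_duplicates()
        extra = extra.assign(
            go_term=extra["go_id"].map(dag.name),
            category=extra["go_id"].map(dag.category),
        )
        table = pd.concat([table, extra], ignore_index=True)
    return (
        table.drop_duplicates(subset=["gene_id", "go_id"])
        .sort_values(["gene_id", "go_id"])
        .reset_index(drop=True)
    )


def write_gene2go(table: pd.DataFrame, path) -> None:
    """Write the 8-column NCBI gene2go dialect (unused columns ``-``)."""
    out = pd.DataFrame(
        {
            "tax_id": "-",
            "GeneID": table["gene_id"],
            "GO_ID": table["go_id"],
            "Evidence": "-",
            "Qualifier": "-",
            "GO_term": table["go_term"],
            "PubMed": "-",
            "Category": table["category"],
        }
    )
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(GENE2GO_COLUMNS) + "\n")
        out.to_csv(fh, sep="\t", index=False, header=False)


def read_gene2go(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GENE2GO_COLUMNS, dtype=str
    )
    return (
        df[["GeneID", "GO_ID", "GO_term", "Category"]]
        .rename(
            columns={
                "GeneID": "gene_id",
                "GO_ID": "go_id",
                "GO_term": "go_term",
                "Category": "category",
            }
        )
        .reset_index(drop=True)
    )
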