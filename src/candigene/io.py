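"""Typed readers/writers and validation for the on-disk formats the pipeline touches.

Formats
-------
- phenotypes: comma-separated CSV, UTF-8, ``.`` decimal, first row header
- counts: featureCounts-style TSV (``#`` comment lines, then
  ``Geneid/Chr/Start/End/Strand/Length`` + one column per sample)
- ontology: OBO 1.2 ``[Term]`` stanzas (parsed with :mod:`obonet`; only
  ``is_a`` edges are retained)
- annotation: two-column TSV ``gene_id<TAB>go_term``, one pair per line
- reference: TSV with columns ``species/gene_name/function/go_terms``
  (GO terms semicolon-separated)
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger("candigene")

LATITUDES = ("high", "central")
TEMPERATURES = (20, 24)
PREDATOR_LEVELS = ("absent", "present")

#: design + trait columns of a phenotype table, in canonical order
PHENO_COLUMNS = [
    "individual_id", "pond_id", "maternal_line", "latitude", "temperature",
    "predator", "mass", "head_width", "wing_pad", "dev_time",
]
DERIVED_COLUMNS = ["grm", "grh"]

_PREDATOR_SYNONYMS = {"0": "absent", "1": "present", "absent": "absent", "present": "present"}
_LATITUDE_SYNONYMS = {"0": "high", "1": "central", "high": "high", "central": "central"}


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


class ValidationError(ValueError):
    """A parsed value violates a domain contract."""


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _normalize_category(series: pd.Series, mapping: dict, column: str) -> pd.Series:
    norm = series.astype(str).str.strip().str.lower()
    bad = ~norm.isin(mapping)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"column {column!r}: unrecognized value {series.iloc[row]!r} at row {row}"
        )
    return norm.map(mapping)


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate a phenotype/design CSV.

    Returns a DataFrame with the columns of :data:`PHENO_COLUMNS` (plus
    ``grm``/``grh`` when present), categorical values normalized, and
    ``dev_time`` as a positive integer.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "pond_id": str, "maternal_line": str})
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype file is missing required column(s): {', '.join(missing)}")
    return validate_phenotypes(df)


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("individual_id", "pond_id", "maternal_line"):
        df[col] = df[col].astype(str)
    if df["individual_id"].duplicated().any():
        dup = df["individual_id"][df["individual_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate individual_id {dup!r}")
    df["latitude"] = _normalize_category(df["latitude"], _LATITUDE_SYNONYMS, "latitude")
    df["predator"] = _normalize_category(df["predator"], _PREDATOR_SYNONYMS, "predator")
    temp = pd.to_numeric(df["temperature"], errors="coerce")
    if temp.isna().any() or not temp.isin(TEMPERATURES).all():
        row = int(np.flatnonzero(~temp.isin(TEMPERATURES).to_numpy())[0])
        raise ValidationError(f"column 'temperature': value {df['temperature'].iloc[row]!r} "
                              f"at row {row} not in {TEMPERATURES}")
    df["temperature"] = temp.astype(int)

    for col in ("mass", "head_width", "wing_pad"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~(vals > 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"column {col!r}: non-positive or missing value at row {row}")
        df[col] = vals.astype(float)

    dev = pd.to_numeric(df["dev_time"], errors="coerce")
    nonint = dev.isna() | (dev <= 0) | (dev != np.round(dev))
    if nonint.any():
        row = int(np.flatnonzero(nonint.to_numpy())[0])
        raise ValidationError(
            f"column 'dev_time': value {df['dev_time'].iloc[row]!r} at row {row} "
            "must be a positive integer (days)"
        )
    df["dev_time"] = dev.astype(int)

    derived_present = [c for c in DERIVED_COLUMNS if c in df.columns]
    if derived_present and len(derived_present) != len(DERIVED_COLUMNS):
        raise ValidationError("derived columns grm/grh must be all present or all absent")
    for col in derived_present:
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals < 0).any() or vals.isna().any():
            raise ValidationError(f"column {col!r}: negative or missing derived value")
        df[col] = vals.astype(float)
    order = PHENO_COLUMNS + derived_present
    return df[order].reset_index(drop=True)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    validate_phenotypes(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

@dataclass
class CountsMatrix:
    """Gene-level count matrix with per-gene chromosome labels.

    ``counts`` is a genes x samples DataFrame of nonnegative integers indexed
    by gene id; ``gene_chrom`` is a Series aligned to the same index.
    """

    counts: pd.DataFrame
    gene_chrom: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate Geneid {dup!r}")
        if pd.Index(self.counts.columns).duplicated().any():
            raise ValidationError("duplicate sample ids in counts matrix")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("counts must be nonnegative")
        self.gene_chrom = self.gene_chrom.reindex(self.counts.index)
        if self.gene_chrom.isna().any():
            raise ValidationError("every gene needs a chromosome label")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def read_counts(path) -> CountsMatrix:
    """Read a featureCounts-style TSV into a :class:`CountsMatrix`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Geneid": str, "Chr": str})
    required = ["Geneid", "Chr", "Start", "End", "Strand", "Length"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"counts file is missing column(s): {', '.join(missing)}")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise FormatError("counts file has no sample columns")
    counts = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    if counts.isna().any().any():
        raise ValidationError("non-numeric count entry")
    counts.index = pd.Index(df["Geneid"], name="Geneid")
    chrom = pd.Series(df["Chr"].to_numpy(), index=counts.index, name="Chr")
    if not np.all(counts.to_numpy() == np.floor(counts.to_numpy())):
        raise ValidationError("counts must be integers")
    return CountsMatrix(counts=counts.astype(np.int64), gene_chrom=chrom)


def write_counts(cm: CountsMatrix, path) -> None:
    """Write a featureCounts-style TSV (Start/End/Strand/Length are placeholders)."""
    n = cm.counts.shape[0]
    out = pd.DataFrame({
        "Geneid": cm.counts.index,
        "Chr": cm.gene_chrom.to_numpy(),
        "Start": np.arange(1, n + 1) * 1000,
        "End": np.arange(1, n + 1) * 1000 + 500,
        "Strand": "+",
        "Length": 500,
    })
    out = pd.concat([out.reset_index(drop=True), cm.counts.reset_index(drop=True)], axis=1)
    with open(path, "w") as fh:
        fh.write("# Program:featureCounts\n")
        out.to_csv(fh, sep="\t", index=False)


def exclude_chromosomes(cm: CountsMatrix, drop: set[str]) -> CountsMatrix:
    """Drop genes on the given chromosomes (e.g. the sex chromosome); unknown
    labels are a no-op; gene order is otherwise preserved."""
    keep = ~cm.gene_chrom.isin(set(drop))
    return CountsMatrix(counts=cm.counts.loc[keep.to_numpy()],
                        gene_chrom=cm.gene_chrom.loc[keep.to_numpy()])


# ---------------------------------------------------------------------------
# ontology / annotation / reference
# ---------------------------------------------------------------------------

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


@dataclass
class OntologyGraph:
    """GO term DAG restricted to ``is_a`` edges.

    ``graph`` stores one node per non-obsolete term and directed edges
    child -> parent; ``terms`` maps term id -> (name, namespace).
    """

    graph: nx.DiGraph
    terms: dict[str, tuple[str, str]] = field(default_factory=dict)

    def namespace_of(self, term: str) -> str:
        return self.terms[term][1]

    def ancestors(self, term: str) -> set[str]:
        """All ``is_a`` ancestors of ``term`` (term itself excluded)."""
        return nx.descendants(self.graph, term)

    def roots(self, namespace: str) -> list[str]:
        return [t for t in self.graph.nodes
                if self.terms[t][1] == namespace and self.graph.out_degree(t) == 0]


def read_ontology(path) -> OntologyGraph:
    """Parse an OBO file; keep is_a edges only, drop obsolete terms, demand a DAG."""
    multi = obonet.read_obo(path, ignore_obsolete=True)
    g = nx.DiGraph()
    terms: dict[str, tuple[str, str]] = {}
    for node, data in multi.nodes(data=True):
        terms[node] = (data.get("name", node), data.get("namespace", "biological_process"))
        g.add_node(node)
    for u, v, key in multi.edges(keys=True):
        if key == "is_a":
            if v not in terms:
                raise FormatError(f"is_a edge references unknown term {v!r}")
            g.add_edge(u, v)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise FormatError(f"ontology is_a graph contains a cycle: {cycle}")
    return OntologyGraph(graph=g, terms=terms)


def write_ontology(onto: OntologyGraph, path) -> None:
    buf = _io.StringIO()
    buf.write("format-version: 1.2\n")
    for term in sorted(onto.terms):
        name, namespace = onto.terms[term]
        buf.write(f"\n[Term]\nid: {term}\nname: {name}\nnamespace: {namespace}\n")
        for parent in sorted(onto.graph.successors(term)):
            buf.write(f"is_a: {parent} ! {onto.terms[parent][0]}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_annotation(path, onto: OntologyGraph | None = None) -> dict[str, set[str]]:
    """Read a two-column gene<TAB>GO-term TSV into gene -> term-set.

    Terms absent from ``onto`` (when given) are dropped with a logged warning.
    """
    ann: dict[str, set[str]] = {}
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"annotation line {lineno}: expected 2 tab-separated fields")
            gene, term = parts
            if onto is not None and term not in onto.terms:
                dropped += 1
                logger.warning("annotation: term %s (gene %s) absent from ontology; dropped",
                               term, gene)
                continue
            ann.setdefault(gene, set()).add(term)
    if dropped:
        logger.warning("annotation: dropped %d entries with unknown terms", dropped)
    return ann


def write_annotation(ann: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(ann):
            for term in sorted(ann[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_reference(path) -> pd.DataFrame:
    """Read a reference insect annotation table.

    Columns: species, gene_name, function, go_terms (semicolon-separated set).
    The go_terms column is parsed into frozensets; empty sets are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["species", "gene_name", "function", "go_terms"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"reference table is missing column(s): {', '.join(missing)}")
    sets = []
    for i, raw in enumerate(df["go_terms"]):
        if pd.isna(raw):
            raise ValidationError(f"reference row {i}: empty go_terms")
        terms = frozenset(t.strip() for t in str(raw).split(";") if t.strip())
        if not terms:
            raise ValidationError(f"reference row {i}: empty go_terms")
        sets.append(terms)
    out = df[["species", "gene_name", "function"]].copy()
    out["go_terms"] = sets
    return out


def write_reference(ref: pd.DataFrame, path) -> None:
    out = ref.copy()
    out["go_terms"] = [";".join(sorted(s)) for s in out["go_terms"]]
    out.to_csv(path, sep="\t", index=False)
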