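"""Knowledge structures for the knowledge-driven stream.

Three graphs feed the model:

* a gene co-expression graph ``G_gene`` from pairwise Pearson correlation of
  expression profiles,
* a perturbation-similarity graph ``G_pert`` from the Jaccard index of the
  genes' GO-style term sets, keeping each gene's top ``h_pert`` neighbours,
* a hierarchical pathway graph (Reactome-style, parsed from flat files) from
  which an additive attention mask is derived: gene pairs sharing a pathway
  at any level may attend to each other, all other pairs are suppressed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "FormatError",
    "PathwayHierarchy",
    "AttentionMask",
    "MASK_NEG",
    "pearson_corr",
    "build_coexpression_graph",
    "jaccard_index",
    "build_perturbation_graph",
    "parse_pathway_hierarchy",
    "pathways_of_gene",
    "genes_of_pathway",
    "build_attention_mask",
]

logger = logging.getLogger(__name__)

#: Additive-mask sentinel standing in for -inf.  Large enough that the
#: softmax underflows masked weights to exact zero in float64, finite enough
#: never to produce NaN gradients.
MASK_NEG = -1e9


class FormatError(ValueError):
    """Raised for malformed knowledge files."""


# --------------------------------------------------------------------------
# Pearson correlation and the co-expression graph
# --------------------------------------------------------------------------

def pearson_corr(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Returns 0.0 (with a logged warning) when either vector is constant,
    where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector in pearson_corr; returning 0.0")
        return 0.0
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def _corr_matrix(expression: np.ndarray) -> np.ndarray:
    """Gene-by-gene correlation with constant genes mapped to 0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(expression, rowvar=False)
    return np.nan_to_num(corr, nan=0.0)


def build_coexpression_graph(dataset, threshold: float = 0.4, use_cells: str = "all") -> nx.Graph:
    """Undirected gene graph with an edge wherever |r| >= threshold.

    `use_cells` selects the cells entering the correlation: "all" or
    "control".  Edge attribute ``weight`` carries the signed coefficient.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if use_cells == "all":
        expr = dataset.expression
    elif use_cells == "control":
        expr = dataset.expression[dataset.control_mask()]
    else:
        raise ValueError(f"unknown cell selector {use_cells!r}")
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 cells to correlate")
    corr = _corr_matrix(expr)
    g = nx.Graph()
    g.add_nodes_from(dataset.gene_names)
    names = dataset.gene_names
    iu, ju = np.triu_indices(len(names), k=1)
    keep = np.abs(corr[iu, ju]) >= threshold
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(names[i], names[j], weight=float(corr[i, j]))
    return g


# --------------------------------------------------------------------------
# GO Jaccard similarity and the perturbation graph
# --------------------------------------------------------------------------

def jaccard_index(set_u, set_v) -> float:
    """|intersection| / |union|; 0.0 when both sets are empty."""
    set_u, set_v = set(set_u), set(set_v)
    union = set_u | set_v
    if not union:
        return 0.0
    return len(set_u & set_v) / len(union)


def build_perturbation_graph(go_sets: dict, perturbable_genes: list, h_pert: int = 20) -> nx.DiGraph:
    """Directed graph linking each gene to its ``h_pert`` most similar peers.

    Similarity is the Jaccard index of the genes' term sets; zero-similarity
    neighbours are never added, so genes with empty term sets stay isolated.
    Ties at the cutoff are broken lexicographically by gene name.
    """
    if h_pert < 1:
        raise ValueError(f"h_pert must be >= 1, got {h_pert}")
    g = nx.DiGraph()
    g.add_nodes_from(perturbable_genes)
    for u in perturbable_genes:
        terms_u = go_sets.get(u, set())
        scored = []
        for v in perturbable_genes:
            if v == u:
                continue
            j = jaccard_index(terms_u, go_sets.get(v, set()))
            if j > 0:
                scored.append((-j, v))
        scored.sort()
        for neg_j, v in scored[:h_pert]:
            g.add_edge(u, v, weight=-neg_j)
    return g


# --------------------------------------------------------------------------
# Pathway hierarchy
# --------------------------------------------------------------------------

@dataclass
class PathwayHierarchy:
    """Multilevel directed pathway graph with gene memberships.

    ``graph`` holds pathway nodes (each with an integer ``level`` attribute)
    and parent->child edges running from higher to lower level.  Gene
    memberships attach genes to pathways (many-to-many).
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    memberships: dict = field(default_factory=dict)  # pathway -> set of genes

    def __post_init__(self):
        self._gene_direct: dict[str, set] = {}
        for pw, genes in self.memberships.items():
            for gene in genes:
                self._gene_direct.setdefault(gene, set()).add(pw)

    @property
    def pathways(self) -> set:
        return set(self.graph.nodes)

    def level_of(self, pathway) -> int:
        return self.graph.nodes[pathway]["level"]

    def annotated_genes(self) -> set:
        return set(self._gene_direct)

    def pathways_of_gene(self, gene) -> set:
        return pathways_of_gene(self, gene)

    def genes_of_pathway(self, pathway) -> set:
        return genes_of_pathway(self, pathway)


def parse_pathway_hierarchy(relations_path, memberships_path) -> PathwayHierarchy:
    """Parse a hierarchy from a relations TSV plus a memberships file.

    Relations TSV columns: ``parent_id  child_id  parent_level  child_level``
    (header row required).  A row with an empty parent declares ``child_id``
    as a root node without a parent edge.  Memberships are either a GMT file
    (set name = pathway id) or a two-column ``pathway  gene`` TSV.
    """
    graph = nx.DiGraph()
    relations_path = Path(relations_path)
    lines = relations_path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{relations_path}: empty relations file")
    header = lines[0].rstrip("\n").split("\t")
    expected = ["parent_id", "child_id", "parent_level", "child_level"]
    if header != expected:
        raise FormatError(f"{relations_path}: expected header {expected}, got {header}")
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{relations_path}:{ln}: expected 4 columns")
        parent, child, plevel, clevel = parts
        try:
            clevel = int(clevel)
        except ValueError as exc:
            raise FormatError(f"{relations_path}:{ln}: bad child level {parts[3]!r}") from exc
        if parent == "":
            _add_pathway(graph, child, clevel, relations_path, ln)
            continue
        try:
            plevel = int(plevel)
        except ValueError as exc:
            raise FormatError(f"{relations_path}:{ln}: bad parent level {plevel!r}") from exc
        if parent == child:
            raise FormatError(f"{relations_path}:{ln}: pathway {parent!r} is its own parent")
        if plevel <= clevel:
            raise FormatError(
                f"{relations_path}:{ln}: parent level {plevel} must exceed child level {clevel}"
            )
        _add_pathway(graph, parent, plevel, relations_path, ln)
        _add_pathway(graph, child, clevel, relations_path, ln)
        graph.add_edge(parent, child)
    if not nx.is_directed_acyclic_graph(graph):
        raise FormatError(f"{relations_path}: cyclic pathway relations")

    memberships = _parse_memberships(Path(memberships_path), set(graph.nodes))
    return PathwayHierarchy(graph=graph, memberships=memberships)


def _add_pathway(graph, pathway, level, path, ln):
    if pathway in graph.nodes and graph.nodes[pathway]["level"] != level:
        raise FormatError(f"{path}:{ln}: pathway {pathway!r} re-declared at a different level")
    graph.add_node(pathway, level=level)


def _parse_memberships(path: Path, declared: set) -> dict:
    memberships: dict[str, set] = {}
    is_gmt = path.suffix.lower() == ".gmt"
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if is_gmt:
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT rows need name, description, >=1 gene")
            pathway, genes = parts[0], parts[2:]
        else:
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 'pathway<TAB>gene'")
            pathway, genes = parts[0], [parts[1]]
        if pathway not in declared:
            raise FormatError(f"{path}:{ln}: membership references undeclared pathway {pathway!r}")
        memberships.setdefault(pathway, set()).update(g for g in genes if g)
    return memberships


def pathways_of_gene(h: PathwayHierarchy, gene) -> set:
    """Direct pathway memberships of `gene` plus all their ancestors."""
    direct = h._gene_direct.get(gene, set())
    result = set(direct)
    for pw in direct:
        result |= nx.ancestors(h.graph, pw)
    return result


def genes_of_pathway(h: PathwayHierarchy, pathway) -> set:
    """Genes of `pathway` and of every descendant sub-pathway."""
    if pathway not in h.graph.nodes:
        raise KeyError(f"unknown pathway {pathway!r}")
    nodes = {pathway} | nx.descendants(h.graph, pathway)
    genes: set = set()
    for pw in nodes:
        genes |= h.memberships.get(pw, set())
    return genes


# --------------------------------------------------------------------------
# Attention mask
# --------------------------------------------------------------------------

@dataclass
class AttentionMask:
    """Additive m x m mask: 0 where attention is permitted, MASK_NEG elsewhere."""

    matrix: np.ndarray
    gene_names: list

    def permitted(self) -> np.ndarray:
        return self.matrix == 0.0


def build_attention_mask(
    gene_names: list,
    hierarchy: PathwayHierarchy,
    dataset=None,
    fallback_threshold: float = 0.4,
    leaf_only: bool = False,
) -> AttentionMask:
    """Derive the pathway attention mask for `gene_names`.

    A pair may attend (entry 0) when both genes are annotated in the
    hierarchy and share at least one pathway — at any level by default, or
    only directly (leaf memberships) with ``leaf_only``.  For pairs with at
    least one unannotated gene the co-expression fallback applies: permitted
    iff |Pearson r| >= ``fallback_threshold`` in `dataset`.  The diagonal is
    always permitted and the mask is symmetric.
    """
    m = len(gene_names)
    if leaf_only:
        sets = [hierarchy._gene_direct.get(g, set()) for g in gene_names]
    else:
        sets = [pathways_of_gene(hierarchy, g) for g in gene_names]
    annotated = np.array([len(s) > 0 for s in sets])

    all_pathways = sorted({pw for s in sets for pw in s})
    pw_index = {pw: i for i, pw in enumerate(all_pathways)}
    incidence = np.zeros((m, max(len(all_pathways), 1)), dtype=bool)
    for i, s in enumerate(sets):
        for pw in s:
            incidence[i, pw_index[pw]] = True
    share = incidence @ incidence.T  # (m, m) boolean: >=1 shared pathway

    permitted = share & annotated[:, None] & annotated[None, :]

    needs_fallback = ~(annotated[:, None] & annotated[None, :])
    np.fill_diagonal(needs_fallback, False)
    if needs_fallback.any():
        if dataset is None:
            raise ValueError("dataset required for the co-expression fallback")
        if list(dataset.gene_names) != list(gene_names):
            raise ValueError("gene_names does not match dataset columns")
        corr = _corr_matrix(dataset.expression)
        permitted = permitted | (needs_fallback & (np.abs(corr) >= fallback_threshold))

    matrix = np.where(permitted, 0.0, MASK_NEG)
    np.fill_diagonal(matrix, 0.0)
    matrix = np.minimum(matrix, matrix.T)  # enforce symmetry
    return AttentionMask(matrix=matrix, gene_names=list(gene_names))
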