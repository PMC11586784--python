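"""Reading and writing the package's on-disk formats.

Expression data round-trips through AnnData-H5AD (condition labels in the
per-cell ``condition`` column) or MTX + ``genes.tsv`` + ``conditions.tsv``;
gene sets through GMT; the pathway hierarchy through a relations TSV plus a
memberships file; weighted graphs through edge-list TSVs.  Readers validate
rather than coerce: NaN or negative expression and missing labels are
errors, and zeros are preserved exactly (they are semantically meaningful
to the sparsity-preserving stream).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .data import DataError, PerturbDataset, parse_condition
from .graphs import FormatError, PathwayHierarchy, parse_pathway_hierarchy

__all__ = [
    "load_dataset",
    "write_h5ad",
    "write_mtx",
    "write_gmt",
    "load_gmt",
    "write_hierarchy",
    "write_edge_list",
    "load_edge_list",
    "load_config",
    "write_manifest",
]


# --------------------------------------------------------------- expression

def write_h5ad(dataset: PerturbDataset, path) -> None:
    adata = ad.AnnData(
        X=sparse.csr_matrix(dataset.expression),
        obs=pd.DataFrame(
            {"condition": dataset.condition_labels()},
            index=[f"cell{i}" for i in range(dataset.n_cells)],
        ),
        var=pd.DataFrame(index=dataset.gene_names),
    )
    adata.write_h5ad(Path(path))


def write_mtx(dataset: PerturbDataset, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(directory / "matrix.mtx", sparse.coo_matrix(dataset.expression))
    (directory / "genes.tsv").write_text("".join(f"{g}\n" for g in dataset.gene_names))
    (directory / "conditions.tsv").write_text(
        "".join(f"{c}\n" for c in dataset.condition_labels())
    )


def load_dataset(path) -> PerturbDataset:
    """Load a dataset from an .h5ad file or an MTX directory."""
    path = Path(path)
    if path.is_dir():
        return _load_mtx(path)
    if path.suffix == ".h5ad":
        return _load_h5ad(path)
    raise FormatError(f"unrecognized dataset path {path} (need .h5ad or MTX directory)")


def _load_h5ad(path: Path) -> PerturbDataset:
    adata = ad.read_h5ad(path)
    if "condition" not in adata.obs.columns:
        raise FormatError(f"{path}: missing per-cell 'condition' column")
    x = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X)
    return _validated(x, list(adata.obs["condition"]), list(adata.var_names), path)


def _load_mtx(directory: Path) -> PerturbDataset:
    matrix_path = directory / "matrix.mtx"
    for required in (matrix_path, directory / "genes.tsv", directory / "conditions.tsv"):
        if not required.exists():
            raise FormatError(f"missing {required}")
    x = np.asarray(spio.mmread(matrix_path).todense())
    genes = (directory / "genes.tsv").read_text().splitlines()
    conditions = (directory / "conditions.tsv").read_text().splitlines()
    return _validated(x, conditions, genes, directory)


def _validated(x, condition_labels, gene_names, origin) -> PerturbDataset:
    if np.isnan(x).any():
        raise DataError(f"{origin}: expression contains NaN")
    if (x < 0).any():
        raise DataError(f"{origin}: expression contains negative entries")
    labels = [parse_condition(c) for c in condition_labels]
    return PerturbDataset(expression=x, labels=labels, gene_names=gene_names)


# ---------------------------------------------------------------- gene sets

def write_gmt(sets: dict, path, description: str = "na") -> None:
    """Write name -> gene/term collection as GMT."""
    lines = []
    for name in sorted(sets):
        members = "\t".join(sorted(sets[name]))
        lines.append(f"{name}\t{description}\t{members}\n")
    Path(path).write_text("".join(lines))


def load_gmt(path) -> dict:
    out: dict[str, set] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: GMT rows need name, description, >=1 member")
        out[parts[0]] = {p for p in parts[2:] if p}
    return out


# ---------------------------------------------------------------- hierarchy

def write_hierarchy(h: PathwayHierarchy, relations_path, memberships_path) -> None:
    """Write the relations TSV (roots as parentless rows) and a memberships GMT."""
    lines = ["parent_id\tchild_id\tparent_level\tchild_level\n"]
    roots = [n for n in sorted(h.graph.nodes) if h.graph.in_degree(n) == 0]
    for node in roots:
        lines.append(f"\t{node}\t\t{h.level_of(node)}\n")
    for parent, child in sorted(h.graph.edges):
        lines.append(f"{parent}\t{child}\t{h.level_of(parent)}\t{h.level_of(child)}\n")
    Path(relations_path).write_text("".join(lines))
    write_gmt(h.memberships, memberships_path)


def load_hierarchy(relations_path, memberships_path) -> PathwayHierarchy:
    return parse_pathway_hierarchy(relations_path, memberships_path)


# ------------------------------------------------------------------- graphs

def write_edge_list(graph, path) -> None:
    lines = ["source\ttarget\tweight\n"]
    for u, v, data in sorted(graph.edges(data=True)):
        lines.append(f"{u}\t{v}\t{data.get('weight', 1.0):.10g}\n")
    Path(path).write_text("".join(lines))


def load_edge_list(path, directed: bool = False):
    g = nx.DiGraph() if directed else nx.Graph()
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["source", "target", "weight"]:
        raise FormatError(f"{path}: expected 'source\\ttarget\\tweight' header")
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{ln}: expected 3 columns")
        g.add_edge(parts[0], parts[1], weight=float(parts[2]))
    return g


# ------------------------------------------------------------ config/manifest

def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return config


def write_manifest(output_dir, config: dict, seeds: dict) -> Path:
    """Record everything needed to reproduce a run."""
    from . import __version__

    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    canonical = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package_version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seeds": seeds,
    }
    path = output_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path
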