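"""Readers and writers for every on-disk format the pipeline touches.

All text outputs begin with a header comment carrying the tool version
and a short hash of the run configuration, so any file can be traced to
the settings that produced it.  Readers skip those comments and
round-trip losslessly within float text precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from psdnet.quantify import AbundanceTensor

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "write_abundance",
    "read_abundance",
    "write_edges",
    "read_edges",
    "write_connectome",
    "read_connectome",
    "write_obo",
    "read_obo",
    "write_annotations",
    "read_annotations",
    "write_json",
    "read_json",
    "write_gexf",
    "write_circos",
    "write_newick",
]

_FLOAT_FMT = "%.10g"


def config_hash(config) -> str:
    """Short stable hash of a configuration mapping or dataclass."""
    if hasattr(config, "__dataclass_fields__"):
        import dataclasses

        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:10]


def _header(cfg_hash: str) -> str:
    from psdnet import __version__

    return f"# psdnet v{__version__} config={cfg_hash}\n"


def write_table(df: pd.DataFrame, path, cfg_hash: str = "na", sep: str = "\t", index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash))
        df.to_csv(fh, sep=sep, index=index, float_format=_FLOAT_FMT)


def read_table(path, sep: str = "\t", index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


def write_abundance(tensor: AbundanceTensor, path, cfg_hash: str = "na") -> None:
    """Wide abundance TSV: protein_id, n_unique_peptides, <REGION>_<k> columns."""
    write_table(tensor.to_frame(), path, cfg_hash)


def read_abundance(path) -> AbundanceTensor:
    """Load and validate an abundance TSV.

    Duplicate protein ids and non-positive intensities are rejected with
    a message naming the offending protein/cell.
    """
    df = read_table(path)
    return AbundanceTensor.from_frame(df)


def write_edges(edges: pd.DataFrame, path, cfg_hash: str = "na") -> None:
    write_table(edges, path, cfg_hash)


def read_edges(path) -> pd.DataFrame:
    df = read_table(path)
    if df.shape[1] < 2:
        raise ValueError("edge list must have two protein-id columns")
    return df


def write_connectome(matrix: pd.DataFrame, path, cfg_hash: str = "na") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash))
        matrix.to_csv(fh, float_format=_FLOAT_FMT)


def read_connectome(path) -> pd.DataFrame:
    m = pd.read_csv(path, comment="#", index_col=0)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"connectome matrix must be square, got {m.shape}")
    return m


def write_obo(dag, path, cfg_hash: str = "na") -> None:
    """Minimal OBO subset: [Term] stanzas with id / name / is_a."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["format-version: 1.2", f"remark: psdnet config={cfg_hash}", ""]
    for term in sorted(dag.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {dag.terms[term]}")
        for parent in sorted(dag.parents.get(term, [])):
            lines.append(f"is_a: {parent} ! {dag.terms[parent]}")
        lines.append("")
    path.write_text("\n".join(lines))


def read_obo(path):
    """Load an OBO file (via obonet) into an :class:`OntologyDAG`."""
    import obonet

    from psdnet.enrichment import OntologyDAG

    graph = obonet.read_obo(path)
    terms = {t: data.get("name", "") for t, data in graph.nodes(data=True)}
    parents: dict[str, list] = {t: [] for t in terms}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].append(parent)
    return OntologyDAG(terms=terms, parents=parents)


def write_annotations(annotations: dict[str, set], path, cfg_hash: str = "na") -> None:
    """Two-column TSV of direct protein -> term annotations."""
    rows = [
        {"protein_id": p, "term_id": t}
        for p in sorted(annotations)
        for t in sorted(annotations[p])
    ]
    write_table(pd.DataFrame(rows, columns=["protein_id", "term_id"]), path, cfg_hash)


def read_annotations(path) -> dict[str, set]:
    df = read_table(path)
    out: dict[str, set] = {}
    for p, t in df[["protein_id", "term_id"]].itertuples(index=False):
        out.setdefault(str(p), set()).add(str(t))
    return out


def write_json(obj, path, cfg_hash: str = "na") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    from psdnet import __version__

    payload = {"_meta": {"version": __version__, "config_hash": cfg_hash}, **obj}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_gexf(graph: nx.Graph, path, partition=None, regional_weights=None) -> None:
    """GEXF export; community ids attached as a node attribute if given.

    ``regional_weights`` maps region name -> weighted graph with the
    same topology; each region's weight is stored as an edge attribute
    ``weight_<region>``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = graph.copy()
    if partition is not None:
        nx.set_node_attributes(g, partition.membership, "community")
    if regional_weights is not None:
        for region, h in regional_weights.items():
            nx.set_edge_attributes(
                g,
                {(a, b): w for a, b, w in h.edges(data="weight")},
                f"weight_{region}",
            )
    nx.write_gexf(g, path)


def write_circos(links: pd.DataFrame, regions: list[str], path_prefix, cfg_hash: str = "na") -> None:
    """Circos karyotype + link files for a module link table.

    ``<prefix>.karyotype.txt`` holds one ``chr`` line per region scaled
    to 1000 units; ``<prefix>.links.txt`` holds one line per link with
    span proportional to its width.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.karyotype.txt", "w") as fh:
        fh.write(_header(cfg_hash))
        for i, region in enumerate(regions):
            fh.write(f"chr - {region} {region} 0 1000 chr{i + 1}\n")
    with open(f"{prefix}.links.txt", "w") as fh:
        fh.write(_header(cfg_hash))
        for _, row in links.iterrows():
            span = max(1, int(round(1000 * row["width"])))
            fh.write(
                f"{row['region_a']} 0 {span} {row['region_b']} 0 {span} "
                f"color=module{int(row['module'])}\n"
            )


def write_newick(newick: str, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(newick + "\n")
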