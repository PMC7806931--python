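"""Readers and writers for the pipeline's table dialects.

All tables are plain TSV/CSV.  Output files start with a comment header
recording the tool version, the resolved seed and a hash of the resolved
configuration, so any artifact can be traced to the run that produced
it; readers skip ``#`` comment lines.  Gene symbols are standardized on
input (whitespace-trimmed, upper-cased) and duplicate gene rows are
merged with label union.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .containers import NO_LABEL, GeneUniverse, Layer, Partition
from .ontology import validate_ontology

log = logging.getLogger("comorbnet")

GENES_FILE = "genes.tsv"
PPI_FILE = "ppi_edges.tsv"
ONTOLOGY_FILE = "ontology.tsv"
SCORES_FILE = "scores.tsv"

# preference order when duplicate rows disagree: keep the stronger label
_EPI_ORDER = {"1": 0, "2": 1, "3": 2, "4": 3, NO_LABEL: 9}
_AUT_ORDER = {"1": 0, "2": 1, "3": 2, "S": 3, NO_LABEL: 9}


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(seed: int | None, cfg_hash: str | None) -> str:
    parts = [f"# comorbnet version={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config_hash={cfg_hash}")
    return " ".join(parts) + "\n"


def write_table(
    df: pd.DataFrame,
    path: Path | str,
    seed: int | None = None,
    cfg_hash: str | None = None,
    sep: str = "\t",
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(seed, cfg_hash))
        df.to_csv(fh, sep=sep, index=False)


def read_table(path: Path | str, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def _standardize(symbol: str) -> str:
    return str(symbol).strip().upper()


def read_gene_table(path: Path | str) -> GeneUniverse:
    """Read the gene list with subgroup labels and auxiliary flags.

    Symbols are trimmed and upper-cased; duplicate rows are merged with
    label union (the stronger subgroup label wins; conflicts are logged).
    """
    path = Path(path)
    df = read_table(path)
    _require_columns(df, ["gene", "epilepsy_subgroup", "autism_subgroup"], path)
    df = df.copy()
    df["gene"] = df["gene"].map(_standardize)

    aux_cols = [
        c
        for c in df.columns
        if c not in ("gene", "epilepsy_subgroup", "autism_subgroup", "planted_module")
    ]
    genes: list[str] = []
    epi: dict[str, str] = {}
    aut: dict[str, str] = {}
    aux: dict[str, set[str]] = {c: set() for c in aux_cols}
    planted: dict[str, int] = {}
    has_planted = "planted_module" in df.columns

    for _, row in df.iterrows():
        g = row["gene"]
        e = str(row["epilepsy_subgroup"])
        a = str(row["autism_subgroup"])
        if e not in _EPI_ORDER:
            raise ValueError(f"{path}: bad epilepsy_subgroup {e!r} for gene {g}")
        if a not in _AUT_ORDER:
            raise ValueError(f"{path}: bad autism_subgroup {a!r} for gene {g}")
        if g not in epi:
            genes.append(g)
            epi[g], aut[g] = e, a
        else:
            if e != epi[g] and NO_LABEL not in (e, epi[g]):
                log.warning("conflicting epilepsy subgroup for %s: %s vs %s", g, epi[g], e)
            if a != aut[g] and NO_LABEL not in (a, aut[g]):
                log.warning("conflicting autism subgroup for %s: %s vs %s", g, aut[g], a)
            epi[g] = min(epi[g], e, key=_EPI_ORDER.get)
            aut[g] = min(aut[g], a, key=_AUT_ORDER.get)
        for c in aux_cols:
            if int(row[c]) == 1:
                aux[c].add(g)
        if has_planted:
            planted[g] = int(row["planted_module"])

    return GeneUniverse(
        tuple(genes),
        epi,
        aut,
        {c: frozenset(s) for c, s in aux.items()},
        planted if has_planted else None,
    )


def read_ppi_table(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    df = read_table(path)
    _require_columns(df, ["gene_a", "gene_b", "combined_score"], path)
    df = df.copy()
    df["gene_a"] = df["gene_a"].map(_standardize)
    df["gene_b"] = df["gene_b"].map(_standardize)
    return df


def read_ontology_table(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    df = read_table(path)
    _require_columns(df, ["term_id", "parent_id"], path)
    validate_ontology(df)
    return df


def read_score_table(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    df = read_table(path)
    _require_columns(df, ["term_id", "gene", "score", "skew"], path)
    df = df.copy()
    df["gene"] = df["gene"].map(_standardize)
    if df.duplicated(subset=["term_id", "gene"]).any():
        raise ValueError(f"{path}: duplicate (term_id, gene) rows")
    per_term_skew = df.groupby("term_id")["skew"].nunique()
    if (per_term_skew > 1).any():
        bad = per_term_skew[per_term_skew > 1].index[0]
        raise ValueError(f"{path}: term {bad!r} has inconsistent skew values")
    if (df["score"].astype(float) < 0).any():
        raise ValueError(f"{path}: negative scores")
    return df


def read_tables(directory: Path | str):
    """Read a full input bundle (genes, PPI edges, ontology, scores)."""
    directory = Path(directory)
    return (
        read_gene_table(directory / GENES_FILE),
        read_ppi_table(directory / PPI_FILE),
        read_ontology_table(directory / ONTOLOGY_FILE),
        read_score_table(directory / SCORES_FILE),
    )


def write_bundle(
    bundle,
    directory: Path | str,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    """Write a simulated input bundle as the four TSV dialects."""
    directory = Path(directory)
    if seed is None:
        seed = bundle.config.seed
    if cfg_hash is None:
        cfg_hash = config_hash(bundle.config.__dict__)
    write_table(bundle.universe.to_frame(), directory / GENES_FILE, seed, cfg_hash)
    write_table(bundle.ppi_edges, directory / PPI_FILE, seed, cfg_hash)
    write_table(bundle.ontology, directory / ONTOLOGY_FILE, seed, cfg_hash)
    write_table(bundle.scores, directory / SCORES_FILE, seed, cfg_hash)


def layer_frame(layer: Layer) -> pd.DataFrame:
    edges = sorted(layer.edges)
    return pd.DataFrame(edges, columns=["gene_a", "gene_b"])


def write_layer(
    layer: Layer, path: Path | str, seed: int | None = None, cfg_hash: str | None = None
) -> None:
    write_table(layer_frame(layer), path, seed, cfg_hash)


def read_layer(path: Path | str, nodes, name: str) -> Layer:
    df = read_table(path)
    _require_columns(df, ["gene_a", "gene_b"], Path(path))
    return Layer.from_edges(name, nodes, zip(df["gene_a"], df["gene_b"]))


def write_graphml(layer: Layer, path: Path | str) -> None:
    import networkx as nx

    nx.write_graphml(layer.to_networkx(), str(path))


def partition_frame(partition: Partition) -> pd.DataFrame:
    rows = sorted(partition.assignment.items())
    return pd.DataFrame(rows, columns=["gene", "module_id"])


def write_partition(
    partition: Partition,
    path: Path | str,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    write_table(partition_frame(partition), path, seed, cfg_hash)


def read_partition(path: Path | str) -> Partition:
    df = read_table(path)
    _require_columns(df, ["gene", "module_id"], Path(path))
    return Partition(dict(zip(df["gene"], df["module_id"].astype(int))))


def write_json(obj: dict, path: Path | str, seed: int | None = None, cfg_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"comorbnet_version": __version__}
    if seed is not None:
        payload["seed"] = seed
    if cfg_hash is not None:
        payload["config_hash"] = cfg_hash
    payload.update(obj)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
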