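"""Readers and writers for the pipeline's plain-text formats.

Expression matrices are tab-delimited with features in rows and a header row
of sample identifiers.  Clinical tables are one row per sample with named
columns.  Target maps are two-column ``mirna<TAB>gene`` pair lists.  Gene
sets use the GMT convention (set name, description, then member genes).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .preprocessing import TargetMap


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature")


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    return df


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_target_map(path: str | Path, universe: Iterable[str] | None = None) -> TargetMap:
    """Read ``mirna<TAB>gene`` pairs; the universe defaults to the genes seen."""
    pairs = pd.read_csv(path, sep="\t", header=None, names=["mirna", "gene"], dtype=str)
    targets: dict[str, set[str]] = {}
    for mirna, gene in pairs.itertuples(index=False):
        targets.setdefault(mirna, set()).add(gene)
    if universe is None:
        universe = set(pairs["gene"])
    return TargetMap(
        targets={m: frozenset(g) for m, g in targets.items()},
        universe=frozenset(universe),
    )


def write_target_map(targets: TargetMap, path: str | Path) -> None:
    targets.to_pairs().to_csv(path, sep="\t", header=False, index=False)


def read_partition(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(df["module"].to_numpy(), index=df["gene"], name="module")


def write_partition(partition: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"gene": partition.index, "module": partition.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line has fewer than 3 fields: {line!r}")
        sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, *,
              description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(set(genes))])
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read ``nodeA<TAB>nodeB[<TAB>confidence]`` into an undirected graph."""
    graph = nx.Graph()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"edge line has fewer than 2 fields: {line!r}")
        a, b = fields[0], fields[1]
        if a == b:
            continue  # simple graph: drop self-loops
        if len(fields) >= 3:
            graph.add_edge(a, b, confidence=float(fields[2]))
        else:
            graph.add_edge(a, b)
    return graph


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
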