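"""Readers, writers and core tabular containers.

Every artifact the screen touches — count matrices, sample/group maps, miRNA
target tables, pathway gene sets (GMT) with optional per-gene effect signs,
and network exports (SIF / GraphML / edge table) — goes through this module so
each pipeline stage is testable from plain-text files.  All formats are
tab-separated UTF-8 without quoting; derived outputs are written in
deterministic (lexicographic) order so identical inputs produce byte-identical
files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError

__all__ = [
    "ExpressionMatrix",
    "TargetTable",
    "PathwayCatalog",
    "read_counts",
    "write_counts",
    "read_groups",
    "write_groups",
    "read_targets",
    "write_targets",
    "read_gmt",
    "write_gmt",
    "read_signs",
    "write_signs",
    "write_network",
    "read_network",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Non-negative integer counts, features x samples, with a group per sample.

    Parameters
    ----------
    counts
        DataFrame indexed by feature id with one column per sample id.
    groups
        Mapping sample id -> group label; must cover every sample exactly.
    """

    counts: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise DataError(f"duplicate feature id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise DataError(f"duplicate sample id: {dup!r}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise DataError("counts must be numeric")
        if values.size:
            if not np.isfinite(values).all():
                r, c = np.argwhere(~np.isfinite(values))[0]
                raise DataError(
                    f"non-finite count at feature {idx[r]!r}, sample {cols[c]!r}"
                )
            if (values < 0).any():
                r, c = np.argwhere(values < 0)[0]
                raise DataError(
                    f"negative count at feature {idx[r]!r}, sample {cols[c]!r}"
                )
            if not np.array_equal(values, np.round(values)):
                r, c = np.argwhere(values != np.round(values))[0]
                raise DataError(
                    f"non-integer count at feature {idx[r]!r}, sample {cols[c]!r}"
                )
        missing = [s for s in cols if s not in self.groups]
        if missing:
            raise DataError(f"sample missing from group map: {missing[0]!r}")
        self.counts = self.counts.astype(np.int64)
        # keep only groups for present samples, in column order
        self.groups = {s: self.groups[s] for s in cols}

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def group_labels(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.groups.values():
            seen.setdefault(g)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def subset_groups(self, labels: Iterable[str]) -> "ExpressionMatrix":
        labels = list(labels)
        for lab in labels:
            if lab not in set(self.groups.values()):
                raise DataError(f"unknown group: {lab!r}")
        keep = [s for s in self.sample_ids if self.groups[s] in labels]
        return ExpressionMatrix(self.counts[keep].copy(), {s: self.groups[s] for s in keep})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.groups == other.groups


@dataclass
class TargetTable:
    """Predicted miRNA->gene pairs with a binding confidence score in [0, 1].

    Duplicate (mirna, gene) rows are collapsed keeping the maximum score — the
    most permissive choice with respect to a strict ``score > threshold``
    filter downstream.
    """

    records: pd.DataFrame  # columns: mirna_id, gene_id, binding_score

    COLUMNS = ("mirna_id", "gene_id", "binding_score")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"target table missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        scores = pd.to_numeric(df["binding_score"], errors="coerce")
        if scores.isna().any():
            bad = df.loc[scores.isna()].iloc[0]
            raise DataError(
                f"non-numeric binding score for ({bad['mirna_id']!r}, {bad['gene_id']!r})"
            )
        df["binding_score"] = scores.astype(float)
        out_of_range = (df["binding_score"] < 0) | (df["binding_score"] > 1)
        if out_of_range.any():
            bad = df.loc[out_of_range].iloc[0]
            raise DataError(
                f"binding score outside [0, 1] for ({bad['mirna_id']!r}, "
                f"{bad['gene_id']!r}): {bad['binding_score']}"
            )
        df = (
            df.groupby(["mirna_id", "gene_id"], as_index=False, sort=True)["binding_score"]
            .max()
        )
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def mirna_ids(self) -> set[str]:
        return set(self.records["mirna_id"])

    @property
    def gene_ids(self) -> set[str]:
        return set(self.records["gene_id"])

    def targets_of(self, mirna_id: str) -> set[str]:
        rec = self.records
        return set(rec.loc[rec["mirna_id"] == mirna_id, "gene_id"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TargetTable):
            return NotImplemented
        return self.records.equals(other.records)


@dataclass
class PathwayCatalog:
    """Gene sets with optional per-gene expected effect signs.

    ``signs[pathway][gene]`` is +1 when the gene's up-regulation indicates
    increased pathway activity and -1 when its down-regulation does; sign map
    keys must be members of the gene set.  Pathways without a sign map yield
    an "unknown" activity call downstream.
    """

    sets: dict[str, frozenset[str]]
    signs: dict[str, dict[str, int]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.sets.items():
            if not genes:
                raise DataError(f"empty gene set: {pid!r}")
            self.sets[pid] = frozenset(genes)
        for pid, smap in self.signs.items():
            if pid not in self.sets:
                raise DataError(f"sign annotation for unknown pathway: {pid!r}")
            stray = set(smap) - self.sets[pid]
            if stray:
                raise DataError(
                    f"sign for gene not in pathway {pid!r}: {sorted(stray)[0]!r}"
                )
            for gene, sign in smap.items():
                if sign not in (1, -1):
                    raise DataError(
                        f"sign must be +1 or -1 for ({pid!r}, {gene!r}): {sign}"
                    )

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.sets)

    def genes(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayCatalog):
            return NotImplemented
        return (
            self.sets == other.sets
            and self.signs == other.signs
            and self.descriptions == other.descriptions
        )


# ---------------------------------------------------------------------------
# Count matrices and group maps
# ---------------------------------------------------------------------------


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> group TSV (header row optional)."""
    groups: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and parts == ["sample", "group"]:
                continue
            sample, group = parts
            if sample in groups:
                raise DataError(f"{path}: duplicate sample in group map: {sample!r}")
            groups[sample] = group
    if not groups:
        raise DataError(f"{path}: empty group map")
    return groups


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def read_counts(path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read a TSV count matrix (first column feature id, header of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"{path}: non-numeric count at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    groups = read_groups(groups_path)
    return ExpressionMatrix(numeric, groups)


def write_counts(
    matrix: ExpressionMatrix,
    path: str | Path,
    groups_path: str | Path | None = None,
) -> None:
    """Write a count matrix (and optionally its group map) as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in zip(matrix.feature_ids, matrix.counts.to_numpy()):
            fh.write(fid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    if groups_path is not None:
        write_groups(matrix.groups, groups_path)


# ---------------------------------------------------------------------------
# Target tables
# ---------------------------------------------------------------------------


def read_targets(path: str | Path) -> TargetTable:
    """Read a three-column miRNA / gene / binding-score TSV (with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str})
    return TargetTable(df)


def write_targets(table: TargetTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tgene_id\tbinding_score\n")
        for row in table.records.itertuples(index=False):
            fh.write(f"{row.mirna_id}\t{row.gene_id}\t{row.binding_score:.6g}\n")


# ---------------------------------------------------------------------------
# Pathway catalogs (GMT + sign annotations)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, signs_path: str | Path | None = None) -> PathwayCatalog:
    """Read a standard GMT file (name, description, tab-separated genes).

    Gene lists are deduplicated preserving first appearance.  An optional
    three-column sign file (pathway, gene, +1/-1) attaches effect directions.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(
                    f"{path}: line {lineno}: GMT needs name, description and >=1 gene"
                )
            name, desc = parts[0], parts[1]
            if name in sets:
                raise DataError(f"{path}: duplicate pathway id: {name!r}")
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise DataError(f"{path}: line {lineno}: empty gene set for {name!r}")
            sets[name] = frozenset(genes)
            descriptions[name] = desc
    signs = read_signs(signs_path) if signs_path is not None else {}
    return PathwayCatalog(sets=sets, signs=signs, descriptions=descriptions)


def write_gmt(catalog: PathwayCatalog, path: str | Path,
              signs_path: str | Path | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(catalog.sets):
            desc = catalog.descriptions.get(pid, "")
            genes = "\t".join(sorted(catalog.sets[pid]))
            fh.write(f"{pid}\t{desc}\t{genes}\n")
    if signs_path is not None:
        write_signs(catalog.signs, signs_path)


def read_signs(path: str | Path) -> dict[str, dict[str, int]]:
    """Read a (pathway, gene, sign) TSV; sign must be +1 or -1."""
    signs: dict[str, dict[str, int]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise DataError(f"{path}: line {lineno}: expected 3 columns")
            if lineno == 1 and parts == ["pathway_id", "gene_id", "sign"]:
                continue
            pid, gene, raw = parts
            try:
                sign = int(raw)
            except ValueError:
                raise DataError(f"{path}: line {lineno}: bad sign {raw!r}") from None
            if sign not in (1, -1):
                raise DataError(f"{path}: line {lineno}: sign must be +1 or -1")
            signs.setdefault(pid, {})[gene] = sign
    return signs


def write_signs(signs: Mapping[str, Mapping[str, int]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pathway_id\tgene_id\tsign\n")
        for pid in sorted(signs):
            for gene in sorted(signs[pid]):
                fh.write(f"{pid}\t{gene}\t{signs[pid][gene]:+d}\n")


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

#: SIF relation label by (source node type, target node type)
_RELATIONS = {
    ("mirna", "gene"): "targets",
    ("gene", "pathway"): "member_of",
    ("mirna", "pathway"): "regulates",
}

NETWORK_FORMATS = ("sif", "graphml", "edge-table")


def _relation(graph: nx.Graph, u: str, v: str) -> tuple[str, str, str]:
    """Orient an edge by node types and return (source, relation, target)."""
    tu = graph.nodes[u].get("type")
    tv = graph.nodes[v].get("type")
    if (tu, tv) in _RELATIONS:
        return u, _RELATIONS[(tu, tv)], v
    if (tv, tu) in _RELATIONS:
        return v, _RELATIONS[(tv, tu)], u
    raise DataError(f"no relation defined between node types {tu!r} and {tv!r}")


def _sorted_edges(graph: nx.Graph) -> list[tuple[str, str, str, dict]]:
    rows = []
    for u, v, attrs in graph.edges(data=True):
        s, rel, t = _relation(graph, u, v)
        rows.append((s, rel, t, attrs))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    return rows


def write_network(network: nx.Graph, path: str | Path, format: str = "sif") -> None:
    """Write a typed network as SIF, GraphML or a flat edge table.

    Nodes must carry a ``type`` attribute in {mirna, gene, pathway}; SIF
    relations are derived from the type pair (targets / member_of /
    regulates).  Node and edge ordering is lexicographic so output is
    byte-stable.
    """
    if format not in NETWORK_FORMATS:
        raise ConfigError(
            f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}"
        )
    if format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for s, rel, t, _ in _sorted_edges(network):
                fh.write(f"{s}\t{rel}\t{t}\n")
        return
    if format == "edge-table":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\trelation\ttarget\tcount_score\n")
            for s, rel, t, attrs in _sorted_edges(network):
                cs = attrs.get("count_score", "")
                fh.write(f"{s}\t{rel}\t{t}\t{cs}\n")
        return
    # GraphML: rebuild with sorted nodes/edges and None attributes dropped
    # (GraphML has no null), preserving everything else.
    out: nx.Graph = network.__class__()
    for node in sorted(network.nodes):
        attrs = {k: v for k, v in network.nodes[node].items() if v is not None}
        out.add_node(node, **attrs)
    for u, v, attrs in sorted(network.edges(data=True), key=lambda e: (e[0], e[1])):
        out.add_edge(u, v, **{k: w for k, w in attrs.items() if w is not None})
    nx.write_graphml(out, path, named_key_ids=True, edge_id_from_attribute=None)


def read_network(path: str | Path) -> nx.Graph:
    """Read a GraphML network written by :func:`write_network`."""
    return nx.read_graphml(path)
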