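"""Reading and writing ward tables, adjacency structures and result tables.

Formats are deliberately plain: comma-separated ward tables with a header,
adjacency as either a two-column edge list or the GAL neighbour-block
dialect used by spatial-weights tooling, and CSV/JSON effect tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .graph import GraphError, WardGraph

__all__ = [
    "WardRecord",
    "WardDataset",
    "read_ward_table",
    "write_ward_table",
    "read_adjacency",
    "write_adjacency",
    "write_effect_table",
    "write_ward_classification",
]

REQUIRED_COLUMNS = ("ward_id", "count", "population")


class SchemaError(ValueError):
    """A required column is missing or the schema map is inconsistent."""


class ValidationError(ValueError):
    """Row-level constraint violated (negative count, duplicate id, ...)."""


@dataclass(frozen=True)
class WardRecord:
    """One areal unit: events over the study window, population, covariates."""

    ward_id: str
    count: int
    population: int
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.count < 0:
            raise ValidationError(f"ward {self.ward_id!r}: count must be >= 0")
        if self.population < 1:
            raise ValidationError(f"ward {self.ward_id!r}: population must be >= 1")
        if "over50_pct" in self.covariates:
            v = self.covariates["over50_pct"]
            if not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"ward {self.ward_id!r}: over50_pct = {v} outside [0, 100]"
                )


@dataclass(frozen=True)
class WardDataset:
    """Ordered collection of ward records; order is the canonical unit index."""

    records: tuple[WardRecord, ...]

    def __post_init__(self):
        ids = [r.ward_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate ward_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ward_ids(self) -> tuple[str, ...]:
        return tuple(r.ward_id for r in self.records)

    @property
    def counts(self) -> np.ndarray:
        return np.array([r.count for r in self.records], dtype=int)

    @property
    def populations(self) -> np.ndarray:
        return np.array([r.population for r in self.records], dtype=int)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for r in self.records:
            for k in r.covariates:
                if k not in names:
                    names.append(k)
        return tuple(names)

    def covariate_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [r.covariates for r in self.records], index=list(self.ward_ids)
        )

    def covariate(self, name: str) -> np.ndarray:
        try:
            return np.array([r.covariates[name] for r in self.records], dtype=float)
        except KeyError:
            raise KeyError(f"covariate {name!r} not present in dataset") from None


def read_ward_table(path, schema: Mapping[str, str] | None = None) -> WardDataset:
    """Read a delimited ward table (CSV with header) into a :class:`WardDataset`.

    ``schema`` optionally maps the canonical required names (``ward_id``,
    ``count``, ``population``) to the column names actually present.  Every
    remaining column is carried as a covariate.
    """
    schema = dict(schema or {})
    colmap = {name: schema.get(name, name) for name in REQUIRED_COLUMNS}
    df = pd.read_csv(path, float_precision="round_trip")
    for canonical, col in colmap.items():
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} (for {canonical!r}) missing")
    covariate_cols = [c for c in df.columns if c not in set(colmap.values())]
    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        ward_id = str(row[colmap["ward_id"]])
        try:
            count = int(row[colmap["count"]])
            population = int(row[colmap["population"]])
        except (TypeError, ValueError):
            raise ValidationError(f"row {pos}: non-integer count/population") from None
        covs = {}
        for c in covariate_cols:
            try:
                covs[c] = float(row[c])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"row {pos}: covariate column {c!r} is not numeric"
                ) from None
        try:
            records.append(
                WardRecord(ward_id=ward_id, count=count, population=population, covariates=covs)
            )
        except ValidationError as err:
            raise ValidationError(f"row {pos}: {err}") from None
    return WardDataset(tuple(records))


def write_ward_table(dataset: WardDataset, path) -> None:
    """Write a ward table readable back by :func:`read_ward_table`."""
    covs = dataset.covariate_names
    rows = []
    for r in dataset.records:
        row = {"ward_id": r.ward_id, "count": r.count, "population": r.population}
        row.update({c: r.covariates.get(c, np.nan) for c in covs})
        rows.append(row)
    # %.17g keeps the read-write round trip exact for doubles
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# adjacency


def read_adjacency(path, dialect: str = "edge-list", nodes: Sequence[str] | None = None) -> WardGraph:
    """Read an adjacency structure.

    dialects:
      * ``edge-list`` — one ``id_a id_b`` pair per whitespace-separated line;
        blank lines and ``#`` comments ignored.
      * ``gal`` — header line with the node count (a bare integer, or the
        second field of a 4-field GAL header), then per node a ``id degree``
        line followed by a line of neighbour ids.

    If ``nodes`` is given it fixes the node set and order; edges referencing
    ids outside it raise.  Otherwise the node order is first-appearance order
    (edge list) or header-block order (GAL).
    """
    text = Path(path).read_text(encoding="utf-8")
    if dialect == "edge-list":
        return _parse_edge_list(text, nodes)
    if dialect == "gal":
        return _parse_gal(text, nodes)
    raise ValueError(f"unknown adjacency dialect {dialect!r}")


def _parse_edge_list(text: str, nodes) -> WardGraph:
    known = list(nodes) if nodes is not None else None
    order: list[str] = list(known) if known else []
    seen = set(order)
    edges = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphError(f"line {lineno}: expected 'id_a id_b', got {line!r}")
        a, b = parts
        if a == b:
            raise GraphError(f"line {lineno}: self-loop on {a!r}")
        for nid in (a, b):
            if known is not None and nid not in seen:
                raise GraphError(f"line {lineno}: unknown node {nid!r}")
            if nid not in seen:
                seen.add(nid)
                order.append(nid)
        edges.append((a, b))
    if not order:
        raise GraphError("empty edge list and no node list supplied")
    return WardGraph(tuple(order), tuple(edges))


def _parse_gal(text: str, nodes) -> WardGraph:
    lines = [ln for ln in (l.strip() for l in text.splitlines())]
    # drop leading blank/comment lines
    idx = 0
    while idx < len(lines) and (not lines[idx] or lines[idx].startswith("#")):
        idx += 1
    if idx >= len(lines):
        raise GraphError("empty GAL file")
    header = lines[idx].split()
    idx += 1
    if len(header) == 1:
        n = int(header[0])
    elif len(header) == 4:
        n = int(header[1])
    else:
        raise GraphError(f"unrecognised GAL header: {lines[idx - 1]!r}")
    order: list[str] = []
    edges: list[tuple[str, str]] = []
    nbr_map: dict[str, list[str]] = {}
    for _ in range(n):
        while idx < len(lines) and not lines[idx]:
            idx += 1
        if idx >= len(lines):
            raise GraphError("truncated GAL file: missing node block")
        head = lines[idx].split()
        idx += 1
        if len(head) != 2:
            raise GraphError(f"bad GAL node header: {' '.join(head)!r}")
        nid, k = head[0], int(head[1])
        order.append(nid)
        if k > 0:
            while idx < len(lines) and not lines[idx]:
                idx += 1
            if idx >= len(lines):
                raise GraphError(f"truncated GAL file: neighbours of {nid!r} missing")
            nbrs = lines[idx].split()
            idx += 1
            if len(nbrs) != k:
                raise GraphError(
                    f"node {nid!r}: declared {k} neighbours, found {len(nbrs)}"
                )
            nbr_map[nid] = nbrs
        else:
            nbr_map[nid] = []
            # tolerate (and consume) an explicit empty neighbour line
            if idx < len(lines) and not lines[idx]:
                idx += 1
    known = set(order)
    if nodes is not None:
        if set(nodes) != known:
            raise GraphError("GAL node set differs from supplied node list")
        order = list(nodes)
    for nid, nbrs in nbr_map.items():
        for m in nbrs:
            if m == nid:
                raise GraphError(f"self-loop on {nid!r}")
            if m not in known:
                raise GraphError(f"node {nid!r} lists unknown neighbour {m!r}")
            edges.append((nid, m))
    return WardGraph(tuple(order), tuple(edges))


def write_adjacency(graph: WardGraph, path, dialect: str = "edge-list") -> None:
    path = Path(path)
    if dialect == "edge-list":
        lines = [f"{a} {b}" for a, b in graph.edges]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return
    if dialect == "gal":
        nbrs: dict[str, list[str]] = {nid: [] for nid in graph.node_ids}
        for a, b in graph.edges:
            nbrs[a].append(b)
            nbrs[b].append(a)
        out = [str(graph.n_nodes)]
        for nid in graph.node_ids:
            out.append(f"{nid} {len(nbrs[nid])}")
            out.append(" ".join(nbrs[nid]))
        path.write_text("\n".join(out) + "\n", encoding="utf-8")
        return
    raise ValueError(f"unknown adjacency dialect {dialect!r}")


# ---------------------------------------------------------------------------
# result tables

_EFFECT_COLUMNS = [
    "name",
    "posterior_mean",
    "lower95",
    "upper95",
    "prob_positive",
    "class80",
    "report",
]


def _report_string(mean: float, lo: float, hi: float) -> str:
    return f"{mean:.2f} ({lo:.2f} to {hi:.2f})"


def effect_table_frame(summaries) -> pd.DataFrame:
    """Effect summaries as a DataFrame with a stable column order."""
    if not summaries:
        raise ValueError("no summaries to write")
    rows = []
    for s in summaries:
        rows.append(
            {
                "name": s.name,
                "posterior_mean": s.posterior_mean,
                "lower95": s.lower95,
                "upper95": s.upper95,
                "prob_positive": s.prob_positive,
                "class80": s.class80,
                "report": _report_string(s.posterior_mean, s.lower95, s.upper95),
            }
        )
    return pd.DataFrame(rows, columns=_EFFECT_COLUMNS)


def write_effect_table(summaries, path) -> None:
    """Write one row per quantity; CSV or JSON depending on the suffix."""
    df = effect_table_frame(summaries)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1), encoding="utf-8")
    else:
        df.to_csv(path, index=False)


def write_ward_classification(summaries, path) -> None:
    """Per-ward classification file (choropleth-ready).

    Columns: ward_id, posterior_mean, lower95, upper95, prob_positive,
    class80 (text) and class_code (+1/-1/0).
    """
    if not summaries:
        raise ValueError("no summaries to write")
    code = {"positive": 1, "negative": -1, "null": 0}
    rows = [
        {
            "ward_id": s.name,
            "posterior_mean": s.posterior_mean,
            "lower95": s.lower95,
            "upper95": s.upper95,
            "prob_positive": s.prob_positive,
            "class80": s.class80,
            "class_code": code[s.class80],
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
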