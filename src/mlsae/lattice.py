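"""Cross-classified domain lattice, margins, and district adjacency.

The estimation domains are the full cross-product of geography and
demography: district (nested in division) x place of residence x child
age group x sex.  Everything downstream — design matrices, random-effect
incidence matrices, aggregation maps — references the single canonical
domain ordering owned by :class:`DomainLattice`: lexicographic by
(district, residence, age_group, sex) with the declared level orders.

District adjacency is represented as an undirected :mod:`networkx` graph
and turned into the intrinsic conditional-autoregressive (ICAR) precision
matrix ``Q = D_w - W`` used by the spatial random-effect component.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FACTORS",
    "DEFAULT_RESIDENCE_LEVELS",
    "DEFAULT_AGE_LEVELS",
    "DEFAULT_SEX_LEVELS",
    "DomainLattice",
    "build_lattice",
    "example_lattice",
    "margin_map",
    "AdjacencyGraph",
    "car_precision",
    "read_adjacency",
    "grid_adjacency",
]

#: Factor names in canonical (sort) order.  ``division`` is not a free
#: factor: it is a function of ``district`` through the nesting map.
FACTORS = ("district", "residence", "age_group", "sex")

DEFAULT_RESIDENCE_LEVELS = ("rural", "urban")
DEFAULT_AGE_LEVELS = ("0-11", "12-23", "24-35", "36-47", "48-59")
DEFAULT_SEX_LEVELS = ("female", "male")


@dataclass(frozen=True)
class DomainLattice:
    """The full cross-classification of districts and demographic factors.

    Attributes
    ----------
    frame
        One row per domain in canonical order, with columns
        ``district, division, residence, age_group, sex``.
    level_sets
        Ordered levels for each factor in :data:`FACTORS`.
    nesting
        district -> division map (total, single-valued).
    """

    frame: pd.DataFrame
    level_sets: dict[str, tuple[str, ...]]
    nesting: dict[str, str] = field(default_factory=dict)

    @property
    def n_domains(self) -> int:
        return len(self.frame)

    @property
    def districts(self) -> tuple[str, ...]:
        return self.level_sets["district"]

    @property
    def divisions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for d in self.level_sets["district"]:
            div = self.nesting[d]
            if div not in seen:
                seen.append(div)
        return tuple(seen)

    def codes(self, factor: str) -> np.ndarray:
        """Integer level codes (canonical level order) for one factor."""
        if factor == "division":
            levels: Sequence[str] = self.divisions
        else:
            levels = self.level_sets[factor]
        lookup = {lv: i for i, lv in enumerate(levels)}
        return self.frame[factor].map(lookup).to_numpy(dtype=np.int64)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_domains


def build_lattice(
    level_sets: Mapping[str, Sequence[str]],
    nesting: Mapping[str, str],
) -> DomainLattice:
    """Build the full cross-product lattice with its canonical ordering.

    Parameters
    ----------
    level_sets
        Levels per factor.  Must contain ``district``; ``residence``,
        ``age_group`` and ``sex`` default to the standard survey levels.
    nesting
        district -> division map covering every district.

    Raises
    ------
    ValueError
        On duplicate levels, empty level sets, or districts missing from
        the nesting map.
    """
    defaults = {
        "residence": DEFAULT_RESIDENCE_LEVELS,
        "age_group": DEFAULT_AGE_LEVELS,
        "sex": DEFAULT_SEX_LEVELS,
    }
    levels: dict[str, tuple[str, ...]] = {}
    for factor in FACTORS:
        raw = level_sets.get(factor, defaults.get(factor))
        if raw is None or len(raw) == 0:
            raise ValueError(f"empty level set for factor {factor!r}")
        vals = tuple(str(v) for v in raw)
        if len(set(vals)) != len(vals):
            raise ValueError(f"duplicate levels in factor {factor!r}: {vals}")
        levels[factor] = vals

    missing = [d for d in levels["district"] if d not in nesting]
    if missing:
        raise ValueError(f"districts missing from nesting map: {missing}")

    rows = list(itertools.product(*(levels[f] for f in FACTORS)))
    frame = pd.DataFrame(rows, columns=list(FACTORS))
    frame.insert(1, "division", frame["district"].map(dict(nesting)))
    return DomainLattice(frame=frame, level_sets=levels, nesting=dict(nesting))


def example_lattice(
    n_districts: int = 64,
    n_divisions: int = 8,
    n_ages: int = 5,
) -> DomainLattice:
    """A synthetic lattice with ``n_districts`` districts spread evenly
    over ``n_divisions`` divisions (labels ``d01`` …, ``divA`` …).

    With the defaults this reproduces the 64-district / 8-division /
    2x5x2 demographic structure of a national survey lattice
    (64*2*5*2 = 1280 domains).
    """
    if n_districts % n_divisions:
        raise ValueError("n_districts must be a multiple of n_divisions")
    districts = tuple(f"d{i + 1:02d}" for i in range(n_districts))
    per = n_districts // n_divisions
    divisions = tuple(f"div{chr(ord('A') + j)}" for j in range(n_divisions))
    nesting = {d: divisions[i // per] for i, d in enumerate(districts)}
    return build_lattice(
        {"district": districts, "age_group": DEFAULT_AGE_LEVELS[:n_ages]},
        nesting,
    )


def margin_map(lattice: DomainLattice, margin: Iterable[str]) -> pd.Series:
    """Map every detailed domain to its margin cell.

    ``margin`` is a subset of the lattice factors; ``division`` is
    allowed through the nesting map.  The empty margin is the national
    total.  Returns a Series (canonical domain order) of cell labels;
    cells partition the lattice by construction.
    """
    margin = list(margin)
    allowed = set(FACTORS) | {"division"}
    unknown = [m for m in margin if m not in allowed]
    if unknown:
        raise ValueError(f"unknown margin factor(s): {unknown}")
    if not margin:
        return pd.Series(["national"] * lattice.n_domains, name="cell")
    # keep a stable factor order in the cell label
    order = [f for f in ("division", *FACTORS) if f in margin]
    labels = lattice.frame[order].astype(str).agg("|".join, axis=1)
    return labels.rename("cell")


@dataclass(frozen=True)
class AdjacencyGraph:
    """Validated undirected district adjacency."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        g = self.graph
        if any(u == v for u, v in g.edges):
            raise ValueError("adjacency graph has self-loops")
        if g.number_of_nodes() and not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            raise ValueError(
                "adjacency graph is disconnected; components: "
                + "; ".join(",".join(c) for c in comps)
            )

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate_against(self, lattice: DomainLattice) -> None:
        if set(self.graph.nodes) != set(lattice.districts):
            extra = set(self.graph.nodes) - set(lattice.districts)
            missing = set(lattice.districts) - set(self.graph.nodes)
            raise ValueError(
                f"graph/lattice district mismatch (extra={sorted(extra)}, "
                f"missing={sorted(missing)})"
            )


def car_precision(
    graph: AdjacencyGraph, order: Sequence[str] | None = None
) -> np.ndarray:
    """Intrinsic CAR precision ``Q = D_w - W`` over districts.

    ``W`` is the 0/1 adjacency matrix and ``D_w`` the diagonal of node
    degrees, i.e. the unnormalised graph Laplacian.  ``Q`` is symmetric
    positive semi-definite with zero row sums and rank ``n - 1`` on a
    connected graph; the implied spatial prior is improper and is
    identified downstream by a sum-to-zero constraint.

    ``order`` fixes the row/column ordering (defaults to sorted nodes);
    it must match the lattice's district level order when the matrix is
    used in a model.
    """
    nodes = list(order) if order is not None else sorted(graph.graph.nodes)
    if set(nodes) != set(graph.graph.nodes):
        raise ValueError("order must be a permutation of the graph nodes")
    lap = nx.laplacian_matrix(graph.graph, nodelist=nodes).toarray()
    return np.asarray(lap, dtype=float)


def grid_adjacency(districts: Sequence[str], n_cols: int | None = None) -> AdjacencyGraph:
    """Rook-adjacency on a rectangular arrangement of the districts.

    A convenient synthetic stand-in for a real contiguity structure: the
    districts are laid out row-major on a near-square grid and adjacent
    cells share an edge.  Connected for any non-empty district list.
    """
    n = len(districts)
    if n_cols is None:
        n_cols = max(1, int(np.ceil(np.sqrt(n))))
    g = nx.Graph()
    g.add_nodes_from(districts)
    for i, d in enumerate(districts):
        r, c = divmod(i, n_cols)
        for j in (i + 1, i + n_cols):
            if j < n and (j != i + 1 or (j % n_cols) != 0):
                g.add_edge(d, districts[j])
    return AdjacencyGraph(g)


def read_adjacency(path: str | Path, districts: Sequence[str] | None = None) -> AdjacencyGraph:
    """Read district adjacency from an edge-list CSV or polygon GeoJSON.

    CSV files need ``from,to`` columns; one-directional edge lists are
    symmetrised.  GeoJSON FeatureCollections need a ``district`` property
    per feature; adjacency is queen contiguity (any shared boundary
    point).  If ``districts`` is given the node set is checked against it.
    """
    path = Path(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        g = _graph_from_geojson(path)
    else:
        g = _graph_from_edgelist(path)
    if districts is not None:
        known = set(districts)
        stray = [n for n in g.nodes if n not in known]
        if stray:
            raise ValueError(f"adjacency node(s) absent from lattice: {sorted(stray)}")
        g.add_nodes_from(districts)
    return AdjacencyGraph(g)


def _graph_from_edgelist(path: Path) -> nx.Graph:
    table = pd.read_csv(path, dtype=str)
    cols = {c.lower(): c for c in table.columns}
    if "from" not in cols or "to" not in cols:
        raise ValueError("edge-list CSV must have 'from' and 'to' columns")
    g = nx.Graph()
    for a, b in zip(table[cols["from"]], table[cols["to"]]):
        if a == b:
            raise ValueError(f"self-loop edge for district {a!r}")
        g.add_edge(a, b)  # undirected: (A,B) and (B,A) collapse
    return g


def _graph_from_geojson(path: Path) -> nx.Graph:
    from shapely.geometry import shape

    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", [])
    geoms: dict[str, object] = {}
    for feat in feats:
        props = feat.get("properties") or {}
        name = props.get("district")
        if name is None:
            raise ValueError("GeoJSON feature missing 'district' property")
        geoms[str(name)] = shape(feat["geometry"])
    names = list(geoms)
    g = nx.Graph()
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            # queen contiguity: any shared point (corner contact counts)
            if geoms[a].intersects(geoms[b]):
                g.add_edge(a, b)
    return g
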