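"""Prior-knowledge network of cellular cholesterol regulation.

The model scaffold is a signed, directed (hyper)graph.  Nodes are proteins,
enzymatic activities, intra-/extracellular metabolite pools, intracellular
drug pools, and clamped experimental inputs (extracellular drugs, stimuli,
siRNA knockdowns).  Edges carry a mechanism tag that tells the simulator how
to translate them into rate terms:

``hill_regulatory``
    a normalized-Hill transfer function driving relaxation dynamics of the
    target; multiple sources on one edge are combined conjunctively (AND),
    with negative signs entering as AND-NOT terms.
``mass_action``
    an elementary reaction; metabolite sources are consumed, protein or
    activity sources act as catalysts.  A positive self-loop denotes a
    constant source term (rate ``0.5*k``, i.e. a pool fed at its resting
    level), a negative self-loop a first-order drain (rate ``k*x``).
``michaelis_menten_inhibited``
    a saturable enzymatic flux with competitive inhibition; the
    metabolite source is the substrate, a protein source the enzyme, and a
    negatively signed source the competitive inhibitor.
``uptake_product``
    a production term proportional to the product of its source levels;
    sources are not consumed (e.g. receptor-mediated cholesterol uptake
    from an effectively unlimited medium pool).

Serialization uses a SIF dialect (tab-separated ``source  relation  target``
rows with relation codes 1/-1; conjunctive hyperedges via auxiliary
``and<k>`` gate rows) plus a single CSV metadata table holding node and edge
attributes.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = [
    "NetworkNode",
    "NetworkEdge",
    "PriorKnowledgeNetwork",
    "NetworkParseError",
    "NetworkConsistencyError",
    "read_network",
    "write_network",
    "validate_network",
    "cholesterol_pkn",
    "INPUT_CATEGORIES",
    "METABOLITE_CATEGORIES",
    "NODE_CATEGORIES",
    "MECHANISMS",
]

NODE_CATEGORIES = frozenset(
    {
        "protein",
        "activity",
        "metabolite_intracellular",
        "metabolite_extracellular",
        "drug_extracellular",
        "drug_intracellular",
        "stimulus",
        "knockdown_input",
    }
)

#: categories whose nodes are clamped experimental inputs, never integrated
INPUT_CATEGORIES = frozenset({"stimulus", "knockdown_input", "drug_extracellular"})

#: categories that represent chemical pools with mass balances
METABOLITE_CATEGORIES = frozenset(
    {
        "metabolite_intracellular",
        "metabolite_extracellular",
        "drug_intracellular",
        "drug_extracellular",
    }
)

MECHANISMS = frozenset(
    {"hill_regulatory", "mass_action", "michaelis_menten_inhibited", "uptake_product"}
)


class NetworkParseError(ValueError):
    """Malformed SIF or metadata content."""


class NetworkConsistencyError(ValueError):
    """SIF topology and metadata table disagree."""


@dataclass(frozen=True)
class NetworkNode:
    """A single model node.

    Parameters
    ----------
    id:
        Short unique token used in files and parameter names.
    label:
        Human-readable display name.
    category:
        One of :data:`NODE_CATEGORIES`.
    measured:
        Whether the node was experimentally quantified (implies dynamic).
    initial_level:
        Simulation starting level in [0, 1].  Input nodes are clamped to the
        condition value instead; intracellular drug pools start at 0.
    dynamic:
        Whether the node is integrated by the ODE system.  ``None`` derives
        the default: inputs are static, everything else dynamic.
    species:
        Chemical species identity for metabolite/drug nodes, used to count
        distinct metabolites when one species appears as two pools
        (e.g. intracellular and extracellular cholesterol).
    isolated:
        Set for nodes intentionally disconnected from any input path.
    """

    id: str
    label: str = ""
    category: str = "protein"
    measured: bool = False
    initial_level: float = 0.5
    dynamic: bool | None = None
    species: str | None = None
    isolated: bool = False

    def __post_init__(self):
        if self.category not in NODE_CATEGORIES:
            raise ValueError(f"unknown node category {self.category!r} for {self.id!r}")
        if not 0.0 <= self.initial_level <= 1.0:
            raise ValueError(f"initial_level of {self.id!r} outside [0, 1]")
        dyn = self.dynamic
        if dyn is None:
            dyn = self.category not in INPUT_CATEGORIES
            object.__setattr__(self, "dynamic", dyn)
        if self.category in INPUT_CATEGORIES and dyn:
            raise ValueError(f"input node {self.id!r} cannot be dynamic")
        if self.measured and not dyn:
            raise ValueError(f"measured node {self.id!r} must be dynamic")
        if not self.label:
            object.__setattr__(self, "label", self.id)


@dataclass(frozen=True)
class NetworkEdge:
    """A signed (hyper)edge.

    ``sources`` is an ordered tuple of ``(node_id, sign)`` pairs with sign
    +1 (activating / substrate / catalyst) or -1 (inhibiting).  Repeating a
    source in a ``mass_action`` edge raises its kinetic order (e.g. the
    bimolecular acetyl-CoA condensation).  ``parameter_names`` lists the
    entries this edge contributes to the parameter vector, in mechanism
    order (Hill: k, n per source; Michaelis-Menten: rate constant, Michaelis
    constant, inhibition constant).
    """

    id: str
    sources: tuple[tuple[str, int], ...]
    target: str
    mechanism: str = "hill_regulatory"
    fixed: bool = False
    parameter_names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r} on edge {self.id!r}")
        srcs = tuple((str(s), int(g)) for s, g in self.sources)
        if not srcs:
            raise ValueError(f"edge {self.id!r} has no sources")
        if any(g not in (1, -1) for _, g in srcs):
            raise ValueError(f"edge {self.id!r} has a sign outside {{1, -1}}")
        object.__setattr__(self, "sources", srcs)
        if not self.parameter_names:
            object.__setattr__(
                self, "parameter_names", tuple(_default_parameter_names(self))
            )
        else:
            object.__setattr__(self, "parameter_names", tuple(self.parameter_names))

    @property
    def is_source_term(self) -> bool:
        """Positive mass-action self-loop: constant production at 0.5*k."""
        return (
            self.mechanism == "mass_action"
            and len(self.sources) == 1
            and self.sources[0] == (self.target, 1)
        )

    @property
    def is_drain(self) -> bool:
        """Negative mass-action self-loop: first-order degradation."""
        return (
            self.mechanism == "mass_action"
            and len(self.sources) == 1
            and self.sources[0] == (self.target, -1)
        )


def _default_parameter_names(edge: NetworkEdge) -> list[str]:
    if edge.mechanism == "hill_regulatory":
        names: list[str] = []
        for src, _ in edge.sources:
            names.extend([f"k_{src}_{edge.target}", f"n_{src}_{edge.target}"])
        return names
    if edge.mechanism == "michaelis_menten_inhibited":
        return [f"k_{edge.id}", f"kM_{edge.id}", f"kI_{edge.id}"]
    return [f"k_{edge.id}"]


class PriorKnowledgeNetwork:
    """Container for nodes and edges with validation and counting helpers."""

    def __init__(
        self,
        nodes: Iterable[NetworkNode],
        edges: Iterable[NetworkEdge],
        name: str = "network",
    ):
        self.name = name
        self.nodes: dict[str, NetworkNode] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise ValueError(f"duplicate node id {node.id!r}")
            self.nodes[node.id] = node
        self.edges: dict[str, NetworkEdge] = {}
        for edge in edges:
            if edge.id in self.edges:
                raise ValueError(f"duplicate edge id {edge.id!r}")
            self.edges[edge.id] = edge

    # -- counting helpers -------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def nodes_of_category(self, *categories: str) -> list[NetworkNode]:
        return [n for n in self.nodes.values() if n.category in categories]

    @property
    def protein_node_count(self) -> int:
        return len(self.nodes_of_category("protein"))

    @property
    def metabolite_species(self) -> set[str]:
        """Distinct chemical species among metabolite/drug nodes."""
        out = set()
        for n in self.nodes.values():
            if n.category in METABOLITE_CATEGORIES:
                out.add(n.species or n.id)
        return out

    @property
    def measured_nodes(self) -> list[str]:
        return sorted(n.id for n in self.nodes.values() if n.measured)

    @property
    def dynamic_nodes(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.dynamic]

    @property
    def input_nodes(self) -> list[str]:
        return [n.id for n in self.nodes.values() if not n.dynamic]

    def edges_into(self, node_id: str) -> list[NetworkEdge]:
        return [e for e in self.edges.values() if e.target == node_id]

    def hill_edges_into(self, node_id: str) -> list[NetworkEdge]:
        return [e for e in self.edges_into(node_id) if e.mechanism == "hill_regulatory"]

    # -- validation -------------------------------------------------------
    def validate(self) -> list[str]:
        """Return a list of violations; empty means valid."""
        report: list[str] = []
        seen_pairs: set[tuple[tuple[tuple[str, int], ...], str, str]] = set()
        for edge in self.edges.values():
            for src, _ in edge.sources:
                if src not in self.nodes:
                    report.append(f"edge {edge.id!r}: dangling source {src!r}")
            if edge.target not in self.nodes:
                report.append(f"edge {edge.id!r}: dangling target {edge.target!r}")
                continue
            key = (edge.sources, edge.target, edge.mechanism)
            if key in seen_pairs:
                report.append(f"edge {edge.id!r}: duplicate of an existing edge")
            seen_pairs.add(key)
            target = self.nodes[edge.target]
            if edge.mechanism in ("mass_action", "michaelis_menten_inhibited"):
                if target.category not in METABOLITE_CATEGORIES:
                    report.append(
                        f"edge {edge.id!r}: {edge.mechanism} edge targets "
                        f"non-metabolite node {edge.target!r}"
                    )
            if edge.mechanism == "hill_regulatory":
                if not target.dynamic:
                    report.append(
                        f"edge {edge.id!r}: hill edge targets clamped node "
                        f"{edge.target!r}"
                    )
        report.extend(self._reachability_violations())
        return report

    def _reachability_violations(self) -> list[str]:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        sourced: set[str] = set()
        for edge in self.edges.values():
            if edge.target not in self.nodes:
                continue
            if edge.is_source_term:
                sourced.add(edge.target)
                continue
            for src, _ in edge.sources:
                if src in self.nodes and src != edge.target:
                    g.add_edge(src, edge.target)
        roots = set(self.input_nodes) | sourced
        reachable = set(roots)
        for root in roots:
            reachable |= nx.descendants(g, root)
        out = []
        for node in self.nodes.values():
            if node.id in reachable or node.isolated or not node.dynamic:
                continue
            out.append(f"node {node.id!r}: unreachable from inputs and not flagged isolated")
        return out

    # -- misc -------------------------------------------------------------
    def structurally_equal(self, other: "PriorKnowledgeNetwork") -> bool:
        if set(self.nodes) != set(other.nodes) or set(self.edges) != set(other.edges):
            return False
        for nid, node in self.nodes.items():
            if node != other.nodes[nid]:
                return False
        for eid, edge in self.edges.items():
            if edge != other.edges[eid]:
                return False
        return True

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"PriorKnowledgeNetwork({self.name!r}, {len(self.nodes)} nodes, "
            f"{len(self.edges)} edges)"
        )


def validate_network(network: PriorKnowledgeNetwork) -> list[str]:
    """Report dangling references, duplicate edges and category violations."""
    return network.validate()


# ---------------------------------------------------------------------------
# SIF + metadata I/O
# ---------------------------------------------------------------------------

_NODE_FIELDS = [
    "kind",
    "id",
    "label",
    "category",
    "species",
    "measured",
    "initial_level",
    "dynamic",
    "isolated",
    "mechanism",
    "fixed",
    "parameters",
]


def _edge_sort_key(edge: NetworkEdge):
    return (edge.target, edge.sources, edge.mechanism)


def write_network(
    network: PriorKnowledgeNetwork,
    network_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
) -> tuple[str, str]:
    """Serialize to SIF + metadata CSV text (optionally writing files).

    Output is deterministic: edges are emitted in the stored insertion
    order, gate node names are assigned sequentially.
    """
    sif = io.StringIO()
    gate_of_edge: dict[str, str] = {}
    n_gates = 0
    for edge in network.edges.values():
        if len(edge.sources) == 1:
            src, sign = edge.sources[0]
            sif.write(f"{src}\t{sign}\t{edge.target}\n")
        else:
            n_gates += 1
            gate = f"and{n_gates}"
            gate_of_edge[edge.id] = gate
            for src, sign in edge.sources:
                sif.write(f"{src}\t{sign}\t{gate}\n")
            sif.write(f"{gate}\t1\t{edge.target}\n")

    meta = io.StringIO()
    writer = csv.DictWriter(meta, fieldnames=_NODE_FIELDS, lineterminator="\n")
    writer.writeheader()
    for node in network.nodes.values():
        writer.writerow(
            {
                "kind": "node",
                "id": node.id,
                "label": node.label,
                "category": node.category,
                "species": node.species or "",
                "measured": int(node.measured),
                "initial_level": repr(node.initial_level),
                "dynamic": int(bool(node.dynamic)),
                "isolated": int(node.isolated),
            }
        )
    for edge in network.edges.values():
        key = gate_of_edge.get(edge.id)
        if key is None:
            src, sign = edge.sources[0]
            key = f"{src}{'~' if sign < 0 else '>'}{edge.target}"
        writer.writerow(
            {
                "kind": "edge",
                "id": edge.id,
                "label": key,
                "mechanism": edge.mechanism,
                "fixed": int(edge.fixed),
                "parameters": ";".join(edge.parameter_names),
            }
        )
    sif_text, meta_text = sif.getvalue(), meta.getvalue()
    if network_path is not None:
        Path(network_path).write_text(sif_text)
    if metadata_path is not None:
        Path(metadata_path).write_text(meta_text)
    return sif_text, meta_text


def _parse_sif(text: str):
    """Return (plain rows, gate definitions) from SIF text.

    Plain rows are ``(source, sign, target)``; gates map gate-id to a list of
    signed sources plus the gate target.
    """
    rows: list[tuple[str, int, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3:
            raise NetworkParseError(f"line {lineno}: expected 3 fields, got {len(parts)}")
        src, rel, tgt = parts
        if rel in ("1", "+1"):
            sign = 1
        elif rel in ("-1", "−1"):
            sign = -1
        else:
            raise NetworkParseError(f"line {lineno}: unknown relation code {rel!r}")
        rows.append((src, sign, tgt))

    gate_ids = {s for s, _, _ in rows if s.startswith("and")} | {
        t for _, _, t in rows if t.startswith("and")
    }
    gates: dict[str, dict] = {g: {"sources": [], "target": None} for g in gate_ids}
    plain: list[tuple[str, int, str]] = []
    for src, sign, tgt in rows:
        if tgt in gates:
            gates[tgt]["sources"].append((src, sign))
        elif src in gates:
            if gates[src]["target"] is not None:
                raise NetworkParseError(f"gate {src!r} has multiple targets")
            gates[src]["target"] = (tgt, sign)
        else:
            plain.append((src, sign, tgt))
    for gid, g in gates.items():
        if g["target"] is None or not g["sources"]:
            raise NetworkParseError(f"gate {gid!r} is incomplete")
        if g["target"][1] != 1:
            raise NetworkParseError(f"gate {gid!r} must connect to its target with +1")
    return plain, gates


def read_network(
    network_path: str | Path,
    metadata_path: str | Path,
    name: str | None = None,
) -> PriorKnowledgeNetwork:
    """Read a network from SIF + metadata CSV and validate it.

    The metadata table carries one row per node (category, measured flag,
    initial level, species) and one row per edge (mechanism, fixed flag,
    parameter names), keyed by ``label`` for edges: either the gate id
    (``and1``) or ``source>target`` / ``source~target`` for single-source
    activating / inhibiting edges.
    """
    network_path, metadata_path = Path(network_path), Path(metadata_path)
    plain, gates = _parse_sif(network_path.read_text())

    nodes: list[NetworkNode] = []
    edge_meta: dict[str, dict] = {}
    with open(metadata_path, newline="") as fh:
        for row in csv.DictReader(fh):
            kind = (row.get("kind") or "node").strip()
            if kind == "node":
                nodes.append(
                    NetworkNode(
                        id=row["id"].strip(),
                        label=(row.get("label") or "").strip(),
                        category=row["category"].strip(),
                        species=(row.get("species") or "").strip() or None,
                        measured=_parse_bool(row.get("measured")),
                        initial_level=float(row.get("initial_level") or 0.5),
                        dynamic=_parse_bool(row.get("dynamic"))
                        if (row.get("dynamic") or "").strip() != ""
                        else None,
                        isolated=_parse_bool(row.get("isolated")),
                    )
                )
            elif kind == "edge":
                edge_meta[row["label"].strip()] = row
            else:
                raise NetworkParseError(f"unknown metadata kind {kind!r}")

    node_ids = {n.id for n in nodes}
    referenced = {s for s, _, _ in plain} | {t for _, _, t in plain}
    for g in gates.values():
        referenced |= {s for s, _ in g["sources"]}
        referenced.add(g["target"][0])
    missing = sorted(referenced - node_ids)
    if missing:
        raise NetworkConsistencyError(
            f"SIF references nodes absent from metadata: {', '.join(missing)}"
        )

    edges: list[NetworkEdge] = []
    for src, sign, tgt in plain:
        key = f"{src}{'~' if sign < 0 else '>'}{tgt}"
        meta = edge_meta.pop(key, None)
        edges.append(_edge_from_meta(key, ((src, sign),), tgt, meta))
    for gid in sorted(gates, key=lambda g: int(g[3:]) if g[3:].isdigit() else 0):
        g = gates[gid]
        meta = edge_meta.pop(gid, None)
        edges.append(_edge_from_meta(gid, tuple(g["sources"]), g["target"][0], meta))
    if edge_meta:
        raise NetworkConsistencyError(
            "metadata describes edges absent from SIF: " + ", ".join(sorted(edge_meta))
        )

    network = PriorKnowledgeNetwork(nodes, edges, name=name or network_path.stem)
    problems = network.validate()
    if problems:
        raise NetworkConsistencyError("; ".join(problems))
    return network


def _edge_from_meta(key, sources, target, meta) -> NetworkEdge:
    if meta is None:
        return NetworkEdge(id=key, sources=sources, target=target)
    params = tuple(p for p in (meta.get("parameters") or "").split(";") if p)
    return NetworkEdge(
        id=(meta.get("id") or key).strip(),
        sources=sources,
        target=target,
        mechanism=(meta.get("mechanism") or "hill_regulatory").strip(),
        fixed=_parse_bool(meta.get("fixed")),
        parameter_names=params,
    )


def _parse_bool(value) -> bool:
    if value is None:
        return False
    v = str(value).strip().lower()
    return v in ("1", "true", "yes")


# ---------------------------------------------------------------------------
# Packaged cholesterol-regulation fixture
# ---------------------------------------------------------------------------

def _fixture_path(filename: str) -> Path:
    return Path(resources.files("cholode").joinpath("data").joinpath(filename))


def cholesterol_pkn() -> PriorKnowledgeNetwork:
    """The packaged cholesterol-regulation network.

    Encodes the core feedback system: sterol depletion activates the SREBP
    precursor, which drives SREBP1 and SREBP2 (fixed edges); SREBP2 induces
    the cholesterol-synthesis enzymes and the uptake machinery (LDLR, NPC1);
    LXR, activated by the agonists T0901317 and GW3965, induces its target
    proteins; a hypothetical SREBP1-to-SREBP inhibition captures the
    observed complementation of SREBP1 loss by SREBP2.  Metabolic reactions
    from acetyl-CoA to ER cholesterol are mass-action / Michaelis-Menten
    fluxes, with atorvastatin as a competitive HMGCR inhibitor.  siRNA
    perturbations enter as knockdown inputs forming AND-NOT terms on their
    target's activating edge.
    """
    return read_network(
        _fixture_path("cholesterol.sif"),
        _fixture_path("cholesterol_metadata.csv"),
        name="cholesterol",
    )
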