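"""Hybrid logic-based ODE simulation of a prior-knowledge network.

Regulatory interactions are continuous logic: every signed edge source is
passed through a normalized Hill transfer function

    f(x; k, n) = x^n (1 + k^n) / (x^n + k^n),

which maps [0, 1] onto [0, 1] with f(0) = 0, f(1) = 1, half-effect at
``x = k`` and steepness ``n``.  Sources on the same edge combine
conjunctively (product; inhibiting sources contribute ``1 - f``); parallel
edges onto the same target combine as a continuous OR,
``B = 1 - prod(1 - g_e)``.  Each regulated node then relaxes towards its
combined input with its own time scale:

    dx/dt = tau_x * (B_x - x).

Metabolite nodes instead carry explicit mass balances assembled from the
mechanism-tagged reaction edges (constant sources, mass action,
Michaelis-Menten with competitive inhibition, uptake products), each balance
multiplied by the node's tau.  Levels are dimensionless: regulatory nodes
live in [0, 1], metabolite pools are non-negative.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import odeint, solve_ivp

from .pkn import METABOLITE_CATEGORIES, NetworkEdge, PriorKnowledgeNetwork

__all__ = [
    "ParameterBounds",
    "ParameterVector",
    "ConditionInput",
    "SimulationResult",
    "SimulationError",
    "hill_transfer",
    "compile_model",
    "build_rhs",
    "simulate",
    "flux_summaries",
    "relative_uptake_change",
    "END_TIMES",
]

#: dimensionless simulation horizons for the two treatment classes
END_TIMES = {"48h": 100.0, "72h": 150.0}

#: fixed transfer-function shape of knockdown inputs (half-effect, steepness)
KNOCKDOWN_TRANSFER = (0.5, 4.0)

#: fixed transfer-function shape of fixed regulatory edges
FIXED_TRANSFER = (0.5, 2.0)


class SimulationError(RuntimeError):
    """Integrator failure or non-finite state."""


# ---------------------------------------------------------------------------
# Transfer function
# ---------------------------------------------------------------------------

def hill_transfer(x, k, n):
    """Normalized Hill transfer ``x^n (1+k^n) / (x^n + k^n)``.

    Parameters are validated for scalar use; the simulator calls the
    unchecked vectorized kernel internally.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < -1e-12) or np.any(x_arr > 1 + 1e-12):
        raise ValueError("hill_transfer input outside [0, 1]")
    if np.any(np.asarray(k, dtype=float) <= 0):
        raise ValueError("hill_transfer requires k > 0")
    if np.any(np.asarray(n, dtype=float) < 1):
        raise ValueError("hill_transfer requires n >= 1")
    out = _hill(np.clip(x_arr, 0.0, 1.0), np.asarray(k, float), np.asarray(n, float))
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def _hill(x, k, n):
    xn = np.power(x, n)
    kn = np.power(k, n)
    return xn * (1.0 + kn) / (xn + kn)


# ---------------------------------------------------------------------------
# Parameter vector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterBounds:
    """Shared box constraints per parameter kind (identical across cell lines)."""

    hill_k: tuple[float, float] = (0.01, 1.0)
    hill_n: tuple[float, float] = (1.0, 10.0)
    tau: tuple[float, float] = (0.01, 10.0)
    rate: tuple[float, float] = (0.0, 10.0)
    saturation: tuple[float, float] = (0.01, 10.0)  # Michaelis / inhibition constants


@dataclass
class ParameterVector:
    """Ordered, named, bounded, partially fixed model parameters."""

    names: list[str]
    values: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    fixed: np.ndarray
    kinds: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.fixed = np.asarray(self.fixed, dtype=bool)
        n = len(self.names)
        if not (len(self.values) == len(self.lower) == len(self.upper) == len(self.fixed) == n):
            raise ValueError("parameter vector arrays have inconsistent lengths")
        if len(set(self.names)) != n:
            raise ValueError("duplicate parameter names")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_network(
        cls,
        network: PriorKnowledgeNetwork,
        bounds: ParameterBounds | None = None,
    ) -> "ParameterVector":
        """Build the canonical parameter template for a network.

        Order: per edge (network order) the edge's parameters, then one tau
        per dynamic node.  Fixed entries: all parameters of ``fixed`` edges
        and the transfer shape of knockdown-input sources.
        """
        bounds = bounds or ParameterBounds()
        names: list[str] = []
        kinds: list[str] = []
        values: list[float] = []
        fixed: list[bool] = []

        def add(name, kind, value, fix):
            names.append(name)
            kinds.append(kind)
            values.append(value)
            fixed.append(fix)

        for edge in network.edges.values():
            if edge.mechanism == "hill_regulatory":
                pnames = iter(edge.parameter_names)
                for src, _ in edge.sources:
                    kname, nname = next(pnames), next(pnames)
                    is_kd = network.nodes[src].category == "knockdown_input"
                    if is_kd:
                        kv, nv = KNOCKDOWN_TRANSFER
                        add(kname, "hill_k", kv, True)
                        add(nname, "hill_n", nv, True)
                    elif edge.fixed:
                        kv, nv = FIXED_TRANSFER
                        add(kname, "hill_k", kv, True)
                        add(nname, "hill_n", nv, True)
                    else:
                        add(kname, "hill_k", 0.5, False)
                        add(nname, "hill_n", 2.0, False)
            elif edge.mechanism == "michaelis_menten_inhibited":
                kname, kmname, kiname = edge.parameter_names
                add(kname, "rate", 0.5, edge.fixed)
                add(kmname, "saturation", 0.5, edge.fixed)
                add(kiname, "saturation", 1.0, edge.fixed)
            else:  # mass_action / uptake_product
                (kname,) = edge.parameter_names
                add(kname, "rate", 0.5, edge.fixed)
        for node_id in network.dynamic_nodes:
            add(f"tau_{node_id}", "tau", 1.0, False)

        kind_bounds = {
            "hill_k": bounds.hill_k,
            "hill_n": bounds.hill_n,
            "tau": bounds.tau,
            "rate": bounds.rate,
            "saturation": bounds.saturation,
        }
        lower = np.array([kind_bounds[k][0] for k in kinds])
        upper = np.array([kind_bounds[k][1] for k in kinds])
        return cls(names, np.array(values), lower, upper, np.array(fixed), kinds)

    # -- access -----------------------------------------------------------
    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.names)}

    @property
    def free_names(self) -> list[str]:
        return [n for n, f in zip(self.names, self.fixed) if not f]

    @property
    def free_values(self) -> np.ndarray:
        return self.values[~self.fixed]

    @property
    def free_bounds(self) -> list[tuple[float, float]]:
        free = ~self.fixed
        return list(zip(self.lower[free], self.upper[free]))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.index[name]])

    def copy(self) -> "ParameterVector":
        return ParameterVector(
            list(self.names),
            self.values.copy(),
            self.lower.copy(),
            self.upper.copy(),
            self.fixed.copy(),
            list(self.kinds),
        )

    def with_free_values(self, x: Sequence[float]) -> "ParameterVector":
        out = self.copy()
        out.values[~out.fixed] = np.asarray(x, dtype=float)
        return out

    def updated(self, mapping: Mapping[str, float]) -> "ParameterVector":
        out = self.copy()
        idx = out.index
        for name, value in mapping.items():
            out.values[idx[name]] = float(value)
        return out

    def within_bounds(self, tol: float = 1e-9) -> bool:
        return bool(
            np.all(self.values >= self.lower - tol)
            and np.all(self.values <= self.upper + tol)
        )

    # -- serialization ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "value": self.values,
                "lower": self.lower,
                "upper": self.upper,
                "fixed": self.fixed.astype(int),
                "kind": self.kinds or [""] * len(self.names),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path | io.IOBase) -> "ParameterVector":
        df = pd.read_csv(path)
        return cls(
            list(df["name"]),
            df["value"].to_numpy(),
            df["lower"].to_numpy(),
            df["upper"].to_numpy(),
            df["fixed"].to_numpy().astype(bool),
            list(df["kind"]) if "kind" in df else [],
        )


# ---------------------------------------------------------------------------
# Conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionInput:
    """Clamped input levels for one experimental condition.

    ``inputs`` maps clamped (non-dynamic) node ids to levels in [0, 1];
    unlisted clamped nodes stay at their network default.  ``horizon``
    selects the simulation end time (drug-like treatments equilibrate on a
    shorter horizon than siRNA treatments).
    """

    id: str
    inputs: Mapping[str, float] = field(default_factory=dict)
    horizon: str = "48h"

    def __post_init__(self):
        if self.horizon not in END_TIMES:
            raise ValueError(f"unknown horizon {self.horizon!r}")
        for node, level in self.inputs.items():
            if not 0.0 <= float(level) <= 1.0:
                raise ValueError(f"condition {self.id!r}: level of {node!r} outside [0, 1]")
        object.__setattr__(self, "inputs", dict(self.inputs))

    @property
    def end_time(self) -> float:
        return END_TIMES[self.horizon]


@dataclass
class SimulationResult:
    """Trajectory of all dynamic nodes for one condition."""

    condition: str
    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_dynamic)
    node_order: list[str]
    converged: bool
    max_residual: float
    interpolant: object = None  # dense-output callable t -> state vector

    @property
    def terminal(self) -> dict[str, float]:
        return dict(zip(self.node_order, self.states[-1]))

    def trajectory(self, node: str) -> np.ndarray:
        return self.states[:, self.node_order.index(node)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.node_order)
        df.insert(0, "time", self.times)
        return df


# ---------------------------------------------------------------------------
# Model compilation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rhs_kernel(
    x,
    clamps,
    values,
    hill_pair_src,
    hill_pair_pos,
    hill_pair_k,
    hill_pair_n,
    hill_edge_starts,
    hill_node_edge_starts,
    hill_nodes,
    rxn_type,
    rxn_kidx,
    rxn_km,
    rxn_ki,
    rxn_sub,
    rxn_prod,
    fact_flat,
    fact_start,
    cat_flat,
    cat_start,
    inh_flat,
    inh_start,
    cons_flat,
    cons_start,
    tau_idx,
):  # pragma: no cover - exercised through CompiledModel.rhs
    n_dyn = x.shape[0]
    levels = np.empty(n_dyn + clamps.shape[0])
    dx = np.zeros(n_dyn)
    for i in range(n_dyn):
        levels[i] = x[i] if x[i] > 0.0 else 0.0
    for j in range(clamps.shape[0]):
        levels[n_dyn + j] = clamps[j]

    for hn in range(hill_nodes.shape[0]):
        prod_not = 1.0
        for e in range(hill_node_edge_starts[hn], hill_node_edge_starts[hn + 1]):
            gate = 1.0
            for p in range(hill_edge_starts[e], hill_edge_starts[e + 1]):
                xv = levels[hill_pair_src[p]]
                if xv > 1.0:
                    xv = 1.0
                k = values[hill_pair_k[p]]
                n = values[hill_pair_n[p]]
                xn = xv**n
                kn = k**n
                f = xn * (1.0 + kn) / (xn + kn)
                gate *= f if hill_pair_pos[p] else 1.0 - f
            prod_not *= 1.0 - gate
        node = hill_nodes[hn]
        dx[node] = (1.0 - prod_not) - x[node]

    for r in range(rxn_type.shape[0]):
        t = rxn_type[r]
        if t == 0:  # constant source at the resting level
            rate = 0.5 * values[rxn_kidx[r]]
        elif t == 1:  # first-order drain
            rate = values[rxn_kidx[r]] * levels[rxn_sub[r]]
        elif t == 2:  # Michaelis-Menten with competitive inhibition
            s = levels[rxn_sub[r]]
            cat = 1.0
            for c in range(cat_start[r], cat_start[r + 1]):
                cat *= levels[cat_flat[c]]
            inh = 0.0
            for c in range(inh_start[r], inh_start[r + 1]):
                inh += levels[inh_flat[c]]
            denom = values[rxn_km[r]] * (1.0 + inh / values[rxn_ki[r]]) + s
            rate = values[rxn_kidx[r]] * cat * s / denom if denom > 0.0 else 0.0
        else:  # mass-action / uptake product of source levels
            rate = values[rxn_kidx[r]]
            for c in range(fact_start[r], fact_start[r + 1]):
                rate *= levels[fact_flat[c]]
        for c in range(cons_start[r], cons_start[r + 1]):
            dx[cons_flat[c]] -= rate
        if rxn_prod[r] >= 0:
            dx[rxn_prod[r]] += rate

    for i in range(n_dyn):
        dx[i] *= values[tau_idx[i]]
    return dx


class CompiledModel:
    """Network compiled to a fast derivative function.

    Compilation resolves node references to indices once; repeated
    simulation with different parameter values then avoids any dictionary
    lookups inside the right-hand side.
    """

    def __init__(self, network: PriorKnowledgeNetwork, params: ParameterVector | None = None):
        self.network = network
        self.template = params or ParameterVector.from_network(network)
        self.dynamic = list(network.dynamic_nodes)
        self.clamped = list(network.input_nodes)
        self.n_dyn = len(self.dynamic)
        self._ref = {nid: i for i, nid in enumerate(self.dynamic)}
        self._ref.update({nid: self.n_dyn + j for j, nid in enumerate(self.clamped)})
        pidx = self.template.index

        missing = [n for n in self.template.names if n not in pidx]
        if missing:  # pragma: no cover - defensive
            raise ValueError(f"missing parameters: {missing}")

        self.tau_idx = np.array([pidx[f"tau_{nid}"] for nid in self.dynamic])
        self._compile_hill(network, pidx)
        self._compile_metabolic(network, pidx)

        self.default_clamps = np.array(
            [network.nodes[nid].initial_level for nid in self.clamped]
        )
        self.x0 = np.array([network.nodes[nid].initial_level for nid in self.dynamic])
        cats = [network.nodes[nid].category for nid in self.dynamic]
        self.is_metabolite = np.array([c in METABOLITE_CATEGORIES for c in cats])
        self._finalize_kernel_arrays()

    # -- structure --------------------------------------------------------
    def _compile_hill(self, network, pidx):
        pair_src, pair_sign, pair_k, pair_n = [], [], [], []
        edge_starts, node_edge_starts, hill_nodes = [], [], []
        for node_id in self.dynamic:
            edges = network.hill_edges_into(node_id)
            if not edges:
                continue
            hill_nodes.append(self._ref[node_id])
            node_edge_starts.append(len(edge_starts))
            for edge in edges:
                edge_starts.append(len(pair_src))
                pnames = iter(edge.parameter_names)
                for src, sign in edge.sources:
                    kname, nname = next(pnames), next(pnames)
                    pair_src.append(self._ref[src])
                    pair_sign.append(sign)
                    pair_k.append(pidx[kname])
                    pair_n.append(pidx[nname])
        self.hill_nodes = np.array(hill_nodes, dtype=int)
        self.hill_node_edge_starts = np.array(node_edge_starts, dtype=int)
        self.hill_edge_starts = np.array(edge_starts, dtype=int)
        self.hill_pair_src = np.array(pair_src, dtype=int)
        self.hill_pair_pos = np.array(pair_sign, dtype=int) > 0
        self.hill_pair_k = np.array(pair_k, dtype=int)
        self.hill_pair_n = np.array(pair_n, dtype=int)

    def _compile_metabolic(self, network, pidx):
        self.reactions = []
        met_nodes = set()
        for edge in network.edges.values():
            if edge.mechanism == "hill_regulatory":
                continue
            rxn = self._compile_reaction(network, edge, pidx)
            self.reactions.append(rxn)
            met_nodes.update(rxn["consumed"])
            if rxn["produced"] is not None:
                met_nodes.add(rxn["produced"])
        overlap = met_nodes & set(self.hill_nodes.tolist())
        if overlap:
            bad = [self.dynamic[i] for i in overlap]
            raise ValueError(f"nodes {bad} are both hill-regulated and metabolic")

    def _compile_reaction(self, network, edge: NetworkEdge, pidx):
        k_idx = pidx[edge.parameter_names[0]]
        target_dyn = self._ref[edge.target] if network.nodes[edge.target].dynamic else None
        if edge.is_source_term:
            return {
                "type": "source",
                "k": k_idx,
                "consumed": (),
                "produced": target_dyn,
            }
        if edge.is_drain:
            return {
                "type": "drain",
                "k": k_idx,
                "substrate": self._ref[edge.target],
                "consumed": (self._ref[edge.target],),
                "produced": None,
            }
        if edge.mechanism == "michaelis_menten_inhibited":
            _, km_name, ki_name = edge.parameter_names
            substrate = None
            catalysts, inhibitors = [], []
            for src, sign in edge.sources:
                cat = network.nodes[src].category
                if sign < 0:
                    inhibitors.append(self._ref[src])
                elif cat in METABOLITE_CATEGORIES and substrate is None:
                    substrate = self._ref[src]
                else:
                    catalysts.append(self._ref[src])
            if substrate is None:
                raise ValueError(f"edge {edge.id!r}: no metabolite substrate")
            return {
                "type": "mm",
                "k": k_idx,
                "km": pidx[km_name],
                "ki": pidx[ki_name],
                "substrate": substrate,
                "catalysts": tuple(catalysts),
                "inhibitors": tuple(inhibitors),
                "consumed": (substrate,) if self.dynamic_ref(substrate) else (),
                "produced": target_dyn,
            }
        # plain mass action or uptake product
        factors = tuple(self._ref[src] for src, _ in edge.sources)
        if edge.mechanism == "uptake_product":
            consumed = ()
        else:
            consumed = tuple(
                sorted(
                    {
                        self._ref[src]
                        for src, sign in edge.sources
                        if sign > 0
                        and network.nodes[src].category in METABOLITE_CATEGORIES
                        and network.nodes[src].dynamic
                    }
                )
            )
        return {
            "type": "product",
            "k": k_idx,
            "factors": factors,
            "consumed": consumed,
            "produced": target_dyn,
        }

    def dynamic_ref(self, ref: int) -> bool:
        return ref < self.n_dyn

    def _finalize_kernel_arrays(self):
        """Flatten the compiled structure for the jitted derivative kernel."""
        n_pairs = len(self.hill_pair_src)
        n_edges = len(self.hill_edge_starts)
        self._k_edge_starts = np.append(self.hill_edge_starts, n_pairs).astype(np.int64)
        self._k_node_edge_starts = np.append(
            self.hill_node_edge_starts, n_edges
        ).astype(np.int64)

        type_code = {"source": 0, "drain": 1, "mm": 2, "product": 3}
        n_rxn = len(self.reactions)
        rxn_type = np.zeros(n_rxn, dtype=np.int64)
        rxn_kidx = np.zeros(n_rxn, dtype=np.int64)
        rxn_km = np.zeros(n_rxn, dtype=np.int64)
        rxn_ki = np.zeros(n_rxn, dtype=np.int64)
        rxn_sub = np.full(n_rxn, -1, dtype=np.int64)
        rxn_prod = np.full(n_rxn, -1, dtype=np.int64)
        fact_flat, fact_start = [], [0]
        cat_flat, cat_start = [], [0]
        inh_flat, inh_start = [], [0]
        cons_flat, cons_start = [], [0]
        for r, rxn in enumerate(self.reactions):
            rxn_type[r] = type_code[rxn["type"]]
            rxn_kidx[r] = rxn["k"]
            if rxn["type"] == "mm":
                rxn_km[r] = rxn["km"]
                rxn_ki[r] = rxn["ki"]
                cat_flat.extend(rxn["catalysts"])
                inh_flat.extend(rxn["inhibitors"])
            if rxn["type"] in ("drain", "mm"):
                rxn_sub[r] = rxn["substrate"]
            if rxn["type"] == "product":
                fact_flat.extend(rxn["factors"])
            cons_flat.extend(rxn["consumed"])
            if rxn["produced"] is not None:
                rxn_prod[r] = rxn["produced"]
            fact_start.append(len(fact_flat))
            cat_start.append(len(cat_flat))
            inh_start.append(len(inh_flat))
            cons_start.append(len(cons_flat))
        as_i = lambda a: np.asarray(a, dtype=np.int64)
        self._kernel_args = (
            self.hill_pair_src.astype(np.int64),
            self.hill_pair_pos,
            self.hill_pair_k.astype(np.int64),
            self.hill_pair_n.astype(np.int64),
            self._k_edge_starts,
            self._k_node_edge_starts,
            self.hill_nodes.astype(np.int64),
            rxn_type,
            rxn_kidx,
            rxn_km,
            rxn_ki,
            rxn_sub,
            rxn_prod,
            as_i(fact_flat),
            as_i(fact_start),
            as_i(cat_flat),
            as_i(cat_start),
            as_i(inh_flat),
            as_i(inh_start),
            as_i(cons_flat),
            as_i(cons_start),
            self.tau_idx.astype(np.int64),
        )

    # -- evaluation -------------------------------------------------------
    def rhs(self, t, x, values, clamps):
        """Derivative of the dynamic state vector (jit-compiled kernel)."""
        return _rhs_kernel(np.asarray(x, dtype=float), clamps, values, *self._kernel_args)

    def rhs_reference(self, t, x, values, clamps):
        """Readable reference implementation of the derivative."""
        levels = np.concatenate((np.maximum(x, 0.0), clamps))
        dx = np.zeros(self.n_dyn)

        if len(self.hill_pair_src):
            xin = np.clip(levels[self.hill_pair_src], 0.0, 1.0)
            f = _hill(xin, values[self.hill_pair_k], values[self.hill_pair_n])
            g = np.where(self.hill_pair_pos, f, 1.0 - f)
            gate = np.multiply.reduceat(g, self.hill_edge_starts)
            b = 1.0 - np.multiply.reduceat(1.0 - gate, self.hill_node_edge_starts)
            dx[self.hill_nodes] = b - x[self.hill_nodes]

        for rxn in self.reactions:
            kind = rxn["type"]
            if kind == "source":
                rate = 0.5 * values[rxn["k"]]
            elif kind == "drain":
                rate = values[rxn["k"]] * levels[rxn["substrate"]]
            elif kind == "mm":
                s = levels[rxn["substrate"]]
                cat = 1.0
                for c in rxn["catalysts"]:
                    cat *= levels[c]
                inhib = 0.0
                for i in rxn["inhibitors"]:
                    inhib += levels[i]
                km = values[rxn["km"]]
                denom = km * (1.0 + inhib / values[rxn["ki"]]) + s
                rate = values[rxn["k"]] * cat * s / denom if denom > 0 else 0.0
            else:  # product
                rate = values[rxn["k"]]
                for ref in rxn["factors"]:
                    rate *= levels[ref]
            for ref in rxn["consumed"]:
                dx[ref] -= rate
            produced = rxn["produced"]
            if produced is not None:
                dx[produced] += rate
        return values[self.tau_idx] * dx

    def clamp_vector(self, condition: ConditionInput | None) -> np.ndarray:
        clamps = self.default_clamps.copy()
        if condition is not None:
            for node, level in condition.inputs.items():
                if node not in self._ref:
                    raise ValueError(f"condition {condition.id!r}: unknown node {node!r}")
                ref = self._ref[node]
                if ref < self.n_dyn:
                    raise ValueError(
                        f"condition {condition.id!r}: node {node!r} is dynamic, not clamped"
                    )
                clamps[ref - self.n_dyn] = float(level)
        return clamps

    def simulate(
        self,
        params: ParameterVector | np.ndarray,
        condition: ConditionInput | None = None,
        end_time: float | None = None,
        rtol: float = 1e-7,
        atol: float = 1e-9,
        ss_tol: float = 1e-6,
        t_eval: np.ndarray | None = None,
        method: str = "LSODA",
        dense_output: bool = False,
    ) -> SimulationResult:
        values = params.values if isinstance(params, ParameterVector) else np.asarray(params)
        if not np.all(np.isfinite(values)):
            raise SimulationError("non-finite parameter values")
        if end_time is None:
            end_time = condition.end_time if condition is not None else END_TIMES["48h"]
        if end_time <= 0:
            raise ValueError("end_time must be positive")
        clamps = self.clamp_vector(condition)
        if t_eval is None:
            t_eval = np.linspace(0.0, end_time, 41)
        sol = solve_ivp(
            self.rhs,
            (0.0, float(end_time)),
            self.x0,
            args=(values, clamps),
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            dense_output=dense_output,
        )
        if not sol.success:
            raise SimulationError(f"integration failed: {sol.message}")
        if not np.all(np.isfinite(sol.y)):
            raise SimulationError("non-finite state encountered")
        resid = self.rhs(sol.t[-1], sol.y[:, -1], values, clamps)
        max_resid = float(np.max(np.abs(resid)))
        return SimulationResult(
            condition=condition.id if condition is not None else "untreated",
            times=sol.t,
            states=sol.y.T,
            node_order=self.dynamic,
            converged=max_resid < ss_tol,
            max_residual=max_resid,
            interpolant=sol.sol if dense_output else None,
        )

    def integrate(
        self,
        values: np.ndarray,
        clamps: np.ndarray,
        times: np.ndarray,
        rtol: float = 1e-6,
        atol: float = 1e-8,
    ) -> np.ndarray:
        """States at the given output times (low-overhead objective path)."""
        return _integrate_fast(self, values, clamps, times, rtol, atol)


def _integrate_fast(model: "CompiledModel", values, clamps, times, rtol, atol):
    """Low-overhead LSODA integration at fixed output times.

    Used by the objective, where millions of short integrations dominate
    the cost.  Raises :class:`SimulationError` on failure or non-finite
    states.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y, info = odeint(
            model.rhs,
            model.x0,
            times,
            args=(values, clamps),
            tfirst=True,
            rtol=rtol,
            atol=atol,
            full_output=True,
            printmessg=False,
        )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(y)):
        raise SimulationError(f"integration failed: {info['message']}")
    return y


def compile_model(
    network: PriorKnowledgeNetwork, params: ParameterVector | None = None
) -> CompiledModel:
    """Compile a network (and optional parameter template) for simulation."""
    return CompiledModel(network, params)


def build_rhs(network: PriorKnowledgeNetwork, params: ParameterVector):
    """Return ``rhs(t, x)`` over the dynamic state for default clamps.

    Thin wrapper around :class:`CompiledModel` for direct inspection of the
    derivative function; ``simulate`` is the main entry point.
    """
    model = CompiledModel(network, params)
    clamps = model.default_clamps.copy()
    missing = [n for n in params.names if n not in model.template.index]
    if missing:
        raise ValueError(f"missing parameters: {missing}")

    def rhs(t, x, condition: ConditionInput | None = None):
        c = clamps if condition is None else model.clamp_vector(condition)
        return model.rhs(t, np.asarray(x, dtype=float), params.values, c)

    rhs.model = model
    return rhs


def simulate(
    network: PriorKnowledgeNetwork,
    params: ParameterVector,
    condition: ConditionInput | None = None,
    end_time: float | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    ss_tol: float = 1e-6,
    t_eval: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate one condition to its horizon and report convergence."""
    return CompiledModel(network, params).simulate(
        params, condition, end_time, rtol, atol, ss_tol, t_eval
    )


# ---------------------------------------------------------------------------
# Flux summaries
# ---------------------------------------------------------------------------

def flux_summaries(
    network: PriorKnowledgeNetwork,
    params: ParameterVector,
    terminal_states: Mapping[str, Mapping[str, float]],
    target: str = "CholER",
    conditions: Mapping[str, ConditionInput] | None = None,
) -> pd.DataFrame:
    """Uptake vs synthesis fluxes into a metabolite pool at steady state.

    Uptake is the total rate of ``uptake_product`` edges into ``target``
    (for the cholesterol model, ``k6 * CholMedia * LDLR * NPC1``); synthesis
    the total rate of mass-action production edges (``k5 * Mevalonate``).
    The uptake fraction is ``uptake / (uptake + synthesis)``; with zero
    total flux it is flagged undefined rather than raising.

    ``terminal_states`` maps condition id to terminal node levels (clamped
    nodes may be omitted); ``conditions`` optionally supplies the
    per-condition clamp levels of non-dynamic nodes such as the medium
    cholesterol pool, which otherwise default to the network's resting
    levels.
    """
    uptake_edges = [
        e
        for e in network.edges_into(target)
        if e.mechanism == "uptake_product"
    ]
    synth_edges = [
        e
        for e in network.edges_into(target)
        if e.mechanism == "mass_action" and not e.is_drain and not e.is_source_term
    ]

    def product_rate(edge: NetworkEdge, state, clamp_inputs) -> float:
        rate = params[edge.parameter_names[0]]
        for src, _ in edge.sources:
            node = network.nodes[src]
            level = state.get(src, clamp_inputs.get(src, node.initial_level))
            rate *= max(float(level), 0.0)
        return rate

    rows = []
    for cond, state in terminal_states.items():
        clamp_inputs: Mapping[str, float] = {}
        if conditions is not None and cond in conditions:
            clamp_inputs = conditions[cond].inputs
        uptake = sum(product_rate(e, state, clamp_inputs) for e in uptake_edges)
        synthesis = sum(product_rate(e, state, clamp_inputs) for e in synth_edges)
        total = uptake + synthesis
        rows.append(
            {
                "condition": cond,
                "uptake": uptake,
                "synthesis": synthesis,
                "fraction_uptake": uptake / total if total > 0 else np.nan,
                "undefined_fraction": total <= 0,
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def relative_uptake_change(flux: pd.DataFrame, treated: str, control: str) -> float:
    """Relative change of uptake flux between two conditions.

    Returns ``(uptake_treated - uptake_control) / uptake_control``; NaN if
    the control flux is zero.
    """
    u_t = float(flux.loc[treated, "uptake"])
    u_c = float(flux.loc[control, "uptake"])
    return (u_t - u_c) / u_c if u_c > 0 else float("nan")
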