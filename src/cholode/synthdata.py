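"""Synthetic data with the statistical structure of the MS study design.

The generator draws a ground-truth parameter set for a network, simulates
every condition of the perturbation roster to its quasi-steady state, and
emits replicate-level raw signals with multiplicative lognormal noise:
biological replicates at the configured CV (default 20%, matching the
replicate CVs reported for the MS platforms) and, for metabolite-class
analytes, nested technical replicates at a quarter of that CV.  Signals are
emitted on the model's own [0, 1] scale with known calibration anchors, so
class-based scaling is exactly invertible and zero-noise datasets reproduce
the simulated states.

Also provides the reduced toy network used for fast fitting tests, the
23-condition cholesterol perturbation roster, planted-divergence scenarios
for power analyses of the ensemble comparison, and synthetic identification
tables for the MS statistics module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import ScaledDataset, flag_differential, scale_signals
from .logic_ode import (
    CompiledModel,
    ConditionInput,
    ParameterVector,
    SimulationError,
    compile_model,
)
from .pkn import (
    METABOLITE_CATEGORIES,
    NetworkEdge,
    NetworkNode,
    PriorKnowledgeNetwork,
    cholesterol_pkn,
)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "toy_network",
    "toy_conditions",
    "cholesterol_conditions",
    "generate_ground_truth",
    "simulate_dataset",
    "make_divergence_scenario",
    "draw_parameter_ensemble",
    "generate_id_table",
]


# ---------------------------------------------------------------------------
# Condition rosters
# ---------------------------------------------------------------------------

def cholesterol_conditions() -> dict[str, ConditionInput]:
    """The 23-condition perturbation design of the cholesterol model.

    Two doses of each drug (scaled to the high dose), sterol depletion via
    lipoprotein-deficient medium (a low clamped medium-cholesterol level),
    its combinations with the statin, two independent siRNAs per target
    gene, the combined SREBF1/2 knockdown, and the untreated control (the
    vehicle controls are input-identical to it).  Drug treatments run on
    the 48 h horizon, siRNA treatments on the 72 h horizon.
    """
    c = ConditionInput
    conditions = [
        c("untreated", {}),
        c("atorva_low", {"AtorvaEx": 0.2}),
        c("atorva_high", {"AtorvaEx": 1.0}),
        c("t09_low", {"T09Ex": 0.2}),
        c("t09_high", {"T09Ex": 1.0}),
        c("gw_low", {"GWEx": 0.2}),
        c("gw_high", {"GWEx": 1.0}),
        c("hc25_low", {"HC25": 0.5}),
        c("hc25_high", {"HC25": 1.0}),
        c("lpds", {"CholMedia": 0.05}),
        c("lpds_atorva_low", {"CholMedia": 0.05, "AtorvaEx": 0.1}),
        c("lpds_atorva_high", {"CholMedia": 0.05, "AtorvaEx": 0.5}),
        c("si_srebf1_a", {"siSREBF1": 0.8}, "72h"),
        c("si_srebf1_b", {"siSREBF1": 0.7}, "72h"),
        c("si_srebf2_a", {"siSREBF2": 0.8}, "72h"),
        c("si_srebf2_b", {"siSREBF2": 0.7}, "72h"),
        c("si_ldlr_a", {"siLDLR": 0.8}, "72h"),
        c("si_ldlr_b", {"siLDLR": 0.7}, "72h"),
        c("si_npc1_a", {"siNPC1": 0.8}, "72h"),
        c("si_npc1_b", {"siNPC1": 0.7}, "72h"),
        c("si_hmgcs1_a", {"siHMGCS1": 0.8}, "72h"),
        c("si_hmgcs1_b", {"siHMGCS1": 0.7}, "72h"),
        c("si_srebf12", {"siSREBF1": 0.75, "siSREBF2": 0.75}, "72h"),
    ]
    return {cond.id: cond for cond in conditions}


def toy_conditions() -> dict[str, ConditionInput]:
    """Factorial stimulus x inhibitor design for the reduced toy network."""
    c = ConditionInput
    conditions = [
        c("untreated", {}),
        c("stim", {"S": 1.0}),
        c("drug", {"D": 1.0}),
        c("stim_drug", {"S": 1.0, "D": 1.0}),
    ]
    return {cond.id: cond for cond in conditions}


def toy_network() -> PriorKnowledgeNetwork:
    """A reduced 8-node model for fast fitting experiments.

    A repressive stimulus (sterol-like) controls a transcription factor
    that is constitutively active without it and induces two enzymes; a
    three-metabolite chain (constant source, enzyme-catalyzed conversion,
    saturable second step competitively inhibited by a clamped drug input,
    first-order drains) mirrors the structure of the cholesterol synthesis
    branch at a fraction of the cost.
    """
    N, E = NetworkNode, NetworkEdge
    nodes = [
        N("S", "stimulus", "stimulus", initial_level=0.0),
        N("D", "inhibitor drug", "drug_extracellular", initial_level=0.0),
        N("TF", "transcription factor", "protein", measured=True),
        N("E1", "enzyme 1", "protein", measured=True),
        N("E2", "enzyme 2", "protein", measured=True),
        N("M1", "metabolite 1", "metabolite_intracellular", measured=True, species="M1"),
        N("M2", "metabolite 2", "metabolite_intracellular", measured=True, species="M2"),
        N("M3", "metabolite 3", "metabolite_intracellular", measured=True, species="M3"),
    ]
    edges = [
        E("S~TF", (("S", -1),), "TF"),
        E("TF>E1", (("TF", 1),), "E1"),
        E("TF>E2", (("TF", 1),), "E2"),
        E("R_src", (("M1", 1),), "M1", mechanism="mass_action",
          parameter_names=("k_src",)),
        E("R_cat", (("E1", 1), ("M1", 1)), "M2", mechanism="mass_action",
          parameter_names=("k_cat",)),
        E("R_mm", (("M2", 1), ("E2", 1), ("D", -1)), "M3",
          mechanism="michaelis_menten_inhibited",
          parameter_names=("k_mm", "kM_mm", "kI_mm")),
        E("R_deg1", (("M1", -1),), "M1", mechanism="mass_action",
          parameter_names=("k_deg1",)),
        E("R_deg3", (("M3", -1),), "M3", mechanism="mass_action",
          parameter_names=("k_deg3",)),
    ]
    return PriorKnowledgeNetwork(nodes, edges, name="toy")


def default_conditions(network: PriorKnowledgeNetwork) -> dict[str, ConditionInput]:
    if network.name == "cholesterol":
        return cholesterol_conditions()
    if network.name == "toy":
        return toy_conditions()
    raise ValueError(f"no default condition roster for network {network.name!r}")


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic measurement campaign."""

    truth_seed: int = 1
    measurement_seed: int = 2
    cv: float = 0.20  # biological replicate CV (lognormal, mean-preserving)
    cv_technical: float | None = None  # defaults to cv / 4
    n_bio_protein: int = 3
    n_bio_metabolite: int = 3
    n_tech_metabolite: int = 2
    cell_line: str = "synthetic"
    differential_min_shift: float = 0.2

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be non-negative")

    @property
    def tech_cv(self) -> float:
        return self.cv / 4 if self.cv_technical is None else self.cv_technical


@dataclass
class GroundTruth:
    """Generating parameters plus noise-free terminal states per condition."""

    params: ParameterVector
    terminal_states: dict[str, dict[str, float]]
    conditions: dict[str, ConditionInput]
    seed: int


_ANALYTE_CLASS = {
    "protein": "protein",
    "activity": "protein",
    "metabolite_intracellular": "endogenous_metabolite",
    "metabolite_extracellular": "endogenous_metabolite",
    "drug_intracellular": "drug_or_drug_metabolite",
    "drug_extracellular": "drug_or_drug_metabolite",
}


def generate_ground_truth(
    network: PriorKnowledgeNetwork,
    seed: int,
    conditions: Mapping[str, ConditionInput] | None = None,
    max_retries: int = 100,
    ss_tol: float = 1e-4,
) -> GroundTruth:
    """Draw generating parameters uniformly within bounds, with rejection.

    A draw is kept only if every roster condition integrates successfully,
    the untreated condition reaches a quasi-steady state, and all measured
    terminal levels stay within the model's [0, 1] scale (which keeps the
    class-based scaling exactly invertible).  Deterministic given the seed.
    """
    conditions = dict(conditions or default_conditions(network))
    template = ParameterVector.from_network(network)
    model = compile_model(network, template)
    rng = np.random.default_rng(seed)
    free = ~template.fixed
    lo, hi = template.lower[free], template.upper[free]

    for _ in range(max_retries):
        draw = rng.uniform(lo, hi)
        params = template.with_free_values(draw)
        try:
            terminal: dict[str, dict[str, float]] = {}
            ok = True
            for cond in conditions.values():
                res = model.simulate(params, cond, ss_tol=ss_tol)
                if cond.id == "untreated" and not res.converged:
                    ok = False
                    break
                term = res.terminal
                if any(
                    term[n] > 1.0 + 1e-9 for n in network.measured_nodes
                ):
                    ok = False
                    break
                terminal[cond.id] = term
            if ok:
                return GroundTruth(params, terminal, conditions, seed)
        except SimulationError:
            continue
    raise RuntimeError(
        f"no convergent parameter draw within {max_retries} retries (seed {seed})"
    )


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _lognormal_factors(rng, cv: float, size) -> np.ndarray:
    """Mean-preserving multiplicative noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = math.log1p(cv**2)
    sigma = math.sqrt(sigma2)
    return np.exp(rng.normal(-sigma2 / 2.0, sigma, size=size))


def simulate_dataset(
    network: PriorKnowledgeNetwork,
    ground_truth: GroundTruth,
    config: SynthConfig | None = None,
) -> tuple[pd.DataFrame, ScaledDataset]:
    """Emit a raw replicate-level signal table and its scaled dataset.

    Raw signals are ``terminal level x lognormal noise``; metabolite-class
    analytes additionally receive nested technical-replicate noise which is
    averaged back out during scaling.  The scaled dataset carries
    differential flags (mean shift vs. untreated beyond the configured
    threshold) with the higher objective weight.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.measurement_seed)
    rows = []
    measured = [network.nodes[n] for n in network.measured_nodes]
    for cond_id in sorted(ground_truth.terminal_states):
        term = ground_truth.terminal_states[cond_id]
        for node in measured:
            cls = _ANALYTE_CLASS[node.category]
            level = max(float(term[node.id]), 0.0)
            if cls == "protein":
                n_bio, n_tech = config.n_bio_protein, 1
            else:
                n_bio, n_tech = config.n_bio_metabolite, config.n_tech_metabolite
            bio = level * _lognormal_factors(rng, config.cv, n_bio)
            for b in range(n_bio):
                tech = bio[b] * _lognormal_factors(rng, config.tech_cv, n_tech)
                for t in range(n_tech):
                    rows.append(
                        {
                            "analyte": node.id,
                            "class": cls,
                            "cell_line": config.cell_line,
                            "condition": cond_id,
                            "bio_rep": b,
                            "tech_rep": t,
                            "signal": tech[t],
                        }
                    )
    raw = pd.DataFrame(rows)
    ranges = {node.id: (0.0, 1.0) for node in measured}
    dataset = scale_signals(
        raw,
        roster=ground_truth.conditions,
        ranges=ranges,
        name=f"{network.name}:{config.cell_line}",
    )
    if "untreated" in dataset.conditions:
        dataset = flag_differential(
            dataset,
            control_condition="untreated",
            min_shift=config.differential_min_shift,
        )
    return raw, dataset


# ---------------------------------------------------------------------------
# Divergence scenarios and synthetic ensembles
# ---------------------------------------------------------------------------

def make_divergence_scenario(
    network: PriorKnowledgeNetwork,
    base_truth: GroundTruth,
    shifts: Mapping[str, float],
    n_lines: int = 4,
    shifted_line: int | None = None,
) -> dict[str, GroundTruth]:
    """Cell-line ground truths identical except for planted parameter shifts.

    All lines share ``base_truth``; the designated line (default: the last)
    has the listed parameters shifted by the given amounts.  Shifts must
    stay within the shared bounds.  This is the known-answer construction
    for divergence-detection power analyses.
    """
    if n_lines < 2:
        raise ValueError("need at least two lines")
    shifted_line = n_lines - 1 if shifted_line is None else shifted_line
    if not 0 <= shifted_line < n_lines:
        raise ValueError("shifted_line out of range")
    model = compile_model(network, base_truth.params)
    out: dict[str, GroundTruth] = {}
    for i in range(n_lines):
        label = f"line{i + 1}"
        if i != shifted_line or not shifts:
            out[label] = base_truth
            continue
        params = base_truth.params.copy()
        idx = params.index
        for name, delta in shifts.items():
            j = idx[name]
            new = params.values[j] + delta
            if not params.lower[j] <= new <= params.upper[j]:
                raise ValueError(
                    f"shift of {name!r} leaves bounds "
                    f"[{params.lower[j]}, {params.upper[j]}]"
                )
            params.values[j] = new
        terminal = {
            cond.id: model.simulate(params, cond).terminal
            for cond in base_truth.conditions.values()
        }
        out[label] = GroundTruth(params, terminal, dict(base_truth.conditions), base_truth.seed)
    return out


def draw_parameter_ensemble(
    truth: GroundTruth | ParameterVector,
    sd: float,
    n: int = 100,
    seed: int = 0,
    free_only: bool = True,
) -> pd.DataFrame:
    """Gaussian parameter draws around a ground truth, clipped to bounds.

    Emulates the member-to-member spread of a fitted bootstrap ensemble
    without the cost of refitting; used for calibration and power analyses
    of the ensemble comparison.
    """
    params = truth.params if isinstance(truth, GroundTruth) else truth
    rng = np.random.default_rng(seed)
    mask = ~params.fixed if free_only else np.ones(len(params.names), dtype=bool)
    names = [n_ for n_, m in zip(params.names, mask) if m]
    center = params.values[mask]
    lo, hi = params.lower[mask], params.upper[mask]
    draws = rng.normal(center, sd, size=(n, len(names)))
    draws = np.clip(draws, lo, hi)
    return pd.DataFrame(draws, columns=names)


# ---------------------------------------------------------------------------
# Identification-table fixture generator
# ---------------------------------------------------------------------------

def generate_id_table(
    seed: int,
    n_target: int = 100,
    n_decoy: int = 5,
    n_runs: int = 6,
    n_conditions: int = 2,
    pass_rate: float = 0.7,
    decoy_pass_rate: float = 0.1,
    m_threshold: float = 1e-5,
    shared_fraction: float = 0.1,
    peptides_per_protein: int = 3,
) -> pd.DataFrame:
    """Seeded synthetic identification table for the MS statistics module.

    Every run contains one row per target and decoy precursor; each
    precursor passes the m-score threshold in a run with the configured
    probability.  A fraction of peptides is marked non-proteotypic
    (shared), and intensities are lognormal.
    """
    if min(n_target, n_decoy, n_runs) < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    shared = rng.random(n_target) < shared_fraction
    for run in range(n_runs):
        condition = f"c{run % n_conditions}"
        bio_rep = run // n_conditions
        for i in range(n_target + n_decoy):
            decoy = i >= n_target
            rate = decoy_pass_rate if decoy else pass_rate
            passes = rng.random() < rate
            m_score = (
                rng.uniform(m_threshold / 100, m_threshold)
                if passes
                else rng.uniform(1e-3, 1.0)
            )
            pid = f"DECOY_pep{i - n_target}" if decoy else f"pep{i}"
            protein = (
                f"DECOY_prot{(i - n_target) // peptides_per_protein}"
                if decoy
                else f"prot{i // peptides_per_protein}"
            )
            rows.append(
                {
                    "precursor": pid,
                    "protein": protein,
                    "is_decoy": decoy,
                    "proteotypic": bool(decoy or not shared[i % n_target]) if n_target else True,
                    "m_score": m_score,
                    "run": f"run{run}",
                    "condition": condition,
                    "bio_rep": bio_rep,
                    "intensity": float(rng.lognormal(9.0, 1.0)),
                    "rt": float(rng.uniform(0.0, 7200.0)),
                }
            )
    return pd.DataFrame(rows)
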