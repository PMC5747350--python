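"""Cross-cell-line comparison of fitted parameter ensembles.

A functional interaction is called divergent between cell lines when the
ensembles of its parameters separate strongly and significantly: the
maximum pairwise Cohen's d exceeds a threshold (default 4) and the
Benjamini-Hochberg adjusted p-value of a Kruskal-Wallis rank test across
all cell lines falls below a threshold (default 1e-10).  Fixed parameters
are excluded.  Transfer-function curves of the ensemble members, with
quantile bands, summarize what a divergent edge does to the model's
input-output behavior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .logic_ode import hill_transfer
from .objective_fit import Ensemble
from .pkn import PriorKnowledgeNetwork

__all__ = [
    "cohens_d",
    "kruskal_wallis",
    "compare_ensembles",
    "divergent_edges",
    "TransferCurve",
    "transfer_curves",
]


def cohens_d(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Absolute standardized mean difference with pooled SD.

    ``|mean_a - mean_b| / s_p`` with
    ``s_p = sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2))``.
    With zero pooled SD the effect size is 0 for equal means and the
    ``inf`` sentinel otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("cohens_d requires at least two values per sample")
    diff = abs(a.mean() - b.mean())
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled_var <= 0:
        return 0.0 if diff == 0 else float("inf")
    return float(diff / np.sqrt(pooled_var))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction and its chi-squared p-value.

    Degenerate input (all values identical across groups) yields
    ``(0.0, 1.0)`` instead of raising.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    if any(len(g) < 1 for g in arrays):
        raise ValueError("each group needs at least one value")
    if sum(len(g) for g in arrays) < 3:
        raise ValueError("too few observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


@dataclass
class ParameterComparison:
    """Per-parameter cross-cell-line divergence summary."""

    parameter: str
    summaries: pd.DataFrame  # per cell line: n, mean, sd, median
    max_cohens_d: float
    kw_h: float
    p_value: float
    adjusted_p: float
    divergent: bool


def _parameter_table(ensemble) -> pd.DataFrame:
    """Accept an Ensemble or a ready models-by-parameters DataFrame."""
    if isinstance(ensemble, Ensemble):
        return ensemble.parameter_table(free_only=True)
    if isinstance(ensemble, pd.DataFrame):
        return ensemble
    raise TypeError(f"cannot interpret {type(ensemble).__name__} as an ensemble")


def compare_ensembles(
    ensembles: Mapping[str, object],
    d_threshold: float = 4.0,
    p_threshold: float = 1e-10,
    adjustment: str = "fdr_bh",
    effect_mode: str = "max_pairwise",
) -> pd.DataFrame:
    """Flag parameters that differ strongly between cell-line ensembles.

    ``ensembles`` maps a cell-line label to an :class:`Ensemble` (fixed
    parameters are dropped) or to a models-by-parameters DataFrame.  Per
    free parameter a Kruskal-Wallis test across all cell lines is
    BH-adjusted across parameters, and the effect size is the maximum
    pairwise Cohen's d (``effect_mode='one_vs_rest'`` compares each line
    against the pooled others instead).  The result is sorted by effect
    size, descending.
    """
    if len(ensembles) < 2:
        raise ValueError("need at least two ensembles to compare")
    if effect_mode not in ("max_pairwise", "one_vs_rest"):
        raise ValueError(f"unknown effect_mode {effect_mode!r}")
    tables = {label: _parameter_table(e) for label, e in ensembles.items()}
    labels = list(tables)
    names = list(tables[labels[0]].columns)
    for label, tbl in tables.items():
        if list(tbl.columns) != names:
            raise ValueError(f"ensemble {label!r} has mismatched parameter names")

    rows = []
    p_values = []
    for name in names:
        samples = {label: tables[label][name].to_numpy(dtype=float) for label in labels}
        h, p = kruskal_wallis(list(samples.values()))
        if effect_mode == "max_pairwise":
            d = 0.0
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    d = max(d, cohens_d(samples[labels[i]], samples[labels[j]]))
        else:
            d = 0.0
            for i, label in enumerate(labels):
                rest = np.concatenate([samples[l] for l in labels if l != label])
                d = max(d, cohens_d(samples[label], rest))
        row = {"parameter": name, "cohens_d": d, "kw_h": h, "p_value": p}
        for label in labels:
            s = samples[label]
            row[f"mean_{label}"] = s.mean()
            row[f"sd_{label}"] = s.std(ddof=1)
            row[f"median_{label}"] = np.median(s)
            row[f"n_{label}"] = len(s)
        rows.append(row)
        p_values.append(p)

    df = pd.DataFrame(rows)
    if len(df) == 1:
        df["adjusted_p"] = df["p_value"]
    else:
        df["adjusted_p"] = multipletests(p_values, method=adjustment)[1]
    df["divergent"] = (df["cohens_d"] > d_threshold) & (df["adjusted_p"] < p_threshold)
    return df.sort_values("cohens_d", ascending=False).reset_index(drop=True)


def divergent_edges(
    network: PriorKnowledgeNetwork, comparisons: pd.DataFrame
) -> list[str]:
    """Edges with at least one divergent parameter."""
    flagged = set(comparisons.loc[comparisons["divergent"], "parameter"])
    out = []
    for edge in network.edges.values():
        if flagged & set(edge.parameter_names):
            out.append(edge.id)
    return out


@dataclass
class TransferCurve:
    """Per-member transfer-function curves of one regulatory edge."""

    edge_id: str
    source: str
    grid: np.ndarray
    curves: np.ndarray  # shape (n_members, n_grid)
    quantiles: pd.DataFrame  # columns q10, q25, q50, q75, q90

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, curve in enumerate(self.curves):
            for x, y in zip(self.grid, curve):
                rows.append({"edge": self.edge_id, "member": m, "x": x, "y": y})
        return pd.DataFrame(rows)


def transfer_curves(
    ensemble: Ensemble,
    network: PriorKnowledgeNetwork,
    edge_id: str,
    source: str | None = None,
    grid_size: int = 101,
) -> TransferCurve:
    """Evaluate every ensemble member's Hill transfer along one edge.

    Quantile bands (0.1 / 0.25 / 0.5 / 0.75 / 0.9 across members) summarize
    the ensemble's input-output uncertainty, mirroring the overlay plots
    used to compare cell lines.
    """
    edge = network.edges.get(edge_id)
    if edge is None:
        raise KeyError(f"unknown edge {edge_id!r}")
    if edge.mechanism != "hill_regulatory":
        raise ValueError(f"edge {edge_id!r} is not a regulatory transfer edge")
    if source is None:
        source = edge.sources[0][0]
    if source not in [s for s, _ in edge.sources]:
        raise ValueError(f"{source!r} is not a source of edge {edge_id!r}")
    k_name = f"k_{source}_{edge.target}"
    n_name = f"n_{source}_{edge.target}"
    pnames = dict(zip([s for s, _ in edge.sources], zip(*[iter(edge.parameter_names)] * 2)))
    k_name, n_name = pnames[source]

    grid = np.linspace(0.0, 1.0, grid_size)
    curves = np.array(
        [hill_transfer(grid, f.params[k_name], f.params[n_name]) for f in ensemble.fits]
    )
    qs = np.quantile(curves, [0.1, 0.25, 0.5, 0.75, 0.9], axis=0)
    quantiles = pd.DataFrame(
        {"x": grid, "q10": qs[0], "q25": qs[1], "q50": qs[2], "q75": qs[3], "q90": qs[4]}
    )
    return TransferCurve(edge_id, source, grid, curves, quantiles)
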