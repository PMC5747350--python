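"""Measurement scaling and the MIDAS-backed dataset container.

Raw MS signals are scaled to [0, 1] by analyte class, over the pooled range
of all cell lines and conditions so that between-cell-line differences are
preserved:

* proteins: min-max over the global observed range,
* drugs and drug metabolites: min-max (removes the signal offset),
* endogenous metabolites: 0-to-max (small steady-state variation must not
  blow up into large scaled variation).

Scaled replicate-level values live in a long-format table together with
per-point weights and differential-abundance flags, plus a roster of the
experimental conditions.  Datasets round-trip through a MIDAS-style CSV
(``TR:`` treatment, ``DA:`` acquisition-time, ``DV:`` data-value columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .logic_ode import END_TIMES, ConditionInput

__all__ = [
    "ANALYTE_CLASSES",
    "ScaledDataset",
    "MidasParseError",
    "scale_signals",
    "read_midas",
    "write_midas",
    "augment_pseudo_timepoints",
    "flag_differential",
]

ANALYTE_CLASSES = ("protein", "endogenous_metabolite", "drug_or_drug_metabolite")

RAW_COLUMNS = ["analyte", "class", "cell_line", "condition", "bio_rep", "signal"]


class MidasParseError(ValueError):
    """MIDAS file lacks a required column class or is malformed."""


@dataclass
class ScaledDataset:
    """Replicate-level scaled measurements plus the condition roster.

    ``data`` columns: ``cell_line, node, condition, replicate, value,
    weight, differential``; values are scaled levels in [0, 1].
    """

    data: pd.DataFrame
    roster: dict[str, ConditionInput] = field(default_factory=dict)
    name: str = "dataset"

    def __post_init__(self):
        required = {"cell_line", "node", "condition", "replicate", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        df = self.data.copy()
        if "weight" not in df:
            df["weight"] = 1.0
        if "differential" not in df:
            df["differential"] = False
        if ((df["value"] < -1e-9) | (df["value"] > 1 + 1e-9)).any():
            raise ValueError("scaled values outside [0, 1]")
        if (df["weight"] < 0).any():
            raise ValueError("negative weights")
        self.data = df.reset_index(drop=True)

    # -- views ------------------------------------------------------------
    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.data["cell_line"].unique())

    @property
    def nodes(self) -> list[str]:
        return sorted(self.data["node"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())

    @property
    def n_points(self) -> int:
        return len(self.data)

    def for_cell_line(self, cell_line: str) -> "ScaledDataset":
        sub = self.data[self.data["cell_line"] == cell_line]
        if sub.empty:
            raise KeyError(f"no data for cell line {cell_line!r}")
        return ScaledDataset(sub.copy(), dict(self.roster), name=f"{self.name}:{cell_line}")

    def means(self) -> pd.DataFrame:
        """Replicate means with weights/flags per (cell_line, node, condition)."""
        grouped = (
            self.data.groupby(["cell_line", "node", "condition"], sort=True)
            .agg(value=("value", "mean"), weight=("weight", "max"),
                 differential=("differential", "any"), n=("value", "size"))
            .reset_index()
        )
        return grouped

    def copy(self) -> "ScaledDataset":
        return ScaledDataset(self.data.copy(), dict(self.roster), name=self.name)

    def missing_measured_nodes(self, network) -> list[str]:
        """Measured network nodes absent from this dataset."""
        present = set(self.data["node"].unique())
        return [n for n in network.measured_nodes if n not in present]


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

def scale_signals(
    raw: pd.DataFrame,
    roster: Mapping[str, ConditionInput] | None = None,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    name: str = "scaled",
) -> ScaledDataset:
    """Scale raw signals to [0, 1] by analyte class.

    ``raw`` needs columns ``analyte, class, cell_line, condition, bio_rep,
    signal`` (an optional ``tech_rep`` column is averaged into the
    biological replicate after scaling).  ``ranges`` optionally pins the
    scaling range per analyte (used by the synthetic generator, whose
    signals are emitted on a known scale); otherwise the range is the
    observed one pooled over all cell lines and conditions.

    Analytes with a degenerate range (max == min under a min-max rule, or
    max == 0 under the 0-to-max rule) are assigned the uninformative level
    0.5 with zero weight instead of raising.
    """
    missing = [c for c in RAW_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"raw table missing columns {missing}")
    bad = set(raw["class"].unique()) - set(ANALYTE_CLASSES)
    if bad:
        raise ValueError(f"unknown analyte classes {sorted(bad)}")
    if (raw["signal"] < 0).any():
        raise ValueError("negative raw signals")

    out_rows = []
    for analyte, grp in raw.groupby("analyte", sort=True):
        cls = grp["class"].iloc[0]
        sig = grp["signal"].to_numpy(dtype=float)
        if ranges is not None and analyte in ranges:
            lo, hi = map(float, ranges[analyte])
        elif cls == "endogenous_metabolite":
            lo, hi = 0.0, float(sig.max())
        else:
            lo, hi = float(sig.min()), float(sig.max())
        if cls == "endogenous_metabolite":
            lo = 0.0
        degenerate = hi <= lo
        if degenerate:
            scaled = np.full(len(sig), 0.5)
            weight = 0.0
        else:
            scaled = np.clip((sig - lo) / (hi - lo), 0.0, 1.0)
            weight = 1.0
        sub = grp.copy()
        sub["value"] = scaled
        sub["weight"] = weight
        out_rows.append(sub)
    df = pd.concat(out_rows, ignore_index=True)

    if "tech_rep" in df.columns:
        df = (
            df.groupby(["analyte", "cell_line", "condition", "bio_rep"], sort=True)
            .agg(value=("value", "mean"), weight=("weight", "min"))
            .reset_index()
        )
    data = pd.DataFrame(
        {
            "cell_line": df["cell_line"],
            "node": df["analyte"],
            "condition": df["condition"],
            "replicate": df["bio_rep"],
            "value": df["value"],
            "weight": df["weight"],
            "differential": False,
        }
    )
    return ScaledDataset(data, dict(roster or {}), name=name)


def flag_differential(
    dataset: ScaledDataset,
    control_condition: str = "untreated",
    min_shift: float = 0.2,
    weight: float = 2.0,
) -> ScaledDataset:
    """Flag (node, condition) cells whose mean deviates from the control.

    Flagged points get the higher ``weight`` so that the objective
    emphasizes the perturbations a node actually responded to.
    """
    out = dataset.copy()
    df = out.data
    means = df.groupby(["cell_line", "node", "condition"])['value'].mean()
    for (cl, node, cond), m in means.items():
        if cond == control_condition:
            continue
        try:
            base = means.loc[(cl, node, control_condition)]
        except KeyError:
            continue
        if abs(m - base) > min_shift:
            mask = (
                (df["cell_line"] == cl)
                & (df["node"] == node)
                & (df["condition"] == cond)
                & (df["weight"] > 0)
            )
            df.loc[mask, "differential"] = True
            df.loc[mask, "weight"] = weight
    return out


# ---------------------------------------------------------------------------
# Pseudo-timepoints
# ---------------------------------------------------------------------------

def augment_pseudo_timepoints(
    baseline: float,
    final: float,
    fractions: Sequence[float] = (0.5, 0.8, 0.9),
    pseudo_weight: float = 0.5,
) -> list[tuple[float, float]]:
    """Interpolated anti-oscillation anchors between baseline and endpoint.

    Returns ``(level, weight)`` pairs at the given fractions of the total
    difference in abundance; the reduced weight keeps them subordinate to
    measured points.  They discourage biologically unexpected oscillations
    by asserting a monotone approach to the endpoint.
    """
    if not 0.0 <= baseline <= 1.0 or not 0.0 <= final <= 1.0:
        raise ValueError("baseline and final must lie in [0, 1]")
    delta = final - baseline
    return [(baseline + f * delta, pseudo_weight) for f in fractions]


# ---------------------------------------------------------------------------
# MIDAS I/O
# ---------------------------------------------------------------------------

def write_midas(dataset: ScaledDataset, path: str | Path | None = None) -> str:
    """Serialize to a MIDAS-style CSV.

    One row per (cell line, condition, replicate); ``TR:`` columns carry
    the clamped input levels from the roster, ``DA:ALL`` the acquisition
    time (the simulation horizon), and one ``DV:`` column per node.  ``ID:``
    columns preserve the condition id, replicate index and cell line, which
    plain MIDAS would force us to re-derive from the treatment pattern.
    """
    inputs = sorted({k for c in dataset.roster.values() for k in c.inputs})
    if not inputs:
        inputs = ["none"]
    nodes = dataset.nodes
    rows = []
    for (cl, cond, rep), grp in dataset.data.groupby(
        ["cell_line", "condition", "replicate"], sort=True
    ):
        roster_entry = dataset.roster.get(cond)
        row: dict[str, object] = {
            "ID:cell_line": cl,
            "ID:condition": cond,
            "ID:replicate": rep,
        }
        for inp in inputs:
            level = 0.0
            if roster_entry is not None:
                level = float(roster_entry.inputs.get(inp, 0.0))
            row[f"TR:{inp}"] = level
        row["DA:ALL"] = roster_entry.end_time if roster_entry is not None else END_TIMES["48h"]
        vals = dict(zip(grp["node"], grp["value"]))
        for node in nodes:
            row[f"DV:{node}"] = vals.get(node, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    text = df.to_csv(index=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def read_midas(path: str | Path, name: str | None = None) -> ScaledDataset:
    """Read a MIDAS-style CSV written by :func:`write_midas`."""
    path = Path(path)
    df = pd.read_csv(path)
    tr_cols = [c for c in df.columns if c.startswith("TR:")]
    da_cols = [c for c in df.columns if c.startswith("DA:")]
    dv_cols = [c for c in df.columns if c.startswith("DV:")]
    if not dv_cols:
        raise MidasParseError("no DV: (data value) columns")
    if not tr_cols:
        raise MidasParseError("no TR: (treatment) columns")
    if not da_cols:
        raise MidasParseError("no DA: (acquisition time) columns")

    cell_col = "ID:cell_line" if "ID:cell_line" in df.columns else None
    cond_col = "ID:condition" if "ID:condition" in df.columns else None
    rep_col = "ID:replicate" if "ID:replicate" in df.columns else None

    horizon_of_time = {v: k for k, v in END_TIMES.items()}
    roster: dict[str, ConditionInput] = {}
    records = []
    for i, row in df.iterrows():
        cond = str(row[cond_col]) if cond_col else _condition_key(row, tr_cols)
        if cond not in roster:
            inputs = {
                c[3:]: float(row[c])
                for c in tr_cols
                if c != "TR:none" and float(row[c]) != 0.0
            }
            end_time = float(row[da_cols[0]])
            horizon = horizon_of_time.get(end_time, "48h")
            roster[cond] = ConditionInput(cond, inputs, horizon)
        cl = str(row[cell_col]) if cell_col else "cell"
        rep = row[rep_col] if rep_col else i
        for c in dv_cols:
            value = row[c]
            if pd.isna(value):
                continue
            records.append(
                {
                    "cell_line": cl,
                    "node": c[3:],
                    "condition": cond,
                    "replicate": rep,
                    "value": float(value),
                    "weight": 1.0,
                    "differential": False,
                }
            )
    if not records:
        raise MidasParseError("no data values present")
    return ScaledDataset(pd.DataFrame(records), roster, name=name or path.stem)


def _condition_key(row, tr_cols) -> str:
    parts = [f"{c[3:]}={float(row[c]):g}" for c in tr_cols if float(row[c]) != 0.0]
    return "+".join(parts) if parts else "untreated"
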