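"""Post-processing statistics for DIA proteomics and untargeted metabolomics.

Implements the bespoke decision rules applied downstream of feature
extraction: decoy-based FDR estimation with a fraction-of-false-targets
(FFT / pi0) correction, m-score presence filters, proteotypic top-k peptide
selection, total-intensity normalization (global or within retention-time
windows), the dual-control differential-abundance rule, nested
(hierarchical) replicate statistics, and exact-mass metabolite annotation
of flow-injection ions with a three-step filter.

Identification tables are plain :class:`pandas.DataFrame` objects with the
columns of an identification record: ``precursor, protein, is_decoy,
proteotypic, m_score, run, condition, bio_rep, intensity, rt``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FdrEstimate",
    "IonAnnotation",
    "estimate_fdr",
    "filter_by_presence",
    "select_quant_peptides",
    "total_intensity_normalize",
    "differential_call",
    "nested_cv",
    "nested_anova",
    "annotate_ions",
    "load_toy_table",
    "PROTON_MASS",
    "FLUORIDE_MASS",
]

#: mass of a proton (Da); [M-H]- ions appear at M - PROTON_MASS
PROTON_MASS = 1.00727646
#: monoisotopic mass of fluorine (Da); [M+F]- adducts appear at M + FLUORIDE_MASS
FLUORIDE_MASS = 18.99840322

ADDUCT_SHIFTS = {"[M-H]-": -PROTON_MASS, "[M+F]-": FLUORIDE_MASS}


def load_toy_table(name: str) -> pd.DataFrame:
    """Load a packaged toy table (id_toy, peptides_toy, ions_toy,
    reference_masses)."""
    path = Path(resources.files("cholode").joinpath("data").joinpath("msprep"))
    return pd.read_csv(path / f"{name}.csv")


# ---------------------------------------------------------------------------
# Decoy FDR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FdrEstimate:
    """Decoy-based FDR at one identification level."""

    level: str
    n_targets: int
    n_decoys: int
    fft: float
    fdr: float


def estimate_fdr(
    n_targets: int, n_decoys: int, fft: float, level: str = "peptide"
) -> FdrEstimate:
    """FDR = FFT * decoys / targets.

    The FFT (fraction of false targets, a pi0 estimate) corrects for decoy
    hits overestimating the false-target population.  Reported at full
    precision; round at the call site.
    """
    if n_targets < 1:
        raise ValueError("need at least one target identification")
    if n_decoys < 0:
        raise ValueError("decoy count cannot be negative")
    if not 0.0 < fft <= 1.0:
        raise ValueError("fft must lie in (0, 1]")
    return FdrEstimate(level, int(n_targets), int(n_decoys), float(fft),
                       float(fft) * n_decoys / n_targets)


# ---------------------------------------------------------------------------
# Presence filtering and peptide selection
# ---------------------------------------------------------------------------

def filter_by_presence(
    records: pd.DataFrame,
    m_threshold: float,
    rule: tuple[str, float] = ("fraction_of_files", 0.2),
) -> list:
    """Precursors passing the m-score threshold often enough to keep.

    ``rule`` is either ``("fraction_of_files", q)`` — the precursor must
    pass (m_score <= threshold) in at least ``q`` of all runs — or
    ``("replicates_in_condition", r)`` — it must pass in at least ``r``
    biological replicates of at least one condition.  Boundaries are
    inclusive.  Returns the sorted surviving precursor ids.
    """
    kind, value = rule
    if kind == "fraction_of_files":
        if not 0.0 < value <= 1.0:
            raise ValueError("fraction of files must lie in (0, 1]")
        n_files = records["run"].nunique()
        passing = records[records["m_score"] <= m_threshold]
        counts = passing.groupby("precursor")["run"].nunique()
        survivors = counts[counts >= value * n_files - 1e-9].index
    elif kind == "replicates_in_condition":
        if value < 1:
            raise ValueError("replicate count must be >= 1")
        passing = records[records["m_score"] <= m_threshold]
        counts = passing.groupby(["precursor", "condition"])["bio_rep"].nunique()
        per_prec = counts.groupby("precursor").max()
        survivors = per_prec[per_prec >= value].index
    else:
        raise ValueError(f"unknown presence rule {kind!r}")
    return sorted(survivors)


def select_quant_peptides(records: pd.DataFrame, top_k: int = 7) -> pd.DataFrame:
    """Proteotypic peptides only, the ``top_k`` by total signal per protein.

    Shared (non-proteotypic) peptides are removed regardless of signal.
    Ties in total signal break lexicographically on the peptide id, which
    keeps the selection deterministic.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    proto = records[records["proteotypic"].astype(bool)]
    totals = (
        proto.groupby(["protein", "precursor"], sort=True)["intensity"].sum().reset_index()
    )
    keep: set = set()
    for protein, grp in totals.groupby("protein", sort=True):
        ranked = grp.sort_values(
            ["intensity", "precursor"], ascending=[False, True], kind="mergesort"
        )
        keep.update(ranked["precursor"].head(top_k))
    return proto[proto["precursor"].isin(keep)].copy()


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def total_intensity_normalize(
    records: pd.DataFrame,
    mode: str = "global",
    rt_window: float = 600.0,
) -> pd.DataFrame:
    """Divide intensities by their run's total, preserving magnitudes.

    ``global`` uses one total per run; ``rt_windowed`` tiles retention time
    into ``rt_window``-second bins and normalizes within each bin, which
    corrects elution-phase-dependent intensity drifts.  After division the
    values are rescaled by the cross-run mean total so the output stays on
    the input scale.
    """
    out = records.copy()
    if mode == "global":
        totals = out.groupby("run")["intensity"].transform("sum")
        run_totals = out.groupby("run")["intensity"].sum()
        if (run_totals <= 0).any():
            bad = run_totals[run_totals <= 0].index.tolist()
            raise ValueError(f"zero total intensity in runs {bad}")
        out["intensity"] = out["intensity"] / totals * run_totals.mean()
        return out
    if mode != "rt_windowed":
        raise ValueError(f"unknown normalization mode {mode!r}")
    if "rt" not in out.columns or out["rt"].isna().any():
        raise ValueError("rt_windowed normalization requires retention times")
    out["_window"] = (out["rt"] // rt_window).astype(int)
    win_totals = out.groupby(["run", "_window"])["intensity"].sum()
    if (win_totals <= 0).any():
        bad = win_totals[win_totals <= 0].index.tolist()
        raise ValueError(f"zero total intensity in (run, window) {bad}")
    mean_by_window = win_totals.groupby("_window").mean()
    key = list(zip(out["run"], out["_window"]))
    denom = win_totals.loc[key].to_numpy()
    scale = mean_by_window.loc[out["_window"]].to_numpy()
    out["intensity"] = out["intensity"].to_numpy() / denom * scale
    return out.drop(columns="_window")


# ---------------------------------------------------------------------------
# Differential abundance decision
# ---------------------------------------------------------------------------

def differential_call(
    log2fc_vs_untreated,
    log2fc_vs_vehicle=None,
    fdr: float = 1.0,
    fc_threshold: float = 0.5,
    fdr_threshold: float = 0.01,
) -> bool:
    """Dual-control significance rule for one analyte/condition.

    Significant iff the FDR is below the threshold and the log2
    fold change exceeds ``fc_threshold`` in magnitude against the untreated
    control and, when a vehicle control applies, also against the vehicle
    with a consistent sign.  Fold-change arguments may be scalars or
    sequences (e.g. mean and median), in which case every entry must pass.
    """
    def as_array(x):
        arr = np.atleast_1d(np.asarray(x, dtype=float))
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite fold change")
        return arr

    if not np.isfinite(fdr):
        raise ValueError("non-finite FDR")
    if fdr >= fdr_threshold:
        return False
    fc_u = as_array(log2fc_vs_untreated)
    if not np.all(np.abs(fc_u) > fc_threshold):
        return False
    sign = np.sign(fc_u[0])
    if not np.all(np.sign(fc_u) == sign):
        return False
    if log2fc_vs_vehicle is not None:
        fc_v = as_array(log2fc_vs_vehicle)
        if not np.all(np.abs(fc_v) > fc_threshold):
            return False
        if not np.all(np.sign(fc_v) == sign):
            return False
    return True


# ---------------------------------------------------------------------------
# Nested replicate statistics
# ---------------------------------------------------------------------------

def nested_cv(values: Mapping | pd.DataFrame) -> float:
    """Coefficient of variation over biological-replicate means.

    ``values`` maps biological replicate to its technical measurements
    (or is a DataFrame with ``bio_rep`` and ``value`` columns).  Technical
    replicates are averaged first, then CV = SD / mean over the biological
    means (sample SD).
    """
    means = _bio_means(values)
    if len(means) < 2:
        raise ValueError("need at least two biological replicates")
    m = means.mean()
    if m == 0:
        raise ValueError("zero mean signal")
    return float(means.std(ddof=1) / m)


def _bio_means(values) -> np.ndarray:
    if isinstance(values, pd.DataFrame):
        return values.groupby("bio_rep")["value"].mean().to_numpy()
    return np.array([np.mean(np.atleast_1d(v)) for v in values.values()], dtype=float)


def nested_anova(treated: pd.DataFrame, control: pd.DataFrame) -> tuple[float, float]:
    """Two-level nested ANOVA F-test of a treatment effect.

    Technical replicates are nested in biological replicates, which are
    nested in the two groups.  The treatment mean square is tested against
    the biological-replicate mean square:

        F = MS_treatment / MS_bio(treatment),
        df = (1, n_bio_total - 2).

    Each input frame needs ``bio_rep`` and ``value`` columns.  Returns
    ``(F, p)``; identical data in both groups yields ``(0, 1)``.
    """
    groups = []
    for frame in (treated, control):
        reps = [g["value"].to_numpy(dtype=float) for _, g in frame.groupby("bio_rep")]
        if len(reps) < 2:
            raise ValueError("need at least two biological replicates per group")
        groups.append(reps)

    grand = np.concatenate([np.concatenate(reps) for reps in groups])
    grand_mean = grand.mean()
    ss_treat = 0.0
    ss_bio = 0.0
    df_bio = 0
    for reps in groups:
        all_g = np.concatenate(reps)
        g_mean = all_g.mean()
        ss_treat += len(all_g) * (g_mean - grand_mean) ** 2
        for r in reps:
            ss_bio += len(r) * (r.mean() - g_mean) ** 2
        df_bio += len(reps) - 1
    df_treat = 1
    if ss_bio <= 0:
        return (0.0, 1.0) if ss_treat <= 0 else (float("inf"), 0.0)
    f = (ss_treat / df_treat) / (ss_bio / df_bio)
    p = float(stats.f.sf(f, df_treat, df_bio))
    return float(f), p


# ---------------------------------------------------------------------------
# Exact-mass ion annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonAnnotation:
    """One surviving ion-to-metabolite assignment."""

    ion_mass: float
    metabolite: str
    adduct: str
    mass_error: float
    score: float


def annotate_ions(
    ions: pd.DataFrame,
    reference: pd.DataFrame,
    tolerance: float = 0.001,
    intensity_cutoff: float = 1500.0,
    adducts: Sequence[str] = ("[M-H]-", "[M+F]-"),
    excluded_adducts: Sequence[str] = ("NaCl", "H/Na", "H/K"),
) -> list[IonAnnotation]:
    """Exact-mass annotation with the three-step filter.

    ``ions`` needs ``mass`` and ``intensity`` columns; ``reference`` needs
    ``metabolite`` and ``mass`` plus an optional ``mass_type`` column
    (``neutral`` masses are shifted per adduct; ``ion`` masses — e.g. drug
    ions added manually to the reference list — are matched as-is).

    Ions below the intensity cutoff are skipped.  Candidates within the
    mass tolerance are scored (default: negative absolute mass error, so
    the closest match wins), then filtered in three steps: per ion keep
    only top-scoring metabolites, per metabolite keep only the top-scoring
    annotation, and drop salt-exchange adducts.
    """
    if reference.empty:
        raise ValueError("empty reference mass list")
    if (ions["mass"] <= 0).any() or (reference["mass"] <= 0).any():
        raise ValueError("masses must be positive")
    unknown = set(adducts) - (set(ADDUCT_SHIFTS) | set(excluded_adducts))
    if unknown:
        raise ValueError(f"unknown adducts {sorted(unknown)}")

    ref = reference.copy()
    if "mass_type" not in ref.columns:
        ref["mass_type"] = "neutral"

    candidates: list[IonAnnotation] = []
    for _, ion in ions.iterrows():
        if ion["intensity"] < intensity_cutoff:
            continue
        m_ion = float(ion["mass"])
        for _, row in ref.iterrows():
            if row["mass_type"] == "ion":
                expected = {adducts[0]: float(row["mass"])}
            else:
                expected = {
                    a: float(row["mass"]) + ADDUCT_SHIFTS[a]
                    for a in adducts
                    if a in ADDUCT_SHIFTS
                }
            for adduct, m_exp in expected.items():
                err = m_ion - m_exp
                if abs(err) <= tolerance:
                    score = (
                        float(row["score"]) if "score" in ref.columns and pd.notna(row.get("score"))
                        else -abs(err)
                    )
                    candidates.append(
                        IonAnnotation(m_ion, str(row["metabolite"]), adduct, err, score)
                    )

    # step 1: per ion, keep only annotations with the top score
    by_ion: dict[float, list[IonAnnotation]] = {}
    for ann in candidates:
        by_ion.setdefault(ann.ion_mass, []).append(ann)
    step1 = []
    for anns in by_ion.values():
        best = max(a.score for a in anns)
        step1.extend(a for a in anns if a.score >= best - 1e-15)
    # step 2: per metabolite, keep only the top-scoring annotation
    by_met: dict[str, list[IonAnnotation]] = {}
    for ann in step1:
        by_met.setdefault(ann.metabolite, []).append(ann)
    step2 = []
    for anns in by_met.values():
        best = max(a.score for a in anns)
        top = [a for a in anns if a.score >= best - 1e-15]
        # deterministic tie-break: smallest |error|, then adduct name
        top.sort(key=lambda a: (abs(a.mass_error), a.adduct))
        step2.append(top[0])
    # step 3: drop excluded salt-exchange adducts
    final = [a for a in step2 if a.adduct not in set(excluded_adducts)]
    final.sort(key=lambda a: (a.ion_mass, a.metabolite))
    return final
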