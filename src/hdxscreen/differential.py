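"""Ligand-versus-vehicle perturbation statistics.

Computes d%D (compound mean %D minus vehicle mean %D) per peptide-timepoint,
per-cell Welch t-tests, Benjamini-Hochberg FDR adjustment, and the screening
filter that keeps only peptide-timepoints where enough compounds perturb
exchange significantly.

BH adjustment is applied per compound across its peptide-timepoint family by
default (each compound's perturbation signature is tested against zero as
one family); a global scope over all compounds is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DeltaResult",
    "SignificanceConfig",
    "delta_percent_D",
    "bh_adjust",
    "compute_perturbations",
    "to_matrix",
    "significance_filter",
    "mean_perturbation_over_timepoints",
]

RECORD_COLUMNS = [
    "compound",
    "peptide_id",
    "timepoint_s",
    "delta_percent_d",
    "t_statistic",
    "p_value",
    "adjusted_p",
    "significant",
    "n_treated",
    "n_vehicle",
    "zero_variance",
]


@dataclass(frozen=True)
class DeltaResult:
    delta: float
    t_statistic: float
    p_value: float
    zero_variance: bool = False


@dataclass(frozen=True)
class SignificanceConfig:
    """Thresholds for calling and filtering significant perturbations.

    Exactly one of ``min_significant_compounds`` (absolute count, default
    15) and ``min_significant_fraction`` may be active.  The optional
    ``magnitude_threshold`` (percentage points of |d%D|) defaults to off.
    ``bh_scope`` is ``"per_compound"`` or ``"global"``.
    """

    fdr_threshold: float = 0.05
    magnitude_threshold: float = 0.0
    min_significant_compounds: int | None = 15
    min_significant_fraction: float | None = None
    bh_scope: str = "per_compound"

    def __post_init__(self) -> None:
        if self.fdr_threshold < 0 or self.magnitude_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if (self.min_significant_compounds is None) == (
            self.min_significant_fraction is None
        ):
            raise ValueError(
                "exactly one of min_significant_compounds and "
                "min_significant_fraction must be set"
            )
        if self.bh_scope not in ("per_compound", "global"):
            raise ValueError("bh_scope must be 'per_compound' or 'global'")

    def required_count(self, n_compounds: int) -> int:
        if self.min_significant_compounds is not None:
            return self.min_significant_compounds
        return math.ceil(self.min_significant_fraction * n_compounds)


def delta_percent_D(
    treated, vehicle, require_p: bool = True
) -> DeltaResult:
    """Mean difference and Welch two-sample two-tailed t-test.

    ``delta = mean(treated) - mean(vehicle)``.  With ``require_p`` each arm
    needs at least two replicates; when both arms have zero variance and
    equal means the p-value is reported as 1.0 with ``zero_variance`` set.
    """
    t_arr = np.asarray(treated, dtype=float)
    v_arr = np.asarray(vehicle, dtype=float)
    if t_arr.size < 1 or v_arr.size < 1:
        raise ValueError("each arm needs at least one replicate")
    delta = float(t_arr.mean() - v_arr.mean())
    if not require_p:
        return DeltaResult(delta, float("nan"), float("nan"))
    if t_arr.size < 2 or v_arr.size < 2:
        raise ValueError(
            "insufficient replication: two replicates per arm are required "
            "for a p-value"
        )
    if t_arr.var(ddof=1) == 0.0 and v_arr.var(ddof=1) == 0.0:
        if delta == 0.0:
            return DeltaResult(delta, 0.0, 1.0, zero_variance=True)
        t_stat = math.inf if delta > 0 else -math.inf
        return DeltaResult(delta, t_stat, 0.0, zero_variance=True)
    res = stats.ttest_ind(t_arr, v_arr, equal_var=False)
    return DeltaResult(delta, float(res.statistic), float(res.pvalue))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Adjusted values are monotone transforms of the raw ones (>= raw, capped
    at 1); rejecting where adjusted < q controls the FDR at level q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch_arrays(m1, v1, n1, m2, v2, n2):
    """Vectorised Welch t-test; returns (t, p) with NaN where undefined."""
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def compute_perturbations(
    observations: pd.DataFrame,
    vehicle: str = "vehicle",
    config: SignificanceConfig | None = None,
) -> pd.DataFrame:
    """Long table of perturbation records for every compound and cell.

    ``observations`` is the tidy uptake table (``peptide_id``, ``condition``,
    ``timepoint_s``, ``replicate``, ``percent_d``).  When an ``experiment``
    column is present, each compound is compared against the vehicle rows of
    its own experiment (paired differential runs); otherwise one shared
    vehicle arm serves every comparison.  Cells with fewer than
    two replicates in either arm keep their delta but carry NaN p-values and
    are never significant.  Cells where both arms have zero variance get
    p = 1 (equal means) or p = 0 (different means) with ``zero_variance``
    flagged.  Missing cells stay missing (NaN delta), never silent zeros.
    """
    config = config or SignificanceConfig()
    if vehicle not in set(observations["condition"]):
        raise ValueError(f"vehicle condition {vehicle!r} not present")
    obs = observations
    if "experiment" not in obs.columns:
        # Shared-control layout: one vehicle arm serves every comparison.
        obs = obs.assign(experiment=obs["condition"])
    summ = (
        obs.groupby(["condition", "experiment", "peptide_id", "timepoint_s"])[
            "percent_d"
        ]
        .agg(mean="mean", var="var", n="count")
        .reset_index()
    )
    cells = summ[["peptide_id", "timepoint_s"]].drop_duplicates()
    veh_all = summ[summ["condition"] == vehicle].drop(columns="condition")
    veh_by_exp = dict(tuple(veh_all.groupby("experiment")))
    shared_veh = veh_by_exp.get(vehicle)
    records = []
    for comp, sub in summ[summ["condition"] != vehicle].groupby("condition"):
        veh = veh_by_exp.get(comp, shared_veh)
        if veh is None:
            raise ValueError(f"no vehicle arm available for compound {comp!r}")
        merged = cells.merge(
            sub.drop(columns=["condition", "experiment"]),
            on=["peptide_id", "timepoint_s"],
            how="left",
        ).merge(
            veh.drop(columns="experiment"),
            on=["peptide_id", "timepoint_s"],
            how="left",
            suffixes=("_t", "_v"),
        )
        m1, v1 = merged["mean_t"].to_numpy(), merged["var_t"].to_numpy()
        m2, v2 = merged["mean_v"].to_numpy(), merged["var_v"].to_numpy()
        n1 = merged["n_t"].fillna(0).to_numpy(float)
        n2 = merged["n_v"].fillna(0).to_numpy(float)
        delta = m1 - m2
        t, p = _welch_arrays(m1, v1, n1, m2, v2, n2)
        both_const = (v1 == 0.0) & (v2 == 0.0) & (n1 >= 2) & (n2 >= 2)
        zero_var = both_const.copy()
        eq = both_const & (delta == 0.0)
        ne = both_const & (delta != 0.0)
        t = np.where(eq, 0.0, t)
        p = np.where(eq, 1.0, p)
        with np.errstate(invalid="ignore"):
            signed_inf = np.sign(np.nan_to_num(delta)) * np.inf
        t = np.where(ne, signed_inf, t)
        p = np.where(ne, 0.0, p)
        underrep = (n1 < 2) | (n2 < 2)
        p = np.where(underrep, np.nan, p)
        t = np.where(underrep, np.nan, t)
        records.append(
            pd.DataFrame(
                {
                    "compound": comp,
                    "peptide_id": merged["peptide_id"],
                    "timepoint_s": merged["timepoint_s"],
                    "delta_percent_d": delta,
                    "t_statistic": t,
                    "p_value": p,
                    "n_treated": n1.astype(int),
                    "n_vehicle": n2.astype(int),
                    "zero_variance": zero_var,
                }
            )
        )
    rec = pd.concat(records, ignore_index=True)

    rec["adjusted_p"] = np.nan
    if config.bh_scope == "per_compound":
        for _, idx in rec.groupby("compound").groups.items():
            valid = rec.loc[idx, "p_value"].notna()
            vidx = idx[valid]
            if len(vidx):
                rec.loc[vidx, "adjusted_p"] = bh_adjust(rec.loc[vidx, "p_value"])
    else:
        valid = rec["p_value"].notna()
        rec.loc[valid, "adjusted_p"] = bh_adjust(rec.loc[valid, "p_value"])
    rec["significant"] = (
        (rec["adjusted_p"] < config.fdr_threshold)
        & (rec["delta_percent_d"].abs() >= config.magnitude_threshold)
    ).fillna(False)
    return rec[RECORD_COLUMNS]


def to_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Wide perturbation matrix: compounds x (peptide, timepoint) of d%D.

    Missing cells are NaN, never zero.
    """
    return records.pivot(
        index="compound", columns=["peptide_id", "timepoint_s"],
        values="delta_percent_d",
    )


def significance_filter(
    records: pd.DataFrame,
    config: SignificanceConfig | None = None,
) -> tuple[list[tuple[str, float]], pd.DataFrame]:
    """Keep peptide-timepoints where enough compounds are significant.

    Returns the kept ``(peptide_id, timepoint_s)`` list (sorted) and a
    frame of per-cell significant-compound counts for every cell.
    """
    config = config or SignificanceConfig()
    if records.empty:
        raise ValueError("empty perturbation table")
    n_compounds = records["compound"].nunique()
    required = config.required_count(n_compounds)
    counts = (
        records.groupby(["peptide_id", "timepoint_s"])["significant"]
        .sum()
        .astype(int)
        .reset_index(name="n_significant")
    )
    counts["kept"] = counts["n_significant"] >= required
    kept = sorted(
        counts.loc[counts["kept"], ["peptide_id", "timepoint_s"]].itertuples(
            index=False, name=None
        )
    )
    return kept, counts


def mean_perturbation_over_timepoints(records: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of d%D across available timepoints per compound+peptide.

    Missing timepoints are simply excluded; ``n_timepoints`` records how
    many contributed.  Used for whole-timecourse residue painting.
    """
    if records.empty:
        raise ValueError("empty perturbation table")
    out = (
        records.dropna(subset=["delta_percent_d"])
        .groupby(["compound", "peptide_id"])["delta_percent_d"]
        .agg(mean_delta_percent_d="mean", n_timepoints="count")
        .reset_index()
    )
    return out
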