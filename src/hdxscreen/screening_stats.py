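"""Structure-activity statistics for the perturbation screen.

Given the compounds x peptide-timepoint perturbation matrix this module
provides:

* **activity correlation** - per peptide-timepoint ordinary least squares of
  assay activity on d%D across compounds, with Pearson R^2, two-tailed slope
  p-values and BH adjustment within each assay's family.  By convention a
  cell is *significant* at adjusted p < 0.05 and *predictive* at R^2 > 0.4.
* **covariation** - pairwise Pearson R^2 between peptide-timepoints across
  compounds, BH-adjusted over the upper triangle, with a display mask at
  adjusted p < 0.01 (the correlogram convention).
* **compound clustering** - agglomerative Ward linkage on Euclidean
  distances between perturbation signatures.
* **regression outliers** - compounds outside the 95% prediction interval
  of a fitted line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .differential import bh_adjust

__all__ = [
    "ClusterTree",
    "CovariationResult",
    "activity_correlation",
    "covariation",
    "cluster_compounds",
    "flag_outliers",
]


def _ols(x: np.ndarray, y: np.ndarray):
    """Slope, intercept, r^2 and two-tailed slope p for simple OLS."""
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue**2, res.pvalue


def activity_correlation(
    matrix: pd.DataFrame,
    activities: pd.DataFrame,
    assay: str,
    fdr_threshold: float = 0.05,
    predictive_r2: float = 0.4,
) -> pd.DataFrame:
    """Regress one assay's activity on d%D, per peptide-timepoint.

    Parameters
    ----------
    matrix
        Compounds x (peptide_id, timepoint_s) d%D matrix (``to_matrix``).
    activities
        Tidy activity table (``compound``, ``assay``, ``value``).
    assay
        Which assay family to correlate.

    Cells with fewer than three complete compound pairs or constant d%D are
    flagged ``undefined`` and excluded from the BH family.  Returns one row
    per cell with slope, intercept, ``r_squared``, ``slope_p``,
    ``adjusted_p``, ``n`` and the ``significant`` / ``predictive`` flags.
    """
    act = activities[activities["assay"] == assay]
    if act.empty:
        raise ValueError(f"no activity values for assay {assay!r}")
    y_all = act.set_index("compound")["value"]
    rows = []
    for col in matrix.columns:
        x_all = matrix[col]
        common = x_all.dropna().index.intersection(y_all.index)
        x = x_all.loc[common].to_numpy(float)
        y = y_all.loc[common].to_numpy(float)
        undefined = len(common) < 3 or np.all(x == x[0])
        if undefined:
            slope = intercept = r2 = p = np.nan
        else:
            slope, intercept, r2, p = _ols(x, y)
        rows.append(
            {
                "peptide_id": col[0],
                "timepoint_s": col[1],
                "assay": assay,
                "slope": slope,
                "intercept": intercept,
                "r_squared": r2,
                "slope_p": p,
                "n": len(common),
                "undefined": undefined,
            }
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = np.nan
    ok = ~out["undefined"]
    if ok.any():
        out.loc[ok, "adjusted_p"] = bh_adjust(out.loc[ok, "slope_p"])
    out["significant"] = (out["adjusted_p"] < fdr_threshold).fillna(False)
    out["predictive"] = (out["r_squared"] > predictive_r2).fillna(False)
    return out


@dataclass(frozen=True)
class CovariationResult:
    """Pairwise peptide-timepoint covariation across compounds.

    ``r_squared`` is a symmetric grid with unit diagonal; ``adjusted_p``
    holds BH-adjusted slope p-values (upper-triangle family, mirrored);
    ``mask`` marks cells whose adjusted p is below the display threshold
    (diagonal included).  ``pairs`` is the long upper-triangle table.
    """

    r_squared: pd.DataFrame
    adjusted_p: pd.DataFrame
    mask: pd.DataFrame
    pairs: pd.DataFrame


def covariation(
    matrix: pd.DataFrame,
    alpha: float = 0.01,
) -> CovariationResult:
    """All-pairs Pearson R^2 between peptide-timepoint columns.

    Complete-case across compounds (rows with any missing value in the
    matrix are dropped).  Needs at least three compounds.  Constant columns
    yield undefined correlations (NaN, never masked in, excluded from the
    BH family).
    """
    data = matrix.dropna(axis=0)
    n = len(data)
    if n < 3:
        raise ValueError("covariation needs at least three complete compounds")
    X = data.to_numpy(float)
    m = X.shape[1]
    sd = X.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    r2 = r**2
    # Two-tailed p for the pairwise slopes via the t transform of r.
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
        praw = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    iu, ju = np.triu_indices(m, k=1)
    valid = ~np.isnan(praw[iu, ju])
    adj_flat = np.full(iu.shape, np.nan)
    if valid.any():
        adj_flat[valid] = bh_adjust(praw[iu, ju][valid])
    adj = np.full((m, m), np.nan)
    adj[iu, ju] = adj_flat
    adj[ju, iu] = adj_flat
    np.fill_diagonal(adj, 0.0)
    mask = np.zeros((m, m), dtype=bool)
    with np.errstate(invalid="ignore"):
        mask[~np.isnan(adj)] = adj[~np.isnan(adj)] < alpha
    cols = matrix.columns
    labels = [f"{p}@{t:g}" for p, t in cols]
    pairs = pd.DataFrame(
        {
            "x_peptide_id": [cols[i][0] for i in iu],
            "x_timepoint_s": [cols[i][1] for i in iu],
            "y_peptide_id": [cols[j][0] for j in ju],
            "y_timepoint_s": [cols[j][1] for j in ju],
            "r_squared": r2[iu, ju],
            "slope_p": praw[iu, ju],
            "adjusted_p": adj_flat,
            "n": n,
        }
    )
    pairs["significant"] = (pairs["adjusted_p"] < alpha).fillna(False)
    idx = pd.Index(labels, name="peptide_timepoint")
    return CovariationResult(
        r_squared=pd.DataFrame(r2, index=idx, columns=idx),
        adjusted_p=pd.DataFrame(adj, index=idx, columns=idx),
        mask=pd.DataFrame(mask, index=idx, columns=idx),
        pairs=pairs,
    )


@dataclass(frozen=True)
class ClusterTree:
    """Ward linkage over compound perturbation signatures.

    ``linkage_matrix`` is the (n-1) x 4 SciPy linkage encoding (merged
    pair, height, cluster size); heights are nondecreasing for Ward on
    Euclidean distances.
    """

    linkage_matrix: np.ndarray
    labels: tuple[str, ...]
    method: str = "ward"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in leaves_list(self.linkage_matrix))

    def cut(self, k: int) -> dict[str, int]:
        """Flat clustering into ``k`` groups; compound id -> cluster label."""
        assign = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage_matrix,
            columns=["child_a", "child_b", "height", "n_members"],
        )


def cluster_compounds(
    matrix: pd.DataFrame,
    missing: str = "drop",
) -> ClusterTree:
    """Ward hierarchical clustering of compounds by d%D signature.

    ``missing='drop'`` (default) removes peptide-timepoints with any
    missing value before clustering; ``'impute'`` replaces missing values
    with the column mean.  SciPy's linkage breaks distance ties by lowest
    cluster index, which makes the tree deterministic for a fixed row
    order.
    """
    if len(matrix) < 2:
        raise ValueError("clustering needs at least two compounds")
    if missing == "drop":
        data = matrix.dropna(axis=1)
    elif missing == "impute":
        data = matrix.fillna(matrix.mean(axis=0))
    else:
        raise ValueError("missing must be 'drop' or 'impute'")
    if data.shape[1] == 0:
        raise ValueError("no complete peptide-timepoints to cluster on")
    Z = linkage(data.to_numpy(float), method="ward", metric="euclidean")
    return ClusterTree(linkage_matrix=Z, labels=tuple(data.index))


def flag_outliers(
    x,
    y,
    ids=None,
    alpha: float = 0.05,
) -> list:
    """Points outside the (1 - alpha) prediction interval of the OLS line.

    The prediction interval at x0 is ``yhat(x0) +/- t(1-alpha/2, n-2) * s *
    sqrt(1 + 1/n + (x0 - xbar)^2 / Sxx)``.  Needs n >= 4; a degenerate fit
    (constant x) is an error.  Returns the flagged ids (indices when ids
    are not given).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("outlier flagging needs at least four points")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("degenerate fit: x is constant")
    slope, intercept, _, _ = _ols(x, y)
    resid = y - (intercept + slope * x)
    s = np.sqrt(np.sum(resid**2) / (n - 2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    half = tcrit * s * np.sqrt(1.0 + 1.0 / n + (x - x.mean()) ** 2 / sxx)
    outside = np.abs(resid) > half
    if ids is None:
        ids = list(range(n))
    return [i for i, o in zip(ids, outside) if o]
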