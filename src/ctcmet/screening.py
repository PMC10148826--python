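"""Bulk untargeted-metabolomics differential screening.

Two cell-line pairs (a primary and a metastatic line each) are profiled as
feature x sample intensity matrices. The screen removes unreliably detected
features, imputes the remainder, normalizes out technical variation
(protein amount, internal standard, QC drift), and flags differential
features by the joint rule |log2FC| > 1, p < 0.05, VIP > 1, where VIP comes
from an OPLS-DA model. The candidate panel is the intersection of the
features selected in both pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureMatrix",
    "OplsModel",
    "filter_features",
    "impute_missing",
    "normalize_bulk",
    "opls_da",
    "differential_table",
    "selection_mask",
    "shared_panel",
    "zscore_transform",
]

SAMPLE_COLUMNS = ("group", "batch", "is_qc", "protein_ug")


@dataclass
class FeatureMatrix:
    """Feature x sample intensity matrix with sample annotations.

    Parameters
    ----------
    intensities : DataFrame
        Rows are features, columns are samples; NaN marks a missing
        (undetected) entry. Values must be non-negative where observed.
    samples : DataFrame
        Indexed by sample id, with columns ``group``, ``batch``, ``is_qc``
        and ``protein_ug`` (> 0).
    is_feature_id : str or None
        Row id of the spiked internal-standard feature (fully observed).
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    is_feature_id: str | None = None

    def __post_init__(self) -> None:
        if not self.intensities.columns.equals(self.samples.index):
            if set(self.intensities.columns) != set(self.samples.index):
                raise ValueError("sample annotation does not match matrix columns")
            self.samples = self.samples.loc[self.intensities.columns]
        missing_cols = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if missing_cols:
            raise ValueError(f"sample annotation lacks columns: {sorted(missing_cols)}")
        if (self.samples["protein_ug"] <= 0).any():
            raise ValueError("protein_ug must be positive for every sample")
        vals = self.intensities.to_numpy(dtype=float)
        if vals.size and np.any(vals[~np.isnan(vals)] < 0):
            raise ValueError("intensities must be non-negative")
        if self.is_feature_id is not None:
            if self.is_feature_id not in self.intensities.index:
                raise ValueError(f"internal standard {self.is_feature_id!r} not in matrix")
            if self.intensities.loc[self.is_feature_id].isna().any():
                raise ValueError("internal-standard feature must be fully observed")

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def groups(self) -> pd.Series:
        """Group label per non-QC sample."""
        keep = ~self.samples["is_qc"].astype(bool)
        return self.samples.loc[keep, "group"]


def filter_features(
    matrix: FeatureMatrix,
    min_detect_frac: float = 0.8,
    min_snr: float = 3.0,
    blank_profile: pd.Series | None = None,
) -> FeatureMatrix:
    """Drop unreliably detected features.

    A feature is removed iff its detection fraction is below
    ``min_detect_frac`` in *every* (non-QC) group, or its maximum observed
    intensity is below ``min_snr`` times its blank noise level. Feature
    order is preserved. The internal-standard feature, being fully
    observed, survives the detection rule by construction.
    """
    if not 0 < min_detect_frac <= 1:
        raise ValueError(f"min_detect_frac must be in (0, 1], got {min_detect_frac}")
    groups = matrix.groups
    if groups.empty:
        raise ValueError("no non-QC samples to evaluate detection on")

    observed = matrix.intensities.notna()
    below_everywhere = pd.Series(True, index=matrix.feature_ids)
    for g in groups.unique():
        cols = groups.index[groups == g]
        frac = observed[cols].mean(axis=1)
        below_everywhere &= frac < min_detect_frac

    keep = ~below_everywhere
    if blank_profile is not None:
        blank = blank_profile.reindex(matrix.feature_ids)
        if blank.isna().any():
            missing = blank.index[blank.isna()].tolist()[:5]
            raise ValueError(f"blank_profile does not cover features: {missing}")
        max_int = matrix.intensities.max(axis=1)
        keep &= ~(max_int < min_snr * blank)

    return replace(matrix, intensities=matrix.intensities.loc[keep])


def impute_missing(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace each missing entry by 1/10 of the feature's observed minimum."""
    vals = matrix.intensities
    if vals.isna().all(axis=1).any():
        bad = vals.index[vals.isna().all(axis=1)].tolist()[:5]
        raise ValueError(f"all-missing features must be filtered first: {bad}")
    fill = vals.min(axis=1, skipna=True) / 10.0
    out = vals.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    return replace(matrix, intensities=out)


def normalize_bulk(matrix: FeatureMatrix) -> FeatureMatrix:
    """Normalize intensities by protein amount, internal standard, and QC drift.

    Per sample, intensities are divided by the protein amount and by the
    sample's internal-standard intensity; then, per batch, each feature is
    divided by its median across that batch's QC samples. The internal
    standard row is removed from the output.
    """
    if matrix.is_feature_id is None:
        raise ValueError("normalize_bulk requires an internal-standard feature")
    is_row = matrix.intensities.loc[matrix.is_feature_id]
    if (is_row == 0).any():
        raise ValueError("zero internal-standard intensity in some sample")

    scaled = matrix.intensities.div(matrix.samples["protein_ug"], axis=1).div(
        is_row, axis=1
    )
    scaled = scaled.drop(index=matrix.is_feature_id)

    is_qc = matrix.samples["is_qc"].astype(bool)
    for b in matrix.samples["batch"].unique():
        in_batch = matrix.samples["batch"] == b
        qc_cols = matrix.samples.index[in_batch & is_qc]
        if len(qc_cols) == 0:
            raise ValueError(f"batch {b!r} has no QC sample")
        qc_median = scaled[qc_cols].median(axis=1)
        if (qc_median == 0).any():
            raise ValueError(f"zero QC median for some feature in batch {b!r}")
        batch_cols = matrix.samples.index[in_batch]
        scaled[batch_cols] = scaled[batch_cols].div(qc_median, axis=0)

    return replace(matrix, intensities=scaled, is_feature_id=None)


@dataclass
class OplsModel:
    """Fitted OPLS-DA model (one predictive + n orthogonal components)."""

    weights: pd.Series               # predictive weight vector w (unit norm)
    scores: np.ndarray               # predictive scores t
    loadings: pd.Series              # predictive loadings p
    n_orthogonal: int
    r2x_cum: float
    r2y_cum: float
    q2_cum: float
    vip: pd.Series
    y_coef: float = 0.0              # regression of y on t
    feature_means: pd.Series | None = None
    feature_sds: pd.Series | None = None
    ortho_weights: np.ndarray | None = None   # p x n_ortho
    ortho_loadings: np.ndarray | None = None  # p x n_ortho


def _opls_components(X: np.ndarray, y: np.ndarray, n_ortho: int):
    """NIPALS OPLS for a single centered response.

    Returns (w, t, p, c, W_ortho, P_ortho, X_deflated).
    """
    Xd = X.copy()
    W_o, P_o = [], []
    for _ in range(n_ortho):
        w = Xd.T @ y / (y @ y)
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break
        w_o /= n_o
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
    w = Xd.T @ y / (y @ y)
    w /= np.linalg.norm(w)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    c = (y @ t) / (t @ t)
    return w, t, p, c, W_o, P_o, Xd


def _opls_predict(X_new: np.ndarray, w, c, W_o, P_o) -> np.ndarray:
    Xd = X_new.copy()
    for w_o, p_o in zip(W_o, P_o):
        t_o = Xd @ w_o
        Xd = Xd - np.outer(t_o, p_o)
    return (Xd @ w) * c


def _cv_q2(X: np.ndarray, y: np.ndarray, n_ortho: int, n_folds: int = 7) -> float:
    """7-fold cross-validated Q2 for a given orthogonal-component count.

    Folds are deterministic "venetian blind" assignments within each class
    so both classes appear in every training split.
    """
    n = X.shape[0]
    folds = np.empty(n, dtype=int)
    for cls in np.unique(y):
        rows = np.flatnonzero(y == cls)
        folds[rows] = np.arange(rows.size) % n_folds
    press, ss = 0.0, float(y @ y)
    for f in np.unique(folds):
        test = folds == f
        Xtr, ytr = X[~test], y[~test]
        if np.unique(ytr).size < 2:
            continue
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        ym = ytr.mean()
        w, t, p, c, W_o, P_o, _ = _opls_components(
            (Xtr - mu) / sd, ytr - ym, n_ortho
        )
        yhat = _opls_predict((X[test] - mu) / sd, w, c, W_o, P_o) + ym
        press += float(np.sum((y[test] - yhat) ** 2))
    return 1.0 - press / ss


def opls_da(
    matrix: FeatureMatrix,
    group_labels: pd.Series | None = None,
    max_orthogonal: int = 5,
    q2_improvement: float = 0.01,
) -> OplsModel:
    """Fit OPLS-DA of group membership on autoscaled intensities.

    One predictive component; orthogonal components are added while the
    7-fold cross-validated Q2 improves by more than ``q2_improvement``
    (capped at ``max_orthogonal``). VIP is computed from the predictive
    component; with a unit-norm weight vector the squared VIPs average 1.
    """
    groups = matrix.groups if group_labels is None else group_labels
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"OPLS-DA requires exactly 2 groups, got {levels}")
    counts = groups.value_counts()
    if (counts < 3).any():
        raise ValueError("each group needs >= 3 samples")

    cols = groups.index
    X_df = matrix.intensities[cols].T  # samples x features
    sds = X_df.std(axis=0, ddof=1)
    constant = sds[sds == 0].index
    if len(constant) > 0:
        warnings.warn(f"dropping {len(constant)} constant feature(s)", stacklevel=2)
        X_df = X_df.drop(columns=constant)
        sds = sds.drop(constant)
    means = X_df.mean(axis=0)
    X = ((X_df - means) / sds).to_numpy(dtype=float)
    y = np.where(groups.to_numpy() == levels[1], 1.0, -1.0)
    y = y - y.mean()

    q2_prev = _cv_q2(X, y, 0)
    n_ortho = 0
    for k in range(1, max_orthogonal + 1):
        q2_k = _cv_q2(X, y, k)
        if q2_k - q2_prev > q2_improvement:
            n_ortho, q2_prev = k, q2_k
        else:
            break

    w, t, p, c, W_o, P_o, _ = _opls_components(X, y, n_ortho)
    yhat = t * c
    ss_y = float(y @ y)
    r2y = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_y
    ss_x = float(np.sum(X**2))
    explained = float(t @ t) * float(p @ p)
    # orthogonal score variance accumulated along the deflation sequence
    Xd = X.copy()
    for w_o, p_o in zip(W_o, P_o):
        t_o = Xd @ w_o
        explained += float(t_o @ t_o) * float(p_o @ p_o)
        Xd = Xd - np.outer(t_o, p_o)
    r2x = explained / ss_x

    p_features = X.shape[1]
    vip = np.sqrt(p_features) * np.abs(w)

    feats = X_df.columns
    return OplsModel(
        weights=pd.Series(w, index=feats),
        scores=t,
        loadings=pd.Series(p, index=feats),
        n_orthogonal=n_ortho,
        r2x_cum=r2x,
        r2y_cum=r2y,
        q2_cum=q2_prev,
        vip=pd.Series(vip, index=feats),
        y_coef=c,
        feature_means=means,
        feature_sds=sds,
        ortho_weights=np.column_stack(W_o) if W_o else None,
        ortho_loadings=np.column_stack(P_o) if P_o else None,
    )


def differential_table(
    matrix: FeatureMatrix,
    comparison: tuple[str, str],
    opls: OplsModel,
) -> pd.DataFrame:
    """Per-feature fold change, t-test p, VIP and selection flag.

    Parameters
    ----------
    comparison : (primary_group, metastatic_group)
        Fold change is metastatic over primary on linear-scale
        intensities; the p-value is a two-tailed equal-variance t test on
        log10 intensities. A feature is selected iff |log2FC| > 1 and
        p < 0.05 and VIP > 1, all strict.
    """
    primary, metastatic = comparison
    groups = matrix.groups
    a_cols = groups.index[groups == primary]
    b_cols = groups.index[groups == metastatic]
    if len(a_cols) == 0 or len(b_cols) == 0:
        raise ValueError(f"comparison groups {comparison} not found")

    feats = opls.vip.index
    vals = matrix.intensities.loc[feats]
    mean_a = vals[a_cols].mean(axis=1)
    mean_b = vals[b_cols].mean(axis=1)
    if (mean_a <= 0).any() or (mean_b <= 0).any():
        raise ValueError("group means must be positive to form fold changes")
    log2fc = np.log2(mean_b / mean_a)

    la = np.log10(vals[a_cols].to_numpy(dtype=float))
    lb = np.log10(vals[b_cols].to_numpy(dtype=float))
    with np.errstate(invalid="ignore"):
        _, pvals = stats.ttest_ind(lb, la, axis=1, equal_var=True)
    pvals = pd.Series(pvals, index=feats).fillna(1.0)

    table = pd.DataFrame(
        {
            "feature_id": feats,
            "log2fc": log2fc.to_numpy(),
            "p": pvals.to_numpy(),
            "vip": opls.vip.to_numpy(),
        }
    ).set_index("feature_id", drop=False)
    table["selected"] = selection_mask(table["log2fc"], table["p"], table["vip"])
    return table


def selection_mask(log2fc, p, vip) -> np.ndarray:
    """Strict three-way significance rule: |log2FC| > 1 AND p < 0.05 AND VIP > 1.

    All inequalities are strict; a record sitting exactly on any boundary
    is not selected.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p, dtype=float)
    vip = np.asarray(vip, dtype=float)
    return (np.abs(log2fc) > 1.0) & (p < 0.05) & (vip > 1.0)


def shared_panel(table_a: pd.DataFrame, table_b: pd.DataFrame) -> list[str]:
    """Feature ids selected in both differential tables, sorted."""
    sel_a = set(table_a.index[table_a["selected"]])
    sel_b = set(table_b.index[table_b["selected"]])
    return sorted(sel_a & sel_b)


def zscore_transform(matrix: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-feature z-scores across all samples ((x - mean) / sample sd).

    Accepts a FeatureMatrix or a bare features x samples DataFrame (e.g.
    an already z-scored matrix, for which the transform is idempotent).
    """
    vals = matrix.intensities if isinstance(matrix, FeatureMatrix) else matrix
    sds = vals.std(axis=1, ddof=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0].tolist()[:5]
        raise ValueError(f"zero-variance features cannot be z-scored: {bad}")
    return vals.sub(vals.mean(axis=1), axis=0).div(sds, axis=0)
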