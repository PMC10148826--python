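"""CTC metabolic subtyping: NMF consensus clustering and the risk score.

Single CTCs, described by an 11-metabolite concentration panel (mM), are
clustered without supervision by non-negative matrix factorization (NMF).
The cluster number is chosen by consensus clustering: for each candidate
rank k the factorization is repeated from many random starts, per-run hard
labels (argmax over the basis coefficients W) define connectivity
matrices, and their mean is the consensus matrix. The cophenetic
correlation of the consensus-derived distances picks the rank; here, as in
the source cohort, two subgroups (C1 low-risk, C2 high-risk) emerge.

A logistic regression of subgroup membership on a compact metabolite
fingerprint (glutamic, malic, aspartic, lactic acid) yields a per-cell
risk score on the base-10 logit scale,

    log10(s / (1 - s)) = sum_i beta_i * x_i + beta_0,

with cells called C2 when s >= the Youden-index threshold (published
model: 0.420).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform

from ._logit import fit_logit

__all__ = [
    "SingleCellMatrix",
    "NmfResult",
    "ConsensusResult",
    "RiskModel",
    "nmf",
    "consensus_cluster",
    "select_fingerprint",
    "fit_risk_model",
    "published_risk_model",
    "risk_score",
    "youden_cutoff",
    "assign_subgroups",
]

LN10 = np.log(10.0)

#: Default 11-metabolite panel quantified in single CTCs.
DEFAULT_PANEL = (
    "glutamic acid",
    "malic acid",
    "aspartic acid",
    "lactic acid",
    "glutathione",
    "glutamine",
    "glycine",
    "serine",
    "proline",
    "fumaric acid",
    "citric acid",
)

#: The four fingerprint metabolites driving the published risk score.
FINGERPRINT = ("glutamic acid", "malic acid", "aspartic acid", "lactic acid")


@dataclass
class SingleCellMatrix:
    """Cells x metabolites concentration matrix (mM) with cell annotations."""

    concentrations: pd.DataFrame          # cells x metabolites, >= 0
    cells: pd.DataFrame                   # index cell_id: patient_id, batch

    def __post_init__(self) -> None:
        if not self.concentrations.index.equals(self.cells.index):
            if set(self.concentrations.index) != set(self.cells.index):
                raise ValueError("cell annotation does not match matrix rows")
            self.cells = self.cells.loc[self.concentrations.index]
        if "patient_id" not in self.cells.columns:
            raise ValueError("cell annotation requires a patient_id column")
        vals = self.concentrations.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("concentrations must be finite and non-negative")

    @property
    def cell_ids(self) -> pd.Index:
        return self.concentrations.index

    @property
    def metabolite_names(self) -> pd.Index:
        return self.concentrations.columns

    @property
    def patient_ids(self) -> pd.Series:
        return self.cells["patient_id"]


@dataclass
class NmfResult:
    """One NMF factorization V ~ W @ H."""

    W: np.ndarray                 # cells x k, >= 0
    H: np.ndarray                 # k x metabolites, >= 0
    objective_trace: np.ndarray   # squared Frobenius error per iteration
    k: int
    seed: int

    def labels(self) -> np.ndarray:
        """Hard cluster labels: argmax over each cell's basis coefficients."""
        return self.W.argmax(axis=1)


def nmf(
    matrix: SingleCellMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-5,
) -> NmfResult:
    """Lee-Seung multiplicative-update NMF for squared Frobenius error.

    Iterates H <- H * (W'V)/(W'WH), W <- W * (VH')/(WHH') from a random
    uniform start; the objective is non-increasing and iteration stops at
    ``tol`` relative improvement or ``max_iter``.
    """
    V = (
        matrix.concentrations.to_numpy(dtype=float)
        if isinstance(matrix, SingleCellMatrix)
        else np.asarray(matrix, dtype=float)
    )
    if (V < 0).any():
        raise ValueError("NMF requires non-negative input")
    n, m = V.shape
    if not 0 < k < min(n, m) + 1:
        raise ValueError(f"rank k={k} invalid for a {n}x{m} matrix")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(V.mean(), np.finfo(float).tiny) / k)
    W = rng.uniform(0.0, 1.0, size=(n, k)) * scale + 1e-4
    H = rng.uniform(0.0, 1.0, size=(k, m)) * scale + 1e-4

    eps = 1e-12
    trace = []
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        err = float(np.linalg.norm(V - W @ H) ** 2)
        trace.append(err)
        if prev - err <= tol * max(prev, eps) and np.isfinite(prev):
            break
        prev = err
    return NmfResult(W=W, H=H, objective_trace=np.asarray(trace), k=k, seed=seed)


@dataclass
class ConsensusResult:
    """Consensus-NMF rank selection across a range of candidate ranks."""

    consensus: Mapping[int, np.ndarray]      # k -> cells x cells matrix
    cophenetic: Mapping[int, float]          # k -> cophenetic correlation
    selected_rank: int
    cell_labels: pd.Series                   # cluster id (1..k) per cell


def _cophenetic_coefficient(consensus: np.ndarray):
    """Cophenetic correlation of the 1-consensus distance, with its tree."""
    d = squareform(1.0 - consensus, checks=False)
    Z = average(d)
    if np.ptp(d) == 0:
        # constant distances (e.g. perfectly stable clustering): define as 1
        return 1.0, Z
    c, _ = cophenet(Z, d)
    return float(c), Z


def consensus_cluster(
    matrix: SingleCellMatrix,
    k_range: Sequence[int] = range(2, 7),
    n_runs: int = 30,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-5,
    column_scale: bool = True,
) -> ConsensusResult:
    """Consensus NMF over ``k_range`` with cophenetic rank selection.

    For each k, ``n_runs`` factorizations from distinct seeds produce hard
    partitions; the consensus matrix is the mean connectivity. The selected
    rank maximizes the cophenetic correlation between the (1 - consensus)
    distances and the cophenetic distances of their average-linkage
    dendrogram (ties go to the smaller rank), and cell labels come from
    cutting that dendrogram into ``selected_rank`` clusters.

    With ``column_scale`` (default) each metabolite is divided by its
    cohort mean before factorization, so metabolites with large natural
    concentrations (e.g. lactate) do not dominate the Frobenius objective;
    scaling by a positive constant preserves non-negativity and the
    cluster structure.
    """
    k_range = list(k_range)
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    n_cells = matrix.concentrations.shape[0]
    if n_cells < 2 * max(k_range):
        raise ValueError("need at least 2*max(k_range) cells")

    V = matrix.concentrations.to_numpy(dtype=float)
    if column_scale:
        col_means = V.mean(axis=0)
        if (col_means <= 0).any():
            raise ValueError("column scaling requires metabolites with positive mean")
        V = V / col_means
    child_seeds = np.random.SeedSequence(seed).spawn(len(k_range) * n_runs)
    consensus: dict[int, np.ndarray] = {}
    cophenetics: dict[int, float] = {}
    trees: dict[int, np.ndarray] = {}
    for ki, k in enumerate(k_range):
        acc = np.zeros((n_cells, n_cells))
        for r in range(n_runs):
            run_seed = int(
                child_seeds[ki * n_runs + r].generate_state(1)[0] % (2**31 - 1)
            )
            labels = nmf(V, k, seed=run_seed, max_iter=max_iter, tol=tol).labels()
            acc += labels[:, None] == labels[None, :]
        C = acc / n_runs
        np.fill_diagonal(C, 1.0)
        consensus[k] = C
        cophenetics[k], trees[k] = _cophenetic_coefficient(C)

    selected = max(sorted(k_range), key=lambda k: (cophenetics[k], -k))
    labels = fcluster(trees[selected], t=selected, criterion="maxclust")
    return ConsensusResult(
        consensus=consensus,
        cophenetic=cophenetics,
        selected_rank=selected,
        cell_labels=pd.Series(labels, index=matrix.cell_ids, name="cluster"),
    )


def _binary_labels(cell_labels: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(cell_labels))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 cluster labels, got {levels}")
    return (cell_labels.to_numpy() == levels[1]).astype(float), levels


def select_fingerprint(
    matrix: SingleCellMatrix,
    cell_labels: pd.Series,
    alpha: float = 0.05,
) -> list[str]:
    """Backward-eliminate panel metabolites in a cluster-membership logit.

    Fits a logistic regression of the (binary) cluster label on all
    standardized panel metabolites and repeatedly removes the metabolite
    with the largest Wald p-value while any p >= ``alpha``. Survivors are
    returned ordered by |standardized coefficient|, largest first.
    Complete separation triggers a flagged ridge-penalized fallback fit.
    """
    y, _ = _binary_labels(cell_labels)
    X = matrix.concentrations
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    current = list(Xs.columns)
    while current:
        fit = fit_logit(y, Xs[current].to_numpy(), add_const=True)
        pvals = pd.Series(fit.p_values[1:], index=current)
        worst = pvals.idxmax()
        if pvals[worst] < alpha:
            coefs = pd.Series(np.abs(fit.params[1:]), index=current)
            return coefs.sort_values(ascending=False).index.tolist()
        current.remove(worst)
    return []


@dataclass(frozen=True)
class RiskModel:
    """Base-10 logit risk model over a metabolite fingerprint.

    ``coefficients`` are per-mM on the base-10 logit scale; a cell whose
    score reaches ``threshold`` is called C2 (high risk).
    """

    metabolite_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    threshold: float = 0.420

    def __post_init__(self) -> None:
        if len(self.metabolite_names) != len(self.coefficients):
            raise ValueError("one coefficient per metabolite required")
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must be in (0,1), got {self.threshold}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "metabolite_names": list(self.metabolite_names),
                "coefficients": list(self.coefficients),
                "intercept": self.intercept,
                "threshold": self.threshold,
                "logit_base": 10,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RiskModel":
        d = json.loads(text)
        if d.get("logit_base", 10) != 10:
            raise ValueError("risk models are stored on the base-10 logit scale")
        return cls(
            metabolite_names=tuple(d["metabolite_names"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
            intercept=float(d["intercept"]),
            threshold=float(d["threshold"]),
        )


def published_risk_model() -> RiskModel:
    """The published 4-metabolite CTC risk classifier.

    log10(s/(1-s)) = -0.932*[glutamic acid] + 3.967*[malic acid]
                     - 0.166*[aspartic acid] - 1.822*[lactic acid] - 3.694,
    C2 iff s >= 0.420 (abundances in mM).
    """
    return RiskModel(
        metabolite_names=FINGERPRINT,
        coefficients=(-0.932, 3.967, -0.166, -1.822),
        intercept=-3.694,
        threshold=0.420,
    )


def risk_score(model: RiskModel, abundances) -> np.ndarray | float:
    """Evaluate the base-10 logit risk score on named abundances (mM).

    ``abundances`` may be a mapping, a Series, or a DataFrame with the
    fingerprint metabolites as keys/columns; inputs are matched by name,
    never by position. Missing metabolites raise rather than impute.
    """
    if isinstance(abundances, pd.DataFrame):
        missing = [m for m in model.metabolite_names if m not in abundances.columns]
        if missing:
            raise KeyError(f"missing fingerprint metabolites: {missing}")
        X = abundances[list(model.metabolite_names)].to_numpy(dtype=float)
    else:
        if isinstance(abundances, pd.Series):
            abundances = abundances.to_dict()
        missing = [m for m in model.metabolite_names if m not in abundances]
        if missing:
            raise KeyError(f"missing fingerprint metabolites: {missing}")
        X = np.asarray(
            [float(abundances[m]) for m in model.metabolite_names], dtype=float
        )
    if not np.isfinite(X).all():
        raise ValueError("abundances must be finite")
    eta = X @ np.asarray(model.coefficients) + model.intercept
    score = 1.0 / (1.0 + 10.0 ** (-eta))
    # the sigmoid is mathematically strictly inside (0,1); keep the floating-
    # point result there too when the logit saturates
    score = np.clip(score, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    return float(score) if np.ndim(score) == 0 else score


def fit_risk_model(
    matrix: SingleCellMatrix,
    cell_labels: pd.Series,
    fingerprint: Sequence[str] = FINGERPRINT,
    high_risk_label=None,
    outcomes: pd.Series | None = None,
) -> RiskModel:
    """Fit the logistic risk model of C2 membership on raw mM abundances.

    The maximum-likelihood natural-log coefficients are divided by ln(10)
    so the stored model is on the base-10 logit scale of the published
    formula; the threshold is the Youden cutoff of the training scores.

    Orientation of the high-risk class: ``high_risk_label`` if given;
    otherwise, when per-patient ``outcomes`` are supplied, the cluster
    whose per-patient count correlates positively with the outcome;
    otherwise the lexicographically larger cluster label.
    """
    fingerprint = list(fingerprint)
    missing = [m for m in fingerprint if m not in matrix.metabolite_names]
    if missing:
        raise ValueError(f"fingerprint not in panel: {missing}")
    cell_labels = cell_labels.loc[matrix.cell_ids]
    levels = sorted(pd.unique(cell_labels))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 cluster labels, got {levels}")

    if high_risk_label is None:
        if outcomes is not None:
            pat = matrix.patient_ids
            corr = {}
            for lv in levels:
                counts = (
                    (cell_labels == lv).groupby(pat).sum().reindex(outcomes.index)
                ).fillna(0.0)
                corr[lv] = float(np.corrcoef(counts, outcomes)[0, 1])
            high_risk_label = max(levels, key=lambda lv: corr[lv])
        else:
            high_risk_label = levels[1]
    elif high_risk_label not in levels:
        raise ValueError(f"high_risk_label {high_risk_label!r} not among {levels}")

    y = (cell_labels == high_risk_label).to_numpy(dtype=float)
    X = matrix.concentrations[fingerprint].to_numpy(dtype=float)
    fit = fit_logit(y, X, add_const=True)
    if fit.flagged:
        warnings.warn(
            "risk-model fit used a penalized fallback (separation or "
            "non-convergence)",
            stacklevel=2,
        )
    intercept10 = fit.params[0] / LN10
    coefs10 = tuple(float(b / LN10) for b in fit.params[1:])

    provisional = RiskModel(
        metabolite_names=tuple(fingerprint),
        coefficients=coefs10,
        intercept=float(intercept10),
        threshold=0.5,
    )
    scores = risk_score(provisional, matrix.concentrations)
    thr = youden_cutoff(scores, y.astype(int))
    return RiskModel(
        metabolite_names=tuple(fingerprint),
        coefficients=coefs10,
        intercept=float(intercept10),
        threshold=float(min(max(thr, 1e-9), 1 - 1e-9)),
    )


def youden_cutoff(scores, labels) -> float:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Candidates are the unique observed scores; a case is called positive
    iff its score is >= the cutoff. Ties in J go to the smallest cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label values must be present")
    candidates = np.unique(s)
    if candidates.size < 2:
        raise ValueError("need more than one distinct score")
    pred = s[None, :] >= candidates[:, None]          # candidates x cases
    tp = (pred & (y == 1)).sum(axis=1)
    tn = (~pred & (y == 0)).sum(axis=1)
    j = tp / n_pos + tn / n_neg - 1.0
    best = np.flatnonzero(j == j.max())[0]            # smallest cutoff wins ties
    return float(candidates[best])


def assign_subgroups(scores, threshold: float = 0.420) -> np.ndarray:
    """Label each cell C2 (high risk) iff its score >= threshold, else C1."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    s = np.asarray(scores, dtype=float)
    return np.where(s >= threshold, "C2", "C1")
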