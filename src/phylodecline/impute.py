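"""Phylogenetically informed imputation of traits and trend labels.

Missing continuous predictors and categorical trend labels are filled by
iterative chained imputation: each modeled column is regressed (ridge for
continuous targets, multinomial logistic for the trend) on the leading
phylogenetic eigenvectors plus the current values of the other modeled
columns, and its missing cells are overwritten with predictions until the
imputed values stabilize. Leave-one-out validation hides each observed cell in
turn and scores predictive R^2 (continuous) or a confusion matrix with
accuracy and Cohen's kappa (trend).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, Ridge, RidgeCV

from .trees import PhyloTree, phylo_eigenvectors

#: penalty grid searched by the default leave-one-out-tuned ridge learner
RIDGE_ALPHAS = np.logspace(-4, 5, 19)

#: continuous columns modeled by default; body size is modeled on the log scale
DEFAULT_CONTINUOUS = ["body_size_mm", "amt_mean", "tar_mean", "cmi_mean"]
TREND_CLASSES = ["increasing", "stable", "decreasing"]


@dataclass
class ImputationResult:
    table: pd.DataFrame
    provenance: pd.DataFrame        # bool, True where a cell was imputed
    iterations_used: int
    converged: bool


@dataclass
class ValidationReport:
    """Leave-one-out performance of the imputer on observed cells."""

    r2: dict[str, float]
    confusion: pd.DataFrame | None
    accuracy: float | None
    kappa: float | None
    n_heldout: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "r2": {k: float(v) for k, v in self.r2.items()},
            "confusion": (
                None if self.confusion is None
                else {
                    "classes": list(self.confusion.index),
                    "matrix": self.confusion.to_numpy().tolist(),
                }
            ),
            "accuracy": None if self.accuracy is None else float(self.accuracy),
            "kappa": None if self.kappa is None else float(self.kappa),
            "n_heldout": dict(self.n_heldout),
        }


def kappa(confusion) -> float:
    """Cohen's kappa for a square confusion matrix of counts.

    kappa = (p0 - pe) / (1 - pe) with p0 the observed agreement (trace /
    total) and pe the chance agreement from the row/column margins. The
    degenerate single-class case (pe = 1) is defined as 0.
    """
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (m < 0).any():
        raise ValueError("confusion matrix must be nonnegative")
    total = m.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    p0 = np.trace(m) / total
    pe = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / total**2
    if pe >= 1.0 - 1e-15:
        warnings.warn("degenerate single-class confusion matrix; kappa := 0")
        return 0.0
    return float((p0 - pe) / (1.0 - pe))


# ---------------------------------------------------------------------------
# Internal working representation
# ---------------------------------------------------------------------------


def _to_model_scale(table: pd.DataFrame, cols: list[str]):
    """Column-wise z transform (log first for body size) over observed cells."""
    work = {}
    stats = {}
    for col in cols:
        v = table[col].astype(float)
        if col == "body_size_mm":
            v = np.log(v)
        mu = float(v.mean())
        sd = float(v.std(ddof=0))
        if not np.isfinite(sd) or sd == 0:
            sd = 1.0
        work[col] = (v - mu) / sd
        stats[col] = (mu, sd)
    return pd.DataFrame(work, index=table.index), stats


def _from_model_scale(values: np.ndarray, col: str, stats) -> np.ndarray:
    mu, sd = stats[col]
    out = values * sd + mu
    if col == "body_size_mm":
        out = np.exp(out)
    return out


def _trend_missing(trend: pd.Series) -> np.ndarray:
    return (trend.isna() | (trend == "unknown")).to_numpy()


def _trend_onehot(labels: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [(labels == c).astype(float) for c in TREND_CLASSES[:-1]]
    )


def impute(
    table: pd.DataFrame,
    tree: PhyloTree,
    k_eigen: int | None = None,
    max_iter: int = 10,
    tol: float = 1e-3,
    seed: int = 0,
    continuous_cols: list[str] | None = None,
    trend_col: str | None = "trend",
    ridge_alpha: float | str = "cv",
    eigenvectors: np.ndarray | None = None,
    fixed_cols: list[str] | None = None,
) -> ImputationResult:
    """Fill missing cells of the modeled columns using phylogeny + covariates.

    ``table`` is indexed by species; its index must match the tree's tips.
    ``k_eigen`` defaults to min(30, n_tips - 1). The trend column treats both
    NaN and the label "unknown" as missing; predictions are over the three
    informative classes. Observed cells are never altered. ``eigenvectors``
    may be supplied to skip recomputing them (they depend only on the tree).
    ``fixed_cols`` are auxiliary numeric columns used as features for every
    target but never imputed themselves (z-scored; any missing entries sit at
    the column mean).
    """
    cols = list(continuous_cols) if continuous_cols is not None else [
        c for c in DEFAULT_CONTINUOUS if c in table.columns
    ]
    species = list(table.index)
    tipset = set(tree.tips)
    if set(species) != tipset:
        only_table = sorted(set(species) - tipset)[:5]
        only_tree = sorted(tipset - set(species))[:5]
        raise ValueError(
            f"tree/table species mismatch; table-only={only_table}, "
            f"tree-only={only_tree}"
        )
    n = len(species)
    if k_eigen is None:
        k_eigen = min(30, n - 1)
    for col in cols:
        if table[col].notna().sum() < 10:
            raise ValueError(f"column {col} has fewer than 10 observed values")

    has_trend = trend_col is not None and trend_col in table.columns
    miss_cont = {c: table[c].isna().to_numpy() for c in cols}
    miss_trend = _trend_missing(table[trend_col]) if has_trend else None
    any_missing = any(m.any() for m in miss_cont.values()) or (
        has_trend and miss_trend.any()
    )

    prov = pd.DataFrame(
        {c: miss_cont[c] for c in cols}
        | ({trend_col: miss_trend} if has_trend else {}),
        index=table.index,
    )
    if not any_missing:
        return ImputationResult(table.copy(), prov, 0, True)

    if k_eigen == 0:  # covariates-only learner, no phylogenetic features
        evec = np.zeros((n, 0))
    elif eigenvectors is None:
        labels, vecs = phylo_eigenvectors(tree, k_eigen)
        evec = pd.DataFrame(vecs, index=labels).reindex(species).to_numpy()
    else:
        evec = np.asarray(eigenvectors)[:, :k_eigen]
    evec = evec * np.sqrt(n)  # unit-norm columns -> unit-variance features
    if fixed_cols:
        fixed_work, _ = _to_model_scale(table, list(fixed_cols))
        fixed = np.nan_to_num(fixed_work.to_numpy(), nan=0.0)
        evec = np.column_stack([evec, fixed])

    work, stats = _to_model_scale(table, cols)
    z = work.to_numpy()  # n x n_cols, NaN where missing
    # initialize: column means are 0 on the z scale
    z = np.where(np.isnan(z), 0.0, z)
    if has_trend:
        trend = table[trend_col].to_numpy(dtype=object).copy()
        observed_trend = trend[~miss_trend]
        modal = (
            pd.Series(observed_trend).mode().iloc[0]
            if observed_trend.size else "stable"
        )
        trend[miss_trend] = modal

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        max_change = 0.0
        trend_changed = False
        for j, col in enumerate(cols):
            mask = miss_cont[col]
            if not mask.any():
                continue
            others = np.delete(z, j, axis=1)
            feats = [evec, others]
            if has_trend:
                feats.append(_trend_onehot(trend))
            x = np.column_stack(feats)
            if x.shape[1] == 0:  # no features at all: column-mean prediction
                pred = np.zeros(int(mask.sum()))
            else:
                if ridge_alpha == "cv":
                    # leave-one-out-tuned penalty: collapses to the column
                    # mean when the features carry no signal
                    model = RidgeCV(alphas=RIDGE_ALPHAS)
                else:
                    model = Ridge(alpha=ridge_alpha)
                model.fit(x[~mask], z[~mask, j])
                pred = model.predict(x[mask])
            max_change = max(max_change, float(np.max(np.abs(pred - z[mask, j]))))
            z[mask, j] = pred
        if has_trend and miss_trend.any():
            x = np.column_stack([evec, z])
            y_obs = trend[~miss_trend]
            if len(set(y_obs)) < 2:
                pred = np.repeat(y_obs[0] if y_obs.size else "stable",
                                 int(miss_trend.sum()))
            else:
                clf = LogisticRegression(max_iter=1000, C=1.0)
                clf.fit(x[~miss_trend], y_obs.astype(str))
                pred = clf.predict(x[miss_trend])
            trend_changed = not np.array_equal(
                trend[miss_trend].astype(str), pred.astype(str)
            )
            trend[miss_trend] = pred
        if max_change < tol and not trend_changed:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"imputation did not converge in {max_iter} iterations "
            f"(last change {max_change:.3g})"
        )

    out = table.copy()
    for j, col in enumerate(cols):
        mask = miss_cont[col]
        if mask.any():
            vals = out[col].to_numpy(dtype=float)
            vals[mask] = _from_model_scale(z[mask, j], col, stats)
            out[col] = vals
    if has_trend and miss_trend.any():
        tcol = out[trend_col].to_numpy(dtype=object)
        tcol[miss_trend] = trend[miss_trend]
        out[trend_col] = tcol
    return ImputationResult(out, prov, it, converged)


# ---------------------------------------------------------------------------
# Leave-one-out validation
# ---------------------------------------------------------------------------


def loo_validate(
    table: pd.DataFrame,
    tree: PhyloTree,
    k_eigen: int | None = None,
    max_iter: int = 10,
    tol: float = 1e-3,
    seed: int = 0,
    continuous_cols: list[str] | None = None,
    trend_col: str | None = "trend",
    max_cells_per_column: int | None = None,
    ridge_alpha: float | str = "cv",
    fixed_cols: list[str] | None = None,
) -> ValidationReport:
    """Hide each observed cell in turn, re-impute, and score the predictions.

    Continuous columns report predictive R^2 = 1 - SSE/SST (negative values
    are reported as computed); the trend reports a confusion matrix over the
    held-out labels with overall accuracy and Cohen's kappa.
    ``max_cells_per_column`` caps the held-out cells per column (seeded
    subsample) to bound runtime on large tables.
    """
    cols = list(continuous_cols) if continuous_cols is not None else [
        c for c in DEFAULT_CONTINUOUS if c in table.columns
    ]
    species = list(table.index)
    n = len(species)
    if k_eigen is None:
        k_eigen = min(30, n - 1)
    labels, vecs = phylo_eigenvectors(tree, min(k_eigen, n - 1))
    evec = pd.DataFrame(vecs, index=labels).reindex(species).to_numpy()
    rng = np.random.default_rng(seed)

    def pick(idx: np.ndarray) -> np.ndarray:
        if max_cells_per_column is not None and len(idx) > max_cells_per_column:
            return np.sort(
                rng.choice(idx, size=max_cells_per_column, replace=False)
            )
        return idx

    common = dict(
        tree=tree, k_eigen=k_eigen, max_iter=max_iter, tol=tol, seed=seed,
        continuous_cols=cols, trend_col=trend_col, ridge_alpha=ridge_alpha,
        eigenvectors=evec, fixed_cols=fixed_cols,
    )

    r2: dict[str, float] = {}
    n_heldout: dict[str, int] = {}
    for col in cols:
        obs_idx = np.nonzero(table[col].notna().to_numpy())[0]
        obs_idx = pick(obs_idx)
        if obs_idx.size == 0:
            continue
        preds, obs = [], []
        for i in obs_idx:
            holdout = table.copy()
            holdout.iloc[i, holdout.columns.get_loc(col)] = np.nan
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = impute(holdout, **common)
            preds.append(float(res.table[col].iloc[i]))
            obs.append(float(table[col].iloc[i]))
        preds = np.array(preds)
        obs = np.array(obs)
        if col == "body_size_mm":     # score on the modeled (log) scale
            preds, obs = np.log(preds), np.log(obs)
        sse = float(np.sum((obs - preds) ** 2))
        sst = float(np.sum((obs - obs.mean()) ** 2))
        r2[col] = 1.0 - sse / sst if sst > 0 else float("nan")
        n_heldout[col] = int(obs_idx.size)

    confusion = None
    accuracy = None
    kap = None
    if trend_col is not None and trend_col in table.columns:
        observed = ~_trend_missing(table[trend_col])
        obs_idx = pick(np.nonzero(observed)[0])
        if obs_idx.size:
            true_labels, pred_labels = [], []
            for i in obs_idx:
                holdout = table.copy()
                holdout.iloc[i, holdout.columns.get_loc(trend_col)] = np.nan
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = impute(holdout, **common)
                true_labels.append(str(table[trend_col].iloc[i]))
                pred_labels.append(str(res.table[trend_col].iloc[i]))
            classes = [c for c in TREND_CLASSES
                       if c in set(true_labels) | set(pred_labels)]
            mat = np.zeros((len(classes), len(classes)), dtype=int)
            cidx = {c: k for k, c in enumerate(classes)}
            for t, p in zip(true_labels, pred_labels):
                mat[cidx[t], cidx[p]] += 1
            confusion = pd.DataFrame(mat, index=classes, columns=classes)
            accuracy = float(np.trace(mat) / mat.sum())
            kap = kappa(mat)
            n_heldout[trend_col] = int(obs_idx.size)
    return ValidationReport(r2, confusion, accuracy, kap, n_heldout)
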