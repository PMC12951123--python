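"""Exhaustive all-subsets model comparison by DIC and ensemble validation.

Every subset of the candidate predictors (2^p models, 256 for the canonical
eight) is fitted and ranked by the deviance information criterion; models
within 2 DIC units of the best form the candidate set. The selected model is
then refitted across an ensemble of alternative topologies and its posterior
draws pooled, propagating phylogenetic uncertainty into the reported
coefficients.

Model-search chains default to a shorter profile than the final/ensemble fits:
DIC rankings stabilize well before the coefficient summaries do, and fitting
every subset at full length buys nothing. Both profiles are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CHAIN_PROFILES, PhyloProbitMM, PhyloProbitMMResults
from .trees import PhyloTree


def enumerate_models(predictors: list[str]) -> list[tuple[str, ...]]:
    """All subsets of the predictors, in binary counting order.

    Bit j of the subset index selects ``predictors[j]``; the empty subset
    (intercept-only model) comes first.
    """
    if len(set(predictors)) != len(predictors):
        raise ValueError("predictor names must be unique")
    out = []
    for mask in range(2 ** len(predictors)):
        out.append(
            tuple(p for j, p in enumerate(predictors) if mask >> j & 1)
        )
    return out


@dataclass
class ModelSelectionResult:
    """Per-subset DIC records, the ΔDIC < 2 candidate set, and the selection."""

    records: pd.DataFrame          # columns: subset, n_predictors, dic, delta_dic
    candidates: list[tuple[str, ...]]
    selected: tuple[str, ...]
    policy: str

    def to_dict(self) -> dict:
        return {
            "policy": self.policy,
            "selected": list(self.selected),
            "candidates": [list(c) for c in self.candidates],
            "records": [
                {
                    "subset": list(r.subset),
                    "dic": float(r.dic),
                    "delta_dic": float(r.delta_dic),
                }
                for r in self.records.itertuples()
            ],
        }


def select_by_dic(
    dics: dict[tuple[str, ...], float],
    policy: str = "parsimony",
    forced: list[str] | None = None,
) -> ModelSelectionResult:
    """Apply the ΔDIC < 2 rule and a tie-break policy to per-subset DICs.

    ``parsimony`` picks the candidate with the fewest predictors (ties by
    lower DIC). ``forced`` picks the smallest-ΔDIC candidate containing every
    named predictor — a mechanization of choosing the most informative model
    among statistically equivalent candidates; reports using it must label
    the choice as such.
    """
    if not dics:
        raise ValueError("no models to select among")
    items = sorted(dics.items(), key=lambda kv: (kv[1], len(kv[0]), kv[0]))
    best = items[0][1]
    records = pd.DataFrame(
        {
            "subset": [k for k, _ in items],
            "n_predictors": [len(k) for k, _ in items],
            "dic": [v for _, v in items],
            "delta_dic": [v - best for _, v in items],
        }
    )
    candidates = [k for k, v in items if v - best < 2.0]
    if policy == "parsimony":
        selected = min(candidates, key=lambda c: (len(c), dics[c]))
    elif policy == "forced":
        req = set(forced or [])
        viable = [c for c in candidates if req <= set(c)]
        if not viable:
            raise ValueError(
                f"no ΔDIC<2 candidate contains all of {sorted(req)}"
            )
        selected = min(viable, key=lambda c: dics[c])
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return ModelSelectionResult(records, candidates, selected, policy)


def all_subsets_dic(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    tree: PhyloTree,
    chain: dict | None = None,
    seed: int = 0,
    **model_kwargs,
) -> dict[tuple[str, ...], float]:
    """Fit every predictor subset and return its DIC.

    Rows with any missing value among response/predictors are dropped once,
    up front, so every subset is fitted (and its deviance computed) on the
    identical species set; otherwise DICs would not be comparable.
    """
    chain = dict(chain or CHAIN_PROFILES["search"])
    complete = data[[response] + list(predictors)].dropna()
    subsets = enumerate_models(list(predictors))
    seeds = np.random.SeedSequence(seed).generate_state(len(subsets))
    # the species set is identical for every subset, so the pruned tree and
    # its correlation matrix are computed once
    from .trees import vcv

    tree_p = tree.prune_to(list(complete.index))
    a = vcv(tree_p).correlation()
    order = [a.labels.index(s) for s in complete.index]
    amat = a.matrix[np.ix_(order, order)]
    y = complete[response].to_numpy()
    ones = np.ones(len(complete))
    out: dict[tuple[str, ...], float] = {}
    for sub, s in zip(subsets, seeds):
        x = np.column_stack(
            [ones] + [complete[c].to_numpy(dtype=float) for c in sub]
        )
        m = PhyloProbitMM(
            y, x, amat, exog_names=["intercept"] + list(sub),
            labels=list(complete.index), **model_kwargs,
        )
        res = m.fit(seed=int(s) & 0x7FFFFFFF, **chain)
        out[sub] = res.dic()[2]
    return out


# ---------------------------------------------------------------------------
# Topology-ensemble validation
# ---------------------------------------------------------------------------


@dataclass
class EnsembleSummary:
    """Pooled posterior across a topology ensemble.

    Draws from the per-topology fits are concatenated with equal weight; the
    pooled mean, 95% equal-tail interval and CI-excludes-zero flag are
    reported per coefficient, alongside the per-topology summaries.
    """

    coef: pd.DataFrame              # post_mean, ci_low, ci_high, significant
    sigma2_p: dict[str, float]
    per_topology: list[pd.DataFrame]
    n_topologies: int
    pooled_draws: int

    def to_dict(self) -> dict:
        return {
            "coef": {
                name: {
                    "post_mean": float(row.post_mean),
                    "ci_low": float(row.ci_low),
                    "ci_high": float(row.ci_high),
                    "significant": bool(row.significant),
                }
                for name, row in self.coef.iterrows()
            },
            "sigma2_p": {k: float(v) for k, v in self.sigma2_p.items()},
            "n_topologies": self.n_topologies,
            "pooled_draws": self.pooled_draws,
        }


def ensemble_fit(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    trees: list[PhyloTree],
    chain: dict | None = None,
    seed: int = 0,
    **model_kwargs,
) -> EnsembleSummary:
    """Fit the selected model once per topology and pool the draws."""
    if len(trees) < 1:
        raise ValueError("need at least one tree")
    tipsets = {frozenset(t.tips) for t in trees}
    if len(tipsets) != 1:
        raise ValueError("trees have differing tip sets")
    chain = dict(chain or CHAIN_PROFILES["test"])
    seeds = np.random.SeedSequence(seed).generate_state(len(trees))
    all_beta, all_s2 = [], []
    per_topology = []
    names = None
    for tree, s in zip(trees, seeds):
        m = PhyloProbitMM.from_dataframe(
            data, response, list(predictors), tree, **model_kwargs
        )
        res = m.fit(seed=int(s) & 0x7FFFFFFF, **chain)
        names = m.exog_names
        all_beta.append(res.draws_beta)
        all_s2.append(res.draws_sigma2_p)
        per_topology.append(res.summary())
    beta = np.vstack(all_beta)
    s2 = np.concatenate(all_s2)
    lo, hi = np.quantile(beta, [0.025, 0.975], axis=0)
    coef = pd.DataFrame(
        {
            "post_mean": beta.mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
        },
        index=names,
    )
    coef["significant"] = (coef["ci_low"] > 0) | (coef["ci_high"] < 0)
    return EnsembleSummary(
        coef=coef,
        sigma2_p={
            "post_mean": float(s2.mean()),
            "post_median": float(np.median(s2)),
            "ci_low": float(np.quantile(s2, 0.025)),
            "ci_high": float(np.quantile(s2, 0.975)),
        },
        per_topology=per_topology,
        n_topologies=len(trees),
        pooled_draws=int(beta.shape[0]),
    )
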