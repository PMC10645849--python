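"""Evaluation: ranking metrics and the repeated experiment grid.

AUC-ROC is computed in its Mann–Whitney form — the probability that a
random positive outranks a random negative, ties credited one half — via
midranks. AUC-PR is average precision: the step-wise sum of precision at
each distinct score threshold weighted by the recall increment, which
avoids the optimism of linearly interpolated PR curves.

The experiment grid mirrors the study design: the reconstruction-error
detector is run for the raw-feature baseline plus each embedding method at
dimensions 16/32/64, each repeated over several seeds (embedding and
autoencoder initialisation vary; the cohort is fixed), and mean AUCs are
reported per method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import CohortTable
from .gae import ScoreConfig, score_outliers


class EvalError(ValueError):
    pass


def _check(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise EvalError("scores and labels must be equal-length 1-D arrays")
    if not set(np.unique(y)) <= {0, 1}:
        raise EvalError("labels must be binary 0/1")
    return s, y


def auc_roc(scores, labels) -> float:
    """P(score of random positive > score of random negative), ties → 0.5."""
    s, y = _check(scores, labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvalError("labels must contain both classes")
    ranks = rankdata(s)  # midranks handle ties exactly as half-credit
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_pr(scores, labels) -> float:
    """Average precision with grouped (tied) thresholds, descending scores."""
    s, y = _check(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise EvalError("need at least one positive label")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # indices closing each distinct-threshold group
    ends = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    tp = np.cumsum(y)[ends]
    predicted = ends + 1.0
    precision = tp / predicted
    recall = tp / n_pos
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


@dataclass
class EvalResult:
    method_tag: str
    auc_roc_per_seed: list[float]
    auc_pr_per_seed: list[float]

    @property
    def auc_roc_mean(self) -> float:
        return float(np.mean(self.auc_roc_per_seed))

    @property
    def auc_pr_mean(self) -> float:
        return float(np.mean(self.auc_pr_per_seed))


def run_repeated(table: CohortTable, method_spec: str, outcome: str,
                 config: ScoreConfig | None = None, repeats: int = 10,
                 base_seed: int = 0) -> EvalResult:
    """Score the cohort ``repeats`` times with seeds base_seed..base_seed+r-1."""
    if repeats < 1:
        raise EvalError("repeats must be >= 1")
    if outcome not in table.labels.columns:
        raise EvalError(f"unknown outcome {outcome!r}")
    y = table.labels[outcome].to_numpy()
    config = config or ScoreConfig()
    rocs, prs = [], []
    for r in range(repeats):
        cfg = ScoreConfig(train=config.train, walk=config.walk,
                          skipgram=config.skipgram,
                          include_outcome=config.include_outcome,
                          seed=base_seed + r)
        sc = score_outliers(table, method_spec, cfg)
        rocs.append(auc_roc(sc.errors, y))
        prs.append(auc_pr(sc.errors, y))
    return EvalResult(method_tag=method_spec, auc_roc_per_seed=rocs,
                      auc_pr_per_seed=prs)


#: Row labels of the results table, in publication order.
GRID_METHODS = (
    ("Original", "original"),
    ("FastRP 16", "fastrp-16"),
    ("FastRP 32", "fastrp-32"),
    ("FastRP 64", "fastrp-64"),
    ("Node2Vec 16", "node2vec-16"),
    ("Node2Vec 32", "node2vec-32"),
    ("Node2Vec 64", "node2vec-64"),
    ("combine 16", "combine-16"),
    ("combine 32", "combine-32"),
    ("combine 64", "combine-64"),
)


def experiment_grid(table: CohortTable, outcome: str,
                    config: ScoreConfig | None = None, repeats: int = 10,
                    base_seed: int = 0, dims: tuple = (16, 32, 64)) -> pd.DataFrame:
    """One mean-AUC row per method variant: baseline + 3 families x dims."""
    rows = []
    for label, spec in GRID_METHODS:
        if spec != "original":
            fam, d = spec.rsplit("-", 1)
            if int(d) not in dims:
                continue
        res = run_repeated(table, spec, outcome, config, repeats, base_seed)
        row = {
            "method": label,
            "dim": None if spec == "original" else int(spec.rsplit("-", 1)[1]),
            "auc_roc_mean": res.auc_roc_mean,
            "auc_pr_mean": res.auc_pr_mean,
        }
        for i, (a, p) in enumerate(zip(res.auc_roc_per_seed, res.auc_pr_per_seed)):
            row[f"auc_roc_seed{base_seed + i}"] = a
            row[f"auc_pr_seed{base_seed + i}"] = p
        rows.append(row)
    df = pd.DataFrame(rows)
    best = df["auc_roc_mean"].idxmax()
    df["best_auc_roc"] = False
    df.loc[best, "best_auc_roc"] = True
    return df


def k_sensitivity(table: CohortTable, outcome: str, k_values: list[int],
                  method_spec: str = "original", config: ScoreConfig | None = None,
                  repeats: int = 3, base_seed: int = 0) -> pd.DataFrame:
    """Mean AUC-ROC as a function of the propagation-graph neighbour count k.

    The same seed set is reused at every k so the curve isolates the effect
    of the graph, not of initialisation noise.
    """
    from dataclasses import replace as _replace
    config = config or ScoreConfig()
    rows = []
    for k in k_values:
        if k >= table.n:
            raise EvalError(f"k = {k} must be smaller than n = {table.n}")
        cfg = ScoreConfig(train=_replace(config.train, k=k), walk=config.walk,
                          skipgram=config.skipgram,
                          include_outcome=config.include_outcome, seed=config.seed)
        res = run_repeated(table, method_spec, outcome, cfg, repeats, base_seed)
        rows.append({"k": k, "auc_roc_mean": res.auc_roc_mean,
                     "auc_pr_mean": res.auc_pr_mean})
    return pd.DataFrame(rows)
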