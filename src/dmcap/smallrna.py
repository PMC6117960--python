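"""Small-RNA differential expression: TPM normalization and a
group-label permutation test.

Counts of small-RNA species (miRNA, tRF, piRNA, rRNA, ...) are
normalized to transcripts per kilobase million (TPM): each feature's
count is divided by its length in kb, and the per-sample rates are
rescaled to sum to 1e6.  Because small-RNA lengths are near-constant,
the default length of 1 kb for every feature reduces TPM to counts per
million.  Differential expression between case and control groups is
assessed by a two-sided permutation test on the difference of group
means of log2(TPM + 1), with Benjamini-Hochberg q-values; features with
q < 0.05 are called significant.
"""
from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

SUBTYPES = ("miRNA", "tRF", "piRNA", "rRNA", "other")


def tpm_normalize(counts: pd.DataFrame,
                  lengths: pd.Series | None = None) -> pd.DataFrame:
    """TPM-normalize a feature x sample count table.

    ``lengths`` gives per-feature lengths in nt; absent lengths default
    to 1 kb for all features (counts-per-million equivalent).  Samples
    with zero total count are dropped with a warning.  Each returned
    column sums to 1e6.
    """
    counts = counts.astype(float)
    if (counts < 0).to_numpy().any():
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=0)
    dead = totals[totals == 0].index.tolist()
    if dead:
        logger.warning("dropping zero-total samples: %s", dead)
        counts = counts.drop(columns=dead)
    if lengths is None:
        kb = pd.Series(1.0, index=counts.index)
    else:
        kb = lengths.reindex(counts.index).astype(float) / 1000.0
        if kb.isna().any() or (kb <= 0).any():
            raise ValueError("every feature needs a positive length")
    rates = counts.div(kb, axis=0)
    return rates.div(rates.sum(axis=0), axis=1) * 1e6


def _de_stats(log_tpm: np.ndarray, case_cols: np.ndarray) -> np.ndarray:
    mask = np.zeros(log_tpm.shape[1], dtype=bool)
    mask[case_cols] = True
    return log_tpm[:, mask].mean(axis=1) - log_tpm[:, ~mask].mean(axis=1)


def permutation_de(tpm: pd.DataFrame, groups: pd.Series, n_perm: int = 10000,
                   seed: int = 0, alpha: float = 0.05,
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """Two-sided permutation test per feature between case and control.

    Statistic: difference of group means of log2(TPM + pseudocount).
    Group labels are permuted across samples; all distinct label
    assignments are enumerated when their number is <= n_perm (exact
    test, identity assignment counted in the tail), otherwise n_perm
    random permutations with an add-one estimator.  Constant features
    get p = 1 by convention.  Returns a DataFrame with columns
    feature_id, log2FC, p, q, significant.
    """
    groups = groups.reindex(tpm.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    case_cols = np.flatnonzero((groups == "case").to_numpy())
    ctrl_cols = np.flatnonzero((groups == "control").to_numpy())
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    n_samples = tpm.shape[1]
    log_tpm = np.log2(tpm.to_numpy(dtype=float) + pseudocount)
    obs = _de_stats(log_tpm, case_cols)
    constant = (log_tpm.max(axis=1) - log_tpm.min(axis=1)) == 0

    total = math.comb(n_samples, len(case_cols))
    if total <= n_perm:
        perm_stats = np.column_stack(
            [_de_stats(log_tpm, np.array(c))
             for c in combinations(range(n_samples), len(case_cols))]
        )
        tail = (np.abs(perm_stats) >= np.abs(obs)[:, None]).sum(axis=1)
        p = tail / total
    else:
        rng = np.random.default_rng(seed)
        tail = np.zeros(len(obs))
        for _ in range(n_perm):
            perm = np.sort(rng.permutation(n_samples)[:len(case_cols)])
            tail += np.abs(_de_stats(log_tpm, perm)) >= np.abs(obs)
        p = (1.0 + tail) / (1.0 + n_perm)
    p = np.where(constant, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "feature_id": tpm.index,
        "log2FC": obs,
        "p": p,
        "q": q,
        "significant": q < alpha,
    }).reset_index(drop=True)


def subtype_composition(counts: pd.DataFrame, subtypes: pd.Series) -> pd.DataFrame:
    """Per-sample fraction of counts attributed to each small-RNA subtype.

    Fractions sum to 1 per sample.  Returns a subtype x sample table.
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample needs a positive total count")
    by_subtype = counts.groupby(subtypes.reindex(counts.index)).sum()
    return by_subtype.div(totals, axis=1)


class TPMNormalizer(BaseEstimator, TransformerMixin):
    """TPM normalization as a scikit-learn transformer.

    ``X`` follows the sklearn convention (n_samples, n_features);
    ``transform`` rescales each sample (row) to sum to 1e6 after
    dividing by feature lengths in kb (default 1 kb each).
    """

    def __init__(self, lengths_nt=None):
        self.lengths_nt = lengths_nt

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.lengths_nt is not None and len(self.lengths_nt) != X.shape[1]:
            raise ValueError("lengths_nt must have one entry per feature")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if (X < 0).any():
            raise ValueError("counts must be nonnegative")
        kb = (np.asarray(self.lengths_nt, dtype=float) / 1000.0
              if self.lengths_nt is not None else np.ones(X.shape[1]))
        rates = X / kb
        totals = rates.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise ValueError("zero-total sample cannot be TPM-normalized")
        return rates / totals * 1e6


class SmallRNAPermutationDE(BaseEstimator):
    """Permutation differential-expression test as a sklearn estimator.

    ``fit(X, y)`` with ``X`` (n_samples, n_features) TPM values and
    ``y`` per-sample "case"/"control" labels populates ``results_``.
    """

    def __init__(self, n_perm: int = 10000, random_state: int = 0,
                 alpha: float = 0.05, pseudocount: float = 1.0):
        self.n_perm = n_perm
        self.random_state = random_state
        self.alpha = alpha
        self.pseudocount = pseudocount

    def fit(self, X, y, *, feature_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != len(y):
            raise ValueError("X rows must match y")
        ids = (np.asarray(feature_ids, dtype=object) if feature_ids is not None
               else np.array([f"f{i}" for i in range(X.shape[1])], dtype=object))
        tpm = pd.DataFrame(X.T, index=ids,
                           columns=[f"s{i}" for i in range(X.shape[0])])
        groups = pd.Series(y, index=tpm.columns)
        self.results_ = permutation_de(tpm, groups, n_perm=self.n_perm,
                                       seed=self.random_state, alpha=self.alpha,
                                       pseudocount=self.pseudocount)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X=None) -> np.ndarray:
        sig = self.results_["significant"].to_numpy()
        return np.where(sig, np.sign(self.results_["log2FC"].to_numpy()), 0)
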