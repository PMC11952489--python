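"""Decay-covariate feature engineering and resampled LASSO harness.

Numeric features are standardized (optionally log10 first for features
spanning orders of magnitude).  Categorical features are encoded by ordering
levels on their average outcome, pooling to at most 10 groups, then
z-scoring the per-row group ranks — which makes L1 coefficients comparable
across feature types.  Feature importances are assessed over 100 bootstrap
resamples (regression on log kdeg) or 100 class-balanced downsamplings
(classification of NMD-inhibitor sensitivity), with the L1 penalty chosen by
10-fold cross-validation inside each resample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV, LogisticRegressionCV


@dataclass
class FeatureEncoder:
    """Deterministic feature engineering fit on a training table."""

    categorical: list[str] = field(default_factory=list)
    log10_threshold: float = 100.0
    max_groups: int = 10
    # fitted state
    numeric_stats_: dict[str, tuple[float, float, bool]] = field(default_factory=dict)
    category_ranks_: dict[str, dict] = field(default_factory=dict)
    rank_stats_: dict[str, tuple[float, float]] = field(default_factory=dict)
    dropped_: list[str] = field(default_factory=list)

    def fit_transform(self, raw: pd.DataFrame, outcome: pd.Series) -> pd.DataFrame:
        out = {}
        for col in raw.columns:
            x = raw[col]
            if col in self.categorical:
                out[col] = self._fit_categorical(col, x, outcome)
            else:
                x = pd.to_numeric(x)
                sd = float(x.std(ddof=0))
                if sd == 0:
                    warnings.warn(f"constant feature '{col}' dropped", stacklevel=2)
                    self.dropped_.append(col)
                    continue
                use_log = bool(
                    (x > 0).all() and x.max() / max(x.min(), 1e-300) > self.log10_threshold
                )
                v = np.log10(x) if use_log else x.astype(float)
                mu, sd = float(v.mean()), float(v.std(ddof=0))
                self.numeric_stats_[col] = (mu, sd, use_log)
                out[col] = (v - mu) / sd
        return pd.DataFrame(out, index=raw.index)

    def transform(self, raw: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col, (mu, sd, use_log) in self.numeric_stats_.items():
            v = np.log10(pd.to_numeric(raw[col])) if use_log else raw[col].astype(float)
            out[col] = (v - mu) / sd
        for col, ranks in self.category_ranks_.items():
            mean_rank = float(np.mean(list(ranks.values())))
            vals = raw[col].map(ranks)
            if vals.isna().any():
                warnings.warn(
                    f"unseen level(s) in '{col}' assigned the mean rank", stacklevel=2
                )
                vals = vals.fillna(mean_rank)
            mu, sd = self.rank_stats_[col]
            out[col] = (vals - mu) / sd
        return pd.DataFrame(out, index=raw.index)

    def _fit_categorical(self, col: str, x: pd.Series, outcome: pd.Series) -> pd.Series:
        means = outcome.groupby(x, observed=True).mean().sort_values()
        groups = [[lvl] for lvl in means.index]
        values = list(means.values)
        # pool adjacent (rank-neighbouring) groups with the closest mean
        # outcome until at most max_groups remain
        while len(groups) > self.max_groups:
            gaps = np.diff(values)
            j = int(np.argmin(gaps))
            merged_levels = groups[j] + groups[j + 1]
            sel = x.isin(merged_levels)
            merged_mean = float(outcome[sel].mean())
            groups[j : j + 2] = [merged_levels]
            values[j : j + 2] = [merged_mean]
        ranks = {}
        for rank, levels in enumerate(groups, start=1):
            for lvl in levels:
                ranks[lvl] = float(rank)
        self.category_ranks_[col] = ranks
        v = x.map(ranks).astype(float)
        mu, sd = float(v.mean()), float(v.std(ddof=0))
        if sd == 0:
            sd = 1.0
        self.rank_stats_[col] = (mu, sd)
        return (v - mu) / sd


def encode_features(
    raw: pd.DataFrame,
    outcome: pd.Series,
    categorical: list[str] | None = None,
) -> tuple[pd.DataFrame, FeatureEncoder]:
    """Encode a raw feature table; returns (encoded table, fitted encoder)."""
    enc = FeatureEncoder(categorical=categorical or [])
    return enc.fit_transform(raw, outcome), enc


def lasso_regress(
    features: pd.DataFrame,
    outcome: pd.Series,
    n_boot: int = 100,
    cv: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap distribution of L1-penalized regression coefficients.

    Each of ``n_boot`` bootstrap resamples refits a LASSO with the penalty
    chosen by ``cv``-fold cross-validation (minimum CV error rule).  Returns
    an (n_boot x features) coefficient frame.
    """
    x = features.to_numpy(float)
    y = np.asarray(outcome, float)
    n, p = x.shape
    if n < 10 * p:
        warnings.warn(
            f"only {n} rows for {p} features; coefficient estimates may be unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    coefs = np.empty((n_boot, p))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        model = LassoCV(cv=cv, random_state=int(rng.integers(2**31)), alphas=50)
        model.fit(x[idx], y[idx])
        coefs[b] = model.coef_
    return pd.DataFrame(coefs, columns=list(features.columns))


def label_sensitivity(
    diff: pd.DataFrame,
    l2fc_sensitive: float = -0.7,
    kdeg_ratio: float = 0.65,
    l2fc_insensitive: float = -0.1,
) -> pd.Series:
    """Three-way NMD-inhibitor sensitivity call per isoform.

    ``diff`` is a :func:`isodeg.differential.compare_kdeg` output (condition
    B = inhibitor).  Sensitive: L2FC(kdeg) < ``l2fc_sensitive`` AND the
    post-inhibition kdeg is below ``kdeg_ratio`` of its pre-inhibition value.
    Insensitive: L2FC at or above ``l2fc_insensitive`` (about zero, or
    positive).  Everything else — including rows without a finite
    uncertainty — is excluded.
    """
    ratio = np.exp(diff["mean_log_kdeg_B"] - diff["mean_log_kdeg_A"])
    ok = np.isfinite(diff["se_L2FC"])
    sensitive = ok & (diff["L2FC_kdeg"] < l2fc_sensitive) & (ratio < kdeg_ratio)
    insensitive = ok & (diff["L2FC_kdeg"] >= l2fc_insensitive)
    out = pd.Series("excluded", index=diff.index)
    out[sensitive] = "sensitive"
    out[insensitive] = "insensitive"
    return out


def label_high_confidence_sensitive(
    diff: pd.DataFrame,
    jcc: pd.DataFrame | None = None,
    unsupported: pd.DataFrame | None = None,
    l2fc_cutoff: float = -1.0,
    padj_cutoff: float = 0.01,
    jcc_cutoff: float = 0.4,
) -> pd.Series:
    """High-confidence sensitivity call: L2FC < -1, FDR < 0.01, plus
    annotation-support gates (unsupported-isoform flag and gene JCC < 0.4)."""
    call = (diff["L2FC_kdeg"] < l2fc_cutoff) & (diff["padj"] < padj_cutoff)
    if jcc is not None:
        good_genes = set(jcc[(jcc["jcc"] < jcc_cutoff)]["gene"])
        call &= diff["gene"].isin(good_genes)
    if unsupported is not None:
        bad = set(unsupported[unsupported["unsupported"]]["transcript"])
        call &= ~diff["transcript"].isin(bad)
    return call


def lasso_classify(
    features: pd.DataFrame,
    labels: pd.Series,
    n_downsample: int = 100,
    cv: int = 10,
    seed: int = 0,
    min_positive: int = 20,
) -> pd.DataFrame:
    """Downsampled-balanced L1 logistic coefficient distributions.

    ``labels`` holds 'sensitive' / 'insensitive' (excluded rows should be
    dropped beforehand).  The majority class is downsampled to the minority
    size ``n_downsample`` times; each balanced set is fit with an L1 logistic
    model, penalty by ``cv``-fold cross-validation.
    """
    y = (labels == "sensitive").to_numpy()
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    if len(pos_idx) < min_positive:
        raise ValueError(
            f"only {len(pos_idx)} sensitive isoforms (< {min_positive}); refusing to fit"
        )
    minority, majority = (
        (pos_idx, neg_idx) if len(pos_idx) <= len(neg_idx) else (neg_idx, pos_idx)
    )
    x = features.to_numpy(float)
    rng = np.random.default_rng(seed)
    coefs = np.empty((n_downsample, x.shape[1]))
    for b in range(n_downsample):
        down = rng.choice(majority, size=len(minority), replace=False)
        idx = np.concatenate([minority, down])
        model = LogisticRegressionCV(
            penalty="l1",
            solver="liblinear",
            cv=cv,
            Cs=10,
            random_state=int(rng.integers(2**31)),
            max_iter=2000,
        )
        model.fit(x[idx], y[idx])
        coefs[b] = model.coef_[0]
    return pd.DataFrame(coefs, columns=list(features.columns))


NUCLEOTIDES = "ACGT"


def kozak_score(window: str, pssm: np.ndarray) -> float:
    """Translation-initiation context score: positional sum over a 10-nt window.

    ``pssm`` is a (10, 4) matrix over A, C, G, T.  Ambiguous bases (N)
    contribute zero and trigger a warning.
    """
    pssm = np.asarray(pssm, float)
    if pssm.shape != (10, 4):
        raise ValueError("PSSM must be 10 positions x 4 nucleotides")
    if len(window) != 10:
        raise ValueError("Kozak window must be exactly 10 nt")
    score = 0.0
    flagged = False
    for i, base in enumerate(window.upper()):
        j = NUCLEOTIDES.find(base)
        if j < 0:
            flagged = True
            continue
        score += float(pssm[i, j])
    if flagged:
        warnings.warn("window contains non-ACGT base(s); they contribute 0", stacklevel=2)
    return score


def example_pssm(seed: int = 7) -> np.ndarray:
    """A synthetic stand-in scoring matrix for tests and examples.

    Real analyses should supply a matrix derived from experimentally
    characterized initiation-context preferences; this one is random and
    carries no biological meaning.
    """
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 1.0, size=(10, 4))


__all__ = [
    "FeatureEncoder",
    "encode_features",
    "lasso_regress",
    "lasso_classify",
    "label_sensitivity",
    "label_high_confidence_sensitive",
    "kozak_score",
    "example_pssm",
]
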