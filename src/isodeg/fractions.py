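"""Per-TEC fraction-new estimation from T-to-C mutation counts.

Reads from RNA synthesized during the s4U labeling window ("new" reads)
carry T-to-C conversions at a high per-T rate ``pnew``; pre-existing ("old")
RNA shows only the sequencing/SNP background ``pold``.  For one TEC the read
counts follow a two-component binomial mixture with mixing weight theta, the
TEC fraction new.  ``pold`` comes from unlabeled control samples; ``pnew`` is
estimated per labeled sample by EM with a sample-global nuisance theta; the
per-TEC theta is then a 1-D maximum-likelihood fit with rates held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit, gammaln, logit

from .io import MutationCountTable


@dataclass(frozen=True)
class MixtureRates:
    """Per-T conversion probabilities for new and old reads."""

    pnew: float
    pold: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pold < self.pnew <= 1.0):
            raise ValueError(
                f"require 0 <= pold < pnew <= 1, got pold={self.pold}, pnew={self.pnew}"
            )


class ConvergenceError(RuntimeError):
    """EM failed to converge; carries the log-likelihood trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def _log_binom_pmf(k: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    if p <= 0.0:
        out = np.full(k.shape, -np.inf)
        out[k == 0] = 0.0
        return out
    if p >= 1.0:
        out = np.full(k.shape, -np.inf)
        out[k == n] = 0.0
        return out
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )


def estimate_pold(nolabel: MutationCountTable) -> float:
    """Background T-to-C rate from no-label controls: total TC / total T."""
    df = nolabel.data
    if len(df) == 0:
        raise ValueError("no-label table is empty; cannot estimate pold")
    total_t = float((df["n"] * df["nT"]).sum())
    if total_t == 0:
        return 0.0
    return float((df["n"] * df["TC"]).sum()) / total_t


def estimate_pnew(
    label: MutationCountTable,
    pold: float,
    init_pnew: float = 0.05,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> float:
    """Per-sample high conversion rate via EM on the pooled binomial mixture.

    The marginal likelihood per read signature is
    ``theta * Binom(TC; nT, pnew) + (1 - theta) * Binom(TC; nT, pold)`` with a
    sample-global nuisance theta.  ``pnew > pold`` is enforced at every step.
    """
    df = label.data
    if len(df) == 0:
        raise ValueError("labeled table is empty; cannot estimate pnew")
    k = df["TC"].to_numpy(float)
    nt = df["nT"].to_numpy(float)
    w = df["n"].to_numpy(float)
    usable = nt > 0
    if not usable.any():
        raise ValueError("no reads with T content; pnew unidentifiable")
    k, nt, w = k[usable], nt[usable], w[usable]

    pnew = max(init_pnew, pold * 2 + 1e-4)
    theta = 0.5
    trace: list[float] = []
    ll_old = -np.inf
    for _ in range(max_iter):
        la = _log_binom_pmf(k, nt, pnew) + np.log(theta)
        lb = _log_binom_pmf(k, nt, pold) + np.log1p(-theta)
        m = np.maximum(la, lb)
        ll = float((w * (m + np.log(np.exp(la - m) + np.exp(lb - m)))).sum())
        trace.append(ll)
        r = np.exp(la - m) / (np.exp(la - m) + np.exp(lb - m))
        theta_new = float(np.clip((w * r).sum() / w.sum(), 1e-8, 1 - 1e-8))
        denom = (w * r * nt).sum()
        pnew_new = float((w * r * k).sum() / denom) if denom > 0 else pnew
        pnew_new = min(max(pnew_new, pold * (1 + 1e-9) + 1e-12), 1.0)
        # EM is sublinear when theta sits at a boundary; the estimand pnew
        # stabilizes much earlier, so stop on either criterion
        param_done = (
            abs(pnew_new - pnew) < 1e-7 and abs(theta_new - theta) < 1e-5
        )
        theta, pnew = theta_new, pnew_new
        if param_done or abs(ll - ll_old) < tol * (1 + abs(ll)):
            return pnew
        ll_old = ll
    raise ConvergenceError(
        f"pnew EM did not converge in {max_iter} iterations", trace
    )


@dataclass
class TECEstimate:
    sample: str
    gene: str
    tec: str
    theta_hat: float
    n: int
    se_logit: float


def _mixture_loglik(
    theta: float, k: np.ndarray, nt: np.ndarray, w: np.ndarray, rates: MixtureRates
) -> float:
    la = _log_binom_pmf(k, nt, rates.pnew)
    lb = _log_binom_pmf(k, nt, rates.pold)
    m = np.maximum(la, lb)
    mix = theta * np.exp(la - m) + (1.0 - theta) * np.exp(lb - m)
    return float((w * (m + np.log(np.maximum(mix, 1e-300)))).sum())


def estimate_tec_theta(
    rows: pd.DataFrame, rates: MixtureRates
) -> tuple[float, float]:
    """MLE of a single TEC's fraction new with conversion rates held fixed.

    Returns ``(theta_hat, se_logit)``.  theta_hat is clamped to
    ``[1/(n+2), 1-1/(n+2)]`` (add-a-pseudocount convention) so the Beta
    likelihood used downstream never degenerates; the standard error is from
    the observed Fisher information on the logit scale.
    """
    k = rows["TC"].to_numpy(float)
    nt = rows["nT"].to_numpy(float)
    w = rows["n"].to_numpy(float)
    n_reads = int(w.sum())
    if n_reads < 1:
        raise ValueError("TEC with no reads")
    if not (nt > 0).any():
        raise ValueError("TEC has no T-containing reads; theta undefined")

    lo = 1.0 / (n_reads + 2)
    hi = 1.0 - lo
    res = minimize_scalar(
        lambda th: -_mixture_loglik(th, k, nt, w, rates),
        bounds=(1e-9, 1 - 1e-9),
        method="bounded",
        options={"xatol": 1e-10},
    )
    theta = float(np.clip(res.x, lo, hi))

    # observed information on the logit scale via central differences
    x = logit(theta)
    h = 1e-4

    def ll_logit(xv: float) -> float:
        return _mixture_loglik(float(expit(xv)), k, nt, w, rates)

    info = -(ll_logit(x + h) - 2.0 * ll_logit(x) + ll_logit(x - h)) / h**2
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    return theta, se


def estimate_fractions(
    cb: MutationCountTable,
    nolabel_samples: list[str],
    pnew: float | None = None,
    pold: float | None = None,
) -> tuple[pd.DataFrame, dict[str, MixtureRates]]:
    """Fraction-new estimates for every (sample, gene, TEC) of labeled samples.

    Returns a tidy frame (sample, XF, TEC, theta, n, se_logit) and the
    per-sample mixture rates used.  Rates may be supplied to skip estimation.
    """
    nolabel = set(nolabel_samples)
    df = cb.data
    if pold is None:
        ctrl = df[df["sample"].isin(nolabel)]
        if len(ctrl) == 0:
            raise ValueError(
                "no no-label control rows found and pold not supplied"
            )
        pold = estimate_pold(MutationCountTable(ctrl.copy()))
    labeled = df[~df["sample"].isin(nolabel)]
    rates: dict[str, MixtureRates] = {}
    for sample, sub in labeled.groupby("sample", sort=True):
        pn = pnew if pnew is not None else estimate_pnew(
            MutationCountTable(sub.copy()), pold
        )
        rates[str(sample)] = MixtureRates(pn, pold)

    records = []
    skipped = 0
    for (sample, gene, tec), grp in labeled.groupby(
        ["sample", "XF", "TEC"], sort=True
    ):
        r = rates[str(sample)]
        try:
            theta, se = estimate_tec_theta(grp, r)
        except ValueError:
            skipped += 1
            continue
        records.append((sample, gene, tec, theta, int(grp["n"].sum()), se))
    if skipped:
        warnings.warn(
            f"{skipped} TEC(s) had no T-containing reads and were skipped",
            stacklevel=2,
        )
    out = pd.DataFrame(
        records, columns=["sample", "XF", "TEC", "theta", "n", "se_logit"]
    )
    return out, rates


def binomial_mixture_sample(
    rng: np.random.Generator,
    n_reads: int,
    theta: float,
    rates: MixtureRates,
    nt_mean: int = 20,
) -> pd.DataFrame:
    """Draw cB-style rows from the mixture model (testing/simulation helper)."""
    is_new = rng.random(n_reads) < theta
    nt = rng.binomial(4 * nt_mean, 0.25, size=n_reads)
    p = np.where(is_new, rates.pnew, rates.pold)
    tc = rng.binomial(nt, p)
    df = pd.DataFrame({"nT": nt, "TC": tc})
    out = df.groupby(["nT", "TC"], as_index=False).size()
    return out.rename(columns={"size": "n"})


__all__ = [
    "MixtureRates",
    "TECEstimate",
    "ConvergenceError",
    "estimate_pold",
    "estimate_pnew",
    "estimate_tec_theta",
    "estimate_fractions",
    "binomial_mixture_sample",
]
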