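"""Isoform fraction-new deconvolution and kinetic rate constants.

A short read is often compatible with several isoforms of a gene, so
fraction-new estimates are only available per transcript equivalence class
(TEC).  Each TEC's expected fraction new is a TPM-weighted convex combination
of its member isoforms' fraction news:

    theta_bar_i = sum_j p_ij * theta_j,   p_ij = TPM_j / sum_{k in TEC i} TPM_k

and the observed TEC estimate theta_hat_i is modeled as

    theta_hat_i ~ Beta(alpha = theta_bar_i * n_i, beta = n_i - theta_bar_i * n_i)

i.e. a Beta with mean theta_bar_i and concentration equal to the TEC read
count n_i.  Maximizing the joint Beta log-likelihood over logit(theta_j)
deconvolves isoform-level fraction news; standard errors come from the
inverse observed Hessian.  Fraction news convert to rate constants under the
steady-state one-compartment model:

    kdeg = -ln(1 - theta) / tlabel,      ksyn = TPM * kdeg
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, expit, logit

from .io import AbundanceTable, tec_members


@dataclass
class GeneMixingProblem:
    """One gene's TEC observations plus the TEC-by-isoform mixing weights."""

    gene: str
    tec_labels: list[str]
    theta_hat: np.ndarray  # (M,) clamped TEC fraction news
    n: np.ndarray  # (M,) TEC read counts
    isoforms: list[str]
    tpm: np.ndarray  # (N,) isoform abundances, all > 0
    membership: np.ndarray = field(init=False)  # (M, N) bool
    weights: np.ndarray = field(init=False)  # (M, N) rows sum to 1

    def __post_init__(self) -> None:
        self.theta_hat = np.asarray(self.theta_hat, float)
        self.n = np.asarray(self.n, float)
        self.tpm = np.asarray(self.tpm, float)
        if (self.tpm <= 0).any():
            raise ValueError("all modeled isoforms must have TPM > 0")
        m, nn = len(self.tec_labels), len(self.isoforms)
        idx = {iso: j for j, iso in enumerate(self.isoforms)}
        member = np.zeros((m, nn), dtype=bool)
        for i, label in enumerate(self.tec_labels):
            for iso in tec_members(label):
                if iso in idx:
                    member[i, idx[iso]] = True
        if not member.any(axis=1).all():
            raise ValueError("a TEC has no modeled isoform members")
        if not member.any(axis=0).all():
            raise ValueError("an isoform appears in no TEC")
        w = member * self.tpm[None, :]
        totals = w.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise ValueError("TEC with zero total TPM")
        self.membership = member
        self.weights = w / totals


def expected_tec_theta(
    problem: GeneMixingProblem, thetas: np.ndarray
) -> np.ndarray:
    """TEC-level fraction news implied by isoform fraction news."""
    thetas = np.asarray(thetas, float)
    if ((thetas <= 0) | (thetas >= 1)).any():
        raise ValueError("isoform fraction news must lie strictly in (0, 1)")
    return problem.weights @ thetas


def mixing_loglik(problem: GeneMixingProblem, thetas: np.ndarray) -> float:
    """Joint Beta log-likelihood of the TEC estimates given isoform thetas."""
    # clip rather than reject: quasi-Newton steps can graze the boundary
    thetas = np.clip(np.asarray(thetas, float), 1e-12, 1.0 - 1e-12)
    tbar = problem.weights @ thetas
    a = tbar * problem.n
    b = problem.n - a
    ll = (
        (a - 1.0) * np.log(problem.theta_hat)
        + (b - 1.0) * np.log1p(-problem.theta_hat)
        - betaln(a, b)
    )
    return float(ll.sum())


@dataclass
class IsoformFit:
    gene: str
    isoforms: list[str]
    theta: np.ndarray
    se_logit_theta: np.ndarray
    converged: bool
    identifiable: bool
    loglik: float
    at_boundary: np.ndarray | None = None


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            if i == j:
                val = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h**2
            else:
                val = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h**2)
            hess[i, j] = hess[j, i] = val
    return hess


def fit_isoform_thetas(
    problem: GeneMixingProblem,
    extra_starts: tuple[float, ...] = (0.25, 0.75),
    max_cond: float = 1e8,
) -> IsoformFit:
    """Maximum-likelihood isoform fraction news for one gene.

    Optimization runs on the logit scale with quasi-Newton iterations from
    multiple starting points (a TEC-weighted average plus fixed interior
    points); the best objective wins.  Two isoforms appearing in exactly the
    same TECs with identical weights make the problem singular; such fits are
    returned with ``identifiable=False`` and SEs that are lower bounds.
    """
    n_iso = len(problem.isoforms)

    def neg_ll(x: np.ndarray) -> float:
        return -mixing_loglik(problem, expit(x))

    # start 1: read-weighted average of the TEC estimates each isoform touches
    wt = problem.weights * problem.n[:, None]
    denom = wt.sum(axis=0)
    init = (wt * problem.theta_hat[:, None]).sum(axis=0) / denom
    starts = [np.clip(init, 0.02, 0.98)]
    starts += [np.full(n_iso, s) for s in extra_starts]

    best = None
    converged = False
    for s in starts:
        res = minimize(neg_ll, logit(s), method="L-BFGS-B")
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        converged = converged or bool(res.success)
    x = best.x
    theta = expit(x)
    # same add-a-pseudocount clamp as the TEC estimates: keeps downstream
    # rate-constant conversion finite when all evidence points to 0 or 1
    eps = 1.0 / (float(problem.n.sum()) + 2.0)
    at_boundary = (theta < eps) | (theta > 1.0 - eps)
    theta = np.clip(theta, eps, 1.0 - eps)
    x = logit(theta)

    hess = _numeric_hessian(neg_ll, x)
    identifiable = True
    # duplicated TEC footprint => structurally unidentifiable
    for i in range(n_iso):
        for j in range(i + 1, n_iso):
            if np.allclose(problem.weights[:, i] > 0, problem.weights[:, j] > 0):
                same_tecs = (problem.membership[:, i] == problem.membership[:, j]).all()
                if same_tecs:
                    identifiable = False
    try:
        cond = np.linalg.cond(hess)
        if not np.isfinite(cond) or cond > max_cond:
            identifiable = False
        cov = np.linalg.pinv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        identifiable = False
        se = np.full(n_iso, np.inf)
    if not converged:
        warnings.warn(
            f"gene {problem.gene}: optimizer did not report convergence",
            stacklevel=2,
        )
    return IsoformFit(
        gene=problem.gene,
        isoforms=list(problem.isoforms),
        theta=theta,
        se_logit_theta=se,
        converged=converged,
        identifiable=identifiable,
        loglik=-float(best.fun),
        at_boundary=at_boundary,
    )


def kinetics_from_theta(
    theta: float,
    se_logit_theta: float,
    tpm: float,
    tlabel: float,
) -> dict[str, float]:
    """Convert a fraction new into degradation/synthesis rate constants.

    ``se_log_kdeg`` is the delta-method propagation of the logit-scale
    uncertainty: d log(kdeg) / d logit(theta) = theta / (-ln(1 - theta)).
    """
    if tlabel <= 0:
        raise ValueError("label time must be positive")
    if not (0.0 <= theta < 1.0):
        raise ValueError("theta must lie in [0, 1)")
    if theta == 0.0:
        return {
            "theta": 0.0,
            "kdeg": 0.0,
            "ksyn": 0.0,
            "log_kdeg": -np.inf,
            "se_log_kdeg": np.inf,
            "half_life": np.inf,
        }
    kdeg = -np.log1p(-theta) / tlabel
    grad = theta / (-np.log1p(-theta))
    return {
        "theta": float(theta),
        "kdeg": float(kdeg),
        "ksyn": float(tpm * kdeg),
        "log_kdeg": float(np.log(kdeg)),
        "se_log_kdeg": float(abs(grad) * se_logit_theta),
        "half_life": float(np.log(2.0) / kdeg),
    }


def filter_isoforms(
    abundance: AbundanceTable,
    min_tpm: float = 1.0,
    min_count: float = 10.0,
) -> pd.DataFrame:
    """Isoforms with TPM > min_tpm and expected_count >= min_count in all samples."""
    df = abundance.data
    ok = df.groupby("transcript_id").agg(
        gene_id=("gene_id", "first"),
        min_tpm=("TPM", "min"),
        min_count=("expected_count", "min"),
        mean_tpm=("TPM", "mean"),
    )
    keep = ok[(ok["min_tpm"] > min_tpm) & (ok["min_count"] >= min_count)]
    return keep.reset_index()


def estimate_isoform_kinetics(
    tec_estimates: pd.DataFrame,
    abundance: AbundanceTable,
    tlabel: float,
    min_tpm: float = 1.0,
    min_count: float = 10.0,
) -> pd.DataFrame:
    """Deconvolve TEC fraction news into per-isoform kinetics, per sample.

    ``tec_estimates`` is the output of
    :func:`isodeg.fractions.estimate_fractions` (columns sample, XF, TEC,
    theta, n, se_logit).  Isoforms failing the expression filter are dropped;
    TECs whose members are all dropped are excluded, and the mixing weights
    are renormalized over the surviving members.
    """
    modeled = filter_isoforms(abundance, min_tpm=min_tpm, min_count=min_count)
    modeled_set = set(modeled["transcript_id"])
    ab = abundance.data.set_index(["sample", "transcript_id"])["TPM"]

    records = []
    skipped_genes = 0
    for (sample, gene), grp in tec_estimates.groupby(["sample", "XF"], sort=True):
        iso_ids = sorted(
            {
                t
                for label in grp["TEC"]
                for t in tec_members(label)
                if t in modeled_set
            }
        )
        if not iso_ids:
            skipped_genes += 1
            continue
        try:
            tpm = np.array([ab.loc[(sample, t)] for t in iso_ids], float)
        except KeyError:
            skipped_genes += 1
            continue
        if (tpm <= 0).any():
            skipped_genes += 1
            continue
        keep_rows = []
        labels = []
        for _, row in grp.iterrows():
            members = [t for t in tec_members(row["TEC"]) if t in set(iso_ids)]
            if members:
                keep_rows.append(row)
                labels.append("+".join(sorted(members)))
        if not keep_rows:
            skipped_genes += 1
            continue
        sub = pd.DataFrame(keep_rows)
        covered = {t for lab in labels for t in tec_members(lab)}
        present = [t for t in iso_ids if t in covered]
        if not present:
            skipped_genes += 1
            continue
        tpm = np.array(
            [ab.loc[(sample, t)] for t in present], float
        )
        problem = GeneMixingProblem(
            gene=str(gene),
            tec_labels=labels,
            theta_hat=sub["theta"].to_numpy(float),
            n=sub["n"].to_numpy(float),
            isoforms=present,
            tpm=tpm,
        )
        fit = fit_isoform_thetas(problem)
        for j, iso in enumerate(fit.isoforms):
            kin = kinetics_from_theta(
                fit.theta[j], fit.se_logit_theta[j], float(tpm[j]), tlabel
            )
            records.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "transcript": iso,
                    "TPM": float(tpm[j]),
                    "n_reads": float(
                        (problem.n[:, None] * problem.weights)[:, j].sum()
                    ),
                    "se_logit_theta": float(fit.se_logit_theta[j]),
                    "at_boundary": bool(fit.at_boundary[j]),
                    "identifiable": fit.identifiable,
                    "converged": fit.converged,
                    "tlabel": tlabel,
                    **kin,
                }
            )
    if skipped_genes:
        warnings.warn(
            f"{skipped_genes} (sample, gene) group(s) skipped: no modeled isoforms",
            stacklevel=2,
        )
    return pd.DataFrame(records)


__all__ = [
    "GeneMixingProblem",
    "IsoformFit",
    "expected_tec_theta",
    "mixing_loglik",
    "fit_isoform_thetas",
    "kinetics_from_theta",
    "filter_isoforms",
    "estimate_isoform_kinetics",
]
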