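"""PCR-protocol effects on community composition.

Quantifies how Taq polymerase, BSA addition, and cycling regime (normal vs.
touchdown) shift a community's read composition, irrespective of the true
template proportions.  The model is additive on the log-ratio scale: for
species i in a sample run with Taq j, BSA level k and cycling l,

    eta_ijkl = g0_i + g1_ij + g2_ik + g3_il

and expected read proportions are the softmax of eta over species.  The
reference species' eta is pinned to 0 (so every g is an additive log-ratio
against that species) and the reference condition's effect vectors are 0
(so g1/g2/g3 are changes from the control protocol).  Counts enter a
multinomial likelihood directly — proportions of exactly 0 or 1 need no
special handling — with an optional Dirichlet-multinomial variant for
overdispersed technical replicates.  Inference is MAP with a weak normal
prior plus Laplace (inverse-Hessian) 95% intervals; an effect is called
influential when its interval excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import softmax

from .calibration import ReadTable

__all__ = [
    "TreatmentDesign",
    "CompositionFit",
    "fit_treatment_model",
    "subset_reads",
    "effect_table",
]


@dataclass(frozen=True)
class TreatmentDesign:
    """Reference levels anchoring the treatment model."""

    reference_species: str
    reference_taq: str = "NPHF"
    reference_bsa: bool = False
    reference_cycling: str = "normal"


@dataclass
class CompositionFit:
    """Fitted species x term effects on the additive log-ratio scale."""

    species: list[str]
    terms: list[str]  # "intercept", "taq[X]", "bsa[True]", "cycling[td]"
    estimates: pd.DataFrame  # species x term
    lo: pd.DataFrame
    hi: pd.DataFrame
    design: TreatmentDesign
    log_likelihood: float
    converged: bool
    discarded_fraction: pd.Series | None = field(default=None)


def subset_reads(
    reads: ReadTable,
    taxa: Sequence[str],
    min_fraction: float = 0.01,
) -> tuple[ReadTable, pd.Series]:
    """Restrict a read table to the listed taxa, keeping counts raw.

    Returns the subset and the per-sample fraction of reads discarded.
    Emits a warning when any sample discards more than ``min_fraction`` of
    its reads — dropping off-target taxa is only innocuous when they are a
    trace component of the library.
    """
    if not list(taxa):
        raise ValueError("taxa list is empty")
    present = [t for t in taxa if t in reads.species]
    if not present:
        raise ValueError("none of the listed taxa occur in the read table")
    kept = reads.counts.loc[present]
    discarded = 1.0 - kept.sum(axis=0) / reads.counts.sum(axis=0)
    if (discarded > min_fraction).any():
        worst = float(discarded.max())
        warnings.warn(
            f"subset discards up to {worst:.2%} of reads in some samples "
            f"(tolerance {min_fraction:.2%})",
            stacklevel=2,
        )
    return ReadTable(kept, reads.metadata), discarded


def _sample_design(meta: pd.DataFrame, design: TreatmentDesign):
    """Per-sample design matrix and term names (reference levels omitted)."""
    taq_levels = [t for t in sorted(meta["taq"].unique()) if t != design.reference_taq]
    bsa_levels = [b for b in sorted(meta["bsa"].astype(bool).unique()) if b != design.reference_bsa]
    cyc_levels = [c for c in sorted(meta["cycling"].unique()) if c != design.reference_cycling]
    terms = ["intercept"]
    cols = [np.ones(len(meta))]
    for t in taq_levels:
        terms.append(f"taq[{t}]")
        cols.append((meta["taq"] == t).values.astype(float))
    for b in bsa_levels:
        terms.append(f"bsa[{b}]")
        cols.append((meta["bsa"].astype(bool) == b).values.astype(float))
    for c in cyc_levels:
        terms.append(f"cycling[{c}]")
        cols.append((meta["cycling"] == c).values.astype(float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"confounded treatment design: aliased terms among {terms}"
        )
    return X, terms


def fit_treatment_model(
    reads: ReadTable,
    design: TreatmentDesign,
    prior_sd: float = 10.0,
    ci_level: float = 0.95,
    overdispersion: float = 0.0,
) -> CompositionFit:
    """MAP + Laplace fit of the additive log-ratio treatment model.

    ``overdispersion > 0`` swaps the multinomial likelihood for a
    Dirichlet-multinomial with concentration ``pi/overdispersion``.
    """
    species = reads.species
    if design.reference_species not in species:
        raise ValueError(
            f"reference species {design.reference_species!r} not in read table"
        )
    if len(reads.samples) < 2:
        raise ValueError("need at least two samples")
    singletons = [
        sp for sp in species
        if (reads.counts.loc[sp] > 0).sum() <= 1 and sp != design.reference_species
    ]
    if singletons:
        warnings.warn(
            f"species observed in at most one sample (expect wide intervals): {singletons}",
            stacklevel=2,
        )
    X, terms = _sample_design(reads.metadata, design)
    Y = reads.counts.values.T.astype(float)  # samples x species
    n_samp, S = Y.shape
    P = X.shape[1]
    ref = species.index(design.reference_species)
    free = [i for i in range(S) if i != ref]
    F = len(free)

    def etas(theta):
        G = np.zeros((S, P))
        G[free] = theta.reshape(F, P)
        return X @ G.T  # samples x species

    def neg_log_post(theta):
        eta = etas(theta)
        return -_loglik(Y, eta, overdispersion) + 0.5 * float(
            np.sum((theta / prior_sd) ** 2)
        )

    def grad(theta):
        eta = etas(theta)
        g_eta = -_dloglik_deta(Y, eta, overdispersion)  # samples x species
        g = g_eta.T @ X  # species x P
        return g[free].ravel() + theta / prior_sd**2

    x0 = np.zeros(F * P)
    res = minimize(neg_log_post, x0, jac=grad, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-9})
    theta = res.x
    eta = etas(theta)
    hess = _hessian(Y, eta, X, free, overdispersion)
    hess[np.diag_indices_from(hess)] += 1.0 / prior_sd**2
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None)).reshape(F, P)
    from scipy.stats import norm

    z = float(norm.ppf(1 - (1 - ci_level) / 2))
    est = np.zeros((S, P))
    est[free] = theta.reshape(F, P)
    lo = np.zeros((S, P))
    hi = np.zeros((S, P))
    lo[free] = est[free] - z * se
    hi[free] = est[free] + z * se
    mk = lambda a: pd.DataFrame(a, index=species, columns=terms)
    return CompositionFit(
        species=list(species),
        terms=list(terms),
        estimates=mk(est),
        lo=mk(lo),
        hi=mk(hi),
        design=design,
        log_likelihood=float(_loglik(Y, eta, overdispersion)),
        converged=bool(res.success),
    )


def _loglik(Y, eta, overdispersion):
    z = eta - eta.max(axis=1, keepdims=True)
    log_pi = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    if overdispersion == 0:
        return float((Y * log_pi).sum())
    from scipy.special import gammaln

    pi = np.exp(log_pi)
    conc = pi / overdispersion
    n = Y.sum(axis=1)
    return float(
        (
            gammaln(conc.sum(axis=1)) - gammaln(n + conc.sum(axis=1))
            + (gammaln(Y + conc) - gammaln(conc)).sum(axis=1)
        ).sum()
    )


def _dloglik_deta(Y, eta, overdispersion):
    pi = softmax(eta, axis=1)
    if overdispersion == 0:
        return Y - Y.sum(axis=1, keepdims=True) * pi
    # Dirichlet-multinomial gradient via chain rule through conc = pi/od.
    from scipy.special import digamma

    conc = pi / overdispersion
    n = Y.sum(axis=1, keepdims=True)
    a0 = conc.sum(axis=1, keepdims=True)
    dl_dconc = (
        digamma(a0) - digamma(n + a0) + digamma(Y + conc) - digamma(conc)
    )
    # d conc_j / d eta_m = (pi_j (delta_jm - pi_m)) / od
    inner = (dl_dconc * conc)  # rowwise
    return inner - pi * inner.sum(axis=1, keepdims=True)


def _hessian(Y, eta, X, free, overdispersion):
    """Observed-information Hessian of the negative log-likelihood.

    Exact multinomial expression; for the Dirichlet-multinomial variant a
    numerical row-by-row differentiation of the gradient is used.
    """
    n_samp, S = eta.shape
    P = X.shape[1]
    F = len(free)
    if overdispersion == 0:
        pi = softmax(eta, axis=1)
        n = Y.sum(axis=1)
        H = np.zeros((F * P, F * P))
        for s in range(n_samp):
            W = n[s] * (np.diag(pi[s]) - np.outer(pi[s], pi[s]))
            W = W[np.ix_(free, free)]
            xx = np.outer(X[s], X[s])
            H += np.kron(W, xx)
        return H
    # numerical Hessian of -loglik for the overdispersed case
    def grad_vec(theta):
        G = np.zeros((S, P))
        G[free] = theta.reshape(F, P)
        e = X @ G.T
        g_eta = -_dloglik_deta(Y, e, overdispersion)
        return (g_eta.T @ X)[free].ravel()

    # derive theta back from eta via lstsq on the free species' columns
    coef, *_ = np.linalg.lstsq(X, eta[:, free], rcond=None)
    theta_flat = coef.T.ravel()
    eps = 1e-5
    H = np.zeros((F * P, F * P))
    base = grad_vec(theta_flat)
    for k in range(F * P):
        step = np.zeros(F * P)
        step[k] = eps
        H[:, k] = (grad_vec(theta_flat + step) - base) / eps
    return 0.5 * (H + H.T)


def effect_table(fit: CompositionFit) -> pd.DataFrame:
    """Tidy one-row-per-species-per-term table with influential flags.

    An effect is influential when its interval excludes zero; reference
    species rows are anchored at zero and never flagged.
    """
    rows = []
    for sp in fit.species:
        for term in fit.terms:
            lo = float(fit.lo.loc[sp, term])
            hi = float(fit.hi.loc[sp, term])
            est = float(fit.estimates.loc[sp, term])
            rows.append(
                {
                    "species": sp,
                    "term": term,
                    "estimate": est,
                    "lo": lo,
                    "hi": hi,
                    "influential": bool(lo > 0 or hi < 0),
                }
            )
    return pd.DataFrame(rows)
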