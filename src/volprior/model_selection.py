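"""Random-effects Bayesian model selection (RFX-BMS) over per-subject log
model evidences.

The population is modelled as a mixture over candidate models with unknown
frequencies r ~ Dirichlet(alpha0); each subject's model assignment is a latent
multinomial draw. Variational updates alternate subject-wise posterior
assignments

    u_nk  propto  exp(lme_nk + psi(alpha_k) - psi(sum alpha))

with concentration updates alpha_k = alpha0 + sum_n u_nk. The exceedance
probability ep_k = P(r_k > r_j for all j) quantifies how likely model k is the
most frequent; the protected version shrinks ep toward chance by the Bayes
omnibus risk (BOR), the posterior probability that model frequencies are all
equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, digamma, gammaln, logsumexp


@dataclass
class BMSResult:
    dirichlet_alpha: np.ndarray
    expected_freq: np.ndarray
    ep: np.ndarray
    pxp: np.ndarray | None
    bor: float | None
    n_iter: int
    converged: bool
    free_energy: float

    @property
    def labels(self):
        return getattr(self, "_labels", None)

    def to_dict(self) -> dict:
        return {
            "dirichlet_alpha": self.dirichlet_alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "ep": self.ep.tolist(),
            "pxp": None if self.pxp is None else self.pxp.tolist(),
            "bor": self.bor,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


def exceedance_prob(
    alpha: np.ndarray, n_samples: int = 1_000_000, seed: int = 0
) -> np.ndarray:
    """P(r_k is the largest frequency) under Dirichlet(alpha).

    Exact via the regularized incomplete Beta function for K=2; seeded Monte
    Carlo over Dirichlet draws for K>2.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet concentrations must be positive")
    K = len(alpha)
    if K == 2:
        # P(r1 > 1/2) with r1 ~ Beta(a1, a2)
        p1 = 1.0 - betainc(alpha[0], alpha[1], 0.5)
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed)
    ep = np.zeros(K)
    # chunked to bound memory at large sample counts
    chunk = 200_000
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.dirichlet(alpha, size=m)
        ep += np.bincount(np.argmax(draws, axis=1), minlength=K)
        remaining -= m
    return ep / n_samples


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL(Dir(alpha) || Dir(alpha0))."""
    asum, a0sum = alpha.sum(), alpha0.sum()
    return float(
        gammaln(asum) - gammaln(alpha).sum()
        - gammaln(a0sum) + gammaln(alpha0).sum()
        + np.sum((alpha - alpha0) * (digamma(alpha) - digamma(asum)))
    )


def _free_energy(lme: np.ndarray, alpha: np.ndarray, u: np.ndarray,
                 alpha0: np.ndarray) -> float:
    """Variational free energy (ELBO) of the RFX model."""
    e_ln_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(u > 0, u * np.log(u), 0.0).sum()
    return float((u * (lme + e_ln_r)).sum() + ent - _dirichlet_kl(alpha, alpha0))


def rfx_bms(
    lme: np.ndarray,
    alpha0: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    compute_pxp: bool = True,
    ep_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Variational random-effects BMS over an N-subjects x K-models LME matrix."""
    lme = np.asarray(lme, dtype=float)
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("lme must be N x K with K >= 2")
    if not np.all(np.isfinite(lme)):
        raise ValueError("lme entries must be finite")
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    N, K = lme.shape
    a0 = np.full(K, float(alpha0))
    alpha = a0.copy()
    u = np.full((N, K), 1.0 / K)
    converged = False
    for it in range(1, max_iter + 1):
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = a0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    ep = exceedance_prob(alpha, n_samples=ep_samples, seed=seed)
    expected = alpha / alpha.sum()
    f1 = _free_energy(lme, alpha, u, a0)
    pxp = None
    bor = None
    if compute_pxp:
        # null model: all frequencies equal (r fixed at 1/K)
        f0 = float(np.sum(logsumexp(lme, axis=1) - np.log(K)))
        bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
        pxp = ep * (1.0 - bor) + bor / K
    return BMSResult(
        dirichlet_alpha=alpha,
        expected_freq=expected,
        ep=ep,
        pxp=pxp,
        bor=bor,
        n_iter=it,
        converged=converged,
        free_energy=f1,
    )


def protected_ep(bms: BMSResult) -> tuple[np.ndarray, float]:
    """Protected exceedance probabilities and Bayes omnibus risk of a fitted BMS."""
    if bms.pxp is None or bms.bor is None:
        raise ValueError("BMS was run without pxp computation")
    return bms.pxp, bms.bor


def static_belief_model(data, priors=None, response: str = "softmax", **fit_kwargs):
    """Fit the static-belief reference model (alpha pinned at 0, belief stays at v0).

    Serves as the null comparator for BMS; with v0 = 0.5 its choice likelihood
    is the chance model T*log(1/2) at any beta.
    """
    from .fitting import STATIC_LINEAR_RS, STATIC_SOFTMAX, fit_block

    spec = STATIC_SOFTMAX if response == "softmax" else STATIC_LINEAR_RS
    return fit_block(data, spec, priors, **fit_kwargs)


def lme_matrix(fits, models: list[str], participant_col: str = "participant"):
    """Per-subject summed LMEs (over blocks) as an N x K array plus row labels.

    Blocks are fit independently, so a subject's evidence for a model is the
    sum of its block LMEs.
    """
    import pandas as pd

    if not isinstance(fits, pd.DataFrame):
        raise TypeError("fits must be a DataFrame from fitting.fit_dataset")
    summed = (
        fits[fits["model"].isin(models)]
        .groupby([participant_col, "model"])["lme"].sum().unstack("model")
    )
    missing = [m for m in models if m not in summed.columns]
    if missing:
        raise ValueError(f"no fits for models {missing}")
    summed = summed[models]
    if summed.isna().any().any():
        raise ValueError("missing LMEs for some subject/model combinations")
    return summed.to_numpy(), list(summed.index)
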