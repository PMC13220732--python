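"""Group-level inference for fully-crossed within-subject designs.

Implements the repeated-measures ANOVA (with Mauchly's sphericity test and
conditional Greenhouse-Geisser correction), planned paired t-tests with
Bonferroni adjustment, Pearson correlation, a cluster-based permutation test
for paired position-wise series, and noncentral-t power analysis for the
paired t-test.

The ANOVA uses the contrast formulation: for an effect E with orthonormal
contrast matrix C (Kronecker product over its factors), subject scores
Z = M C on the cell means M give SS_effect = n * sum_j mean(Z_j)^2 and
SS_error = (n-1) * tr(cov Z); F, partial eta^2, Mauchly's W and the GG epsilon
all derive from Z. This is algebraically identical to the classical
sums-of-squares decomposition for balanced designs (each effect's error term
is its interaction with subjects).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


# --------------------------------------------------------------- rm ANOVA

def _orthonormal_contrast(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis orthogonal to the constant (Helmert-based)."""
    H = np.zeros((k, k - 1))
    for j in range(1, k):
        H[:j, j - 1] = 1.0
        H[j, j - 1] = -j
    H /= np.linalg.norm(H, axis=0, keepdims=True)
    return H


def _cell_mean_array(
    data: pd.DataFrame, dv: str, within: list[str], subject: str
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Subject x cells array of means, cells ordered by the factor level grids."""
    levels = [np.array(sorted(data[f].unique(), key=str)) for f in within]
    counts = data.groupby([subject, *within], sort=True)[dv].count()
    if counts.isna().any() or (counts == 0).any():
        raise ValueError("design has empty subject x cell combinations")
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal observations per cell")
    table = data.groupby([subject, *within], sort=True)[dv].mean().unstack(within)
    # enforce the full cartesian grid ordering
    grid = pd.MultiIndex.from_product(levels, names=within) if len(within) > 1 \
        else pd.Index(levels[0], name=within[0])
    table = table.reindex(columns=grid)
    if table.isna().any().any():
        raise ValueError("missing cells in the within-subject design")
    return table.to_numpy(dtype=float), levels


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float
    gg_epsilon: float
    mauchly_w: float
    mauchly_p: float
    corrected: bool

    def as_row(self) -> dict:
        return self.__dict__.copy()


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "participant",
    correction: str = "auto",
) -> pd.DataFrame:
    """Within-subject factorial ANOVA (up to 4 factors, one observation per
    subject x cell; replicate observations are cell-averaged first).

    ``correction``: 'auto' applies Greenhouse-Geisser when Mauchly's p < .05,
    'always' forces it for every multi-level effect, 'never' disables it.
    """
    if not 1 <= len(within) <= 4:
        raise ValueError("supports 1 to 4 within factors")
    if correction not in ("auto", "always", "never"):
        raise ValueError("correction must be auto/always/never")
    Y, levels = _cell_mean_array(data, dv, within, subject)
    n = Y.shape[0]
    if n < 2:
        raise ValueError("needs at least 2 subjects")
    shape = [len(lv) for lv in levels]
    Y = Y.reshape(n, *shape)

    rows = []
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(range(len(within)), r):
            name = " * ".join(within[i] for i in combo)
            # average over factors not in the effect
            other = tuple(1 + i for i in range(len(within)) if i not in combo)
            M = Y.mean(axis=other) if other else Y
            M = M.reshape(n, -1)
            C = _orthonormal_contrast(shape[combo[0]])
            for i in combo[1:]:
                C = np.kron(C, _orthonormal_contrast(shape[i]))
            Z = M @ C
            d = Z.shape[1]
            zbar = Z.mean(axis=0)
            ss_eff = n * float(zbar @ zbar)
            R = Z - zbar
            S = (R.T @ R) / (n - 1)
            ss_err = (n - 1) * float(np.trace(S))
            df1, df2 = float(d), float(d * (n - 1))
            F = (ss_eff / df1) / (ss_err / df2) if ss_err > 0 else np.inf
            peta = ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else np.nan

            eps = 1.0
            w = np.nan
            w_p = np.nan
            if d > 1:
                tr = np.trace(S)
                eps = float(tr**2 / (d * np.sum(S * S))) if tr > 0 else 1.0
                if n - 1 > d:
                    sign, logdet = np.linalg.slogdet(S)
                    if sign > 0:
                        w = float(np.exp(logdet - d * np.log(tr / d)))
                        chi = -(n - 1 - (2 * d**2 + d + 2) / (6.0 * d)) * np.log(w)
                        w_p = float(sps.chi2.sf(chi, d * (d + 1) // 2 - 1))
                    else:
                        w, w_p = 0.0, 0.0
            apply_gg = d > 1 and (
                correction == "always"
                or (correction == "auto" and np.isfinite(w_p) and w_p < 0.05)
            )
            if apply_gg:
                df1c, df2c = df1 * eps, df2 * eps
            else:
                df1c, df2c = df1, df2
            p = float(sps.f.sf(F, df1c, df2c))
            rows.append(
                AnovaResult(
                    effect=name, F=float(F), df_num=df1c, df_den=df2c, p=p,
                    partial_eta_sq=float(peta), gg_epsilon=eps,
                    mauchly_w=w, mauchly_p=w_p, corrected=bool(apply_gg),
                ).as_row()
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------ paired tests

def paired_t(x, y) -> tuple[float, int, float, float]:
    """Paired t-test returning (t, df, p, Cohen's dz); errors on zero-variance
    differences (t undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 2:
        raise ValueError("needs n >= 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t statistic undefined")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p), float(d.mean() / sd)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """min(1, m * p) per test; m defaults to the number of tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, m * p)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with t-based two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("needs equal-length arrays with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ----------------------------------------------- cluster permutation test

@dataclass
class ClusterTestResult:
    clusters: list[tuple[int, int, float]] = field(default_factory=list)
    p_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_permutations: int = 0
    threshold_t: float = np.nan
    t_obs: np.ndarray = field(default_factory=lambda: np.empty(0))

    def significant(self, alpha: float = 0.05):
        return [
            c for c, p in zip(self.clusters, self.p_values) if p < alpha
        ]


def _t_rows(diff: np.ndarray) -> np.ndarray:
    """Position-wise one-sample t over subjects (rows) for each column."""
    n = diff.shape[0]
    m = diff.mean(axis=0)
    s = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(s > 0, m / (s / np.sqrt(n)), 0.0)


def _clusters_from_t(t: np.ndarray, thr: float) -> list[tuple[int, int, float]]:
    """Maximal contiguous suprathreshold runs of one sign, scored by summed t.

    Returned (start, end) indices are 0-based inclusive.
    """
    out = []
    sign = np.where(t > thr, 1, np.where(t < -thr, -1, 0))
    start = None
    for i in range(len(sign) + 1):
        s = sign[i] if i < len(sign) else 0
        if start is not None and (s == 0 or s != sign[start]):
            out.append((start, i - 1, float(t[start:i].sum())))
            start = None
        if s != 0 and start is None:
            start = i
    return out


def cluster_permutation_paired(
    series_a: np.ndarray,
    series_b: np.ndarray,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    exhaustive: bool = False,
) -> ClusterTestResult:
    """Two-tailed cluster-based permutation test for paired position-wise series.

    Position-wise paired t statistics are thresholded at the two-tailed critical
    t (p < ``alpha``, df = n-1); signed contiguous suprathreshold clusters are
    scored by their summed t. The null distribution of the maximum absolute
    cluster statistic is built from per-subject sign flips of the condition
    difference (the identity flip is included, so p >= 1/n_perm). With
    ``exhaustive=True`` all 2^n sign assignments are enumerated instead.
    """
    a = np.atleast_2d(np.asarray(series_a, dtype=float))
    b = np.atleast_2d(np.asarray(series_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("series_a and series_b must have the same shape")
    n, _ = a.shape
    diff = a - b
    thr = float(sps.t.ppf(1.0 - alpha / 2.0, n - 1))
    t_obs = _t_rows(diff)
    clusters = _clusters_from_t(t_obs, thr)

    if exhaustive:
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_perm - 1, n))
        signs = np.vstack([np.ones((1, n)), signs])
    null_max = np.zeros(len(signs))
    for k, sgn in enumerate(signs):
        t_perm = _t_rows(diff * sgn[:, None])
        cl = _clusters_from_t(t_perm, thr)
        null_max[k] = max((abs(c[2]) for c in cl), default=0.0)
    n_eff = len(signs)
    p_vals = np.array(
        [float(np.mean(null_max >= abs(c[2]))) for c in clusters]
    )
    return ClusterTestResult(
        clusters=clusters,
        p_values=p_vals,
        n_permutations=n_eff,
        threshold_t=thr,
        t_obs=t_obs,
    )


# ------------------------------------------------------------------ power

def power_paired_t(
    effect_dz: float,
    alpha: float = 0.05,
    power: float = 0.9,
    tails: int = 2,
    n_max: int = 100_000,
) -> int:
    """Smallest n with noncentral-t power >= ``power`` for a paired t-test.

    Noncentrality dz * sqrt(n), df = n - 1; two-tailed by default (the design
    convention throughout this package).
    """
    if effect_dz <= 0:
        raise ValueError("effect_dz must be positive")
    if not (0 < alpha < power < 1):
        raise ValueError("need 0 < alpha < power < 1")
    for n in range(2, n_max + 1):
        if _paired_t_power(n, effect_dz, alpha, tails) >= power:
            return n
    raise RuntimeError("no n found below n_max")


def _paired_t_power(n: int, dz: float, alpha: float, tails: int) -> float:
    df = n - 1
    nc = dz * np.sqrt(n)
    if tails == 2:
        tc = sps.t.ppf(1.0 - alpha / 2.0, df)
        return float(sps.nct.sf(tc, df, nc) + sps.nct.cdf(-tc, df, nc))
    tc = sps.t.ppf(1.0 - alpha, df)
    return float(sps.nct.sf(tc, df, nc))
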