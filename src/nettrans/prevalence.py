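"""Smooth age-specific weight-category prevalence from survey data.

The three-category prevalence curve for one sex-by-group stratum is
estimated with a survey-weighted multinomial logit whose age effect is a
penalized B-spline (P-spline): the log-odds of each non-reference category
versus normal weight is a cubic B-spline in age, with a difference penalty
on adjacent spline coefficients controlling smoothness.  The smoothing
parameter is chosen by AIC over a log-spaced grid.  Uncertainty is carried
as a cluster-robust (PSU-within-stratum) sandwich covariance of the spline
coefficients, which downstream code resamples to propagate uncertainty into
the net transition probabilities.

A single smooth spans ages 2-80; nothing special happens at the child/adult
classification switch at age 20, mirroring the absence of discontinuities
in the category definitions' overlap region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .classification import CATEGORY_LABELS

AGE_MIN, AGE_MAX = 2, 80
AGE_GRID = np.arange(AGE_MIN, AGE_MAX + 1)


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SplineSpec:
    """Basis and penalty configuration for the age smooth.

    ``n_interior_knots`` equally spaced interior knots on [age_min, age_max],
    cubic B-splines and a second-order difference penalty by default, so the
    infinite-penalty limit of each log-odds curve is a straight line in age.
    """

    n_interior_knots: int = 20
    degree: int = 3
    penalty_order: int = 2
    age_min: float = float(AGE_MIN)
    age_max: float = float(AGE_MAX)
    lambda_grid: tuple = tuple(np.logspace(-2, 4, 7))

    @property
    def n_basis(self) -> int:
        return self.n_interior_knots + self.degree + 1

    @property
    def knots(self) -> np.ndarray:
        # equally spaced knots extended `degree` intervals beyond each end
        # (the canonical P-spline construction): uniform spacing everywhere is
        # what makes the coefficient-difference penalty's null space coincide
        # with polynomial functions of age, so heavy smoothing tends to a
        # straight log-odds line with no edge artifacts
        h = (self.age_max - self.age_min) / (self.n_interior_knots + 1)
        return self.age_min + h * np.arange(
            -self.degree, self.n_interior_knots + self.degree + 2
        )

    def basis(self, ages) -> np.ndarray:
        ages = np.clip(np.asarray(ages, float), self.age_min, self.age_max)
        return BSpline.design_matrix(ages, self.knots, self.degree, extrapolate=False).toarray()

    def penalty(self) -> np.ndarray:
        d = np.diff(np.eye(self.n_basis), n=self.penalty_order, axis=0)
        return d.T @ d


@dataclass
class PrevalenceCurve:
    """Fitted age-by-category prevalence surface with coefficient uncertainty.

    ``P[t, k]`` is the probability of category ``k`` (normal, overweight,
    obese) at ``ages[t]``.  ``coef`` stacks the spline coefficients of each
    estimated (non-reference) category; ``vcov`` is their sandwich
    covariance.  ``cat_index`` maps estimated-category position to the 0-based
    category column, so degenerate strata (categories absent from the data)
    keep a consistent 3-column surface with structural zeros.
    """

    stratum: str
    ages: np.ndarray
    P: np.ndarray
    coef: np.ndarray
    vcov: np.ndarray
    spec: SplineSpec
    lambda_: float
    cat_index: tuple
    ref_cat: int
    loglik: float = np.nan
    edf: float = np.nan

    def surface(self, coef=None) -> np.ndarray:
        """Prevalence surface on the age grid for coefficient vector(s).

        ``coef`` may be the fitted vector (default), or an array of shape
        (R, n_coef) of bootstrap draws, giving an (R, n_ages, 3) stack.
        """
        spec = self.spec
        coef = self.coef if coef is None else np.asarray(coef, float)
        single = coef.ndim == 1
        coef2 = np.atleast_2d(coef)
        m = spec.n_basis
        B = spec.basis(self.ages)  # (n_ages, m)
        n_free = len(self.cat_index)
        eta = np.zeros((coef2.shape[0], len(self.ages), 3))
        eta[:] = -np.inf  # absent categories get probability 0
        eta[:, :, self.ref_cat] = 0.0
        for j, k in enumerate(self.cat_index):
            eta[:, :, k] = coef2[:, j * m : (j + 1) * m] @ B.T
        eta -= eta.max(axis=2, keepdims=True)
        with np.errstate(under="ignore"):
            ex = np.exp(eta)
        P = ex / ex.sum(axis=2, keepdims=True)
        return P[0] if single else P

    def at(self, age: int) -> np.ndarray:
        """Probability vector at a grid age."""
        idx = np.where(self.ages == age)[0]
        if idx.size == 0:
            raise ValueError(f"age {age} outside the fitted grid {self.ages[0]}..{self.ages[-1]}")
        return self.P[idx[0]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "age": self.ages,
                **{f"p_{lbl}": self.P[:, k] for k, lbl in enumerate(CATEGORY_LABELS)},
            }
        )


def curve_at(curve: PrevalenceCurve, age: int) -> np.ndarray:
    return curve.at(age)


def combine_cycles(records: pd.DataFrame, mode: str = "pooled") -> pd.DataFrame:
    """Rescale survey weights when pooling multiple survey cycles.

    ``pooled`` divides each weight by the number of distinct cycles (the
    standard multi-cycle convention, so pooled weights still sum to one
    population); ``per_cycle`` passes records through unchanged.
    """
    if mode == "per_cycle":
        return records.copy()
    if mode != "pooled":
        raise ValueError(f"unknown cycle-combination mode {mode!r}")
    if "cycle" not in records.columns:
        raise ValueError("records need a 'cycle' column to combine cycles")
    n_cycles = records["cycle"].nunique()
    out = records.copy()
    out["survey_weight"] = out["survey_weight"] / n_cycles
    return out


def _aggregate(records: pd.DataFrame):
    """Collapse records to (age, category) weight sums, keeping cluster labels.

    The multinomial likelihood depends on the data only through these sums,
    which keeps the Newton solver O(#distinct ages) regardless of n.
    """
    df = records[["age", "category", "survey_weight"]].copy()
    df["age"] = df["age"].astype(float)
    if {"stratum", "psu"}.issubset(records.columns):
        df["cluster"] = records["stratum"].astype(str) + "|" + records["psu"].astype(str)
    else:
        df["cluster"] = np.arange(len(records)).astype(str)
    w_total = df["survey_weight"].sum()
    if w_total <= 0:
        raise ValueError("survey weights must be positive")
    # normalize to effective n so results are invariant to weight rescaling
    df["w"] = df["survey_weight"] * len(df) / w_total
    df["w2"] = df["w"] ** 2
    agg = (
        df.groupby(["cluster", "age", "category"], sort=True)
        .agg(w=("w", "sum"), w2=("w2", "sum"), n=("w", "size"))
        .reset_index()
    )
    record_level_clusters = agg["n"].max() == 1 and agg["cluster"].nunique() == len(df)
    return agg, record_level_clusters


def _newton_fit(X, W, lam, pen, beta0=None, max_iter=100, tol=1e-8):
    """Maximize the penalized weighted multinomial log-likelihood.

    ``X`` is the (n_ages, m) basis at the distinct ages; ``W`` the
    (n_ages, K) matrix of summed weights per age and category (column 0 is
    the reference).  Returns (beta, loglik_unpenalized, A_penalized) where
    ``A_penalized`` is the negative penalized Hessian.
    """
    n_a, m = X.shape
    K = W.shape[1]
    nf = K - 1
    d = nf * m
    beta = np.zeros(d) if beta0 is None else beta0.copy()
    row_tot = W.sum(axis=1)

    def probs(b):
        eta = np.zeros((n_a, K))
        for j in range(nf):
            eta[:, j + 1] = X @ b[j * m : (j + 1) * m]
        eta -= eta.max(axis=1, keepdims=True)
        ex = np.exp(eta)
        return ex / ex.sum(axis=1, keepdims=True)

    def pen_loglik(b):
        p = probs(b)
        ll = float((W * np.log(np.clip(p, 1e-300, None))).sum())
        quad = sum(
            b[j * m : (j + 1) * m] @ pen @ b[j * m : (j + 1) * m] for j in range(nf)
        )
        return ll - 0.5 * lam * quad, ll, p

    pl, ll, p = pen_loglik(beta)
    for _ in range(max_iter):
        grad = np.empty(d)
        H = np.zeros((d, d))
        for j in range(nf):
            resid = W[:, j + 1] - row_tot * p[:, j + 1]
            grad[j * m : (j + 1) * m] = X.T @ resid - lam * pen @ beta[j * m : (j + 1) * m]
            for l in range(j, nf):
                wjl = row_tot * (
                    p[:, j + 1] * ((j == l) - p[:, l + 1])
                )
                blk = -(X.T * wjl) @ X
                if j == l:
                    blk -= lam * pen
                H[j * m : (j + 1) * m, l * m : (l + 1) * m] = blk
                H[l * m : (l + 1) * m, j * m : (j + 1) * m] = blk.T
        gnorm = np.linalg.norm(grad)
        # ridge fallback keeps the step defined when the Hessian is near-singular
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(-H + 1e-8 * np.eye(d), grad)
        # Newton decrement: scale-invariant, robust to the extreme Hessian
        # conditioning that very large penalties induce
        if 0.5 * abs(grad @ step) < tol * max(1.0, abs(pl)):
            break
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            pl_new, ll_new, p_new = pen_loglik(cand)
            if pl_new >= pl - 1e-12:
                beta, pl, ll, p = cand, pl_new, ll_new, p_new
                break
            t *= 0.5
        else:
            break
    else:
        raise ConvergenceError(f"Newton did not converge; |grad| = {gnorm:.3e}")
    A = -H  # negative penalized Hessian at the optimum
    return beta, ll, p, A


def fit_prevalence(
    records: pd.DataFrame,
    stratum: str = "all",
    spec: SplineSpec | None = None,
    lambda_: float | None = None,
) -> PrevalenceCurve:
    """Fit the P-spline multinomial prevalence curve for one stratum.

    ``records`` must carry ``age``, ``category`` (1..3) and
    ``survey_weight`` columns; ``stratum``/``psu`` columns, when present,
    define the clusters for the robust covariance.  ``lambda_`` fixes the
    smoothing parameter; by default it is chosen by AIC over
    ``spec.lambda_grid``.
    """
    spec = spec or SplineSpec()
    if records.empty:
        raise ValueError("no records to fit")
    if records["age"].nunique() < 2:
        raise ValueError("need records at >= 2 distinct ages")
    agg, record_level = _aggregate(records)

    cats_present = sorted(agg["category"].unique())
    if len(cats_present) == 1:
        warnings.warn(
            f"stratum {stratum!r} contains a single category; returning degenerate curve",
            stacklevel=2,
        )
        only = int(cats_present[0]) - 1
        P = np.zeros((len(AGE_GRID), 3))
        P[:, only] = 1.0
        return PrevalenceCurve(
            stratum=stratum, ages=AGE_GRID.copy(), P=P,
            coef=np.zeros(0), vcov=np.zeros((0, 0)), spec=spec, lambda_=np.nan,
            cat_index=(), ref_cat=only, loglik=0.0, edf=0.0,
        )

    ref = int(cats_present[0]) - 1  # normal weight whenever present
    free_cats = tuple(int(c) - 1 for c in cats_present[1:])
    K = len(cats_present)
    m = spec.n_basis

    ages_u = np.sort(agg["age"].unique())
    age_pos = {a: i for i, a in enumerate(ages_u)}
    X = spec.basis(ages_u)
    W = np.zeros((len(ages_u), K))
    cat_pos = {c: j for j, c in enumerate(cats_present)}
    for _, r in agg.iterrows():
        W[age_pos[r["age"]], cat_pos[r["category"]]] += r["w"]
    pen = spec.penalty()

    if lambda_ is not None:
        lam_grid = [float(lambda_)]
    else:
        lam_grid = list(spec.lambda_grid)
    best = None
    beta0 = None
    for lam in lam_grid:
        beta, ll, p_hat, A = _newton_fit(X, W, lam, pen, beta0=beta0)
        beta0 = beta
        A_unpen = A.copy()
        for j in range(K - 1):
            A_unpen[j * m : (j + 1) * m, j * m : (j + 1) * m] -= lam * pen
        edf = float(np.trace(np.linalg.solve(A, A_unpen)))
        aic = -2.0 * ll + 2.0 * edf
        if best is None or aic < best["aic"]:
            best = dict(lam=lam, beta=beta, ll=ll, A=A, edf=edf, aic=aic)
    lam, beta, A = best["lam"], best["beta"], best["A"]

    # cluster-robust meat: per-(age, category) score directions, summed per cluster
    d = (K - 1) * m
    agg = agg.assign(
        ai=agg["age"].map(age_pos), ci=agg["category"].map(cat_pos)
    )
    p_hat = _probs_from_beta(X, beta, K, m)
    U = np.zeros((len(agg), d))
    for j in range(K - 1):
        ind = (agg["ci"].to_numpy() == j + 1).astype(float)
        resid = ind - p_hat[agg["ai"].to_numpy(), j + 1]
        U[:, j * m : (j + 1) * m] = resid[:, None] * X[agg["ai"].to_numpy()]
    if record_level:
        B = (U * agg["w2"].to_numpy()[:, None]).T @ U
    else:
        codes, _ = pd.factorize(agg["cluster"])
        S = np.zeros((codes.max() + 1, d))
        np.add.at(S, codes, U * agg["w"].to_numpy()[:, None])
        B = S.T @ S
    # add the penalty curvature back into the meat: the robust analogue of the
    # Bayesian P-spline covariance, whose extra lam*S term absorbs smoothing
    # bias and restores across-the-function interval calibration
    for j in range(K - 1):
        B[j * m : (j + 1) * m, j * m : (j + 1) * m] += lam * pen
    Ainv = np.linalg.inv(A)
    vcov = Ainv @ B @ Ainv
    vcov = 0.5 * (vcov + vcov.T)

    curve = PrevalenceCurve(
        stratum=stratum, ages=AGE_GRID.copy(), P=np.empty(0),
        coef=beta, vcov=vcov, spec=spec, lambda_=lam,
        cat_index=free_cats, ref_cat=ref, loglik=best["ll"], edf=best["edf"],
    )
    curve.P = curve.surface()
    return curve


def _probs_from_beta(X, beta, K, m):
    eta = np.zeros((X.shape[0], K))
    for j in range(K - 1):
        eta[:, j + 1] = X @ beta[j * m : (j + 1) * m]
    eta -= eta.max(axis=1, keepdims=True)
    ex = np.exp(eta)
    return ex / ex.sum(axis=1, keepdims=True)
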