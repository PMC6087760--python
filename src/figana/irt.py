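"""Rasch and linear logistic test model (LLTM) fitting by conditional
maximum likelihood, with the model tests used to evaluate generated items.

The Rasch model gives person *v* probability ``logistic(theta_v - beta_i)``
of solving item *i*.  Conditioning on each person's raw score removes the
person parameters from the likelihood, leaving the item difficulties ``beta``
identified up to an additive constant (reported mean-centered here).  The
conditional likelihood is evaluated through elementary symmetric functions
(ESFs) of ``eps_i = exp(-beta_i)`` computed by the summation recursion, and
maximized by Newton-Raphson with analytic gradient and Hessian.

The LLTM constrains ``beta = Q @ alpha``: each item difficulty is the sum of
the *basic parameters* ``alpha_j`` of the cognitive operations (rules) that
item requires, weighted by the binary Q matrix.  It is a nested submodel of
the Rasch model, compared by a conditional likelihood-ratio (deviance) test
on ``(n_items - 1) - p`` degrees of freedom.

Model-fit tests: Andersen's likelihood-ratio test (subgroup vs pooled
estimates) and a per-item Wald test across two subgroups.  Cronbach's alpha
is provided as a classical reliability utility.

Usage follows the Model/Results convention::

    model = RaschModel(resp)            # resp: ResponseMatrix
    res = model.fit()
    print(res.summary())
    lltm = LLTM(resp, q).fit()
    test = compare_deviance(res, lltm)
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResponseMatrix",
    "QMatrix",
    "RaschModel",
    "LLTM",
    "RaschResults",
    "LltmResults",
    "TestResult",
    "WaldResults",
    "fit_rasch_cml",
    "fit_lltm_cml",
    "lltm_predict",
    "andersen_lr",
    "wald_item_test",
    "compare_deviance",
    "cronbach_alpha",
    "EstimationError",
    "ConvergenceError",
    "IdentifiabilityError",
]

GRAD_TOL = 1e-8
MAX_ITER = 200


class EstimationError(RuntimeError):
    """The conditional likelihood carries no information (e.g. all persons
    have extreme raw scores)."""


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge within the iteration cap."""


class IdentifiabilityError(RuntimeError):
    """The Q matrix does not identify the basic parameters."""


class NestingViolationError(RuntimeError):
    """The LLTM likelihood exceeds the Rasch likelihood beyond tolerance."""


# ---------------------------------------------------------------------------
# data containers


class ResponseMatrix:
    """Persons × items binary responses, optionally with missing entries.

    Parameters
    ----------
    values : array-like
        0/1 entries; ``NaN`` (or ``None``) marks a missing response.
    person_ids, item_ids : sequence of str, optional
        Labels; generated when omitted.
    """

    def __init__(self, values, person_ids=None, item_ids=None):
        v = np.asarray(values, dtype=float)
        if v.ndim != 2:
            raise ValueError("response matrix must be two-dimensional")
        if v.shape[1] < 2:
            raise ValueError("at least 2 items are required")
        ok = np.isnan(v) | (v == 0) | (v == 1)
        if not ok.all():
            raise ValueError("responses must be 0, 1 or missing")
        self.values = v
        self.person_ids = (
            list(person_ids)
            if person_ids is not None
            else [f"P{i + 1}" for i in range(v.shape[0])]
        )
        self.item_ids = (
            list(item_ids)
            if item_ids is not None
            else [f"I{i + 1}" for i in range(v.shape[1])]
        )
        if len(self.person_ids) != v.shape[0] or len(self.item_ids) != v.shape[1]:
            raise ValueError("label lengths do not match the matrix shape")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def raw_scores(self) -> np.ndarray:
        return np.nansum(self.values, axis=1)

    def extreme_persons(self) -> np.ndarray:
        """Mask of persons with all-correct or all-incorrect observed scores;
        they contribute nothing to the conditional likelihood."""
        obs = (~np.isnan(self.values)).sum(axis=1)
        s = self.raw_scores()
        return (s == 0) | (s == obs) | (obs == 0)

    def subset_persons(self, mask) -> "ResponseMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ResponseMatrix(
            self.values[idx], [self.person_ids[i] for i in idx], self.item_ids
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.person_ids, columns=self.item_ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="person")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ResponseMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns))

    @classmethod
    def from_csv(cls, path) -> "ResponseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls.from_dataframe(df)


class QMatrix:
    """Binary items × basic-parameters weight matrix.

    Row *i* marks which cognitive operations item *i* requires; column *j*
    belongs to basic parameter ``alpha_j``.
    """

    def __init__(self, weights, rule_names=None, item_ids=None, strict=True):
        w = np.asarray(weights, dtype=float)
        if w.ndim != 2:
            raise ValueError("Q matrix must be two-dimensional")
        if not np.isin(w, (0.0, 1.0)).all():
            raise ValueError("Q matrix entries must be binary")
        # strict: the invariants a calibration-ready Q must satisfy; bank
        # descriptions of tiny item sets may relax them (fitting re-checks)
        if strict:
            if (w.sum(axis=0) == 0).any():
                raise ValueError("Q matrix has an all-zero column")
            if w.shape[1] >= w.shape[0]:
                raise ValueError(
                    "Q matrix must have fewer basic parameters than items "
                    f"(got {w.shape[1]} columns for {w.shape[0]} items)"
                )
        self.weights = w
        self.rule_names = (
            list(rule_names)
            if rule_names is not None
            else [f"rule{j + 1}" for j in range(w.shape[1])]
        )
        self.item_ids = (
            list(item_ids)
            if item_ids is not None
            else [f"I{i + 1}" for i in range(w.shape[0])]
        )

    @property
    def n_items(self) -> int:
        return self.weights.shape[0]

    @property
    def n_params(self) -> int:
        return self.weights.shape[1]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.weights.astype(int), index=self.item_ids, columns=self.rule_names
        ).to_csv(path, index_label="item")

    @classmethod
    def from_csv(cls, path) -> "QMatrix":
        df = pd.read_csv(path, index_col=0)
        # loading is lenient; fitting re-checks the calibration invariants
        return cls(
            df.to_numpy(dtype=float),
            list(df.columns),
            list(df.index.astype(str)),
            strict=False,
        )


# ---------------------------------------------------------------------------
# elementary symmetric functions


def esf(eps: np.ndarray) -> np.ndarray:
    """Elementary symmetric functions gamma_0..gamma_n of ``eps`` by the
    summation recursion (coefficients of prod_i (1 + eps_i x))."""
    eps = np.asarray(eps, dtype=float)
    n = eps.size
    g = np.zeros(n + 1)
    g[0] = 1.0
    for e in eps:
        g[1:] += e * g[:-1]
    return g


def _esf_leave_one_out(eps: np.ndarray) -> np.ndarray:
    """Row *i* holds the ESFs of ``eps`` with item *i* removed (order n-1)."""
    n = eps.size
    G = np.zeros((n, n + 1))
    G[:, 0] = 1.0
    rows = np.arange(n)
    for j in range(n):
        m = rows != j
        G[m, 1:] += eps[j] * G[m, :-1]
    return G


def _esf_leave_two_out(eps: np.ndarray):
    """ESFs with each unordered pair of items removed."""
    n = eps.size
    pairs = np.array(list(itertools.combinations(range(n), 2)), dtype=int)
    P = np.zeros((len(pairs), n + 1))
    P[:, 0] = 1.0
    for j in range(n):
        m = (pairs[:, 0] != j) & (pairs[:, 1] != j)
        P[m, 1:] += eps[j] * P[m, :-1]
    return pairs, P


# ---------------------------------------------------------------------------
# conditional likelihood core


class _Pattern:
    """Per missing-data-pattern sufficient statistics."""

    __slots__ = ("idx", "scores", "counts", "s_items")

    def __init__(self, idx: np.ndarray, rows: np.ndarray):
        self.idx = idx  # observed item indices, length k
        k = idx.size
        r = rows.sum(axis=1).astype(int)
        keep = (r > 0) & (r < k)
        rows = rows[keep]
        self.scores = np.arange(1, k)  # possible informative scores
        self.counts = np.bincount(r[keep], minlength=k + 1)[1:k].astype(float)
        self.s_items = rows.sum(axis=0)  # per observed item correct counts

    @property
    def n_informative(self) -> int:
        return int(self.counts.sum())


class _CMLProblem:
    """Conditional log-likelihood, gradient and Hessian in item space."""

    def __init__(self, data: ResponseMatrix):
        self.n_items = data.n_items
        v = data.values
        self.n_extreme = int(data.extreme_persons().sum())
        patterns: Dict[Tuple[bool, ...], List[int]] = {}
        obs = ~np.isnan(v)
        for p in range(v.shape[0]):
            patterns.setdefault(tuple(obs[p]), []).append(p)
        self.patterns: List[_Pattern] = []
        for mask, rows in patterns.items():
            idx = np.flatnonzero(np.array(mask))
            if idx.size < 2:
                continue
            pat = _Pattern(idx, v[np.array(rows)][:, idx])
            if pat.n_informative > 0:
                self.patterns.append(pat)
        if not self.patterns:
            raise EstimationError(
                "no informative persons: every raw score is extreme"
            )
        self.s_total = np.zeros(self.n_items)
        for pat in self.patterns:
            self.s_total[pat.idx] += pat.s_items
        self.n_informative = sum(p.n_informative for p in self.patterns)

    def loglik(self, beta: np.ndarray) -> float:
        ll = 0.0
        for pat in self.patterns:
            b = beta[pat.idx]
            b = b - b.mean()  # shift-invariant; keeps eps well-scaled
            g = esf(np.exp(-b))
            ll += -float(pat.s_items @ b)
            ll -= float(pat.counts @ np.log(g[1 : pat.idx.size]))
        return ll

    def loglik_grad_hess(self, beta: np.ndarray):
        n = self.n_items
        ll = 0.0
        grad = np.zeros(n)
        hess = np.zeros((n, n))
        for pat in self.patterns:
            k = pat.idx.size
            b = beta[pat.idx]
            b = b - b.mean()
            eps = np.exp(-b)
            g = esf(eps)
            G1 = _esf_leave_one_out(eps)
            ll += -float(pat.s_items @ b)
            ll -= float(pat.counts @ np.log(g[1:k]))
            # pi[i, r-1] = P(x_i = 1 | raw score r), r = 1..k-1
            pi = eps[:, None] * G1[:, 0 : k - 1] / g[None, 1:k]
            grad[pat.idx] += -pat.s_items + pi @ pat.counts
            # pairwise conditional expectations E[x_i x_j | r]
            pairs, P2 = _esf_leave_two_out(eps)
            H = np.zeros((k, k))
            w = pat.counts
            d = (pi * (1.0 - pi)) @ w
            H[np.arange(k), np.arange(k)] = -d
            if len(pairs):
                r_idx = np.arange(1, k)  # scores
                # gamma^{(ij)}_{r-2}: column r-2 for score r (zero when r < 2)
                g2 = np.zeros((len(pairs), k - 1))
                g2[:, 1:] = P2[:, 0 : k - 2]
                e_ij = eps[pairs[:, 0]] * eps[pairs[:, 1]]
                exy = e_ij[:, None] * g2 / g[None, 1:k]
                cov = (pi[pairs[:, 0]] * pi[pairs[:, 1]] - exy) @ w
                H[pairs[:, 0], pairs[:, 1]] = cov
                H[pairs[:, 1], pairs[:, 0]] = cov
            hess[np.ix_(pat.idx, pat.idx)] += H
        return ll, grad, hess


def _newton(problem, x0, grad_map, hess_map, label):
    """Maximize the mapped conditional log-likelihood by Newton-Raphson with
    step halving.  ``grad_map``/``hess_map`` project item-space derivatives
    onto the free parameters."""
    x = np.asarray(x0, dtype=float).copy()
    ll, g, H = problem(x)
    for it in range(MAX_ITER):
        gm, Hm = grad_map(g), hess_map(H)
        if np.max(np.abs(gm)) < GRAD_TOL:
            return x, ll, g, H, it, True
        try:
            step = np.linalg.solve(Hm, gm)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"{label}: singular Hessian at iteration {it}") from exc
        step = -step  # ascent direction (H is negative definite)
        scale = 1.0
        for _ in range(40):
            x_new = x + scale * step
            ll_new, g_new, H_new = problem(x_new)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError(f"{label}: step halving failed at iteration {it}")
        if ll_new == ll and np.allclose(x_new, x):
            # at the numerical floor of the likelihood surface
            return x_new, ll_new, g_new, H_new, it + 1, True
        x, ll, g, H = x_new, ll_new, g_new, H_new
        if np.max(np.abs(x)) > 50:
            raise ConvergenceError(
                f"{label}: parameters diverging (a response margin is likely extreme)"
            )
    raise ConvergenceError(f"{label}: no convergence in {MAX_ITER} iterations")


def _centered_cov(V_free: np.ndarray, free_idx: np.ndarray, n: int) -> np.ndarray:
    """Covariance of mean-centered difficulties from the covariance of the
    free (reference-anchored) parameters, by the delta method."""
    V = np.zeros((n, n))
    V[np.ix_(free_idx, free_idx)] = V_free
    C = np.eye(n) - np.full((n, n), 1.0 / n)
    return C @ V @ C.T


# ---------------------------------------------------------------------------
# results objects


@dataclass(frozen=True)
class TestResult:
    """A chi-square test: statistic, degrees of freedom and upper-tail p."""

    statistic: float
    df: int
    p_value: float

    def __repr__(self) -> str:
        return (
            f"TestResult(statistic={self.statistic:.4f}, df={self.df}, "
            f"p_value={self.p_value:.4g})"
        )


class RaschResults:
    """Conditional-ML estimates of mean-centered item difficulties."""

    def __init__(self, model, beta, cov, cond_loglik, n_iter, converged):
        self.model = model
        self.beta = beta
        self.cov = cov
        self.se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        self.cond_loglik = float(cond_loglik)
        self.n_iter = n_iter
        self.converged = converged

    @property
    def item_ids(self):
        return self.model.data.item_ids

    @property
    def n_items(self) -> int:
        return self.beta.size

    @property
    def deviance(self) -> float:
        return -2.0 * self.cond_loglik

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se}, index=self.item_ids
        )

    def summary(self) -> str:
        head = (
            "Rasch model (conditional maximum likelihood)\n"
            f"  items: {self.n_items}   informative persons: "
            f"{self.model._problem.n_informative}   excluded (extreme): "
            f"{self.model._problem.n_extreme}\n"
            f"  conditional log-likelihood: {self.cond_loglik:.4f}   "
            f"iterations: {self.n_iter}\n"
            "  item difficulties are mean-centered\n"
        )
        return head + self.to_frame().round(4).to_string()


class LltmResults:
    """Conditional-ML estimates of the LLTM basic parameters."""

    def __init__(self, model, alpha, cov, cond_loglik, n_iter, converged):
        self.model = model
        self.alpha = alpha
        self.cov = cov
        self.se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        self.cond_loglik = float(cond_loglik)
        self.n_iter = n_iter
        self.converged = converged

    @property
    def q(self) -> QMatrix:
        return self.model.q

    @property
    def beta_hat(self) -> np.ndarray:
        """Predicted item difficulties, beta_i = sum_j w_ij alpha_j exactly."""
        return self.q.weights @ self.alpha

    @property
    def beta_hat_centered(self) -> np.ndarray:
        b = self.beta_hat
        return b - b.mean()

    @property
    def deviance(self) -> float:
        return -2.0 * self.cond_loglik

    def to_frame(self) -> pd.DataFrame:
        z = self.alpha / self.se
        return pd.DataFrame(
            {
                "alpha": self.alpha,
                "se": self.se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=self.q.rule_names,
        )

    def summary(self) -> str:
        head = (
            "Linear logistic test model (conditional maximum likelihood)\n"
            f"  items: {self.q.n_items}   basic parameters: {self.q.n_params}\n"
            f"  conditional log-likelihood: {self.cond_loglik:.4f}   "
            f"iterations: {self.n_iter}\n"
        )
        return head + self.to_frame().round(4).to_string()


# ---------------------------------------------------------------------------
# models


class RaschModel:
    """Rasch model for a binary response matrix, estimated by CML."""

    def __init__(self, data: ResponseMatrix):
        if not isinstance(data, ResponseMatrix):
            data = ResponseMatrix(np.asarray(data))
        self.data = data
        self._problem = _CMLProblem(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RaschModel":
        return cls(ResponseMatrix.from_dataframe(df))

    def _start(self) -> np.ndarray:
        v = self.data.values
        n_obs = (~np.isnan(v)).sum(axis=0)
        s = np.nansum(v, axis=0)
        beta = np.log((n_obs - s + 0.5) / (s + 0.5))
        return beta - beta[0]

    def fit(self) -> RaschResults:
        n = self.data.n_items
        free = np.arange(1, n)  # item 1 anchors the scale during iteration

        def problem(beta):
            return self._problem.loglik_grad_hess(beta)

        def wrap(x):
            beta = np.concatenate([[0.0], x])
            return problem(beta)

        x0 = self._start()[1:]
        x, ll, g, H, it, conv = _newton(
            wrap, x0, lambda g: g[1:], lambda H: H[1:, 1:], "Rasch CML"
        )
        beta = np.concatenate([[0.0], x])
        info = -H[1:, 1:]
        V_free = np.linalg.inv(info)
        cov = _centered_cov(V_free, free, n)
        return RaschResults(self, beta - beta.mean(), cov, ll, it, conv)


class LLTM:
    """LLTM: a Rasch model with difficulties constrained to ``Q @ alpha``."""

    def __init__(self, data: ResponseMatrix, q: QMatrix):
        if not isinstance(data, ResponseMatrix):
            data = ResponseMatrix(np.asarray(data))
        if not isinstance(q, QMatrix):
            q = QMatrix(np.asarray(q))
        if q.n_items != data.n_items:
            raise ValueError(
                f"Q matrix has {q.n_items} rows for {data.n_items} items"
            )
        self.data = data
        self.q = q
        self._problem = _CMLProblem(data)
        W = q.weights
        if (W.sum(axis=0) == 0).any():
            raise IdentifiabilityError("Q matrix has an all-zero column")
        if q.n_params >= q.n_items:
            raise IdentifiabilityError(
                "Q matrix must have fewer basic parameters than items"
            )
        if np.linalg.matrix_rank(W) < q.n_params:
            raise IdentifiabilityError("Q matrix is rank deficient")
        # the conditional likelihood only sees difficulty contrasts: a Q whose
        # column span contains the constant vector cannot identify alpha
        Wc = W - W.mean(axis=0, keepdims=True)
        if np.linalg.matrix_rank(Wc) < q.n_params:
            raise IdentifiabilityError(
                "Q matrix spans the constant vector; basic parameters are not "
                "identified by the conditional likelihood"
            )

    def fit(self) -> LltmResults:
        W = self.q.weights

        def wrap(alpha):
            ll, g, H = self._problem.loglik_grad_hess(W @ alpha)
            return ll, g, H

        beta0 = np.log(
            ((~np.isnan(self.data.values)).sum(axis=0) - np.nansum(self.data.values, axis=0) + 0.5)
            / (np.nansum(self.data.values, axis=0) + 0.5)
        )
        a0, *_ = np.linalg.lstsq(W, beta0, rcond=None)
        a, ll, g, H, it, conv = _newton(
            wrap, a0, lambda g: W.T @ g, lambda H: W.T @ H @ W, "LLTM CML"
        )
        info = -(W.T @ H @ W)
        cov = np.linalg.inv(info)
        return LltmResults(self, a, cov, ll, it, conv)


def fit_rasch_cml(data) -> RaschResults:
    """Fit a Rasch model by conditional maximum likelihood."""
    return RaschModel(data).fit()


def fit_lltm_cml(data, q) -> LltmResults:
    """Fit an LLTM by conditional maximum likelihood."""
    return LLTM(data, q).fit()


def lltm_predict(q: QMatrix, alpha) -> np.ndarray:
    """Item difficulties implied by basic parameters: beta_i = sum_j w_ij a_j."""
    if not isinstance(q, QMatrix):
        q = QMatrix(np.asarray(q))
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (q.n_params,):
        raise ValueError(
            f"alpha has shape {alpha.shape}, expected ({q.n_params},)"
        )
    return q.weights @ alpha


# ---------------------------------------------------------------------------
# model tests


def _split_groups(data: ResponseMatrix, split) -> List[ResponseMatrix]:
    if isinstance(split, str):
        if split != "median":
            raise ValueError(f"unknown split {split!r}")
        s = data.raw_scores()
        med = np.median(s)
        labels = np.where(s <= med, 0, 1)  # ties go to the lower group
    else:
        labels = np.asarray(split)
        if labels.shape[0] != data.n_persons:
            raise ValueError("split labels must have one entry per person")
    groups = []
    for lab in np.unique(labels):
        groups.append(data.subset_persons(labels == lab))
    if len(groups) < 2:
        raise ValueError("split produced fewer than two groups")
    return groups


def andersen_lr(data: ResponseMatrix, split="median") -> TestResult:
    """Andersen's conditional likelihood-ratio test of Rasch homogeneity.

    Items are refitted within each subgroup; the statistic
    ``2 * (sum of subgroup log-likelihoods - pooled log-likelihood)`` is
    chi-square with ``(groups - 1) * (items - 1)`` degrees of freedom under
    the Rasch model.  The default split dichotomizes at the raw-score median
    (ties to the lower group).
    """
    groups = _split_groups(data, split)
    total = fit_rasch_cml(data)
    ll_groups = 0.0
    for g in groups:
        try:
            ll_groups += fit_rasch_cml(g).cond_loglik
        except EstimationError as exc:
            raise EstimationError(
                "a subgroup has no informative persons; choose another split"
            ) from exc
    stat = max(2.0 * (ll_groups - total.cond_loglik), 0.0)
    df = (len(groups) - 1) * (data.n_items - 1)
    return TestResult(stat, df, float(stats.chi2.sf(stat, df)))


class WaldResults:
    """Per-item Wald tests of difficulty invariance across two subgroups."""

    def __init__(self, item_ids, z, p):
        self.item_ids = item_ids
        self.z = z
        self.p_value = p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.z, "p": self.p_value}, index=self.item_ids)

    def summary(self) -> str:
        return (
            "Wald test of item-difficulty invariance (two subgroups)\n"
            + self.to_frame().round(4).to_string()
        )


def wald_item_test(data: ResponseMatrix, split="median") -> WaldResults:
    """Wald test per item: ``z = (b1 - b2) / sqrt(se1^2 + se2^2)`` on the
    mean-centered subgroup estimates, with two-sided normal p-values."""
    groups = _split_groups(data, split)
    if len(groups) != 2:
        raise ValueError("the Wald test requires exactly two groups")
    f1, f2 = (fit_rasch_cml(g) for g in groups)
    z = (f1.beta - f2.beta) / np.sqrt(f1.se**2 + f2.se**2)
    return WaldResults(data.item_ids, z, 2 * stats.norm.sf(np.abs(z)))


def compare_deviance(
    rasch: RaschResults, lltm: LltmResults, n_items: Optional[int] = None,
    p: Optional[int] = None,
) -> TestResult:
    """Likelihood-ratio comparison of the Rasch model against a nested LLTM.

    ``statistic = 2 * (loglik_Rasch - loglik_LLTM)`` on
    ``(n_items - 1) - p`` degrees of freedom.
    """
    n_items = n_items if n_items is not None else rasch.n_items
    p = p if p is not None else lltm.q.n_params
    diff = rasch.cond_loglik - lltm.cond_loglik
    if diff < -1e-6:
        raise NestingViolationError(
            f"LLTM log-likelihood exceeds the Rasch log-likelihood by {-diff:.3g}; "
            "the models are not nested on these data"
        )
    stat = max(2.0 * diff, 0.0)
    df = (n_items - 1) - p
    return TestResult(stat, df, float(stats.chi2.sf(stat, df)))


def cronbach_alpha(data: Union[ResponseMatrix, np.ndarray]) -> float:
    """Cronbach's alpha: ``k/(k-1) * (1 - sum(item variances)/var(total))``
    over complete response rows."""
    v = data.values if isinstance(data, ResponseMatrix) else np.asarray(data, float)
    if v.shape[1] < 2:
        raise ValueError("at least 2 items are required")
    v = v[~np.isnan(v).any(axis=1)]
    if v.shape[0] < 2:
        raise ValueError("at least 2 complete rows are required")
    k = v.shape[1]
    total_var = v.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ZeroDivisionError("total-score variance is zero; alpha undefined")
    item_var = v.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))
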