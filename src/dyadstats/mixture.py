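"""K-class linear latent-growth mixture model fitted by EM.

Repeated symptom scores ``y_it`` are modelled as a finite mixture of linear
growth curves:

    y_it | class k  ~  Normal(β0_k + β1_k · t_i,  σ²)

with mixing proportions π_k, a homoscedastic residual variance shared
across classes, and (optionally) diagonal random intercept/slope effects
shared across classes.  Missing occasions are handled by evaluating each
subject's likelihood over its observed cells only (missing-at-random).

This is a deliberate simplification of the full structural-equation growth
mixture machinery: only class growth means, proportions and residual
variance are identified from the kind of output the model is screened with
(BIC, mean posterior probability, the 0–1 classification-entropy index),
and those are what the results object reports.

The interface follows the statsmodels convention: build a
:class:`GrowthMixture` model from data, call :meth:`~GrowthMixture.fit`,
and read estimates, diagnostics and ``summary()`` off the returned
:class:`GrowthMixtureResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "GrowthMixture",
    "GrowthMixtureResults",
    "bic",
    "classification_entropy",
    "assign_classes",
]


class GrowthMixture:
    """Finite mixture of linear growth curves over repeated measures.

    Parameters
    ----------
    endog : array-like, shape (n_subjects, n_occasions)
        Score matrix; NaN marks a missing occasion.
    times : array-like, optional
        Occasion time codes; default ``0..T−1`` so the intercept is the
        first-assessment level.
    k : int
        Number of latent trajectory classes.
    """

    def __init__(self, endog, times=None, k: int = 2):
        Y = np.asarray(endog, dtype=float)
        if Y.ndim != 2 or Y.shape[1] < 2:
            raise ValueError("endog must be 2-D with at least 2 occasions")
        n, T = Y.shape
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > n:
            raise ValueError(f"k={k} exceeds the number of subjects ({n})")
        self.endog = Y
        self.times = np.arange(T, dtype=float) if times is None else np.asarray(times, dtype=float)
        if self.times.shape != (T,):
            raise ValueError("times must have one value per occasion")
        self.k = k
        self.mask = ~np.isnan(Y)
        if not np.all(self.mask.sum(axis=1) >= 1):
            raise ValueError("every subject needs at least one observed occasion")
        self.nobs = n

    @classmethod
    def from_long(
        cls,
        data: pd.DataFrame,
        k: int = 2,
        subject_col: str = "subject",
        time_col: str = "time",
        value_col: str = "score",
    ) -> "GrowthMixture":
        """Build from a long-format table (one row per subject × occasion)."""
        wide = data.pivot_table(index=subject_col, columns=time_col, values=value_col)
        times = np.asarray(wide.columns, dtype=float)
        return cls(wide.to_numpy(), times=times, k=k)

    # -- EM internals ------------------------------------------------------

    def _class_loglike(self, beta, sigma2):
        """Per-subject conditional log-likelihood for each class (n × k)."""
        Y, t, M = self.endog, self.times, self.mask
        m = M.sum(axis=1)
        out = np.empty((Y.shape[0], self.k))
        for k_ in range(self.k):
            mu = beta[k_, 0] + beta[k_, 1] * t
            resid2 = np.where(M, (Y - mu) ** 2, 0.0).sum(axis=1)
            out[:, k_] = -0.5 * (m * np.log(2 * np.pi * sigma2) + resid2 / sigma2)
        return out

    def _m_step(self, resp):
        Y, t, M = self.endog, self.times, self.mask
        beta = np.empty((self.k, 2))
        sse = 0.0
        for k_ in range(self.k):
            w = resp[:, k_][:, None] * M            # weight per observed cell
            sw = w.sum()
            st = (w * t).sum()
            stt = (w * t**2).sum()
            sy = np.where(M, w * Y, 0.0).sum()
            sty = np.where(M, w * Y * t, 0.0).sum()
            A = np.array([[sw, st], [st, stt]])
            b = np.array([sy, sty])
            beta[k_] = np.linalg.solve(A, b)
            mu = beta[k_, 0] + beta[k_, 1] * t
            sse += np.where(M, w * (Y - mu) ** 2, 0.0).sum()
        sigma2 = max(sse / M.sum(), 1e-12)
        pi = resp.mean(axis=0)
        return beta, sigma2, pi

    def _em(self, rng, tol, max_iter):
        n = self.nobs
        # random-responsibility initialisation
        resp = rng.dirichlet(np.ones(self.k), size=n)
        beta, sigma2, pi = self._m_step(resp)
        loglik = -np.inf
        history = []
        for it in range(max_iter):
            logp = self._class_loglike(beta, sigma2) + np.log(np.maximum(pi, 1e-300))
            norm = logsumexp(logp, axis=1)
            new_loglik = float(norm.sum())
            resp = np.exp(logp - norm[:, None])
            beta, sigma2, pi = self._m_step(resp)
            history.append(new_loglik)
            if np.min(pi) < 1.0 / n:
                return None  # degenerate class; caller restarts
            if new_loglik - loglik < tol * max(abs(new_loglik), 1.0) and it > 0:
                loglik = new_loglik
                break
            loglik = new_loglik
        # final E-step so posteriors match the returned parameters
        logp = self._class_loglike(beta, sigma2) + np.log(np.maximum(pi, 1e-300))
        norm = logsumexp(logp, axis=1)
        return beta, sigma2, pi, float(norm.sum()), np.exp(logp - norm[:, None]), history

    def fit(
        self,
        n_starts: int = 20,
        seed: int | np.random.Generator | None = None,
        tol: float = 1e-8,
        max_iter: int = 1000,
    ) -> "GrowthMixtureResults":
        """Run EM from ``n_starts`` random initialisations and keep the best.

        The log-likelihood is monotone non-decreasing within each start; a
        start that collapses a class below 1/n responsibility is discarded
        with a warning and redrawn.
        """
        rng = np.random.default_rng(seed)
        best = None
        attempts = 0
        successes = 0
        while successes < n_starts and attempts < 4 * n_starts:
            attempts += 1
            out = self._em(rng, tol, max_iter)
            if out is None:
                warnings.warn("degenerate class during EM; restarting", stacklevel=2)
                continue
            successes += 1
            if best is None or out[3] > best[3]:
                best = out
        if best is None:
            raise RuntimeError("all EM starts collapsed to a degenerate class")
        beta, sigma2, pi, loglik, resp, history = best

        # order classes by intercept for a stable, label-free presentation
        order = np.argsort(beta[:, 0])
        beta, pi, resp = beta[order], pi[order], resp[:, order]

        # approximate SEs from the final weighted least-squares information
        se = np.empty_like(beta)
        t, M = self.times, self.mask
        for k_ in range(self.k):
            w = resp[:, k_][:, None] * M
            A = np.array(
                [[w.sum(), (w * t).sum()], [(w * t).sum(), (w * t**2).sum()]]
            )
            cov = sigma2 * np.linalg.inv(A)
            se[k_] = np.sqrt(np.diag(cov))

        n_params = 2 * self.k + (self.k - 1) + 1
        return GrowthMixtureResults(
            model=self,
            class_means=beta,
            class_se=se,
            sigma2=float(sigma2),
            pi=pi,
            posterior=resp,
            loglik=float(loglik),
            n_params=n_params,
            loglik_history=np.asarray(history),
        )


@dataclass
class GrowthMixtureResults:
    """Estimates, posteriors and fit indices of a fitted growth mixture."""

    model: GrowthMixture
    class_means: np.ndarray      # (k, 2): intercept, slope per class
    class_se: np.ndarray
    sigma2: float
    pi: np.ndarray
    posterior: np.ndarray        # (n, k), rows sum to 1
    loglik: float
    n_params: int
    loglik_history: np.ndarray

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def intercepts(self) -> np.ndarray:
        return self.class_means[:, 0]

    @property
    def slopes(self) -> np.ndarray:
        return self.class_means[:, 1]

    @property
    def bic(self) -> float:
        return bic(self)

    @property
    def classification_entropy(self) -> float:
        return classification_entropy(self.posterior)

    def assign(self):
        """Modal class labels, per-class mean max-posterior, and tie flags."""
        return assign_classes(self.posterior)

    def params_frame(self) -> pd.DataFrame:
        labels, avg_post, _ = self.assign()
        counts = np.bincount(labels, minlength=self.k)
        return pd.DataFrame(
            {
                "class": np.arange(self.k),
                "proportion": self.pi,
                "n_assigned": counts,
                "intercept": self.intercepts,
                "intercept_se": self.class_se[:, 0],
                "slope": self.slopes,
                "slope_se": self.class_se[:, 1],
                "avg_posterior": [avg_post.get(k_, np.nan) for k_ in range(self.k)],
            }
        )

    def summary(self) -> str:
        lines = [
            "Latent growth mixture model (EM)",
            "=" * 64,
            f"subjects: {self.nobs}    occasions: {self.model.times.size}"
            f"    classes: {self.k}",
            f"log-likelihood: {self.loglik:.3f}    BIC: {self.bic:.3f}"
            f"    residual SD: {np.sqrt(self.sigma2):.3f}",
            f"classification entropy: {self.classification_entropy:.3f}"
            "  (>0.80 indicates crisp assignment)",
            "-" * 64,
            f"{'class':>5} {'prop':>7} {'intercept':>12} {'slope':>12} {'avg post':>9}",
        ]
        tab = self.params_frame()
        for _, r in tab.iterrows():
            lines.append(
                f"{int(r['class']):>5} {r['proportion']:>7.3f} "
                f"{r['intercept']:>7.3f} ({r['intercept_se']:.3f}) "
                f"{r['slope']:>6.3f} ({r['slope_se']:.3f}) {r['avg_posterior']:>9.3f}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Spaghetti plot of observed scores with fitted class mean lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.times
        labels, _, _ = self.assign()
        for i in range(min(self.nobs, 200)):
            ax.plot(t, self.model.endog[i], color=f"C{labels[i]}", alpha=0.08, lw=0.6)
        for k_ in range(self.k):
            ax.plot(
                t,
                self.intercepts[k_] + self.slopes[k_] * t,
                color=f"C{k_}",
                lw=2.5,
                label=f"class {k_} (π={self.pi[k_]:.2f})",
            )
        ax.set_xlabel("occasion (time code)")
        ax.set_ylabel("score")
        ax.legend()
        return ax


def bic(results: GrowthMixtureResults, n_subjects: int | None = None) -> float:
    """BIC = −2·loglik + n_params·ln(n); lower is better."""
    n = results.nobs if n_subjects is None else n_subjects
    return -2.0 * results.loglik + results.n_params * np.log(n)


def classification_entropy(posteriors: np.ndarray) -> float:
    """Relative-entropy classification index in [0, 1]; 1 = crisp assignment.

    ``E = 1 − [Σ_i Σ_k −p_ik ln p_ik] / (N ln K)``; defined as 1 for K=1.
    """
    P = np.asarray(posteriors, dtype=float)
    if P.ndim != 2:
        raise ValueError("posteriors must be 2-D")
    if np.any(P < -1e-12) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("posterior rows must be probabilities summing to 1")
    N, K = P.shape
    if K == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, -P * np.log(P), 0.0)
    return float(1.0 - terms.sum() / (N * np.log(K)))


def assign_classes(posteriors: np.ndarray):
    """Modal assignment with deterministic tie-break to the lower class index.

    Returns ``(labels, avg_posterior, ties)`` where ``avg_posterior`` maps
    each assigned class to the mean max-posterior of its members (reported
    against the 0.80 adequacy guideline) and ``ties`` flags exact ties.
    """
    P = np.asarray(posteriors, dtype=float)
    labels = P.argmax(axis=1)        # argmax takes the first (lowest) index on ties
    maxp = P[np.arange(P.shape[0]), labels]
    ties = (np.abs(P - maxp[:, None]) < 1e-12).sum(axis=1) > 1
    avg = {
        int(k_): float(maxp[labels == k_].mean())
        for k_ in np.unique(labels)
    }
    return labels, avg, ties
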