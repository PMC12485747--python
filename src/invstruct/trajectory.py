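"""Haplotype-frequency trajectories through time by multinomial logit.

Each resolved ancient individual contributes its two haplotype
category observations (H1.β1, H1.β2+, H2.α1, H2.α2+) at its sample age
in years before present.  The model places a linear predictor on time
for each non-reference category,

    log(f_c(t) / f_ref(t)) = a_c + b_c * t,

with t in kiloyears oriented toward the present (t = -age/1000), so a
positive slope b_c means the category has risen toward the present.
The fit is a Newton ascent on the exact multinomial log-likelihood
with analytic gradient and Hessian; the observed-information inverse
provides standard errors, and fold changes between two times carry
delta-method intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "SeparationError",
    "HaplotypeTrajectoryModel",
    "TrajectoryResults",
    "bin_counts",
]

#: the four short-read-reportable haplotype categories
CATEGORIES = ("H1.β1", "H1.β2+", "H2.α1", "H2.α2+")


class SeparationError(ValueError):
    """Raised when the data cannot identify the model (e.g. a single
    observed category: complete separation, no finite estimates)."""


def _age_to_t(age_bp: np.ndarray) -> np.ndarray:
    return -np.asarray(age_bp, dtype=float) / 1000.0


class HaplotypeTrajectoryModel:
    """Multinomial logistic regression of haplotype category on time.

    Parameters
    ----------
    categories :
        Per-observation category labels (one haplotype = one
        observation; a resolved individual contributes two).
    age_bp :
        Sample age in years before present, one per observation.
    reference :
        Reference category (coefficients fixed at zero).  Defaults to
        the first category in sorted order; predicted frequencies are
        invariant to this choice.

    Categories configured but absent from the data are kept in the
    output with frequency fixed at zero (a separation guard) and
    reported in ``absent_categories``.
    """

    def __init__(
        self,
        categories,
        age_bp,
        category_order: tuple[str, ...] | None = None,
        reference: str | None = None,
    ) -> None:
        cats = np.asarray(categories, dtype=object)
        ages = np.asarray(age_bp, dtype=float)
        if cats.shape != ages.shape or cats.ndim != 1:
            raise ValueError("categories and age_bp must be equal-length 1-D")
        if not np.isfinite(ages).all():
            raise ValueError("ages must be finite")
        if (ages < 0).any():
            raise ValueError("ages are years before present and must be >= 0")
        observed = sorted(set(cats.tolist()))
        if len(observed) < 2:
            raise SeparationError(
                f"only one category observed ({observed}); the model is "
                "completely separated and has no finite estimates"
            )
        order = tuple(category_order) if category_order else tuple(observed)
        unknown = set(observed) - set(order)
        if unknown:
            raise ValueError(f"data contain categories not in category_order: {unknown}")
        self.absent_categories = tuple(c for c in order if c not in observed)
        self.categories = tuple(c for c in order if c in observed)
        self.reference = reference if reference is not None else self.categories[0]
        if self.reference not in self.categories:
            raise ValueError(f"reference {self.reference!r} not among observed categories")
        # non-reference categories keep the configured order
        self.nonref = tuple(c for c in self.categories if c != self.reference)
        idx = {c: k for k, c in enumerate((self.reference,) + self.nonref)}
        self._y = np.array([idx[c] for c in cats])  # 0 = reference
        self._t = _age_to_t(ages)
        # a constant time covariate is collinear with the intercept:
        # drop it from the design and pin the slopes at exactly zero
        self.constant_time = bool(np.ptp(self._t) == 0.0)
        if self.constant_time:
            self._X = np.ones((len(self._t), 1))
        else:
            self._X = np.column_stack([np.ones_like(self._t), self._t])
        self.nobs = len(cats)
        if self.nobs < 10:
            raise ValueError("need at least 10 observations to fit")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        category: str = "category",
        age: str = "age_bp",
        category_order: tuple[str, ...] | None = CATEGORIES,
        reference: str | None = None,
    ) -> "HaplotypeTrajectoryModel":
        order = category_order
        if order is not None and not set(df[category]) <= set(order):
            order = None  # fall back to observed categories
        return cls(df[category].to_numpy(), df[age].to_numpy(),
                   category_order=order, reference=reference)

    # --- likelihood machinery -------------------------------------------
    @property
    def _p(self) -> int:
        return self._X.shape[1]

    @property
    def k_params(self) -> int:
        return self._p * len(self.nonref)

    def _probs(self, params: np.ndarray) -> np.ndarray:
        """n x K probabilities; column 0 is the reference category."""
        B = params.reshape(len(self.nonref), self._p)
        eta = np.concatenate(
            [np.zeros((self.nobs, 1)), self._X @ B.T], axis=1
        )
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)

    def loglike(self, params: np.ndarray) -> float:
        p = self._probs(params)
        return float(np.log(p[np.arange(self.nobs), self._y]).sum())

    def score(self, params: np.ndarray) -> np.ndarray:
        p = self._probs(params)
        Y = np.zeros_like(p)
        Y[np.arange(self.nobs), self._y] = 1.0
        resid = Y[:, 1:] - p[:, 1:]  # n x (K-1)
        return (resid.T @ self._X).reshape(-1)  # category-major [a_c, b_c]

    def hessian(self, params: np.ndarray) -> np.ndarray:
        p = self._probs(params)
        K1 = len(self.nonref)
        H = np.zeros((self.k_params, self.k_params))
        q = self._p
        for j in range(K1):
            for k in range(j, K1):
                w = p[:, j + 1] * ((1.0 if j == k else 0.0) - p[:, k + 1])
                block = -(self._X * w[:, None]).T @ self._X
                H[q * j : q * j + q, q * k : q * k + q] = block
                H[q * k : q * k + q, q * j : q * j + q] = block.T
        return H

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> "TrajectoryResults":
        """Newton ascent with step halving; likelihood never decreases."""
        params = np.zeros(self.k_params)
        ll = self.loglike(params)
        history = [ll]
        converged = False
        for _ in range(maxiter):
            g = self.score(params)
            H = self.hessian(params)
            try:
                step = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                step = -np.linalg.pinv(H) @ g
            # backtrack until the likelihood does not decrease
            scale = 1.0
            for _ in range(60):
                cand = params + scale * step
                ll_new = self.loglike(cand)
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            else:
                break
            params, ll_prev, ll = cand, ll, ll_new
            history.append(ll)
            if abs(ll - ll_prev) < tol:
                converged = True
                break
        H = self.hessian(params)
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(-H)
        K1 = len(self.nonref)
        if self.constant_time:
            # re-embed into the (intercept, slope) convention: slopes are
            # identically zero with zero variance
            full = np.zeros((K1, 2))
            full[:, 0] = params
            cov_full = np.zeros((2 * K1, 2 * K1))
            cov_full[0::2, 0::2] = cov
            params_out, cov = full, cov_full
        else:
            params_out = params.reshape(K1, 2)
        return TrajectoryResults(
            model=self, params=params_out,
            cov_params=cov, llf=ll, converged=converged,
            loglike_history=np.array(history),
        )


@dataclass
class TrajectoryResults:
    """Fitted trajectory: coefficients, uncertainty and predictions."""

    model: HaplotypeTrajectoryModel
    params: np.ndarray  # (K-1) x 2: intercept, slope per kiloyear
    cov_params: np.ndarray
    llf: float
    converged: bool
    loglike_history: np.ndarray

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params)).reshape(self.params.shape)

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(self.model.nonref),
                "intercept": self.params[:, 0],
                "slope_per_ky": self.params[:, 1],
                "se_intercept": self.bse[:, 0],
                "se_slope": self.bse[:, 1],
            }
        )

    def _freqs_from(self, B: np.ndarray, ages: np.ndarray) -> np.ndarray:
        t = _age_to_t(ages)
        X = np.column_stack([np.ones_like(t), t])
        eta = np.concatenate([np.zeros((len(t), 1)), X @ B.T], axis=1)
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, age_bp) -> pd.DataFrame:
        """Category frequencies at the given ages; rows sum to 1.

        Categories configured but unobserved appear with frequency 0.
        """
        ages = np.atleast_1d(np.asarray(age_bp, dtype=float))
        p = self._freqs_from(self.params, ages)
        cols = (self.model.reference,) + self.model.nonref
        out = pd.DataFrame(p, columns=list(cols), index=ages)
        for c in self.model.absent_categories:
            out[c] = 0.0
        out.index.name = "age_bp"
        return out

    def fold_change(
        self, t0_bp: float, t1_bp: float, categories
    ) -> tuple[float, tuple[float, float]]:
        """Ratio of summed category frequencies at t1 vs t0 (ages in BP).

        Returns the estimate and a 95% delta-method interval on the log
        ratio.  A denominator below 1e-6 is reported as unbounded
        (inf with a degenerate interval).
        """
        if t0_bp == t1_bp:
            raise ValueError("t0 and t1 must differ")
        cats = [c for c in categories]
        for c in cats:
            if c not in self.model.categories and c not in self.model.absent_categories:
                raise ValueError(f"unknown category {c!r}")
        cols = (self.model.reference,) + self.model.nonref
        sel = np.array([c in cats for c in cols])

        def ratio_log(flat: np.ndarray) -> float:
            p = self._freqs_from(
                flat.reshape(self.params.shape), np.array([t1_bp, t0_bp])
            )
            num = float(p[0, sel].sum())
            den = float(p[1, sel].sum())
            if den < 1e-6:
                return np.inf
            return np.log(num / den)

        flat = self.params.reshape(-1).copy()
        lr = ratio_log(flat)
        if not np.isfinite(lr):
            return float("inf"), (float("inf"), float("inf"))
        # numerical gradient of the log ratio for the delta method
        grad = np.zeros_like(flat)
        h = 1e-6
        for i in range(len(flat)):
            up, dn = flat.copy(), flat.copy()
            up[i] += h
            dn[i] -= h
            grad[i] = (ratio_log(up) - ratio_log(dn)) / (2 * h)
        var = float(grad @ self.cov_params @ grad)
        se = np.sqrt(max(var, 0.0))
        est = float(np.exp(lr))
        return est, (float(np.exp(lr - 1.96 * se)), float(np.exp(lr + 1.96 * se)))

    def summary(self) -> str:
        lines = [
            "Haplotype trajectory: multinomial logistic regression",
            f"  observations (haplotypes): {self.model.nobs}",
            f"  reference category:        {self.model.reference}",
            f"  log-likelihood:            {self.llf:.4f}",
            f"  converged:                 {self.converged}",
            "",
            f"  {'category':<10} {'intercept':>10} {'(se)':>8} "
            f"{'slope/ky':>10} {'(se)':>8}",
        ]
        for row in self.coef_frame().itertuples():
            lines.append(
                f"  {row.category:<10} {row.intercept:>10.4f} "
                f"({row.se_intercept:>6.4f}) {row.slope_per_ky:>10.4f} "
                f"({row.se_slope:>6.4f})"
            )
        if self.model.absent_categories:
            lines.append(
                f"  categories fixed at frequency 0 (unobserved): "
                f"{', '.join(self.model.absent_categories)}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "reference": self.model.reference,
            "categories": list(self.model.nonref),
            "params": self.params.tolist(),
            "cov_params": self.cov_params.tolist(),
            "loglik": self.llf,
            "converged": self.converged,
        }

    def plot(self, ages=None, ax=None):  # pragma: no cover - visual aid
        import matplotlib.pyplot as plt

        if ages is None:
            ages = np.linspace(self.model._t.min() * -1000.0, 0.0, 200)
        freqs = self.predict(ages)
        if ax is None:
            _, ax = plt.subplots()
        for c in freqs.columns:
            ax.plot(ages, freqs[c], label=c)
        ax.set_xlabel("age (years BP)")
        ax.set_ylabel("haplotype frequency")
        ax.invert_xaxis()
        ax.legend()
        return ax


def bin_counts(
    obs: pd.DataFrame,
    bin_width: float,
    category: str = "category",
    age: str = "age_bp",
) -> pd.DataFrame:
    """Per-category haplotype counts in half-open age bins [k*w, (k+1)*w).

    An observation exactly on a boundary belongs to the bin whose lower
    edge it sits on.  Counts are conserved: they sum to the number of
    observations.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ages = obs[age].to_numpy(dtype=float)
    k = np.floor(ages / bin_width).astype(int)
    frame = pd.DataFrame({"bin": k, "category": obs[category]})
    counts = (
        frame.groupby(["bin", "category"]).size().unstack(fill_value=0).sort_index()
    )
    counts.index = pd.IntervalIndex.from_arrays(
        counts.index * bin_width, (counts.index + 1) * bin_width, closed="left"
    )
    counts.index.name = "age_bin_bp"
    return counts
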