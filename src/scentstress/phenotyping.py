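"""Freezing-phenotype classification.

Two ingredients: (i) Gaussian-mixture evidence that the distribution of
exposure-session freezing times across animals is bimodal, selected by AIC
with Akaike weights, and (ii) the actual subgrouping used downstream — a
tertile split (top/bottom thirds -> high-/low-freezing) or a median split for
small cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = ["GmmSelection", "PhenotypeAssignment", "fit_gmm_series", "akaike_weights", "assign_phenotype"]


@dataclass(frozen=True)
class GmmFit:
    """One fitted 1-D Gaussian mixture: weights, means, sds, max log-likelihood."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    aic: float

    @property
    def n_params(self) -> int:
        # free weights (k-1) + means (k) + variances (k)
        return 3 * self.k - 1


@dataclass(frozen=True)
class GmmSelection:
    """AIC model selection over mixtures with k = 1..k_max components."""

    fits: tuple[GmmFit, ...]
    delta_aic: np.ndarray
    weights: np.ndarray  # Akaike weights, one per candidate k
    selected_k: int


def akaike_weights(delta_aic) -> np.ndarray:
    """Akaike weights w_i = exp(-d_i/2) / sum_j exp(-d_j/2).

    Invariant to adding a constant to every AIC, so raw AICs are accepted and
    normalized internally.
    """
    d = np.asarray(delta_aic, dtype=float).ravel()
    if d.size == 0 or not np.all(np.isfinite(d)):
        raise ValueError("AIC differences must be non-empty and finite")
    d = d - d.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def fit_gmm_series(
    values,
    k_max: int = 3,
    n_restarts: int = 20,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    sd_floor_frac: float = 0.20,
) -> GmmSelection:
    """Fit 1-D Gaussian mixtures with 1..k_max components; select by AIC.

    Each candidate is fit by EM from ``n_restarts`` seeded initializations and
    the best *non-degenerate* log-likelihood is kept. The unequal-variance 1-D
    mixture likelihood is unbounded — a component can collapse onto a few
    near-duplicate observations with vanishing variance — so restarts whose
    smallest component sd falls below ``sd_floor_frac`` of the data sd, or
    whose smallest weight carries fewer than ~1.5 observations, are treated as
    spurious likelihood spikes and discarded; if every restart collapses, the
    candidate is refit with the variance bound imposed as a covariance
    regularizer. AIC_k = 2 p_k - 2 lnL with p_k = 3k - 1
    free parameters (free weights, means, unequal variances). Zero-variance
    input is degenerate and raises.
    """
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("freezing values must be finite")
    if x.size < 3 * k_max:
        raise ValueError(f"need at least {3 * k_max} observations for k_max={k_max}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all values identical")
    X = x[:, None]
    sd_floor = sd_floor_frac * x.std()
    w_floor = 1.5 / x.size
    rng = np.random.default_rng(seed)

    def _fit_once(k: int, reg_sd: float, state: int) -> GaussianMixture:
        return GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=1,
            init_params="k-means++",
            max_iter=max_iter,
            tol=tol,
            reg_covar=reg_sd**2,
            random_state=state,
        ).fit(X)

    def _degenerate(gm: GaussianMixture) -> bool:
        sds = np.sqrt(gm.covariances_.ravel())
        return bool(sds.min() < sd_floor or gm.weights_.min() < w_floor)

    fits = []
    for k in range(1, k_max + 1):
        candidates = [
            _fit_once(k, 1e-6 * x.std(), int(rng.integers(2**31 - 1)))
            for _ in range(max(1, n_restarts))
        ]
        usable = [gm for gm in candidates if not _degenerate(gm)]
        if not usable:
            # every restart collapsed: refit with the variance bound imposed
            usable = [_fit_once(k, sd_floor, int(rng.integers(2**31 - 1)))]
        gm = max(usable, key=lambda g: g.score(X))
        lnl = float(gm.score(X) * x.size)
        order = np.argsort(gm.means_.ravel())
        fits.append(
            GmmFit(
                k=k,
                weights=gm.weights_.ravel()[order],
                means=gm.means_.ravel()[order],
                sds=np.sqrt(gm.covariances_.ravel())[order],
                log_likelihood=lnl,
                aic=float(2 * (3 * k - 1) - 2 * lnl),
            )
        )

    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    return GmmSelection(
        fits=tuple(fits),
        delta_aic=delta,
        weights=akaike_weights(delta),
        selected_k=int(np.argmin(aics)) + 1,
    )


@dataclass(frozen=True)
class PhenotypeAssignment:
    labels: tuple[str, ...]  # per subject, input order: low / middle / high
    method: str
    cuts: tuple[float, float]  # (upper edge of low, lower edge of high)
    n_low: int
    n_middle: int
    n_high: int


def assign_phenotype(freezing, method: str = "tertile") -> PhenotypeAssignment:
    """Split subjects into low-/high-freezing subgroups by freezing time.

    ``tertile``: the bottom and top round(n/3) subjects become low and high,
    the remainder middle (62 animals -> 21/20/21). ``median``: bottom half low,
    top half high; requires even n. Ties are broken by stable input order.
    """
    x = np.asarray(freezing, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("freezing values must be finite")
    n = x.size
    order = np.argsort(x, kind="stable")
    if method == "tertile":
        if n < 3:
            raise ValueError("tertile split needs n >= 3")
        n_cut = int(round(n / 3))
    elif method == "median":
        if n < 2 or n % 2:
            raise ValueError("median split needs an even n >= 2")
        n_cut = n // 2
    else:
        raise ValueError(f"unknown method {method!r}")

    labels = np.full(n, "middle", dtype=object)
    labels[order[:n_cut]] = "low"
    labels[order[n - n_cut:]] = "high"
    return PhenotypeAssignment(
        labels=tuple(labels),
        method=method,
        cuts=(float(x[order[n_cut - 1]]), float(x[order[n - n_cut]])),
        n_low=n_cut,
        n_middle=n - 2 * n_cut,
        n_high=n_cut,
    )
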