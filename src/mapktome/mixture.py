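"""Volume-varying Gaussian mixture clustering with controlled MAP assignment.

Expression profiles (one row per probe, one column per contrast) are
modelled as a K-component Gaussian mixture whose covariances share one
orientation/shape matrix C (symmetric positive definite, det C = 1) while
the component volumes lambda_k differ: Sigma_k = lambda_k * C.  The
constrained M-step has no closed form and is solved by an inner
alternation between the volumes and the shared shape.  The number of
components is selected by BIC (minimising -2 loglik + m log n), and
observations are assigned to their maximum a posteriori component only
when the posterior clears a data-driven threshold tau chosen so that the
estimated proportion of misassigned observations among those classified
stays below a control level alpha — a clustering analogue of the
Bayesian false discovery rate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

_VOLUME_FLOOR = 1e-8


class StartFailed(RuntimeError):
    """An EM start aborted after repeated component collapse."""


@dataclass
class MixtureModel:
    """Fitted constrained mixture: Sigma_k = volumes[k] * shape, det(shape)=1."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    volumes: np.ndarray  # (K,)
    shape: np.ndarray  # (d, d), unit determinant
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def d(self) -> int:
        return self.means.shape[1]

    @property
    def n_params(self) -> int:
        K, d = self.K, self.d
        return (K - 1) + K * d + K + (d * (d + 1) // 2 - 1)

    def bic(self, n: int) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(n)

    def covariances(self) -> np.ndarray:
        return self.volumes[:, None, None] * self.shape[None, :, :]

    def validate(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if abs(np.linalg.det(self.shape) - 1.0) > 1e-6:
            raise ValueError("shape matrix must have unit determinant")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be positive")

    def log_responsibilities(self, X: np.ndarray) -> tuple[np.ndarray, float]:
        """(log posterior matrix, total log-likelihood) for data X."""
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        shape_inv = np.linalg.inv(self.shape)
        log_dens = np.empty((n, self.K))
        for k in range(self.K):
            diff = X - self.means[k]
            quad = np.einsum("ij,jk,ik->i", diff, shape_inv, diff) / self.volumes[k]
            # log det Sigma_k = d log lambda_k since det(shape) = 1
            log_dens[:, k] = -0.5 * (d * np.log(2 * np.pi) + d * np.log(self.volumes[k]) + quad)
        weighted = log_dens + np.log(self.weights)
        norm = logsumexp(weighted, axis=1)
        return weighted - norm[:, None], float(norm.sum())

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        log_resp, _ = self.log_responsibilities(X)
        return np.exp(log_resp)

    def to_json(self, path) -> None:
        payload = {
            "K": self.K,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "volumes": self.volumes.tolist(),
            "shape": self.shape.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MixtureModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            weights=np.asarray(payload["weights"]),
            means=np.asarray(payload["means"]),
            volumes=np.asarray(payload["volumes"]),
            shape=np.asarray(payload["shape"]),
            loglik=payload["loglik"],
        )


@dataclass
class Assignment:
    """Threshold-MAP assignment with misassignment control.

    ``table`` has one row per observation: the MAP label, the maximum
    posterior, and whether the observation cleared the threshold (strictly
    greater than tau).  ``fap`` is the estimated false assignment
    proportion of the classified set — the mean posterior probability of
    not belonging to the assigned component.
    """

    table: pd.DataFrame  # columns: label, max_posterior, classified
    posteriors: np.ndarray
    tau: float
    alpha: float
    fap: float

    @property
    def n_classified(self) -> int:
        return int(self.table["classified"].sum())

    @property
    def expected_misassigned(self) -> int:
        return expected_misassigned(self.n_classified, self.alpha)


def expected_misassigned(n_classified: int, alpha: float) -> int:
    """Expected misassigned count when the control level is saturated."""
    return int(round(n_classified * alpha))


def _m_step_constrained(
    W: np.ndarray, nk: np.ndarray, shape: np.ndarray, max_inner: int = 50, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Alternate volumes and shared shape for the constrained covariances.

    Given weighted scatter matrices W_k, repeats
    lambda_k <- trace(C^-1 W_k) / (n_k d); C <- sum_k W_k / lambda_k
    rescaled to unit determinant, until the volumes stabilise.
    """
    d = W.shape[1]
    C = shape.copy()
    volumes = np.ones(len(nk))
    for _ in range(max_inner):
        C_inv = np.linalg.inv(C)
        new_volumes = np.einsum("kij,ji->k", W, C_inv) / (nk * d)
        new_volumes = np.maximum(new_volumes, 0.0)
        if np.any(new_volumes < _VOLUME_FLOOR):
            return new_volumes, C  # caller handles the collapse
        M = np.tensordot(1.0 / new_volumes, W, axes=1)
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0:
            raise StartFailed("pooled scatter matrix not positive definite")
        C_new = M / np.exp(logdet / d)
        C_new = (C_new + C_new.T) / 2.0
        done = np.allclose(new_volumes, volumes, rtol=tol) and np.allclose(C_new, C, rtol=tol)
        volumes, C = new_volumes, C_new
        if done:
            break
    return volumes, C


def _em_single_start(
    X: np.ndarray, K: int, rng: np.random.Generator, tol: float, max_iter: int
) -> MixtureModel:
    n, d = X.shape
    km = KMeans(n_clusters=K, init="k-means++", n_init=1,
                random_state=int(rng.integers(2**31 - 1)), max_iter=30)
    labels = km.fit_predict(X)
    resp = np.zeros((n, K))
    resp[np.arange(n), labels] = 1.0

    model = MixtureModel(
        weights=np.full(K, 1.0 / K),
        means=np.zeros((K, d)),
        volumes=np.ones(K),
        shape=np.eye(d),
        loglik=-np.inf,
    )
    collapsed_once = np.zeros(K, dtype=bool)
    prev_ll = -np.inf
    for _ in range(max_iter):
        # M-step
        nk = resp.sum(axis=0)
        if np.any(nk < max(d, 1)):
            k_bad = int(np.argmin(nk))
            if collapsed_once[k_bad]:
                raise StartFailed(f"component {k_bad} collapsed twice")
            collapsed_once[k_bad] = True
            resp[:, k_bad] = 1.0 / n
            resp /= resp.sum(axis=1, keepdims=True)
            nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        W = np.empty((K, d, d))
        for k in range(K):
            diff = X - means[k]
            W[k] = (resp[:, k][:, None] * diff).T @ diff
        volumes, shape = _m_step_constrained(W, nk, model.shape)
        if np.any(volumes < _VOLUME_FLOOR):
            k_bad = int(np.argmin(volumes))
            if collapsed_once[k_bad]:
                raise StartFailed(f"component {k_bad} volume collapsed twice")
            collapsed_once[k_bad] = True
            means[k_bad] = X[rng.integers(n)]
            volumes[k_bad] = max(float(np.median(volumes[volumes >= _VOLUME_FLOOR])), 1.0) \
                if np.any(volumes >= _VOLUME_FLOOR) else 1.0
        model = MixtureModel(weights=weights, means=means, volumes=volumes,
                             shape=shape, loglik=model.loglik,
                             loglik_trace=model.loglik_trace)
        # E-step
        log_resp, ll = model.log_responsibilities(X)
        resp = np.exp(log_resp)
        model.loglik = ll
        model.loglik_trace.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * abs(prev_ll):
            break
        prev_ll = ll
    model.validate()
    return model


def fit_vee_em(
    X,
    K: int,
    n_starts: int = 10,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureModel:
    """Fit the K-component constrained mixture by EM.

    Runs ``n_starts`` k-means++-initialised EM chains and returns the one
    with the best log-likelihood.  The log-likelihood is non-decreasing
    along each chain (``loglik_trace`` records it).  Requires n > K * d.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if n <= K * d:
        raise ValueError(f"need n > K*d = {K * d} observations, got {n}")
    rng = np.random.default_rng(seed)
    best: MixtureModel | None = None
    failures = 0
    for _ in range(n_starts):
        try:
            model = _em_single_start(X, K, rng, tol, max_iter)
        except StartFailed:
            failures += 1
            continue
        if best is None or model.loglik > best.loglik:
            best = model
    if best is None:
        raise StartFailed(f"all {n_starts} EM starts failed for K={K}")
    if failures:
        warnings.warn(f"{failures}/{n_starts} EM starts aborted for K={K}")
    return best


def select_K(
    X,
    K_range=range(2, 41),
    n_starts: int = 10,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[MixtureModel, pd.DataFrame]:
    """Fit every K in ``K_range`` and return the BIC-minimising model.

    The second return value is the full trace (K, loglik, n_params, BIC);
    values of K whose every start failed are skipped with a warning.
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range is empty")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    rows, models = [], {}
    seeds = np.random.SeedSequence(seed).spawn(len(K_range))
    for K, ss in zip(K_range, seeds):
        try:
            model = fit_vee_em(X, K, n_starts=n_starts,
                               seed=ss.generate_state(1)[0], tol=tol, max_iter=max_iter)
        except (StartFailed, ValueError) as err:
            warnings.warn(f"K={K} skipped: {err}")
            continue
        models[K] = model
        rows.append({"K": K, "loglik": model.loglik,
                     "n_params": model.n_params, "bic": model.bic(n)})
    if not models:
        raise StartFailed("no K in the range could be fitted")
    trace = pd.DataFrame(rows)
    best_K = int(trace.loc[trace["bic"].idxmin(), "K"])
    return models[best_K], trace


def threshold_map_assign(model: MixtureModel, X, alpha: float = 0.05,
                         index=None) -> Assignment:
    """Classify observations whose maximum posterior clears a threshold.

    Candidate thresholds run over the sorted distinct maximum posteriors
    (plus a value just below the smallest, so that classifying everything
    is a candidate).  For each tau, the classified set is
    {i : max_k p_ik > tau} and its estimated false assignment proportion
    is FAP(tau) = mean(1 - max_k p_ik).  The smallest tau with
    FAP(tau) <= alpha is chosen, classifying as many observations as the
    control level allows; if no tau qualifies nothing is classified.
    """
    X = np.asarray(X, dtype=float)
    post = model.predict_proba(X)
    labels = post.argmax(axis=1)
    maxp = post.max(axis=1)
    candidates = np.unique(maxp)
    candidates = np.concatenate([[np.nextafter(candidates[0], -np.inf)], candidates])
    tau, fap = None, np.nan
    for cand in candidates:
        mask = maxp > cand
        if not mask.any():
            break
        value = float(np.mean(1.0 - maxp[mask]))
        if value <= alpha:
            tau, fap = float(cand), value
            break
    if tau is None:
        warnings.warn("no threshold satisfies the misassignment constraint; "
                      "nothing classified")
        tau, fap = 1.0, 0.0
    classified = maxp > tau
    table = pd.DataFrame(
        {"label": labels, "max_posterior": maxp, "classified": classified},
        index=index if index is not None else pd.RangeIndex(len(maxp)),
    )
    return Assignment(table=table, posteriors=post, tau=tau, alpha=alpha, fap=fap)


def summarise_clusters(
    assignment: Assignment,
    X: pd.DataFrame,
    de_flags: pd.DataFrame | None = None,
    interpretable_fraction: float = 0.5,
    low_n: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Boxplot-style profile summaries and the interpretability call.

    For every cluster and comparison: quartiles (linear interpolation
    between order statistics), whiskers Q1 - 1.5 (Q3 - Q1) and
    Q3 + 1.5 (Q3 - Q1), the count of values outside the whiskers, and —
    when DE flags are supplied — the percentage of member rows called
    differentially expressed.  A cluster is interpretable when that
    percentage exceeds ``interpretable_fraction`` in some comparison.
    Returns (per-cluster-per-comparison profiles, per-cluster table).
    """
    tab = assignment.table
    if not tab["classified"].any():
        raise ValueError("no classified observations to summarise")
    members = tab[tab["classified"]]
    profile_rows, cluster_rows = [], []
    for cluster, sub in members.groupby("label"):
        rows = X.loc[sub.index]
        pct_by_comp = {}
        for comp in X.columns:
            vals = rows[comp].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            pct = np.nan
            if de_flags is not None:
                pct = 100.0 * de_flags.loc[rows.index, comp].mean()
            pct_by_comp[comp] = pct
            profile_rows.append(
                {
                    "cluster": cluster,
                    "comparison": comp,
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                    "whisker_low": lo,
                    "whisker_high": hi,
                    "n_outliers": int(np.sum((vals < lo) | (vals > hi))),
                    "pct_de": pct,
                }
            )
        interpretable = (
            bool(np.nanmax(list(pct_by_comp.values())) > 100.0 * interpretable_fraction)
            if de_flags is not None
            else False
        )
        cluster_rows.append(
            {
                "cluster": cluster,
                "size": len(rows),
                "low_n": len(rows) < low_n,
                "interpretable": interpretable,
            }
        )
    return pd.DataFrame(profile_rows), pd.DataFrame(cluster_rows)
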