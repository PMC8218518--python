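"""De novo signature extraction by Kullback-Leibler NMF.

The cohort count matrix V (96 channels x N samples) is approximated as
V ~ W H with W >= 0 the signatures (96 x K, columns normalized to sum 1)
and H >= 0 the per-sample contributions on the mutation-count scale.
The factorization minimizes the generalized KL divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ]

by Lee-Seung multiplicative updates, which never increase the objective.
Because the problem is non-convex, the best of several random restarts is
kept; with a fixed seed the result is fully deterministic.

:class:`KLNMF` follows the scikit-learn estimator contract (``fit`` /
``transform`` on samples-by-channels arrays); :func:`nmf_factorize` is the
domain-facing wrapper operating on a channels-by-samples profile matrix.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .channels import CHANNEL_LABELS
from .errors import ConfigurationError, DataError
from .profiles import ProfileMatrix

_EPS = 1e-12


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    # 0 * log 0 := 0 by continuity; the -V + WH part is kept for all entries
    # so the objective is a true (generalized) divergence, zero iff V == WH.
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(V > 0, V * np.log(V / (WH + _EPS)), 0.0)
    return float(np.sum(logterm - V + WH))


def _multiplicative_fit(
    V: np.ndarray,
    rank: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One restart of Lee-Seung KL updates. Returns (W, H, objective trace)."""
    n_chan, n_samp = V.shape
    scale = np.sqrt(V.mean() / rank) + _EPS
    W = rng.uniform(_EPS, 1.0, size=(n_chan, rank)) * scale
    H = rng.uniform(_EPS, 1.0, size=(rank, n_samp)) * scale
    trace = np.empty(max_iter)
    prev = np.inf
    n_done = 0
    for it in range(max_iter):
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        obj = _kl_divergence(V, W @ H + _EPS)
        trace[it] = obj
        n_done = it + 1
        if np.isfinite(prev) and prev - obj < tol * max(prev, _EPS):
            break
        prev = obj
    return W, H, trace[:n_done]


class KLNMF(TransformerMixin, BaseEstimator):
    """Non-negative matrix factorization with generalized KL loss.

    Parameters
    ----------
    n_components : int, default 4
        Number of signatures K to extract.
    n_restarts : int, default 30
        Random restarts; the factorization with the lowest final
        divergence wins, ties broken by the lowest restart index.
    max_iter : int, default 2000
        Maximum multiplicative-update iterations per restart.
    tol : float, default 1e-6
        Stop a restart when the relative objective decrease per iteration
        falls below this.
    random_state : int or None
        Seed for the restart initializations.

    Attributes
    ----------
    components_ : ndarray of shape (n_components, 96)
        Extracted signatures; each row sums to 1.
    reconstruction_err_ : float
        Final KL divergence of the winning restart.
    objective_trace_ : ndarray
        Per-iteration divergence of the winning restart (non-increasing).
    best_restart_ : int
        Index of the winning restart.
    n_iter_ : int
        Iterations run by the winning restart.
    """

    def __init__(
        self,
        n_components: int = 4,
        n_restarts: int = 30,
        max_iter: int = 2000,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _validate(self, X: np.ndarray) -> np.ndarray:
        X = check_array(X, dtype=np.float64)
        if (X < 0).any():
            raise DataError("profile counts must be non-negative")
        if not X.any():
            raise DataError("degenerate input: the count matrix is all zeros")
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")
        if self.n_components > min(X.shape):
            raise ConfigurationError(
                f"n_components={self.n_components} exceeds min matrix dimension {min(X.shape)}"
            )
        return X

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        """Fit on X (samples x channels) and return contributions (samples x K)."""
        X = self._validate(X)
        V = X.T  # channels x samples internally
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_restarts)
        best = None
        for r, seed in enumerate(seeds):
            rng = np.random.default_rng(seed)
            W, H, trace = _multiplicative_fit(V, self.n_components, rng, self.max_iter, self.tol)
            if best is None or trace[-1] < best[3][-1]:
                best = (r, W, H, trace)
        r, W, H, trace = best
        # absorb signature scale into the contributions: W columns sum to 1,
        # H stays on the mutation-count scale
        col = W.sum(axis=0)
        col[col == 0] = 1.0
        W = W / col
        H = H * col[:, None]
        self.components_ = W.T
        self.reconstruction_err_ = float(trace[-1])
        self.objective_trace_ = trace
        self.best_restart_ = r
        self.n_iter_ = len(trace)
        self.n_features_in_ = X.shape[1]
        return H.T

    def transform(self, X):
        """Contributions of new samples against the fitted signatures.

        Runs H-only multiplicative updates with W frozen, from a
        deterministic (column-total based) initialization.
        """
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=np.float64)
        V = X.T
        W = self.components_.T
        H = np.tile(V.sum(axis=0) / self.n_components, (self.n_components, 1)) + _EPS
        prev = np.inf
        for _ in range(self.max_iter):
            WH = W @ H + _EPS
            H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
            obj = _kl_divergence(V, W @ H + _EPS)
            if np.isfinite(prev) and prev - obj < self.tol * max(prev, _EPS):
                break
            prev = obj
        return H.T

    def inverse_transform(self, Xt):
        check_is_fitted(self, "components_")
        return np.asarray(Xt) @ self.components_


@dataclasses.dataclass
class Factorization:
    """Result of :func:`nmf_factorize` in the domain orientation.

    W is 96 x K (columns sum to 1), H is K x N on the count scale.
    Samples whose profile column was all zero are excluded from the fit
    and reported in ``dropped_samples``; their H columns are zero.
    """

    W: pd.DataFrame
    H: pd.DataFrame
    objective_trace: np.ndarray
    best_restart_seed: int
    dropped_samples: list[str]

    @property
    def signature_names(self) -> list[str]:
        return list(self.W.columns)

    def reconstruction(self) -> pd.DataFrame:
        return self.W @ self.H


def nmf_factorize(
    profiles: ProfileMatrix | pd.DataFrame,
    rank: int = 4,
    n_restarts: int = 30,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int | None = None,
) -> Factorization:
    """Extract ``rank`` de novo signatures from a 96 x N profile matrix."""
    counts = profiles.counts if isinstance(profiles, ProfileMatrix) else profiles
    V = counts.to_numpy(dtype=np.float64)
    if V.shape[0] != 96:
        raise ConfigurationError(f"expected 96 channel rows, got {V.shape[0]}")
    sample_ids = list(counts.columns)
    nonzero = V.sum(axis=0) > 0
    dropped = [s for s, nz in zip(sample_ids, nonzero) if not nz]
    if not nonzero.any():
        raise DataError("degenerate input: every sample has zero counts")
    if rank > int(nonzero.sum()):
        raise ConfigurationError(f"rank={rank} exceeds the {int(nonzero.sum())} non-empty samples")
    model = KLNMF(
        n_components=rank, n_restarts=n_restarts, max_iter=max_iter, tol=tol, random_state=seed
    )
    H_fit = model.fit_transform(V[:, nonzero].T).T
    H = np.zeros((rank, len(sample_ids)))
    H[:, nonzero] = H_fit
    sig_names = [f"Signature_{chr(ord('A') + k)}" for k in range(rank)]
    W_df = pd.DataFrame(model.components_.T, index=list(CHANNEL_LABELS), columns=sig_names)
    H_df = pd.DataFrame(H, index=sig_names, columns=sample_ids)
    return Factorization(
        W=W_df,
        H=H_df,
        objective_trace=model.objective_trace_,
        best_restart_seed=model.best_restart_,
        dropped_samples=dropped,
    )


def reconstruction_similarity(
    V: ProfileMatrix | pd.DataFrame | np.ndarray,
    W: pd.DataFrame | np.ndarray,
    H: pd.DataFrame | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample cosine similarity between V and its reconstruction WH.

    Returns ``(cosines, zero_flags)``; a sample whose observed or
    reconstructed column is all zero gets cosine 0 with its flag set.
    """
    if isinstance(V, ProfileMatrix):
        V = V.counts
    V = np.asarray(V, dtype=float)
    R = np.asarray(W, dtype=float) @ np.asarray(H, dtype=float)
    if V.shape != R.shape:
        raise ConfigurationError(f"shape mismatch: V {V.shape} vs WH {R.shape}")
    num = (V * R).sum(axis=0)
    den = np.linalg.norm(V, axis=0) * np.linalg.norm(R, axis=0)
    flags = den == 0
    cos = np.zeros(V.shape[1])
    np.divide(num, den, out=cos, where=~flags)
    return np.clip(cos, 0.0, 1.0), flags
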