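"""Canonical Analysis of Principal Coordinates (CAP) for group classification.

CAP (Anderson & Willis 2003) is a constrained ordination: a principal
coordinates analysis (PCoA) of a distance matrix, followed by a canonical
discriminant analysis of the first ``m`` orthonormal PCoA axes against the
group-indicator space.  With Euclidean distances on a z-scored parameter
matrix — the default here — PCoA is equivalent to PCA of the centered data,
and CAP becomes a regularized discriminant analysis whose axis count ``m``
is chosen by maximizing leave-one-out (LOO) allocation success.

The implementation follows the classical recipe:

* Gower double-centering ``G = -1/2 J D∘D J`` and a symmetric
  eigendecomposition give PCoA eigenvalues and orthonormal axes ``Q``
  (axes with non-positive eigenvalues are reported but excluded);
* the canonical eigenproblem is ``Q_m' H Q_m`` with ``H`` the projector
  onto the group-indicator column space; its eigenvalues are squared
  canonical correlations and their sum the trace statistic;
* LOO allocation re-estimates the PCoA per holdout and places the held-out
  sample by Gower's formula for adding a point to an existing ordination,
  then assigns it to the nearest group centroid in canonical space;
* significance of group separation comes from a permutation test of the
  trace statistic under random relabeling.  Because "auto" chooses ``m``
  with the help of the labels, each permutation re-runs the entire
  procedure — LOO scan, axis selection, trace — under the permuted labels;
  permuting only the final trace at the observed ``m`` would be
  anti-conservative.

Two geometric facts keep this affordable.  The per-holdout ordinations and
point projections depend only on the data, never on the labels, so they
are computed once and reused for every permutation.  And nearest-centroid
allocation in the canonical space equals nearest-centroid allocation in
the first ``m`` orthonormal PCoA coordinates: the canonical axes are an
orthonormal rotation of (a subspace of) those coordinates that contains
every group centroid, so the components it discards add the same amount
to the distance from a point to every centroid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-9  # relative cutoff for a "positive" PCoA eigenvalue


@dataclass(frozen=True)
class CapConfig:
    """Settings for a CAP run.

    m : number of PCoA axes to retain, or "auto" to maximize LOO success
        (ties broken toward the smallest m).
    n_permutations : relabelings for the trace permutation test.
    seed : RNG seed for the permutations.
    normalization : "zscore" (column-wise standardization) or "none".
    """

    m: int | str = "auto"
    n_permutations: int = 999
    seed: int = 0
    normalization: str = "zscore"


@dataclass(frozen=True)
class CapResult:
    """Outcome of a CAP fit."""

    eigenvalues: np.ndarray
    m_used: int
    squared_correlations: np.ndarray
    canonical_scores: pd.DataFrame
    allocation: pd.DataFrame
    n_correct: int
    trace_statistic: float
    p_perm: float
    loo_success: dict[int, float]


def normalize_matrix(X: pd.DataFrame | np.ndarray, mode: str = "zscore"):
    """Column-standardize a samples × parameters matrix.

    Each column is centered to mean 0 and scaled to unit (population)
    standard deviation.  Rows containing missing values are dropped with a
    warning, zero-variance columns likewise.  ``mode="none"`` returns the
    input unchanged (after the missing-row drop).

    Raises
    ------
    ValidationError
        If fewer than 2 complete rows remain or every column has zero
        variance.
    """
    if mode not in ("zscore", "none"):
        raise ValueError(f"unknown normalization {mode!r}")
    is_df = isinstance(X, pd.DataFrame)
    df = X if is_df else pd.DataFrame(np.asarray(X, dtype=float))
    complete = df.notna().all(axis=1)
    if not complete.all():
        warnings.warn(f"dropping {int((~complete).sum())} row(s) with missing values")
        df = df.loc[complete]
    if len(df) < 2:
        raise ValidationError("need at least 2 complete samples")
    if mode == "none":
        return df if is_df else df.to_numpy()
    sd = df.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValidationError("all columns have zero variance")
    if not keep.all():
        warnings.warn(f"dropping zero-variance column(s): {list(df.columns[~keep])}")
        df = df.loc[:, keep]
        sd = sd[keep]
    out = (df - df.mean(axis=0)) / sd
    return out if is_df else out.to_numpy()


def _gower_center(sq_dists: np.ndarray) -> np.ndarray:
    a = -0.5 * sq_dists
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _pcoa_eig(G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecompose a Gower-centered matrix; eigenvalues descending."""
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(abs(vals[0]), abs(vals[-1]), 1.0e-300)
    positive = vals > scale * _EIG_TOL
    return vals, vecs, positive


def pcoa(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates analysis of a distance matrix.

    Returns all eigenvalues (descending) and the sample scores
    ``eigvec * sqrt(eigval)`` for the positive-eigenvalue axes only;
    negative eigenvalues (possible for non-Euclidean distances) are
    reported in the eigenvalue vector but contribute no axis.

    Raises
    ------
    ValidationError
        If D is not square/symmetric, has a nonzero diagonal or negative
        entries.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValidationError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValidationError("distances must be non-negative")
    vals, vecs, positive = _pcoa_eig(_gower_center(D ** 2))
    scores = vecs[:, positive] * np.sqrt(vals[positive])
    return vals, scores


def _project_holdout(G: np.ndarray, sq_d_new: np.ndarray) -> np.ndarray:
    """Centered inner products of a new point with an existing ordination.

    Gower's addition of a point: with training PCoA configuration ``Y``
    (rows centered) and squared distances ``d_j`` of the new point to the
    training points, ``Y' z = c`` where
    ``c_j = 1/2 (G_jj - d_j + mean(d) - mean(diag G))``.
    """
    diag = np.diag(G)
    return 0.5 * (diag - sq_d_new + sq_d_new.mean() - diag.mean())


def _canonical_eig(Q: np.ndarray, y_idx: np.ndarray, n_groups: int):
    """Eigendecompose Q' H Q for orthonormal axes Q and group labels.

    Returns squared canonical correlations (descending, clipped to [0, 1]),
    the canonical weight vectors (columns), and the number of meaningful
    canonical axes min(m, g-1).
    """
    counts = np.bincount(y_idx, minlength=n_groups).astype(float)
    sums = np.zeros((n_groups, Q.shape[1]))
    np.add.at(sums, y_idx, Q)
    means = sums / counts[:, None]
    B = (means * counts[:, None]).T @ means  # Q' H Q = Σ_g n_g m̄_g m̄_g'
    vals, vecs = np.linalg.eigh(B)
    vals = np.clip(vals[::-1], 0.0, 1.0)
    vecs = vecs[:, ::-1]
    n_axes = min(Q.shape[1], n_groups - 1)
    return vals, vecs, n_axes


def _group_trace(Q: np.ndarray, y_idx: np.ndarray, counts: np.ndarray) -> float:
    """trace(Q' H Q) = Σ_g |column sums within group g|² / n_g."""
    sums = np.zeros((counts.size, Q.shape[1]))
    np.add.at(sums, y_idx, Q)
    return float((sums ** 2 / counts[:, None]).sum())


class _LooEngine:
    """Label-independent leave-one-out geometry, reused across permutations.

    For each holdout the PCoA of the remaining n-1 samples is computed once;
    ``train_coords[i]`` holds the training samples' coordinates on that
    ordination's orthonormal axes (zero-padded to ``m_max`` columns) and
    ``holdout_coords[i]`` the Gower projection of the held-out sample.
    Given any labeling, :meth:`loo_success` classifies every holdout by the
    nearest group centroid in the first m coordinates, for all m at once
    (cumulative squared distances over axes).
    """

    def __init__(self, D2: np.ndarray, m_max: int):
        n = D2.shape[0]
        self.n = n
        self.m_max = m_max
        self.train_idx = np.stack([np.delete(np.arange(n), i) for i in range(n)])
        self.train_coords = np.zeros((n, n - 1, m_max))
        self.holdout_coords = np.zeros((n, m_max))
        for i in range(n):
            mask = self.train_idx[i]
            G = _gower_center(D2[np.ix_(mask, mask)])
            vals, vecs, positive = _pcoa_eig(G)
            r = min(int(positive.sum()), m_max)
            V, lam = vecs[:, :r], vals[:r]
            self.train_coords[i, :, :r] = V
            c = _project_holdout(G, D2[i, mask])
            self.holdout_coords[i, :r] = (V.T @ c) / lam

    def loo_predictions(self, y_idx: np.ndarray, n_groups: int) -> np.ndarray:
        """(n, m_max) LOO-predicted group index; column m-1 = retain m axes."""
        onehot = np.zeros((self.n, n_groups))
        onehot[np.arange(self.n), y_idx] = 1.0
        oh = onehot[self.train_idx]                      # (n, n-1, g)
        counts = oh.sum(axis=1)                          # (n, g) >= 1 each
        sums = np.einsum("hng,hnr->hgr", oh, self.train_coords)
        centroids = sums / counts[:, :, None]
        sq = (centroids - self.holdout_coords[:, None, :]) ** 2
        return np.argmin(sq.cumsum(axis=2), axis=1)      # (n, m_max)

    def loo_success(self, y_idx: np.ndarray, n_groups: int) -> np.ndarray:
        """LOO allocation success rate for every candidate m (length m_max)."""
        preds = self.loo_predictions(y_idx, n_groups)
        return (preds == y_idx[:, None]).mean(axis=0)


def _cumulative_traces(Q: np.ndarray, y_idx: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """trace(Q_m' H Q_m) for every prefix m = 1..Q.shape[1], in one pass."""
    sums = np.zeros((counts.size, Q.shape[1]))
    np.add.at(sums, y_idx, Q)
    return (sums ** 2 / counts[:, None]).sum(axis=0).cumsum()


class CapOrdination(BaseEstimator, ClassifierMixin):
    """Canonical Analysis of Principal Coordinates as a classifier.

    Parameters
    ----------
    m : int or "auto", default "auto"
        Number of PCoA axes retained for the canonical analysis.  "auto"
        scans 1..min(rank, n-2) and keeps the m with the highest LOO
        allocation success (smallest m on ties).
    n_permutations : int, default 999
        Relabelings for the permutation test of the trace statistic.
    normalization : {"zscore", "none"}, default "zscore"
        Column standardization applied before computing Euclidean distances.
    random_state : int or None
        Seed for the permutation RNG.

    Attributes (after ``fit``)
    --------------------------
    classes_ : group labels.
    eigenvalues_ : all PCoA eigenvalues, descending.
    m_used_ : retained axis count.
    squared_correlations_ : canonical squared correlations (length min(m, g-1)).
    trace_ : sum of all squared canonical correlations (the test statistic).
    canonical_scores_ : DataFrame of per-sample canonical coordinates.
    loo_predictions_ : LOO-predicted group per sample at ``m_used_``.
    allocation_ : confusion table, true groups × predicted groups, from LOO.
    n_correct_ : correctly allocated sample count under LOO.
    p_perm_ : permutation p-value for group separation.
    loo_success_ : dict mapping each candidate m to its LOO success rate.
    """

    def __init__(self, m: int | str = "auto", n_permutations: int = 999,
                 normalization: str = "zscore", random_state: int | None = 0):
        self.m = m
        self.n_permutations = n_permutations
        self.normalization = normalization
        self.random_state = random_state

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        """Fit the ordination and run LOO allocation and the permutation test.

        X : samples × parameters matrix (DataFrame keeps sample ids).
        y : group label per sample.
        """
        is_df = isinstance(X, pd.DataFrame)
        index = X.index if is_df else pd.RangeIndex(len(np.asarray(X)))
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim != 2:
            raise ValidationError("X must be a 2-d samples × parameters matrix")
        y = np.asarray(y)
        if len(y) != Xv.shape[0]:
            raise ValidationError("X and y must have the same number of samples")
        if np.isnan(Xv).any():
            complete = ~np.isnan(Xv).any(axis=1)
            warnings.warn(f"dropping {int((~complete).sum())} sample(s) with missing values")
            Xv, y, index = Xv[complete], y[complete], index[complete]
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValidationError("need at least 2 groups")
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            small = self.classes_[np.argmin(counts)]
            raise ValidationError(f"group {small!r} has fewer than 2 samples")
        n = Xv.shape[0]

        if self.normalization == "zscore":
            mu = Xv.mean(axis=0)
            sd = Xv.std(axis=0, ddof=0)
            keep = sd > 0
            if not keep.all():
                warnings.warn("dropping zero-variance column(s) before ordination")
            if not keep.any():
                raise ValidationError("all columns have zero variance")
            self._mu, self._sd, self._keep = mu[keep], sd[keep], keep
            Xn = (Xv[:, keep] - self._mu) / self._sd
        elif self.normalization == "none":
            self._mu = self._sd = None
            self._keep = np.ones(Xv.shape[1], dtype=bool)
            Xn = Xv
        else:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        self._Xn = Xn
        self._index = index

        D = squareform(pdist(Xn, metric="euclidean"))
        D2 = D ** 2
        G = _gower_center(D2)
        vals, vecs, positive = _pcoa_eig(G)
        self.eigenvalues_ = vals
        rank = int(positive.sum())
        if rank == 0:
            raise ValidationError("distance matrix has no positive PCoA eigenvalues")
        m_max = min(rank, n - 2)
        auto = self.m == "auto"
        if not auto:
            m_fixed = int(self.m)
            if not (1 <= m_fixed <= n - 2):
                raise ValidationError(f"m={m_fixed} must lie in 1..n-2={n - 2}")
            if m_fixed > rank:
                raise ValidationError(f"m={m_fixed} exceeds the PCoA rank {rank}")
            m_max = m_fixed

        engine = _LooEngine(D2, m_max)
        g = len(self.classes_)
        preds_all = engine.loo_predictions(y_idx, g)
        success_all = (preds_all == y_idx[:, None]).mean(axis=0)
        if auto:
            # highest LOO success; ties broken toward the smallest m
            m_used = int(np.argmax(success_all)) + 1
            self.loo_success_ = {m + 1: float(s) for m, s in enumerate(success_all)}
        else:
            m_used = m_fixed
            self.loo_success_ = {m_fixed: float(success_all[m_fixed - 1])}
        self.m_used_ = m_used

        V, lam = vecs[:, positive], vals[positive]
        Q = V[:, :m_used]
        corr, U, n_axes = _canonical_eig(Q, y_idx, len(self.classes_))
        self.squared_correlations_ = corr[:n_axes]
        self.trace_ = float(corr.sum())
        self._Q, self._lam_m = Q, lam[:m_used]
        self._G = G
        self._U = U[:, :n_axes]
        scores = Q @ self._U
        self.canonical_scores_ = pd.DataFrame(
            scores, index=index,
            columns=[f"CAP{i + 1}" for i in range(n_axes)],
        )
        self._centroids = np.stack([
            scores[y_idx == k].mean(axis=0) for k in range(len(self.classes_))
        ])

        loo_pred = preds_all[:, m_used - 1]
        self.loo_predictions_ = pd.Series(
            self.classes_[loo_pred], index=index, name="predicted"
        )
        self.n_correct_ = int(np.sum(loo_pred == y_idx))
        labels = [str(c) for c in self.classes_]
        conf = np.zeros((len(labels), len(labels)), dtype=int)
        np.add.at(conf, (y_idx, loo_pred), 1)
        self.allocation_ = pd.DataFrame(conf, index=pd.Index(labels, name="true"),
                                        columns=pd.Index(labels, name="predicted"))

        # Permutation test: the whole procedure (LOO scan, axis selection,
        # trace) is re-run under every relabeling so that the reference
        # distribution reflects the label-dependent choice of m.
        rng = np.random.default_rng(self.random_state)
        counts_f = counts.astype(float)
        Q_all = V[:, :m_max]
        exceed = 0
        for _ in range(int(self.n_permutations)):
            perm = rng.permutation(y_idx)
            if auto:
                m_p = int(np.argmax(engine.loo_success(perm, g))) + 1
            else:
                m_p = m_used
            tr = _cumulative_traces(Q_all, perm, counts_f)[m_p - 1]
            if tr >= self.trace_ - 1e-12:
                exceed += 1
        self.p_perm_ = (exceed + 1) / (int(self.n_permutations) + 1)
        self._y_idx = y_idx
        return self

    def transform(self, X) -> np.ndarray:
        """Canonical coordinates of new samples (Gower projection)."""
        check_is_fitted(self, "m_used_")
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[None, :]
        Xn = Xv[:, self._keep]
        if self._mu is not None:
            Xn = (Xn - self._mu) / self._sd
        out = np.empty((Xn.shape[0], self._U.shape[1]))
        for i, row in enumerate(Xn):
            d2 = ((self._Xn - row) ** 2).sum(axis=1)
            c = _project_holdout(self._G, d2)
            v = (self._Q.T @ c) / self._lam_m
            out[i] = self._U.T @ v
        return out

    def predict(self, X):
        """Assign new samples to the nearest group centroid in canonical space."""
        z = self.transform(X)
        d = ((z[:, None, :] - self._centroids[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d, axis=1)]

    def result(self) -> CapResult:
        """Bundle the fitted attributes into a CapResult."""
        check_is_fitted(self, "m_used_")
        return CapResult(
            eigenvalues=self.eigenvalues_,
            m_used=self.m_used_,
            squared_correlations=self.squared_correlations_,
            canonical_scores=self.canonical_scores_,
            allocation=self.allocation_,
            n_correct=self.n_correct_,
            trace_statistic=self.trace_,
            p_perm=self.p_perm_,
            loo_success=self.loo_success_,
        )


def cap_fit(X, groups, cfg: CapConfig | None = None) -> CapResult:
    """Run CAP on a samples × parameters matrix with group labels."""
    cfg = cfg or CapConfig()
    est = CapOrdination(m=cfg.m, n_permutations=cfg.n_permutations,
                        normalization=cfg.normalization, random_state=cfg.seed)
    est.fit(X, groups)
    return est.result()


def plot_cap(result: CapResult, metadata: pd.DataFrame, path) -> None:
    """Scatter the samples on the first two canonical axes, colored by group.

    Falls back to a one-dimensional strip plot when only a single canonical
    axis exists.  ``metadata`` must be indexed by sample_id and contain
    population, season and period columns for every plotted sample.
    """
    from matplotlib.figure import Figure

    scores = result.canonical_scores
    missing = scores.index.difference(metadata.index)
    if len(missing):
        raise ValidationError(f"metadata missing for sample(s): {list(missing)[:5]}")
    meta = metadata.loc[scores.index]
    groups = meta["population"].astype(str) + "/" + meta["season"].astype(str) \
        + "/" + meta["period"].astype(str)
    fig = Figure(figsize=(6.5, 5.5))
    ax = fig.add_subplot(111)
    one_d = scores.shape[1] < 2
    rng = np.random.default_rng(0)
    for i, g in enumerate(sorted(groups.unique())):
        sel = groups == g
        x = scores.loc[sel].iloc[:, 0]
        y = (rng.normal(0.0, 0.03, sel.sum()) + i * 0.0
             if one_d else scores.loc[sel].iloc[:, 1])
        ax.scatter(x, y, s=22, label=g)
    ax.set_xlabel("CAP1")
    ax.set_ylabel("jitter" if one_d else "CAP2")
    ax.legend(fontsize=7, loc="best")
    ax.set_title(f"CAP: {result.n_correct}/{len(scores)} correct (LOO), "
                 f"p = {result.p_perm:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
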