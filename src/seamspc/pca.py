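"""Autoscaled principal component analysis by NIPALS, tolerant of missing cells.

The calibration model at the heart of the monitoring workflow: each variable
is mean-centred and scaled to unit variance (so a current meter and a
fluorometer get the same leverage), components are extracted one at a time by
NIPALS alternating regressions restricted to observed cells, and new
observations are projected onto the fixed loadings by least squares over
whatever cells they have.

The estimator follows scikit-learn conventions (``fit`` / ``transform``,
``get_params``, trailing-underscore fitted attributes) and accepts a
DataFrame, an :class:`~seamspc.alignment.AlignedTable` or a plain ndarray with
NaN marking missing values.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .alignment import AlignedTable

__all__ = [
    "NipalsPCA",
    "correlation_loadings",
    "cross_validate",
    "fit_pca",
]

_SCHEMA_VERSION = 1


def as_frame(X) -> pd.DataFrame:
    """Coerce AlignedTable / DataFrame / ndarray to a float DataFrame."""
    if isinstance(X, AlignedTable):
        return X.frame
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    arr = np.atleast_2d(np.asarray(X, dtype=float))
    return pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])


class NipalsPCA(TransformerMixin, BaseEstimator):
    """PCA by NIPALS with autoscaling and native missing-value support.

    Parameters
    ----------
    n_components : int, default 2
        Number of components A to extract.
    scale : bool, default True
        Divide each centred variable by its calibration standard deviation
        (autoscaling).  Centring always happens.
    tol : float, default 1e-10
        Convergence threshold on the relative change of the score vector.
    max_iter : int, default 5000
        Iteration cap per component (near-degenerate eigenpairs converge
        slowly at tight tolerances).

    Attributes
    ----------
    feature_names_in_ : list of str
        Variable labels in model order.
    mean_, scale_ : ndarray (p,)
        Per-variable centring/scaling, computed over available cells only.
    components_ : ndarray (A, p)
        Orthonormal loadings, one row per component.  Sign convention: the
        entry of largest magnitude in each loading is positive.
    scores_ : ndarray (n, A)
        Calibration scores.
    score_variances_ : ndarray (A,)
        lambda_a = t_a' t_a / (n - 1), decreasing.
    explained_variance_ratio_ : ndarray (A,)
        Fraction of preprocessed (observed-cell) sum of squares removed by
        each component.
    explained_variance_per_variable_ : ndarray (p, A)
        Cumulative fraction of each variable's sum of squares explained
        after 1..A components.
    residual_variance_per_variable_ : ndarray (p,)
        Mean squared residual per variable after A components.
    residual_eigenvalues_ : ndarray
        Eigenvalues of the calibration residual covariance (for Q limits).
    n_samples_ : int
        Number of calibration observations.
    """

    def __init__(self, n_components: int = 2, scale: bool = True,
                 tol: float = 1e-10, max_iter: int = 5000):
        self.n_components = n_components
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter

    # ------------------------------------------------------------------ fit
    def fit(self, X, y=None) -> "NipalsPCA":
        frame = as_frame(X)
        labels = [str(c) for c in frame.columns]
        Xraw = frame.to_numpy(dtype=float)
        n, p = Xraw.shape
        A = int(self.n_components)
        if A < 1:
            raise ValueError("n_components must be >= 1")
        if A > min(n - 1, p):
            raise ValueError(
                f"n_components={A} exceeds min(n-1, p) = {min(n - 1, p)}"
            )
        obs = np.isfinite(Xraw)
        n_avail = obs.sum(axis=0)
        if (n_avail == 0).any():
            bad = [labels[j] for j in np.flatnonzero(n_avail == 0)]
            raise ValueError(f"variables with no observed values: {bad}")

        mean = np.array([Xraw[obs[:, j], j].mean() for j in range(p)])
        with np.errstate(invalid="ignore"):
            sd = np.array(
                [Xraw[obs[:, j], j].std(ddof=1) if n_avail[j] > 1 else 0.0
                 for j in range(p)]
            )
        zero_var = ~(sd > 0)
        if zero_var.any():
            bad = [labels[j] for j in np.flatnonzero(zero_var)]
            raise ValueError(f"zero-variance variables cannot be autoscaled: {bad}")
        scale = sd if self.scale else np.ones(p)

        R = np.where(obs, (Xraw - mean) / scale, 0.0)
        M = obs.astype(float)
        ss0_var = (R**2).sum(axis=0)
        tss = ss0_var.sum()

        T = np.empty((n, A))
        P = np.empty((A, p))
        ev_comp = np.empty(A)
        ev_var = np.empty((p, A))
        ss_prev = tss
        for a in range(A):
            col_ss = (R**2).sum(axis=0)
            if col_ss.max() <= tss * 1e-14:
                raise ValueError(
                    f"data rank exhausted before component {a + 1}; "
                    f"reduce n_components"
                )
            t = R[:, int(np.argmax(col_ss))].copy()
            norm_cap = 1e6 * max(np.linalg.norm(t), 1.0)
            lam_prev, delta_prev, stall = None, None, 0
            for _ in range(self.max_iter):
                pl = (R.T @ t) / np.maximum(M.T @ (t * t), np.finfo(float).tiny)
                if a > 0:
                    # re-orthogonalise against extracted loadings: keeps
                    # P orthonormal to machine precision despite round-off
                    pl -= P[:a].T @ (P[:a] @ pl)
                pl /= np.linalg.norm(pl)
                t_new = (R @ pl) / np.maximum(M @ (pl * pl), np.finfo(float).tiny)
                t_norm = np.linalg.norm(t_new)
                if t_norm > norm_cap:
                    # the observed-cell ALS objective is unbounded for some
                    # missingness patterns (scores of sparsely observed rows
                    # blow up); refuse rather than return garbage
                    raise RuntimeError(
                        f"NIPALS diverged for component {a + 1}: the missing-"
                        f"value pattern leaves a score unidentified"
                    )
                delta = np.linalg.norm(t_new - t) / max(t_norm, np.finfo(float).tiny)
                t = t_new
                if delta < self.tol:
                    break
                # Near-tied eigenvalues make the direction converge at a
                # crawl while the eigenvalue (score norm) has long settled;
                # any direction inside the tied subspace is then equivalent.
                # Accept when the eigenvalue is stable, the linear rate is
                # demonstrably slow, and the direction is close.
                lam_cur = t_norm * t_norm
                slow = delta_prev is not None and delta > 0.99 * delta_prev
                if (slow and lam_prev is not None
                        and abs(lam_cur - lam_prev) <= self.tol * lam_cur):
                    stall += 1
                    if (stall >= 10 and delta < 1e-6) or (stall >= 50 and delta < 1e-4):
                        break
                else:
                    stall = 0
                lam_prev, delta_prev = lam_cur, delta
            else:
                if delta >= 1e-4:
                    raise RuntimeError(
                        f"NIPALS did not converge for component {a + 1} "
                        f"after {self.max_iter} iterations"
                    )
                # direction still creeping inside an extremely tied subspace;
                # the retained basis is equivalent to working precision
            k = int(np.argmax(np.abs(pl)))
            if pl[k] < 0:
                pl, t = -pl, -t
            R -= np.outer(t, pl)
            R[~obs] = 0.0
            ss_curr = (R**2).sum()
            ev_comp[a] = (ss_prev - ss_curr) / tss
            ss_prev = ss_curr
            ev_var[:, a] = 1.0 - (R**2).sum(axis=0) / np.maximum(ss0_var, np.finfo(float).tiny)
            T[:, a] = t
            P[a] = pl

        lam = (T**2).sum(axis=0) / (n - 1)
        order = np.argsort(lam)[::-1]
        if not np.array_equal(order, np.arange(A)):
            # NIPALS can extract near-equal components out of order; re-sort
            # and rebuild the cumulative per-variable bookkeeping
            T, P, lam, ev_comp = T[:, order], P[order], lam[order], ev_comp[order]
            Z0 = np.where(obs, (Xraw - mean) / scale, 0.0)
            for a in range(A):
                Ra = Z0 - T[:, : a + 1] @ P[: a + 1]
                Ra[~obs] = 0.0
                ev_var[:, a] = 1.0 - (Ra**2).sum(axis=0) / np.maximum(
                    ss0_var, np.finfo(float).tiny)

        self.feature_names_in_ = labels
        self.n_features_in_ = p
        self.n_samples_ = n
        self.n_components_ = A
        self.mean_ = mean
        self.scale_ = scale
        self.components_ = P
        self.scores_ = T
        self.score_variances_ = lam
        self.explained_variance_ratio_ = ev_comp
        self.explained_variance_per_variable_ = ev_var
        res_counts = np.maximum(obs.sum(axis=0), 1)
        self.residual_variance_per_variable_ = (R**2).sum(axis=0) / res_counts
        sv = np.linalg.svd(R, compute_uv=False)
        eig = sv**2 / (n - 1)
        self.residual_eigenvalues_ = eig[eig > max(eig[0], 1.0) * 1e-12] if eig.size else eig
        self.calibration_residuals_ = np.where(obs, R, np.nan)
        return self

    @property
    def monitored_variables_(self) -> list[str]:
        """Labels of the variables the model space is built over."""
        return self.feature_names_in_

    # ------------------------------------------------------------- project
    def _preprocess(self, X) -> tuple[np.ndarray, pd.Index]:
        frame = as_frame(X)
        if list(map(str, frame.columns)) != self.feature_names_in_:
            missing = set(self.feature_names_in_) - set(map(str, frame.columns))
            extra = set(map(str, frame.columns)) - set(self.feature_names_in_)
            if missing or extra:
                raise ValueError(
                    f"variable mismatch with model: missing {sorted(missing)}, "
                    f"unknown {sorted(extra)}"
                )
            frame = frame[self.feature_names_in_]  # order-insensitive by label
        Z = (frame.to_numpy(dtype=float) - self.mean_) / self.scale_
        return Z, frame.index

    def project(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Scores and residuals of new observations.

        Scores are the least-squares solution over observed cells only; for a
        complete row this reduces to ``t = P x``.  Residuals are NaN at
        missing cells.  Rows with fewer than A observed values get NaN scores
        (flagged, not scored).

        Returns
        -------
        scores : ndarray (m, A)
        residuals : ndarray (m, p)
        """
        Z, _ = self._preprocess(X)
        m, p = Z.shape
        A = self.n_components_
        P = self.components_
        obs = np.isfinite(Z)
        scores = np.full((m, A), np.nan)
        complete = obs.all(axis=1)
        if complete.any():
            scores[complete] = Z[complete] @ P.T
        for i in np.flatnonzero(~complete):
            o = obs[i]
            if o.sum() < A:
                continue
            Po = P[:, o]
            t, *_ = np.linalg.lstsq(Po.T, Z[i, o], rcond=None)
            scores[i] = t
        residuals = Z - scores @ P
        residuals[~obs] = np.nan
        return scores, residuals

    def transform(self, X) -> np.ndarray:
        """Scores only (sklearn transformer contract)."""
        return self.project(X)[0]

    def inverse_transform(self, T) -> np.ndarray:
        Z = np.asarray(T, dtype=float) @ self.components_
        return Z * self.scale_ + self.mean_

    # -------------------------------------------------------- serialization
    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": _SCHEMA_VERSION,
            "kind": "NipalsPCA",
            "params": self.get_params(),
            "feature_names": self.feature_names_in_,
            "n_samples": self.n_samples_,
            "n_components": self.n_components_,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "components": self.components_.tolist(),
            "score_variances": self.score_variances_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "explained_variance_per_variable": self.explained_variance_per_variable_.tolist(),
            "residual_variance_per_variable": self.residual_variance_per_variable_.tolist(),
            "residual_eigenvalues": self.residual_eigenvalues_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "NipalsPCA":
        if d.get("kind") != "NipalsPCA" or d.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError("not a NipalsPCA model file (or wrong schema version)")
        model = cls(**d["params"])
        model.feature_names_in_ = list(d["feature_names"])
        model.n_features_in_ = len(model.feature_names_in_)
        model.n_samples_ = int(d["n_samples"])
        model.n_components_ = int(d["n_components"])
        model.mean_ = np.asarray(d["mean"], dtype=float)
        model.scale_ = np.asarray(d["scale"], dtype=float)
        model.components_ = np.asarray(d["components"], dtype=float)
        model.score_variances_ = np.asarray(d["score_variances"], dtype=float)
        model.explained_variance_ratio_ = np.asarray(d["explained_variance_ratio"], dtype=float)
        model.explained_variance_per_variable_ = np.asarray(
            d["explained_variance_per_variable"], dtype=float)
        model.residual_variance_per_variable_ = np.asarray(
            d["residual_variance_per_variable"], dtype=float)
        model.residual_eigenvalues_ = np.asarray(d["residual_eigenvalues"], dtype=float)
        return model

    def save(self, path: str | Path) -> None:
        """Serialize to a versioned JSON text file (bit-exact round trip)."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "NipalsPCA":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_pca(data, n_components: int, scale: bool = True,
            tol: float = 1e-10, max_iter: int = 5000) -> NipalsPCA:
    """Functional wrapper: fit a :class:`NipalsPCA` on an aligned table."""
    return NipalsPCA(n_components=n_components, scale=scale,
                     tol=tol, max_iter=max_iter).fit(data)


def correlation_loadings(model: NipalsPCA, data) -> pd.DataFrame:
    """Pearson correlation of each variable with each score vector.

    Computed on the calibration data used to fit the model, over jointly
    observed cells.  Squared row sums give the fraction of each variable
    explained by the model — the quantity the inner (50%) and outer (100%)
    circles of a correlation-loading plot display.
    """
    frame = as_frame(data)[model.feature_names_in_]
    X = frame.to_numpy(dtype=float)
    T = model.scores_
    if X.shape[0] != T.shape[0]:
        raise ValueError("data must be the calibration table used to fit the model")
    out = np.empty((X.shape[1], model.n_components_))
    for j in range(X.shape[1]):
        o = np.isfinite(X[:, j])
        x = X[o, j]
        if x.std() <= 1e-12 * max(np.abs(x).max(), 1.0):
            raise ValueError(
                f"variable {model.feature_names_in_[j]!r} is constant; "
                f"correlation undefined"
            )
        for a in range(model.n_components_):
            t = T[o, a]
            out[j, a] = np.corrcoef(x, t)[0, 1]
    return pd.DataFrame(out, index=model.feature_names_in_,
                        columns=[f"PC{a + 1}" for a in range(model.n_components_)])


def _loo_scores(P: np.ndarray, z: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """For one row: scores recomputed leaving each variable out in turn.

    Returns (p, A): row j is the score vector estimated from the observed
    cells excluding variable j, so that variable j can be predicted without
    using itself.  Rank-one downdate of the normal equations.
    """
    A, p = P.shape
    Po = P[:, obs]
    M = Po @ Po.T
    b = Po @ z[obs]
    out = np.full((p, A), np.nan)
    for j in np.flatnonzero(obs):
        pj = P[:, j]
        Mj = M - np.outer(pj, pj)
        bj = b - pj * z[j]
        try:
            out[j] = np.linalg.solve(Mj, bj)
        except np.linalg.LinAlgError:
            continue
    return out


def cross_validate(data, max_components: int, n_segments: int = 10,
                   increment_threshold: float = 0.01, scale: bool = True,
                   tol: float = 1e-10, max_iter: int = 5000) -> dict:
    """Segmented cross-validation of the component count.

    The rows are split into ``n_segments`` CONTIGUOUS time blocks (the
    observations are serially correlated, so random segments would leak
    information between train and test).  Each segment is held out in turn,
    the model refit on the rest, and every held-out cell predicted from the
    other variables of its own row through the refit loadings.  Validated
    variance after a components is ``1 - PRESS_a / TSS``.

    Returns
    -------
    dict with keys ``explained_variance`` (cumulative, full fit),
    ``validated_variance`` (cumulative), and ``suggested_components`` — the
    last component whose validated-variance increment exceeds
    ``increment_threshold`` (default one percentage point), 0 if none.
    """
    frame = as_frame(data)
    n, p = frame.shape
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if n_segments > n:
        raise ValueError("more segments than observations")
    A = int(max_components)

    def fit_up_to(data_, A_):
        # rank-deficient data (e.g. noiseless low-rank) supports fewer
        # components than requested; fit as many as exist
        for a in range(A_, 0, -1):
            try:
                return NipalsPCA(n_components=a, scale=scale, tol=tol,
                                 max_iter=max_iter).fit(data_)
            except ValueError as exc:
                if "rank exhausted" not in str(exc):
                    raise
        raise ValueError("degenerate refit: no component extractable")

    bounds = np.linspace(0, n, n_segments + 1).astype(int)
    press = np.zeros(A)
    tss = 0.0
    for s in range(n_segments):
        lo, hi = bounds[s], bounds[s + 1]
        test = frame.iloc[lo:hi]
        train = pd.concat([frame.iloc[:lo], frame.iloc[hi:]])
        model = fit_up_to(train, A)
        Z, _ = model._preprocess(test)
        obs_mat = np.isfinite(Z)
        for i in range(Z.shape[0]):
            o = obs_mat[i]
            if o.sum() <= 1:
                continue
            tss += float((Z[i, o] ** 2).sum())
            loo = _loo_scores(model.components_, Z[i], o)
            for a in range(A):
                a_eff = min(a + 1, model.n_components_)
                pred = np.einsum("jk,kj->j", loo[:, :a_eff],
                                 model.components_[:a_eff])
                err = Z[i, o] - pred[o]
                press[a] += float(np.nansum(err**2))
    validated = 1.0 - press / tss
    full = fit_up_to(frame, A)
    explained = np.cumsum(full.explained_variance_ratio_)
    if full.n_components_ < A:  # pad: nothing left to explain
        explained = np.concatenate(
            [explained, np.full(A - full.n_components_, explained[-1])])
    increments = np.diff(np.concatenate([[0.0], validated]))
    above = np.flatnonzero(increments > increment_threshold)
    suggested = int(above[-1] + 1) if above.size else 0
    return {
        "explained_variance": explained,
        "validated_variance": validated,
        "suggested_components": suggested,
    }
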