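"""Hotelling's T², Q-residuals, control limits and contribution diagnostics.

Two complementary statistics watch a calibrated PCA model:

* **Hotelling's T²** — the Mahalanobis distance of an observation's scores
  from the model centre, ``T²_i = Σ_a t_ia² / λ_a``.  Large values mean the
  observation is extreme *within* the model plane (e.g. a seasonal trend that
  keeps running).
* **Q-residual** (squared prediction error) — ``Q_i = Σ_j r_ij²``, the
  squared distance *off* the model plane.  Large values mean the correlation
  structure learned in calibration is broken (e.g. one redundant sensor
  deviating from its partners).

Critical limits follow the standard chemometric practice: an F-distribution
limit for T² and the Jackson–Mudholkar normal approximation (with a scaled-χ²
fallback) for Q.  Both statistics decompose into per-variable contributions
so an alarm can be traced to the sensors that caused it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "ControlLimits",
    "MonitoringResult",
    "hotelling_t2",
    "t2_limit",
    "q_residuals",
    "q_limit",
    "t2_contributions",
    "q_contributions",
    "classify",
    "PCAMonitor",
]


@dataclass(frozen=True)
class ControlLimits:
    """Critical values for the two monitoring statistics at level ``alpha``."""

    alpha: float
    t2_critical: float
    q_critical: float
    n_calibration: int
    n_components: int


def hotelling_t2(scores: np.ndarray, score_variances: np.ndarray) -> np.ndarray:
    """``T²_i = Σ_a t_ia² / λ_a`` per observation (NaN scores give NaN)."""
    lam = np.asarray(score_variances, dtype=float)
    if (lam <= 0).any():
        raise ValueError("score variances must be strictly positive")
    T = np.atleast_2d(np.asarray(scores, dtype=float))
    return (T**2 / lam).sum(axis=1)


def t2_limit(n: int, n_components: int, alpha: float = 0.05) -> float:
    """F-distribution critical limit for T² of a *new* observation.

    ``T²_crit = A (n-1)(n+1) / (n (n-A)) · F_{1-alpha}(A, n-A)`` — the
    classical limit for an observation not used in calibration.
    """
    A = int(n_components)
    n = int(n)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n <= A:
        raise ValueError(f"need n > A (got n={n}, A={A})")
    f_crit = stats.f.ppf(1 - alpha, A, n - A)
    return A * (n - 1) * (n + 1) / (n * (n - A)) * f_crit


def q_residuals(residuals: np.ndarray) -> np.ndarray:
    """``Q_i = Σ_j r_ij²`` over observed (non-NaN) cells."""
    R = np.atleast_2d(np.asarray(residuals, dtype=float))
    q = np.nansum(R**2, axis=1)
    q[np.isnan(R).all(axis=1)] = np.nan
    return q


def q_limit(residuals: np.ndarray | None = None,
            eigenvalues: np.ndarray | None = None,
            alpha: float = 0.05) -> float:
    """Critical limit for the Q-residual at level ``alpha``.

    Uses the Jackson–Mudholkar approximation from the residual-eigenvalue
    moments ``θ_k = Σ λ_i^k``; falls back to the scaled-χ² (g·χ²_h, with
    g = θ₂/θ₁ and h = θ₁²/θ₂) when the shape parameter h₀ is non-positive.

    Provide either the calibration residual matrix (NaN allowed) or the
    residual covariance eigenvalues directly.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if eigenvalues is None:
        if residuals is None:
            raise ValueError("provide residuals or eigenvalues")
        R = np.where(np.isfinite(residuals), residuals, 0.0)
        sv = np.linalg.svd(np.atleast_2d(R), compute_uv=False)
        eigenvalues = sv**2 / max(R.shape[0] - 1, 1)
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0 or lam.sum() <= 0:
        raise ValueError("all-zero residuals: Q limit undefined")
    th1, th2, th3 = lam.sum(), (lam**2).sum(), (lam**3).sum()
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    z = stats.norm.ppf(1 - alpha)
    if h0 > 0:
        term = (z * np.sqrt(2.0 * th2 * h0**2) / th1
                + 1.0 + th2 * h0 * (h0 - 1.0) / th1**2)
        if term > 0:
            return float(th1 * term ** (1.0 / h0))
    g = th2 / th1
    h = th1**2 / th2
    return float(g * stats.chi2.ppf(1 - alpha, h))


def t2_contributions(model, X) -> pd.DataFrame:
    """Per-variable decomposition of T² (score-weighted form).

    Contribution of variable j in observation i:
    ``c_ij = Σ_a (t_ia / λ_a) · p_aj · z_ij`` with z the autoscaled value.
    For complete observations the contributions sum exactly to T²_i.
    Missing cells contribute zero.
    """
    Z, index = model._preprocess(X)
    scores, _ = model.project(X)
    W = scores / model.score_variances_          # (m, A)
    back = W @ model.components_                 # (m, p)
    contrib = back * np.where(np.isfinite(Z), Z, 0.0)
    return pd.DataFrame(contrib, index=index, columns=model.monitored_variables_)


def q_contributions(model, X) -> pd.DataFrame:
    """Per-variable squared residuals; rows sum to Q (observed cells)."""
    _, residuals = model.project(X)
    _, index = model._preprocess(X)
    return pd.DataFrame(residuals**2, index=index, columns=model.monitored_variables_)


def classify(values: np.ndarray, critical: float,
             warning_fraction: float = 0.8) -> np.ndarray:
    """Map statistic values to ``inside`` / ``warning`` / ``alarm``.

    Alarm above the critical limit, warning above
    ``warning_fraction * critical``, inside otherwise; NaN maps to
    ``"unscored"``.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, "inside", dtype=object)
    out[v > warning_fraction * critical] = "warning"
    out[v > critical] = "alarm"
    out[~np.isfinite(v)] = "unscored"
    return out


@dataclass
class MonitoringResult:
    """Per-observation monitoring output plus drill-down contributions."""

    frame: pd.DataFrame                 # timestamped t2, q, statuses
    t2_contributions: pd.DataFrame
    q_contributions: pd.DataFrame
    limits: ControlLimits

    @property
    def n_alarms(self) -> int:
        return int(((self.frame["t2_status"] == "alarm")
                    | (self.frame["q_status"] == "alarm")).sum())

    def top_contributors(self, row, statistic: str = "q", k: int = 3) -> list[str]:
        """Largest per-variable contributors for one observation."""
        table = self.q_contributions if statistic == "q" else self.t2_contributions
        s = table.loc[row].astype(float)
        return list(s.abs().sort_values(ascending=False).index[:k])

    def to_csv(self, path, contributions: bool = False) -> None:
        path = Path(path)
        self.frame.to_csv(path, float_format="%.12g", lineterminator="\n")
        if contributions:
            self.t2_contributions.to_csv(
                path.with_name(path.stem + "_t2_contributions.csv"),
                float_format="%.12g", lineterminator="\n")
            self.q_contributions.to_csv(
                path.with_name(path.stem + "_q_contributions.csv"),
                float_format="%.12g", lineterminator="\n")


class PCAMonitor(BaseEstimator):
    """Calibrate-then-monitor wrapper around a PCA-type model.

    ``fit`` calibrates the underlying model (a :class:`~seamspc.pca.NipalsPCA`
    by default, or a :class:`~seamspc.multiblock.MultiblockPCA`) on an
    in-control reference period and derives the T² and Q control limits;
    ``monitor`` projects new observations one at a time (results are
    identical batched or streamed, the pipeline being deterministic) and
    classifies them.

    Parameters
    ----------
    model : estimator, optional
        Unfitted PCA-type model exposing ``fit``/``project``; default
        ``NipalsPCA(n_components=4)``.
    alpha : float, default 0.05
        Significance level of both control limits.
    warning_fraction : float, default 0.8
        Warning threshold as a fraction of the critical limit.
    """

    def __init__(self, model=None, alpha: float = 0.05,
                 warning_fraction: float = 0.8):
        self.model = model
        self.alpha = alpha
        self.warning_fraction = warning_fraction

    def fit(self, X, y=None) -> "PCAMonitor":
        from .pca import NipalsPCA  # local import avoids cycle at module load
        from sklearn.base import clone

        base = self.model if self.model is not None else NipalsPCA(n_components=4)
        self.model_ = clone(base).fit(X)
        m = self.model_
        self.limits_ = ControlLimits(
            alpha=self.alpha,
            t2_critical=t2_limit(m.n_samples_, m.n_components_, self.alpha),
            q_critical=q_limit(eigenvalues=m.residual_eigenvalues_, alpha=self.alpha),
            n_calibration=m.n_samples_,
            n_components=m.n_components_,
        )
        self.calibration_t2_ = hotelling_t2(m.scores_, m.score_variances_)
        return self

    def monitor(self, X) -> MonitoringResult:
        m = self.model_
        scores, residuals = m.project(X)
        _, index = m._preprocess(X)
        t2 = hotelling_t2(scores, m.score_variances_)
        q = q_residuals(residuals)
        incomplete = np.isnan(np.atleast_2d(
            np.asarray(residuals, dtype=float))).any(axis=1)
        frame = pd.DataFrame(
            {
                "t2": t2,
                "q": q,
                "t2_status": classify(t2, self.limits_.t2_critical, self.warning_fraction),
                "q_status": classify(q, self.limits_.q_critical, self.warning_fraction),
                "has_missing": incomplete,  # Q over observed cells only; limit unadjusted
            },
            index=index,
        )
        frame.index.name = "timestamp"
        return MonitoringResult(
            frame=frame,
            t2_contributions=t2_contributions(m, X),
            q_contributions=q_contributions(m, X),
            limits=self.limits_,
        )

    def predict(self, X) -> np.ndarray:
        """Scikit-learn outlier convention: +1 inside both limits, -1 alarm."""
        res = self.monitor(X).frame
        alarm = (res["t2_status"] == "alarm") | (res["q_status"] == "alarm")
        return np.where(alarm, -1, 1)

    def score_samples(self, X) -> np.ndarray:
        """Negative combined exceedance ratio (higher = more normal)."""
        res = self.monitor(X).frame
        ratio = np.maximum(res["t2"] / self.limits_.t2_critical,
                           res["q"] / self.limits_.q_critical)
        return -ratio.to_numpy()

    # ------------------------------------------------------ serialization
    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "schema_version": 1,
            "kind": "PCAMonitor",
            "alpha": self.alpha,
            "warning_fraction": self.warning_fraction,
            "limits": asdict(self.limits_),
            "model": self.model_.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAMonitor":
        from .multiblock import MultiblockPCA
        from .pca import NipalsPCA

        if d.get("kind") != "PCAMonitor":
            raise ValueError("not a PCAMonitor file")
        kinds = {"NipalsPCA": NipalsPCA, "MultiblockPCA": MultiblockPCA}
        model = kinds[d["model"]["kind"]].from_dict(d["model"])
        monitor = cls(model=None, alpha=d["alpha"],
                      warning_fraction=d["warning_fraction"])
        monitor.model_ = model
        monitor.limits_ = ControlLimits(**d["limits"])
        return monitor

    def save(self, path) -> None:
        import json

        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path) -> "PCAMonitor":
        import json

        return cls.from_dict(json.loads(Path(path).read_text()))
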