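"""Sensor quality assurance from redundancy and raw-signal screening.

A deployment with overlapping sensors (three thermometers; two current
profilers sharing depth bins) can separate environmental change from sensor
failure: redundant pairs should stay highly correlated whatever the ocean
does, so a *dropping correlation* indicts a sensor while a constant offset
between two healthy sensors is benign.  Raw-signal screening catches the
classic failure mode of a mis-ranged sensor pegged at its ceiling
(flat-line/saturation) and variables accumulating too many missing values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AlignedTable
from .pca import as_frame

__all__ = [
    "RedundancyGroup",
    "DiagnosticReport",
    "redundancy_check",
    "saturation_check",
    "missing_alert",
]


@dataclass
class RedundancyGroup:
    """A set of >= 2 variables declared mutually redundant."""

    name: str
    members: Sequence[str]

    def __post_init__(self) -> None:
        self.members = list(self.members)
        if len(self.members) < 2:
            raise ValueError(f"redundancy group {self.name!r} needs >= 2 members")


@dataclass
class DiagnosticReport:
    """Pairwise redundancy table plus per-variable screening tables."""

    pairs: pd.DataFrame        # group, var_a, var_b, n, correlation, offset, flagged
    saturation: pd.DataFrame | None = None
    missing: pd.DataFrame | None = None

    @property
    def flagged_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["flagged"]]

    def summary(self) -> str:
        lines = ["sensor diagnostics"]
        for _, r in self.pairs.iterrows():
            mark = "FLAG" if r["flagged"] else " ok "
            lines.append(
                f"  [{mark}] {r['group']}: {r['var_a']} ~ {r['var_b']}  "
                f"r={r['correlation']:.3f} offset={r['offset']:.4g} (n={r['n']})"
            )
        if self.saturation is not None:
            for var, row in self.saturation[self.saturation["flagged"]].iterrows():
                lines.append(
                    f"  [FLAG] saturation: {var} mode fraction "
                    f"{row['mode_fraction']:.2f} at ceiling {row['mode_value']:.4g}"
                )
        if self.missing is not None and len(self.missing):
            for var, row in self.missing.iterrows():
                lines.append(
                    f"  [FLAG] missing: {var} {100 * row['missing_fraction']:.1f}%"
                )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        path = Path(path)
        self.pairs.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")
        if self.saturation is not None:
            self.saturation.to_csv(path.with_name(path.stem + "_saturation.csv"),
                                   float_format="%.12g", lineterminator="\n")
        if self.missing is not None:
            self.missing.to_csv(path.with_name(path.stem + "_missing.csv"),
                                float_format="%.12g", lineterminator="\n")


def redundancy_check(data: AlignedTable | pd.DataFrame,
                     groups: Sequence[RedundancyGroup],
                     corr_threshold: float = 0.7,
                     min_overlap: int = 30) -> DiagnosticReport:
    """Pairwise Pearson correlation and mean offset within each group.

    Correlations are computed over jointly observed cells on *raw* values.
    Only a correlation below ``corr_threshold`` raises a flag; the offset is
    reported but treated as benign (two healthy thermometers may disagree by
    a constant while tracking the same water).
    """
    frame = as_frame(data)
    rows = []
    for g in groups:
        unknown = [m for m in g.members if m not in frame.columns]
        if unknown:
            raise ValueError(f"group {g.name!r}: unknown variables {unknown}")
        for i, a in enumerate(g.members):
            for b in g.members[i + 1:]:
                x, y = frame[a].to_numpy(), frame[b].to_numpy()
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < min_overlap:
                    raise ValueError(
                        f"pair ({a}, {b}): only {int(ok.sum())} jointly "
                        f"observed points (< {min_overlap})")
                r = float(np.corrcoef(x[ok], y[ok])[0, 1])
                rows.append({
                    "group": g.name, "var_a": a, "var_b": b,
                    "n": int(ok.sum()), "correlation": r,
                    "offset": float(np.mean(x[ok] - y[ok])),
                    "flagged": bool(r < corr_threshold),
                })
    return DiagnosticReport(pairs=pd.DataFrame(rows))


def _round_sig(x: np.ndarray, digits: int) -> np.ndarray:
    """Round to ``digits`` significant figures (0 stays 0)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = x != 0
    mag = np.floor(np.log10(np.abs(x[nz])))
    factor = 10.0 ** (digits - 1 - mag)
    out[nz] = np.round(x[nz] * factor) / factor
    return out


def saturation_check(data: AlignedTable | pd.DataFrame,
                     mode_fraction_threshold: float = 0.5,
                     sig_digits: int = 3,
                     min_count: int = 30) -> pd.DataFrame:
    """Detect the clipped-ceiling signature of a mis-ranged sensor.

    A variable is flagged when, after rounding raw values to the sensor's
    resolution (``sig_digits`` significant figures), a single value accounts
    for more than ``mode_fraction_threshold`` of the observations AND that
    value is the variable's maximum — a flat-line at the top of the range.
    Variables with fewer than ``min_count`` observed values are skipped.
    """
    frame = as_frame(data)
    rows = {}
    for var in frame.columns:
        x = frame[var].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if x.size < min_count:
            rows[var] = {"n": int(x.size), "mode_value": np.nan,
                         "mode_fraction": np.nan, "at_maximum": False,
                         "flagged": False}
            continue
        rounded = _round_sig(x, sig_digits)
        values, counts = np.unique(rounded, return_counts=True)
        k = int(np.argmax(counts))
        mode_value = float(values[k])
        mode_fraction = counts[k] / x.size
        at_max = bool(mode_value == values.max())
        flagged = bool(mode_fraction > mode_fraction_threshold and at_max)
        rows[var] = {"n": int(x.size), "mode_value": mode_value,
                     "mode_fraction": float(mode_fraction),
                     "at_maximum": at_max, "flagged": flagged}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "variable"
    return out


def missing_alert(data: AlignedTable | pd.DataFrame,
                  threshold: float = 0.10) -> pd.DataFrame:
    """Variables whose missing fraction exceeds ``threshold`` (default 10%)."""
    frame = as_frame(data)
    frac = frame.isna().mean()
    out = pd.DataFrame({"missing_fraction": frac[frac > threshold]})
    out.index.name = "variable"
    return out


def diagnose(data, groups: Sequence[RedundancyGroup] = (),
             corr_threshold: float = 0.7,
             mode_fraction_threshold: float = 0.5,
             missing_threshold: float = 0.10) -> DiagnosticReport:
    """Run every screening stage and collect one report."""
    report = (redundancy_check(data, groups, corr_threshold) if groups
              else DiagnosticReport(pairs=pd.DataFrame(
                  columns=["group", "var_a", "var_b", "n",
                           "correlation", "offset", "flagged"])))
    report.saturation = saturation_check(data, mode_fraction_threshold)
    report.missing = missing_alert(data, missing_threshold)
    return report
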