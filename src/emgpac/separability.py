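"""Bhattacharyya and Jeffries-Matusita class separability.

Each feature is treated as univariate Gaussian within each class; the
Bhattacharyya distance between the two class-conditional distributions is

    D_B = 1/4 ln[ 1/4 (s_p^2/s_q^2 + s_q^2/s_p^2 + 2) ]
        + 1/4 (mu_p - mu_q)^2 / (s_p^2 + s_q^2)

and the Jeffries-Matusita distance JM = 2 (1 - exp(-D_B)) maps it onto
[0, 2), which makes feature sets of different scales comparable.  A
feature *set* is summarised by the mean per-feature JM (max and median
are also reported; the reduction is an explicit choice, not implied by
the distances themselves).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClassStats", "bhattacharyya", "jm_distance", "featureset_jm"]


@dataclass(frozen=True)
class ClassStats:
    """Per-class mean/variance/count of one feature."""

    mu_p: float
    mu_q: float
    var_p: float
    var_q: float
    n_p: int = 2
    n_q: int = 2

    def validate(self, name: str = "feature") -> None:
        if self.var_p <= 0 or self.var_q <= 0:
            raise ValueError(f"{name}: class variance must be positive")
        if self.n_p < 2 or self.n_q < 2:
            raise ValueError(f"{name}: need at least 2 rows per class")


def bhattacharyya(stats: ClassStats, name: str = "feature") -> float:
    """Bhattacharyya distance between two univariate Gaussians."""
    stats.validate(name)
    vp, vq = stats.var_p, stats.var_q
    term_var = 0.25 * np.log(0.25 * (vp / vq + vq / vp + 2.0))
    term_mean = 0.25 * (stats.mu_p - stats.mu_q) ** 2 / (vp + vq)
    return float(term_var + term_mean)


def jm_distance(d_b: float) -> float:
    """Jeffries-Matusita distance, 2(1 - e^-D_B) in [0, 2)."""
    if d_b < 0:
        raise ValueError("Bhattacharyya distance cannot be negative")
    return float(2.0 * (1.0 - np.exp(-d_b)))


def featureset_jm(table: pd.DataFrame, feature_names, label_col: str = "group",
                  classes=("case", "control")) -> dict:
    """Per-feature and aggregate JM separability of a feature table.

    Returns ``{"per_feature": DataFrame[D_B, JM], "mean": .., "max": ..,
    "median": ..}``.  Raises when a class is missing, has fewer than two
    rows, or a feature has zero variance in either class.
    """
    p = table[table[label_col] == classes[0]]
    q = table[table[label_col] == classes[1]]
    if len(p) < 2 or len(q) < 2:
        raise ValueError(
            f"need >=2 rows per class, got {len(p)} {classes[0]} / "
            f"{len(q)} {classes[1]}")
    records = []
    for name in feature_names:
        xp = p[name].to_numpy(dtype=float)
        xq = q[name].to_numpy(dtype=float)
        st = ClassStats(xp.mean(), xq.mean(), xp.var(ddof=1), xq.var(ddof=1),
                        len(xp), len(xq))
        d_b = bhattacharyya(st, name)
        records.append((name, d_b, jm_distance(d_b)))
    per_feature = pd.DataFrame(records, columns=["feature", "D_B", "JM"])
    per_feature = per_feature.set_index("feature")
    jm = per_feature["JM"]
    return {"per_feature": per_feature, "mean": float(jm.mean()),
            "max": float(jm.max()), "median": float(jm.median())}
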