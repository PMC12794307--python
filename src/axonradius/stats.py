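"""Repeatability and agreement statistics for tract-profile metrics.

Test-retest variability (TRV), between-subject coefficient of variation
(CoV), Lin's concordance correlation coefficient with its accuracy
component, paired t-tests per segment, and segment-level aggregation of
voxel metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "TractProfile",
    "segment_aggregate",
    "trv",
    "cov_percent",
    "lins_ccc",
    "paired_comparison",
    "bh_adjust",
    "profile_report",
]


@dataclass
class TractProfile:
    """Subjects x sessions x segments array of a scalar metric."""

    values: np.ndarray
    segment_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (subjects, sessions, segments)")
        if self.segment_ids is None:
            self.segment_ids = np.arange(self.values.shape[2])
        self.segment_ids = np.asarray(self.segment_ids)
        if self.segment_ids.shape[0] != self.values.shape[2]:
            raise ValueError("segment_ids must match the segment axis")


def segment_aggregate(voxel_values: np.ndarray, labels: np.ndarray,
                      segment_ids=None):
    """Mean of voxel values per integer segment label, ignoring NaNs.

    Returns (means, counts) aligned with ``segment_ids`` (default: sorted
    unique positive labels).  Empty segments yield NaN with a warning.
    """
    voxel_values = np.asarray(voxel_values, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if labels.shape != voxel_values.shape:
        raise ValueError("labels must align with voxel_values")
    if segment_ids is None:
        segment_ids = np.unique(labels[labels > 0])
    segment_ids = np.asarray(segment_ids)
    means = np.full(segment_ids.shape, np.nan)
    counts = np.zeros(segment_ids.shape, dtype=int)
    for k, sid in enumerate(segment_ids):
        vals = voxel_values[(labels == sid) & np.isfinite(voxel_values)]
        counts[k] = vals.size
        if vals.size:
            means[k] = vals.mean()
    if np.any(counts == 0):
        warnings.warn("empty segment(s) produced NaN means", RuntimeWarning)
    return means, counts


def trv(a, b) -> float:
    """Test-retest variability in percent.

    ``TRV = (1/N) * sum_i sqrt(pi/2) * (2 |a_i - b_i| / (a_i + b_i)) * 100``
    over paired measurements; invariant under common positive rescaling.
    Pairs with ``a + b = 0`` are excluded with a warning.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 1:
        raise ValueError("a and b must be paired with N >= 1")
    denom = a + b
    valid = denom != 0
    if not np.all(valid):
        warnings.warn("pairs with a + b = 0 excluded from TRV", RuntimeWarning)
    if not np.any(valid):
        raise ValueError("no valid pairs for TRV")
    rel = 2.0 * np.abs(a[valid] - b[valid]) / denom[valid]
    return float(np.mean(np.sqrt(np.pi / 2.0) * rel) * 100.0)


def cov_percent(values) -> float:
    """Between-subject coefficient of variation, percent.

    ``100 * sd / mean`` with the sample (N-1) standard deviation.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("CoV requires N >= 2")
    mean = values.mean()
    if mean <= 0:
        warnings.warn("CoV with non-positive mean is ill-defined", RuntimeWarning)
    return float(100.0 * values.std(ddof=1) / mean)


def lins_ccc(x, y) -> tuple[float, float]:
    """Lin's concordance correlation coefficient and accuracy coefficient.

    ``rho_c = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)`` with
    population (N) moments; ``C_b = rho_c / rho`` (Pearson) isolates the
    location/scale (accuracy) component.  Always ``|rho_c| <= |rho|``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 3:
        raise ValueError("paired inputs with N >= 3 required")
    sx2 = x.var()
    sy2 = y.var()
    if sx2 == 0 or sy2 == 0:
        raise ValueError("Lin's CCC undefined for zero-variance input")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    rho_c = 2.0 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)
    rho = sxy / np.sqrt(sx2 * sy2)
    cb = rho_c / rho
    return float(rho_c), float(cb)


def paired_comparison(x, y, alpha: float = 0.05):
    """Paired two-sided t-test; returns (t, p, significant).

    Zero-variance differences are degenerate: returns (0 or inf-like t
    suppressed, NaN, False) with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired inputs with N >= 2 required")
    d = x - y
    if np.allclose(d, d[0]):
        if d[0] == 0:
            return 0.0, 1.0, False
        warnings.warn("constant nonzero difference: t-test degenerate",
                      RuntimeWarning)
        return np.nan, np.nan, False
    t, p = sp_stats.ttest_rel(x, y)
    return float(t), float(p), bool(p < alpha)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    return multipletests(pvals, method="fdr_bh")[1]


def profile_report(df: pd.DataFrame, metric: str = "metric",
                   alpha: float = 0.05, bh: bool = False) -> dict:
    """TRV / CoV / CCC / paired-test report from a long-format profile table.

    ``df`` columns: subject, session (two levels), segment, ``metric``.
    TRV and CoV are computed per segment across subjects and averaged;
    Lin's CCC between sessions is computed per subject across segments.
    """
    required = {"subject", "session", "segment", metric}
    if not required.issubset(df.columns):
        raise ValueError(f"profile table needs columns {sorted(required)}")
    sessions = sorted(df["session"].unique())
    if len(sessions) != 2:
        raise ValueError("profile report requires exactly two sessions")
    wide = df.pivot_table(index=["subject", "segment"], columns="session",
                          values=metric)
    if wide.isna().any().any():
        raise ValueError("mismatched segments across sessions/subjects")
    a = wide[sessions[0]]
    b = wide[sessions[1]]

    seg_trv, seg_cov, seg_t, seg_p = {}, {}, {}, {}
    for seg, sub in wide.groupby(level="segment"):
        seg_trv[seg] = trv(sub[sessions[0]].values, sub[sessions[1]].values)
        mean_per_subject = sub.mean(axis=1).values
        seg_cov[seg] = (cov_percent(mean_per_subject)
                        if mean_per_subject.size >= 2 else np.nan)
        if sub.shape[0] >= 2:
            t, p, _ = paired_comparison(sub[sessions[0]].values,
                                        sub[sessions[1]].values, alpha)
        else:
            t, p = np.nan, np.nan
        seg_t[seg], seg_p[seg] = t, p

    ccc_by_subject = {}
    for subj, sub in wide.groupby(level="subject"):
        if sub.shape[0] >= 3:
            rho_c, cb = lins_ccc(sub[sessions[0]].values, sub[sessions[1]].values)
            ccc_by_subject[subj] = {"rho_c": rho_c, "accuracy": cb}

    pvals = np.array([seg_p[s] for s in sorted(seg_p)])
    report = {
        "metric": metric,
        "sessions": [str(s) for s in sessions],
        "trv_per_segment": {str(k): v for k, v in seg_trv.items()},
        "trv_mean": float(np.nanmean(list(seg_trv.values()))),
        "cov_per_segment": {str(k): v for k, v in seg_cov.items()},
        "cov_mean": float(np.nanmean(list(seg_cov.values()))),
        "paired_t_per_segment": {str(k): {"t": seg_t[k], "p": seg_p[k]}
                                 for k in seg_t},
        "ccc_per_subject": {str(k): v for k, v in ccc_by_subject.items()},
        "ccc_mean": float(np.nanmean([v["rho_c"] for v in ccc_by_subject.values()]))
        if ccc_by_subject else np.nan,
        "accuracy_mean": float(np.nanmean([v["accuracy"]
                                           for v in ccc_by_subject.values()]))
        if ccc_by_subject else np.nan,
    }
    if bh:
        finite = np.isfinite(pvals)
        adj = np.full(pvals.shape, np.nan)
        if finite.any():
            adj[finite] = bh_adjust(pvals[finite])
        report["paired_p_bh"] = {str(s): float(v)
                                 for s, v in zip(sorted(seg_p), adj)}
    return report
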