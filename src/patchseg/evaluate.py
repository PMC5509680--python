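"""Segmentation evaluation: Dice overlap, voxelwise ROC AUC, and ICC-based
stability of repeated sampling/training runs.

The ICC is the two-way random-effects, absolute-agreement, single-rating
form (ICC(A,1) in the McGraw & Wong taxonomy) with the F-based 95% CI;
this choice is recorded in every report.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .infer import ProbabilityMap, SegMask
from .volume import LabelMap

ICC_FORM = "two-way random effects, absolute agreement, single rating (ICC(A,1))"


def _as_mask(x) -> np.ndarray:
    if isinstance(x, SegMask):
        return x.mask.astype(bool)
    if isinstance(x, LabelMap):
        return x.mask.astype(bool)
    return np.asarray(x).astype(bool)


def dsc(a, b) -> float:
    """Dice similarity coefficient 2|a & b| / (|a| + |b|).

    Defined as 1.0 when both masks are empty (and hence 0.0 when exactly
    one is empty).
    """
    am, bm = _as_mask(a), _as_mask(b)
    if am.shape != bm.shape:
        raise ValueError(f"shape mismatch: {am.shape} vs {bm.shape}")
    denom = int(am.sum()) + int(bm.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((am & bm).sum()) / denom


def voxel_auc(p, truth) -> float:
    """Tie-aware (midrank) area under the ROC curve over all voxels."""
    scores = p.p if isinstance(p, ProbabilityMap) else np.asarray(p, dtype=float)
    labels = _as_mask(truth)
    if scores.shape != labels.shape:
        raise ValueError(f"shape mismatch: {scores.shape} vs {labels.shape}")
    y = labels.ravel().astype(int)
    if y.min() == y.max():
        raise ValueError("truth contains a single class; AUC undefined")
    return float(roc_auc_score(y, scores.ravel()))


def _two_way_mean_squares(matrix: np.ndarray):
    """Mean squares of the two-way (subjects x runs) ANOVA, no interaction
    replicate: MSR (rows), MSC (columns), MSE (residual)."""
    n, k = matrix.shape
    grand = matrix.mean()
    row_means = matrix.mean(axis=1)
    col_means = matrix.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((matrix - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)  # guard against float cancellation
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_agreement(matrix, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(A,1) of a subjects x runs rating matrix, with F-based 95% CI.

    A degenerate matrix (all cells equal) returns (1.0, (1.0, 1.0)).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("matrix must be 2D with >= 2 subjects and >= 2 runs")
    if np.isnan(m).any():
        raise ValueError("matrix must have no missing cells")
    n, k = m.shape
    if np.ptp(m) == 0:
        return 1.0, (1.0, 1.0)
    msr, msc, mse = _two_way_mean_squares(m)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0, (1.0, 1.0)
    icc = (msr - mse) / denom
    tiny = 1e-12 * max(abs(msr), 1.0)
    if mse <= tiny and msc <= tiny:
        return float(np.clip(icc, -1.0, 1.0)), (1.0, 1.0)

    # McGraw & Wong F-based interval for ICC(A,1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fj = msc / mse if mse > 0 else np.inf
        df2 = (n - 1) * (k - 1)
        vn = df2 * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
        f2u = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f2l = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f2u * mse) / (f2u * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f2l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2l * msr)
    lower = float(np.clip(np.nan_to_num(lower, nan=-1.0), -1.0, 1.0))
    upper = float(np.clip(np.nan_to_num(upper, nan=1.0), -1.0, 1.0))
    est = float(np.clip(icc, -1.0, 1.0))
    return est, (min(lower, est), max(upper, est))


@dataclass
class MetricsReport:
    """Per-subject DSC and AUC with cohort mean/SD."""

    table: pd.DataFrame  # columns: subject_id, dsc, auc

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def mean_dsc(self) -> float:
        return float(self.table["dsc"].mean())

    @property
    def sd_dsc(self) -> float:
        return float(self.table["dsc"].std(ddof=1)) if len(self.table) > 1 else 0.0

    @property
    def mean_auc(self) -> float:
        return float(self.table["auc"].mean())

    @property
    def sd_auc(self) -> float:
        return float(self.table["auc"].std(ddof=1)) if len(self.table) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "mean_dsc": self.mean_dsc,
            "sd_dsc": self.sd_dsc,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
        }


def metrics_report(rows: list[dict]) -> MetricsReport:
    """Build a MetricsReport from dicts with subject_id, dsc, auc keys."""
    table = pd.DataFrame(rows, columns=["subject_id", "dsc", "auc"])
    if ((table["dsc"] < 0) | (table["dsc"] > 1)).any():
        raise ValueError("DSC out of [0, 1]")
    if ((table["auc"] < 0) | (table["auc"] > 1)).any():
        raise ValueError("AUC out of [0, 1]")
    return MetricsReport(table=table)


@dataclass
class StabilityReport:
    """DSC matrix across repeated runs, with its ICC and 95% CI."""

    dsc_matrix: np.ndarray  # (subjects, runs)
    icc: float
    ci95: tuple[float, float]
    n_runs: int
    subject_ids: list[str] = field(default_factory=list)
    run_seeds: list[int] = field(default_factory=list)
    icc_form: str = ICC_FORM

    def to_table(self) -> pd.DataFrame:
        cols = {f"run_{r}": self.dsc_matrix[:, r] for r in range(self.n_runs)}
        return pd.DataFrame({"subject_id": self.subject_ids, **cols})


def paired_dsc_ttest(a, b) -> tuple[float, float]:
    """Paired two-sided t-test between two per-subject DSC samples."""
    res = sps.ttest_rel(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def stability_run(
    cohort_discovery,
    cohort_validation,
    config,
    n_runs: int = 4,
    seeds: list[int] | None = None,
) -> StabilityReport:
    """Repeat the full sampling/training/prediction procedure ``n_runs``
    times and measure agreement of the per-subject DSC across runs."""
    from .experiment import run_stability  # deferred to avoid an import cycle

    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    return run_stability(cohort_discovery, cohort_validation, config, n_runs, seeds)
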