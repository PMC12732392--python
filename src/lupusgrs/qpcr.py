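"""Relative qPCR quantification by the 2^-ddCt method, with group tests.

Each sample carries replicate cycle-threshold (Ct) measurements for a
target gene and an endogenous reference gene. Technical replicates are
collapsed to their mean first (the sample is the inferential unit), then:

    dCt   = mean target Ct - mean reference Ct            (per sample)
    ddCt  = dCt - mean dCt of the calibrator group
    rel   = 2 ** (-ddCt)                                  (fold change)

The calibrator defaults to the non-carrier (wild-type) genotype group, so
fold changes are expressed relative to subjects without the risk allele.
Group comparisons use a one-way fixed-effects ANOVA on the fold-change
scale by default; a log2 scale (equivalently -ddCt) option is provided
because fold changes are right-skewed. Clinical-feature comparisons and a
rank-based disease-activity correlation operate on the same per-sample
relative-expression values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtRecord",
    "AnovaResult",
    "ExpressionResult",
    "GroupComparison",
    "CorrelationResult",
    "delta_delta_ct",
    "group_anova",
    "clinical_feature_compare",
    "sledai_correlation",
]

_REL_VAR_TOL = 1e-12  # relative tolerance for "zero" sums of squares


@dataclass(frozen=True)
class CtRecord:
    """Replicate Ct measurements for one sample.

    ``genotype_class`` is "noncarrier" (no risk allele) or "carrier"
    (>= 1 risk allele); ``clinical_flags`` holds optional dichotomous
    indicators coded 0/1 (e.g. pericarditis present); ``sledai`` is an
    optional disease-activity score.
    """

    sample_id: str
    phenotype: str
    genotype_class: str
    target_cts: tuple[float, ...]
    reference_cts: tuple[float, ...]
    clinical_flags: Mapping[str, int] = field(default_factory=dict)
    sledai: Optional[float] = None

    def __post_init__(self) -> None:
        if self.phenotype not in ("case", "control"):
            raise ValueError(f"phenotype must be 'case' or 'control', got {self.phenotype!r}")
        if self.genotype_class not in ("noncarrier", "carrier"):
            raise ValueError(
                f"genotype_class must be 'noncarrier' or 'carrier', got {self.genotype_class!r}"
            )
        for name in ("target_cts", "reference_cts"):
            cts = tuple(float(x) for x in getattr(self, name))
            if len(cts) < 1:
                raise ValueError(f"{name}: at least one replicate is required")
            if not all(math.isfinite(x) and x > 0 for x in cts):
                raise ValueError(f"{name}: Ct values must be finite and positive")
            object.__setattr__(self, name, cts)

    @property
    def dct(self) -> float:
        """Mean target Ct minus mean reference Ct, in cycles."""
        return float(np.mean(self.target_cts) - np.mean(self.reference_cts))

    @property
    def single_replicate(self) -> bool:
        return len(self.target_cts) == 1 or len(self.reference_cts) == 1


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA summary.

    ``degenerate`` marks a zero within-group variance: F is 0 (all groups
    identical) or infinite (separated constant groups, p reported as 0).
    """

    f: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class GroupComparison:
    """Mean +/- SE per group plus the ANOVA across groups."""

    summary: pd.DataFrame
    anova: AnovaResult


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p: float
    method: str
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class ExpressionResult:
    """Per-sample relative expression and group-level summaries.

    ``samples`` has one row per sample with columns ``sample_id``,
    ``phenotype``, ``genotype_class``, ``dct``, ``ddct``, ``rel_expr``,
    ``log2_rel`` plus any clinical flags and ``sledai``. The calibrator
    group's mean ddCt is zero by construction, so its geometric-mean fold
    change is exactly 1.
    """

    samples: pd.DataFrame
    group_summary: pd.DataFrame
    anova: Optional[AnovaResult]
    calibrator: str
    group_by: str
    scale: str

    def values_for_anova(self, frame: Optional[pd.DataFrame] = None) -> np.ndarray:
        frame = self.samples if frame is None else frame
        col = "rel_expr" if self.scale == "fold" else "log2_rel"
        return frame[col].to_numpy(dtype=float)


def group_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """One-way fixed-effects ANOVA by direct sum-of-squares decomposition.

    F = (SS_between / (k-1)) / (SS_within / (N-k)) with the p-value from
    the F distribution. Every group must contain at least two samples.
    Degenerate inputs (zero within-group variance) are flagged rather than
    propagated as NaN: identical groups give F = 0, p = 1; perfectly
    separated constant groups give an infinite F with p reported as 0.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape or v.ndim != 1:
        raise ValueError("values and groups must be equal-length 1-d sequences")
    labels, inverse = np.unique(g, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("at least two groups are required")
    counts = np.bincount(inverse)
    for lab, n in zip(labels, counts):
        if n < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
    grand = v.mean()
    group_means = np.bincount(inverse, weights=v) / counts
    ss_between = float((counts * (group_means - grand) ** 2).sum())
    ss_within = float(((v - group_means[inverse]) ** 2).sum())
    df_b, df_w = len(labels) - 1, len(v) - len(labels)
    scale = max(float(((v - grand) ** 2).sum()), np.finfo(float).tiny)
    if ss_within <= _REL_VAR_TOL * scale:
        if ss_between <= _REL_VAR_TOL * scale:
            return AnovaResult(0.0, df_b, df_w, 1.0, degenerate=True)
        return AnovaResult(math.inf, df_b, df_w, 0.0, degenerate=True)
    f = (ss_between / df_b) / (ss_within / df_w)
    return AnovaResult(float(f), df_b, df_w, float(stats.f.sf(f, df_b, df_w)))


def delta_delta_ct(
    records: Iterable[CtRecord],
    calibrator: str = "noncarrier",
    *,
    group_by: str = "genotype_class",
    scale: str = "fold",
) -> ExpressionResult:
    """Relative expression of every sample by 2^-ddCt.

    Parameters
    ----------
    records
        Replicate Ct measurements, one :class:`CtRecord` per sample.
    calibrator
        The level of ``group_by`` whose mean dCt anchors ddCt = 0 (default
        the non-carrier genotype group). Must be non-empty.
    group_by
        Column used both for the calibrator and the group summary/ANOVA:
        ``"genotype_class"`` or ``"phenotype"``.
    scale
        ``"fold"`` runs the ANOVA on 2^-ddCt; ``"log2"`` on -ddCt.

    Group summaries report the mean and standard error of the per-sample
    fold changes (biological, between-sample error; technical replicates
    are already collapsed). The ANOVA is attached when every group has at
    least two samples, otherwise left as None.
    """
    if scale not in ("fold", "log2"):
        raise ValueError(f"scale must be 'fold' or 'log2', got {scale!r}")
    records = list(records)
    if not records:
        raise ValueError("no Ct records supplied")
    flag_names = sorted({k for r in records for k in r.clinical_flags})
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "phenotype": r.phenotype,
            "genotype_class": r.genotype_class,
            "dct": r.dct,
            "single_replicate": r.single_replicate,
            "sledai": np.nan if r.sledai is None else float(r.sledai),
        }
        for k in flag_names:
            row[k] = r.clinical_flags.get(k, np.nan)
        rows.append(row)
    samples = pd.DataFrame(rows)
    if group_by not in ("genotype_class", "phenotype"):
        raise ValueError(f"group_by must be 'genotype_class' or 'phenotype', got {group_by!r}")
    cal_mask = samples[group_by] == calibrator
    if not cal_mask.any():
        raise ValueError(f"calibrator group {calibrator!r} is empty")
    cal_dct = float(samples.loc[cal_mask, "dct"].mean())
    samples["ddct"] = samples["dct"] - cal_dct
    samples["rel_expr"] = 2.0 ** (-samples["ddct"])
    samples["log2_rel"] = -samples["ddct"]

    value_col = "rel_expr" if scale == "fold" else "log2_rel"
    grp = samples.groupby(group_by)[value_col]
    group_summary = grp.agg(n="size", mean="mean", sd="std").reset_index()
    group_summary["se"] = group_summary["sd"] / np.sqrt(group_summary["n"])

    anova = None
    if len(group_summary) >= 2 and (group_summary["n"] >= 2).all():
        anova = group_anova(samples[value_col], samples[group_by])
    return ExpressionResult(
        samples=samples,
        group_summary=group_summary,
        anova=anova,
        calibrator=calibrator,
        group_by=group_by,
        scale=scale,
    )


def clinical_feature_compare(
    result: ExpressionResult, flag: str, *, phenotype: str = "case"
) -> GroupComparison:
    """Compare relative expression between levels of a dichotomous clinical flag.

    Restricted to one phenotype arm (cases by default, where clinical
    manifestations are recorded). Both flag levels (0 and 1) must be
    present; otherwise an informative error names the missing level.
    """
    frame = result.samples
    if flag not in frame.columns:
        raise KeyError(f"clinical flag {flag!r} not present in the expression table")
    sub = frame[(frame["phenotype"] == phenotype) & frame[flag].notna()]
    levels = set(sub[flag].astype(int))
    for level in (0, 1):
        if level not in levels:
            raise ValueError(
                f"flag {flag!r} level {level} absent among {phenotype} samples; "
                "both levels are required for a comparison"
            )
    values = result.values_for_anova(sub)
    groups = sub[flag].astype(int).to_numpy()
    col = "rel_expr" if result.scale == "fold" else "log2_rel"
    summary = (
        sub.groupby(sub[flag].astype(int))[col]
        .agg(n="size", mean="mean", sd="std")
        .reset_index()
        .rename(columns={flag: "level"})
    )
    summary["se"] = summary["sd"] / np.sqrt(summary["n"])
    return GroupComparison(summary=summary, anova=group_anova(values, groups))


def sledai_correlation(
    result: ExpressionResult,
    sledai: Optional[Sequence[float]] = None,
    *,
    method: str = "spearman",
) -> CorrelationResult:
    """Correlate relative expression with disease-activity (SLEDAI) scores.

    Uses the ``sledai`` column of the expression table (cases only) unless
    explicit scores are passed. Spearman's rank correlation is the default
    (activity scores are ordinal); Pearson is available. Constant input on
    either side has no defined coefficient and is returned flagged.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    if sledai is None:
        sub = result.samples[
            (result.samples["phenotype"] == "case") & result.samples["sledai"].notna()
        ]
        x = sub["rel_expr"].to_numpy(dtype=float)
        y = sub["sledai"].to_numpy(dtype=float)
    else:
        y = np.asarray(sledai, dtype=float)
        x = result.samples["rel_expr"].to_numpy(dtype=float)
        if len(x) != len(y):
            raise ValueError("sledai length does not match the number of samples")
        keep = ~np.isnan(y)
        x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("at least 3 paired observations are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(math.nan, math.nan, method, n, degenerate=True)
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    else:
        rho, p = stats.pearsonr(x, y)
    return CorrelationResult(float(rho), float(p), method, n)
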