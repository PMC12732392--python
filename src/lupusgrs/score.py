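"""Weighted genetic risk scores (wGRS) from risk-allele counts.

A subject's raw score is the sum over loci of the risk-allele count (0/1/2)
times the locus weight. Weights default to the raw per-locus odds ratios,
matching how the score was defined in the source cohort analysis; the
conventional ln(OR) weighting is available through ``weight_transform``.
Raw scores are rounded half-up to whole numbers and binned into risk
classes: low (rounded score <= 2), mid (3-4) and high (>= 5).

Class frequencies are compared between arms with the same uncorrected 2x2
Pearson chi-square used for the dominant association test, applied to the
low-threshold (<= low cut) and high-threshold (>= high cut) dichotomies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .association import pearson_chi2_2x2

__all__ = [
    "WeightSpec",
    "RiskProfile",
    "ClassComparison",
    "compute_wgrs",
    "class_distribution",
    "score_histogram",
    "round_half_up_int",
    "assign_risk_class",
]

RISK_CLASSES = ("low", "mid", "high")


def round_half_up_int(x: float) -> int:
    """Round a nonnegative score half-up to the nearest whole number (5.5 -> 6)."""
    return int(math.floor(x + 0.5))


def assign_risk_class(rounded_score: int, low_cut: int = 2, high_cut: int = 5) -> str:
    if low_cut >= high_cut:
        raise ValueError("low_cut must be below high_cut")
    if rounded_score <= low_cut:
        return "low"
    if rounded_score >= high_cut:
        return "high"
    return "mid"


@dataclass(frozen=True)
class WeightSpec:
    """Per-variant score weight: the risk allele and its odds ratio."""

    variant_id: str
    risk_allele: str
    or_weight: float

    def __post_init__(self) -> None:
        if not self.or_weight > 0:
            raise ValueError(f"or_weight must be positive, got {self.or_weight!r}")


@dataclass(frozen=True)
class RiskProfile:
    """Per-subject weighted genetic risk score and class.

    ``excluded`` marks subjects whose missing-genotype fraction exceeds the
    tolerance; their scores are computed over the observed loci but they are
    dropped from between-arm class comparisons.
    """

    subject_id: str
    raw_score: float
    rounded_score: int
    risk_class: str
    n_missing: int = 0
    excluded: bool = False


@dataclass(frozen=True)
class ClassComparison:
    """Between-arm comparison of risk-score classes.

    ``score_table`` and ``class_table`` hold per-arm counts and frequencies
    by rounded score and by risk class; the chi-square fields test the
    low-threshold and high-threshold dichotomies (class membership x arm).
    """

    score_table: pd.DataFrame
    class_table: pd.DataFrame
    low_chi2: float
    low_p: float
    high_chi2: float
    high_p: float
    n_cases: int
    n_controls: int
    n_excluded: int = 0


def _genotype_frame(genotypes) -> pd.DataFrame:
    if hasattr(genotypes, "genotypes"):  # GenotypeCohort
        return genotypes.genotypes
    return pd.DataFrame(genotypes)


def compute_wgrs(
    genotypes,
    weights: Sequence[WeightSpec],
    *,
    weight_transform: str = "or",
    low_cut: int = 2,
    high_cut: int = 5,
    max_missing_frac: float = 1 / 6,
) -> list[RiskProfile]:
    """Compute per-subject weighted genetic risk scores.

    Parameters
    ----------
    genotypes
        A ``GenotypeCohort`` or a DataFrame indexed by subject with one
        column per variant, entries the risk-allele dose 0/1/2 (NaN for
        missing).
    weights
        One :class:`WeightSpec` per variant column; a column without a
        weight is a hard error.
    weight_transform
        ``"or"`` (raw odds-ratio weights, the default) or ``"log"``
        (ln OR, the conventional wGRS weighting).
    max_missing_frac
        Subjects missing a larger fraction of variants than this are
        flagged ``excluded`` (scores still computed over observed loci).
    """
    frame = _genotype_frame(genotypes)
    by_id = {w.variant_id: w for w in weights}
    if len(by_id) != len(list(weights)):
        raise ValueError("duplicate variant_id in weights")
    missing_weights = [v for v in frame.columns if v not in by_id]
    if missing_weights:
        raise KeyError(f"no weight supplied for variant(s): {missing_weights}")

    w = np.array([by_id[v].or_weight for v in frame.columns], dtype=float)
    if weight_transform == "log":
        w = np.log(w)
    elif weight_transform != "or":
        raise ValueError(f"unknown weight_transform {weight_transform!r}")

    counts = frame.to_numpy(dtype=float)
    valid = np.isin(counts, (0.0, 1.0, 2.0)) | np.isnan(counts)
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise ValueError(
            f"genotype for subject {frame.index[i]!r} at {frame.columns[j]!r} "
            f"is {counts[i, j]!r}; expected 0, 1, 2 or missing"
        )
    observed = ~np.isnan(counts)
    raw = np.nansum(counts * w, axis=1)
    n_missing = (~observed).sum(axis=1)
    n_var = counts.shape[1]
    excluded = n_missing / n_var > max_missing_frac + 1e-12

    profiles = []
    for sid, r, miss, excl in zip(frame.index, raw, n_missing, excluded):
        rounded = round_half_up_int(float(r))
        profiles.append(
            RiskProfile(
                subject_id=str(sid),
                raw_score=float(r),
                rounded_score=rounded,
                risk_class=assign_risk_class(rounded, low_cut, high_cut),
                n_missing=int(miss),
                excluded=bool(excl),
            )
        )
    return profiles


def _profiles_frame(
    profiles: Iterable[RiskProfile], phenotypes: Mapping[str, str]
) -> tuple[pd.DataFrame, int]:
    rows = []
    n_excluded = 0
    for p in profiles:
        if p.excluded:
            n_excluded += 1
            continue
        try:
            arm = phenotypes[p.subject_id]
        except KeyError:
            raise KeyError(f"no phenotype label for subject {p.subject_id!r}")
        if arm not in ("case", "control"):
            raise ValueError(f"phenotype must be 'case' or 'control', got {arm!r}")
        rows.append((p.subject_id, arm, p.rounded_score, p.risk_class))
    frame = pd.DataFrame(rows, columns=["subject_id", "phenotype", "score", "class"])
    return frame, n_excluded


def class_distribution(
    profiles: Iterable[RiskProfile],
    phenotypes: Mapping[str, str],
    *,
    low_cut: int = 2,
    high_cut: int = 5,
) -> ClassComparison:
    """Compare risk-score class frequencies between cases and controls.

    The low (rounded score <= ``low_cut``) and high (>= ``high_cut``)
    thresholds are each tested with an uncorrected 2x2 Pearson chi-square
    on membership x arm; middle strata are never tested on their own, so
    empty classes simply carry frequency zero.
    """
    frame, n_excluded = _profiles_frame(profiles, phenotypes)
    n_cases = int((frame["phenotype"] == "case").sum())
    n_controls = int((frame["phenotype"] == "control").sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("both arms must contain at least one (non-excluded) subject")

    def _tab(column: str, order) -> pd.DataFrame:
        counts = (
            frame.groupby(["phenotype", column]).size().unstack(fill_value=0).T
        ).reindex(order, fill_value=0)
        for arm in ("case", "control"):
            if arm not in counts:
                counts[arm] = 0
        tab = counts[["case", "control"]].rename(
            columns={"case": "case_n", "control": "control_n"}
        )
        tab["case_freq"] = tab["case_n"] / n_cases
        tab["control_freq"] = tab["control_n"] / n_controls
        return tab

    score_range = range(int(frame["score"].min()), int(frame["score"].max()) + 1)
    score_table = _tab("score", list(score_range))
    class_table = _tab("class", list(RISK_CLASSES))

    case_scores = frame.loc[frame["phenotype"] == "case", "score"]
    control_scores = frame.loc[frame["phenotype"] == "control", "score"]

    def _threshold_chi2(predicate) -> tuple[float, float]:
        a = int(predicate(case_scores).sum())
        c = int(predicate(control_scores).sum())
        return pearson_chi2_2x2(a, n_cases - a, c, n_controls - c)

    low_chi2, low_p = _threshold_chi2(lambda s: s <= low_cut)
    high_chi2, high_p = _threshold_chi2(lambda s: s >= high_cut)
    return ClassComparison(
        score_table=score_table,
        class_table=class_table,
        low_chi2=low_chi2,
        low_p=low_p,
        high_chi2=high_chi2,
        high_p=high_p,
        n_cases=n_cases,
        n_controls=n_controls,
        n_excluded=n_excluded,
    )


def score_histogram(
    profiles: Iterable[RiskProfile], phenotypes: Mapping[str, str]
) -> pd.DataFrame:
    """Normalised per-arm frequency of each rounded score, ready to plot.

    Returns a DataFrame indexed by rounded score with ``case`` and
    ``control`` columns of within-arm frequencies (each column sums to 1
    when its arm is non-empty).
    """
    frame, _ = _profiles_frame(profiles, phenotypes)
    if frame.empty:
        raise ValueError("no subjects to histogram")
    scores = range(int(frame["score"].min()), int(frame["score"].max()) + 1)
    hist = pd.DataFrame(index=pd.Index(list(scores), name="rounded_score"))
    for arm in ("case", "control"):
        s = frame.loc[frame["phenotype"] == arm, "score"].value_counts()
        n = s.sum()
        hist[arm] = (s.reindex(hist.index, fill_value=0) / n) if n else 0.0
    return hist
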