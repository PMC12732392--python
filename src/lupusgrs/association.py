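"""Single-variant case-control association statistics.

The statistics here are the genotype-level workhorses of a candidate-gene
case-control study at a biallelic locus:

* Hardy-Weinberg equilibrium (HWE) testing by Pearson's chi-square, with the
  allele frequency estimated from the observed genotype counts (1 df).
* Dominant-model association: heterozygous and variant-homozygous subjects
  are collapsed into a single "carrier" exposure, and the resulting 2x2
  table is summarised by the odds ratio with a Woolf (log-scale) 95%
  confidence interval and an uncorrected Pearson chi-square p-value.
* Genotype percentage summaries formatted the way association tables are
  conventionally printed (one decimal, half-up rounding).
* Goodness-of-fit of observed genotype counts against fixed
  reference-population proportions (e.g. gnomAD non-Finnish Europeans),
  either over the three genotype cells (2 df) or after collapsing to
  carrier/non-carrier (1 df).

Genotypes are coded throughout as risk-allele dose: 0 (homozygous
non-risk), 1 (heterozygous), 2 (homozygous risk).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

#: Two-sided 95% standard-normal quantile used in the Woolf interval.
Z_95 = 1.959963984540054

__all__ = [
    "GenotypeCounts",
    "HweResult",
    "AssociationResult",
    "GofResult",
    "hwe_test",
    "dominant_association",
    "genotype_percentages",
    "reference_gof",
    "pearson_chi2_2x2",
]


def _round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, as tables in the clinical literature do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at one biallelic locus, coded by risk-allele dose.

    ``n_hom_ref`` subjects carry 0 risk alleles, ``n_het`` carry 1 and
    ``n_hom_alt`` carry 2.
    """

    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        for name in ("n_hom_ref", "n_het", "n_hom_alt"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("at least one genotype is required")

    @property
    def total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def carriers(self) -> int:
        """Subjects with at least one risk allele (dominant-model exposure)."""
        return self.n_het + self.n_hom_alt

    @property
    def noncarriers(self) -> int:
        return self.n_hom_ref

    @property
    def risk_allele_freq(self) -> float:
        return (self.n_het + 2 * self.n_hom_alt) / (2 * self.total)

    @classmethod
    def from_doses(cls, doses: Iterable[float]) -> "GenotypeCounts":
        """Tally an iterable of risk-allele doses (0/1/2); NaN entries are dropped."""
        arr = np.asarray(list(doses), dtype=float)
        arr = arr[~np.isnan(arr)]
        if not np.isin(arr, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(arr[~np.isin(arr, (0.0, 1.0, 2.0))].tolist()))
            raise ValueError(f"doses must be 0, 1 or 2; found {bad}")
        return cls(int((arr == 0).sum()), int((arr == 1).sum()), int((arr == 2).sum()))


@dataclass(frozen=True)
class HweResult:
    """Pearson chi-square test of Hardy-Weinberg proportions (1 df)."""

    chi2: float
    df: int
    p: float
    estimated_raf: float
    monomorphic: bool = False


@dataclass(frozen=True)
class AssociationResult:
    """Dominant-model 2x2 association summary.

    ``table`` holds (case carriers, case non-carriers, control carriers,
    control non-carriers). When a cell is zero the odds ratio and interval
    are computed on the Haldane-Anscombe corrected table (+0.5 everywhere)
    and ``continuity_corrected`` is set; the chi-square is then left NaN.
    """

    table: tuple[int, int, int, int]
    or_estimate: float
    ci_low: float
    ci_high: float
    chi2: float
    p: float
    continuity_corrected: bool = False


@dataclass(frozen=True)
class GofResult:
    """Goodness-of-fit of genotype counts against fixed reference proportions."""

    chi2: float
    df: int
    p: float
    mode: str
    low_expected: bool = False


def pearson_chi2_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Uncorrected Pearson chi-square for the 2x2 table [[a, b], [c, d]].

    Computed from expected counts under independence of the row and column
    margins; the p-value comes from the chi-square distribution with 1 df.
    A table with an empty margin carries no information and returns (0, 1).
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any():
        raise ValueError("cell counts must be nonnegative")
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if n == 0 or rows.min() == 0 or cols.min() == 0:
        return 0.0, 1.0
    expected = rows * cols / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, 1))


def hwe_test(counts: GenotypeCounts) -> HweResult:
    """Test genotype counts for Hardy-Weinberg proportions.

    The risk-allele frequency q is estimated from the counts; expected
    counts are N*(1-q)^2, N*2q(1-q), N*q^2 and the Pearson statistic is
    referred to chi-square with 1 df (three cells, one estimated allele
    frequency). A monomorphic sample fits HWE trivially and is returned
    with ``chi2 = 0`` and ``monomorphic=True`` rather than raising.
    """
    n = counts.total
    q = counts.risk_allele_freq
    if q == 0.0 or q == 1.0:
        return HweResult(chi2=0.0, df=1, p=1.0, estimated_raf=q, monomorphic=True)
    expected = np.array([n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2])
    observed = np.array([counts.n_hom_ref, counts.n_het, counts.n_hom_alt], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(chi2=chi2, df=1, p=float(stats.chi2.sf(chi2, 1)), estimated_raf=q)


def dominant_association(
    case_counts: GenotypeCounts, control_counts: GenotypeCounts
) -> AssociationResult:
    """Dominant-model association between carrier status and case status.

    Carriers (>=1 risk allele) are compared with non-carriers across the
    two arms. The odds ratio is the cross-product ratio; its 95% interval
    is Woolf's: exp(ln OR +/- 1.96 * sqrt(sum of reciprocal cells)). The
    chi-square is Pearson's without continuity correction.
    """
    a, b = case_counts.carriers, case_counts.noncarriers
    c, d = control_counts.carriers, control_counts.noncarriers
    zero_cell = min(a, b, c, d) == 0
    if zero_cell:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
        chi2, p = math.nan, math.nan
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
        chi2, p = pearson_chi2_2x2(a, b, c, d)
    or_estimate = (aa * dd) / (bb * cc)
    se_log = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = math.exp(math.log(or_estimate) - Z_95 * se_log)
    ci_high = math.exp(math.log(or_estimate) + Z_95 * se_log)
    return AssociationResult(
        table=(a, b, c, d),
        or_estimate=or_estimate,
        ci_low=ci_low,
        ci_high=ci_high,
        chi2=chi2,
        p=p,
        continuity_corrected=zero_cell,
    )


def genotype_percentages(counts: GenotypeCounts) -> tuple[float, float, float]:
    """Percent of subjects per genotype, rounded half-up to one decimal."""
    n = counts.total
    return tuple(
        _round_half_up(100.0 * x / n, 1)
        for x in (counts.n_hom_ref, counts.n_het, counts.n_hom_alt)
    )


def reference_gof(
    observed: GenotypeCounts,
    reference_props: Sequence[float],
    mode: str = "dominant_collapse",
) -> GofResult:
    """Pearson goodness-of-fit of observed genotypes to reference proportions.

    The reference proportions (hom-ref, het, hom-alt) are treated as fixed —
    the reference cohort is assumed large enough that its sampling error is
    negligible. ``mode`` selects the construction:

    * ``"three_genotype"`` — all three genotype cells, 2 df.
    * ``"dominant_collapse"`` — non-carrier vs carrier, 1 df (the default;
      this is the construction consistent with a dominant-model analysis).

    An expected cell below 1 sets ``low_expected`` as a warning flag.
    """
    props = np.asarray(reference_props, dtype=float)
    if props.shape != (3,) or (props < 0).any() or props.sum() <= 0:
        raise ValueError("reference_props must be three nonnegative fractions")
    props = props / props.sum()
    n = observed.total
    if mode == "three_genotype":
        obs = np.array(
            [observed.n_hom_ref, observed.n_het, observed.n_hom_alt], dtype=float
        )
        expected = n * props
        df = 2
    elif mode == "dominant_collapse":
        obs = np.array([observed.noncarriers, observed.carriers], dtype=float)
        expected = n * np.array([props[0], props[1] + props[2]])
        df = 1
    else:
        raise ValueError(f"unknown GOF mode {mode!r}")
    if (expected == 0).any():
        raise ValueError("a reference proportion of zero with observed total > 0")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return GofResult(
        chi2=chi2,
        df=df,
        p=float(stats.chi2.sf(chi2, df)),
        mode=mode,
        low_expected=bool(expected.min() < 1),
    )
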