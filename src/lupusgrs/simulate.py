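"""Synthetic case-control cohorts and qPCR measurement tables.

The generators reproduce the statistical structure the analysis modules
assume, so the whole pipeline can be exercised and calibrated without any
subject-level data.

Cohort model
------------
Population genotypes at each locus are drawn independently under
Hardy-Weinberg equilibrium at the locus's source-population risk-allele
frequency. Disease status follows a logistic model whose intercept is the
logit of the baseline prevalence and whose per-locus coefficient is
ln(per-allele OR), applied to the risk-allele count (additive model) or to
a carrier indicator (dominant model). Cases and controls are collected by
rejection sampling from this population model until both arm quotas are
filled — exact for multi-locus models and easy to audit. Note the two
distinct uses of odds ratios in this package: the disease model uses
ln(OR) on the logit scale (the standard construction), while the risk
score in :mod:`lupusgrs.score` deliberately weights by the raw OR.

Expression model
----------------
Per sample, replicate reference-gene Ct values are Normal(reference mean,
replicate SD) and target-gene Ct values are Normal(reference mean + group
dCt, replicate SD), where the group dCt is the non-carrier mean dCt plus a
carrier shift (a negative shift means higher expression in carriers, the
direction reported for risk-allele carriers). The reference mean Ct is
arbitrary and cancels in dCt.

Both generators are bit-reproducible given their seed; each call owns one
seeded generator and touches no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import GenotypeCohort
from .qpcr import CtRecord
from .score import WeightSpec

__all__ = [
    "VariantSimSpec",
    "CohortSimParams",
    "ExpressionSimParams",
    "QuotaError",
    "simulate_cohort",
    "simulate_expression",
    "default_study_variants",
    "default_weight_specs",
    "carrier_labels_from_cohort",
]

#: Population draws allowed per unfilled arm before giving up.
DRAW_CAP = 1_000_000
_CHUNK = 8192


class QuotaError(RuntimeError):
    """An arm quota could not be filled within the draw cap."""


@dataclass(frozen=True)
class VariantSimSpec:
    """One simulated biallelic locus.

    ``control_raf`` is the risk-allele frequency in the source population
    (with a rare disease this is, to first order, the control-arm
    frequency); ``per_allele_or`` the odds ratio per risk allele; ``model``
    chooses how genotype enters the disease model ("additive" applies
    ln(OR) per allele, "dominant" applies it to a carrier indicator).
    """

    variant_id: str
    control_raf: float
    per_allele_or: float
    model: str = "additive"

    def __post_init__(self) -> None:
        if not 0.0 <= self.control_raf <= 1.0:
            raise ValueError(f"control_raf must be in [0, 1], got {self.control_raf!r}")
        if not self.per_allele_or > 0:
            raise ValueError(f"per_allele_or must be positive, got {self.per_allele_or!r}")
        if self.model not in ("additive", "dominant"):
            raise ValueError(f"model must be 'additive' or 'dominant', got {self.model!r}")


def default_study_variants() -> list[VariantSimSpec]:
    """Default six-locus lupus susceptibility panel.

    rs2836882 (the ETS2 enhancer variant) carries the control risk-allele
    frequency and per-allele OR estimated in the reference cohort analysis
    (raf 0.26, OR 1.54). The five companion loci are PLACEHOLDERS: their
    cohort-specific ORs are not republished alongside the rs2836882
    analysis, so frequencies and effects are set to literature-plausible
    values and should be overridden with cohort estimates for real use.
    """
    return [
        VariantSimSpec("rs2836882", 0.26, 1.54),
        VariantSimSpec("rs2230926", 0.04, 1.90),   # TNFAIP3, placeholder
        VariantSimSpec("rs6920220", 0.22, 1.70),   # TNFAIP3, placeholder
        VariantSimSpec("rs33980500", 0.08, 1.70),  # TRAF3IP2, placeholder
        VariantSimSpec("rs7574865", 0.22, 1.60),   # STAT4, placeholder
        VariantSimSpec("rs573775", 0.35, 1.30),    # ATG5, placeholder
    ]


def default_weight_specs() -> list[WeightSpec]:
    """Risk-score weights matching :func:`default_study_variants` (raw ORs)."""
    return [
        WeightSpec(v.variant_id, "A", v.per_allele_or) for v in default_study_variants()
    ]


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of the case-control cohort generator.

    Defaults mirror the reference study design: 246 cases, 216 controls,
    the six-locus panel, and a rare-disease baseline prevalence (0.001,
    the order of magnitude of lupus prevalence). The case-control
    statistics computed downstream are invariant to the intercept — under
    the null, genotypes are independent of case status; under the
    alternative, the carrier odds ratio equals exp(beta) exactly for any
    prevalence — so a larger intercept may be passed to speed up
    large-replicate calibration runs without changing what is measured.
    """

    n_cases: int = 246
    n_controls: int = 216
    variants: tuple[VariantSimSpec, ...] = field(
        default_factory=lambda: tuple(default_study_variants())
    )
    baseline_prevalence: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("both arm sizes must be at least 1")
        if not self.variants:
            raise ValueError("at least one variant is required")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must lie strictly in (0, 1)")
        object.__setattr__(self, "variants", tuple(self.variants))


def simulate_cohort(params: CohortSimParams) -> GenotypeCohort:
    """Draw a case-control cohort by rejection from the population model.

    Population subjects are generated in chunks (HWE genotypes per locus,
    then a Bernoulli disease draw from the logistic model) and assigned to
    whichever arm still has an open quota, preserving draw order. Raises
    :class:`QuotaError` naming the unfilled arm(s) if more than
    ``DRAW_CAP`` population draws per unfilled arm are consumed.
    """
    rng = np.random.default_rng(params.seed)
    raf = np.array([v.control_raf for v in params.variants])
    log_or = np.log([v.per_allele_or for v in params.variants])
    dominant = np.array([v.model == "dominant" for v in params.variants])
    p0 = params.baseline_prevalence
    intercept = np.log(p0 / (1 - p0))

    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    draws = 0
    budget = DRAW_CAP * 2  # at most two unfilled arms
    while len(cases) < params.n_cases or len(controls) < params.n_controls:
        if draws >= budget:
            open_arms = [
                arm
                for arm, have, want in (
                    ("case", len(cases), params.n_cases),
                    ("control", len(controls), params.n_controls),
                )
                if have < want
            ]
            raise QuotaError(
                f"could not fill {' and '.join(open_arms)} arm quota within "
                f"{draws} population draws (baseline_prevalence={p0}, "
                f"effects may be pathological)"
            )
        g = rng.binomial(2, raf, size=(_CHUNK, len(raf))).astype(float)
        x = np.where(dominant, (g > 0).astype(float), g)
        eta = intercept + x @ log_or
        prob = 1.0 / (1.0 + np.exp(-eta))
        is_case = rng.random(_CHUNK) < prob
        draws += _CHUNK
        for row, case in zip(g, is_case):
            if case and len(cases) < params.n_cases:
                cases.append(row)
            elif not case and len(controls) < params.n_controls:
                controls.append(row)

    width = len(str(max(params.n_cases, params.n_controls)))
    ids = [f"SLE{i + 1:0{width}d}" for i in range(params.n_cases)] + [
        f"CTRL{i + 1:0{width}d}" for i in range(params.n_controls)
    ]
    matrix = np.vstack(cases + controls)
    genotypes = pd.DataFrame(
        matrix, index=ids, columns=[v.variant_id for v in params.variants]
    )
    phenotype = pd.Series(
        ["case"] * params.n_cases + ["control"] * params.n_controls, index=ids
    )
    return GenotypeCohort(genotypes=genotypes, phenotype=phenotype)


@dataclass(frozen=True)
class ExpressionSimParams:
    """Parameters of the replicate-Ct generator.

    Defaults emulate the reference expression study: 15 samples per
    (genotype class x phenotype) cell — 30 cases and 30 controls in all —
    triplicate measurements, a non-carrier dCt of 5 cycles (target less
    abundant than the reference housekeeping gene), a carrier shift of -1
    cycle (a twofold expression increase in risk-allele carriers) and a
    0.2-cycle replicate SD, a typical qPCR technical noise level.
    """

    n_per_group: int = 15
    mean_dct_noncarrier: float = 5.0
    carrier_dct_shift: float = -1.0
    replicate_sd: float = 0.2
    n_replicates: int = 3
    reference_mean_ct: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be at least 1")


def carrier_labels_from_cohort(
    cohort: GenotypeCohort, variant_id: str
) -> pd.DataFrame:
    """Sample labels (phenotype, carrier/non-carrier at one variant) for expression simulation."""
    doses = cohort.genotypes[variant_id]
    keep = doses.notna()
    return pd.DataFrame(
        {
            "sample_id": cohort.genotypes.index[keep],
            "phenotype": cohort.phenotype[keep].to_numpy(),
            "genotype_class": np.where(doses[keep] > 0, "carrier", "noncarrier"),
        }
    ).reset_index(drop=True)


def simulate_expression(
    params: ExpressionSimParams,
    cohort_labels: Optional[pd.DataFrame] = None,
) -> list[CtRecord]:
    """Generate replicate Ct measurements per sample.

    ``cohort_labels`` (columns ``sample_id``, ``phenotype``,
    ``genotype_class``) fixes the design; when omitted, a balanced design
    with ``n_per_group`` samples per (phenotype x genotype class) cell is
    generated. Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    if cohort_labels is None:
        rows = []
        i = 0
        for phenotype in ("case", "control"):
            for genotype_class in ("noncarrier", "carrier"):
                for _ in range(params.n_per_group):
                    i += 1
                    rows.append((f"EXP{i:04d}", phenotype, genotype_class))
        labels = pd.DataFrame(rows, columns=["sample_id", "phenotype", "genotype_class"])
    else:
        required = {"sample_id", "phenotype", "genotype_class"}
        missing = required - set(cohort_labels.columns)
        if missing:
            raise ValueError(f"cohort_labels is missing column(s): {sorted(missing)}")
        labels = cohort_labels

    records = []
    for row in labels.itertuples(index=False):
        shift = params.carrier_dct_shift if row.genotype_class == "carrier" else 0.0
        target_mean = params.reference_mean_ct + params.mean_dct_noncarrier + shift
        target = rng.normal(target_mean, params.replicate_sd, params.n_replicates)
        reference = rng.normal(
            params.reference_mean_ct, params.replicate_sd, params.n_replicates
        )
        records.append(
            CtRecord(
                sample_id=str(row.sample_id),
                phenotype=str(row.phenotype),
                genotype_class=str(row.genotype_class),
                target_cts=tuple(target),
                reference_cts=tuple(reference),
            )
        )
    return records
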