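"""In-memory container for a genotyped case-control cohort."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import GenotypeCounts

__all__ = ["GenotypeCohort"]

PHENOTYPES = ("case", "control")


@dataclass
class GenotypeCohort:
    """Samples x variants risk-allele-dose matrix with phenotype labels.

    ``genotypes`` is indexed by subject id with one float column per
    variant; entries are 0/1/2 risk-allele doses with NaN for missing.
    ``phenotype`` is a Series aligned to the same index with values
    "case" or "control".
    """

    genotypes: pd.DataFrame
    phenotype: pd.Series

    def __post_init__(self) -> None:
        self.genotypes = self.genotypes.astype(float)
        self.phenotype = pd.Series(self.phenotype)
        if not self.genotypes.index.equals(self.phenotype.index):
            raise ValueError("genotype matrix and phenotype labels are misaligned")
        if self.genotypes.index.has_duplicates:
            dupes = self.genotypes.index[self.genotypes.index.duplicated()].tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        if self.phenotype.isna().any():
            raise ValueError("phenotype labels must be non-missing")
        bad = set(self.phenotype) - set(PHENOTYPES)
        if bad:
            raise ValueError(f"phenotype labels must be 'case'/'control'; found {sorted(bad)}")
        vals = self.genotypes.to_numpy()
        ok = np.isin(vals, (0.0, 1.0, 2.0)) | np.isnan(vals)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"genotype for subject {self.genotypes.index[i]!r} at "
                f"{self.genotypes.columns[j]!r} is {vals[i, j]!r}; expected 0/1/2 or NaN"
            )

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.genotypes.index]

    @property
    def variant_ids(self) -> list[str]:
        return [str(v) for v in self.genotypes.columns]

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == "control").sum())

    @property
    def n_missing(self) -> int:
        return int(self.genotypes.isna().to_numpy().sum())

    def arm(self, phenotype: str) -> pd.DataFrame:
        """Genotype sub-matrix for one arm ("case" or "control")."""
        if phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {phenotype!r}")
        return self.genotypes.loc[self.phenotype == phenotype]

    def variant_counts(self, variant_id: str, phenotype: str) -> GenotypeCounts:
        """Genotype counts for one variant in one arm (missing dropped)."""
        if variant_id not in self.genotypes.columns:
            raise KeyError(f"unknown variant {variant_id!r}")
        return GenotypeCounts.from_doses(self.arm(phenotype)[variant_id])

    def phenotype_map(self) -> dict[str, str]:
        return {str(k): str(v) for k, v in self.phenotype.items()}
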