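"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
* Genotype TSV — header ``subject_id<TAB>phenotype<TAB><variant>...``; one
  row per subject; entries are risk-allele doses ``0``/``1``/``2`` or
  ``NA``.
* VCF 4.x (read-only, via cyvcf2) — GT fields are converted to risk-allele
  doses, oriented by a declared risk allele per site so REF/ALT polarity
  does not matter.
* Weight config — YAML or JSON list of ``{variant_id, risk_allele,
  or_weight}`` objects.
* Ct CSV — long form with columns ``sample_id, phenotype, genotype_class,
  gene ("target"|"reference"), replicate_index, ct`` (plus optional
  per-sample ``sledai`` and 0/1 clinical-flag columns); a wide form with
  ``target_ct_1..k`` / ``reference_ct_1..k`` columns is also accepted.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import GenotypeCohort
from .qpcr import CtRecord
from .score import WeightSpec

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_vcf_as_cohort",
    "read_weight_config",
    "write_weight_config",
    "read_ct_csv",
    "write_ct_csv",
]

log = logging.getLogger("lupusgrs")

_VALID_ENTRIES = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan}


def read_genotype_table(path) -> GenotypeCohort:
    """Read the genotype TSV dialect, validating entry by entry.

    Malformed headers, non-0/1/2/NA entries, bad phenotype labels and
    duplicate subject ids raise ``ValueError`` naming the offending line
    (1-based, header included) and column.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if header[:2] != ["subject_id", "phenotype"] or len(header) < 3:
        raise ValueError(
            f"{path}:1: header must be 'subject_id<TAB>phenotype<TAB><variant>...', "
            f"got {header!r}"
        )
    variants = header[2:]
    if len(set(variants)) != len(variants):
        raise ValueError(f"{path}:1: duplicate variant columns")
    ids, phenos, rows = [], [], []
    seen = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        sid, pheno = fields[0], fields[1]
        if sid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate subject_id {sid!r}")
        seen.add(sid)
        if pheno not in ("case", "control"):
            raise ValueError(
                f"{path}:{lineno}: phenotype must be 'case' or 'control', got {pheno!r}"
            )
        row = []
        for col, entry in zip(variants, fields[2:]):
            if entry not in _VALID_ENTRIES:
                raise ValueError(
                    f"{path}:{lineno}: column {col!r}: entry {entry!r} is not 0/1/2/NA"
                )
            row.append(_VALID_ENTRIES[entry])
        ids.append(sid)
        phenos.append(pheno)
        rows.append(row)
    if not ids:
        raise ValueError(f"{path}: no subjects")
    genotypes = pd.DataFrame(rows, index=ids, columns=variants)
    n_missing = int(genotypes.isna().to_numpy().sum())
    if n_missing:
        log.info("%s: %d missing genotype entries", path, n_missing)
    return GenotypeCohort(genotypes=genotypes, phenotype=pd.Series(phenos, index=ids))


def write_genotype_table(cohort: GenotypeCohort, path) -> None:
    """Write the genotype TSV dialect (inverse of :func:`read_genotype_table`)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["subject_id", "phenotype", *cohort.variant_ids]) + "\n")
        for sid in cohort.subject_ids:
            doses = cohort.genotypes.loc[sid]
            entries = ["NA" if np.isnan(d) else str(int(d)) for d in doses]
            fh.write("\t".join([sid, str(cohort.phenotype[sid]), *entries]) + "\n")


def read_vcf_as_cohort(
    path,
    phenotype_map: Mapping[str, str],
    risk_allele_map: Mapping[str, str],
) -> GenotypeCohort:
    """Read genotypes from a VCF, oriented to risk-allele doses.

    ``risk_allele_map`` maps each variant id (the VCF ID field, or
    ``chrom:pos`` when absent) to its declared risk allele, which must be
    the site's REF or its single ALT; counting is oriented to that allele
    regardless of polarity. Missing GT becomes a missing dose. Every VCF
    sample must appear in ``phenotype_map``.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - environment guard
        raise ImportError(
            "VCF ingestion requires cyvcf2 (install the 'vcf' extra)"
        ) from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unlabelled = [s for s in samples if s not in phenotype_map]
    if unlabelled:
        raise ValueError(f"samples absent from phenotype map: {unlabelled}")
    columns: dict[str, list[float]] = {}
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if vid not in risk_allele_map:
            raise ValueError(f"no risk allele declared for variant {vid!r}")
        risk = risk_allele_map[vid]
        if len(var.ALT) != 1:
            raise ValueError(
                f"variant {vid!r} is not biallelic (ALT={var.ALT}); "
                "risk allele cannot be resolved"
            )
        if risk == var.ALT[0]:
            orient_alt = True
        elif risk == var.REF:
            orient_alt = False
        else:
            raise ValueError(
                f"variant {vid!r}: risk allele {risk!r} matches neither "
                f"REF {var.REF!r} nor ALT {var.ALT[0]!r}"
            )
        doses = []
        for gt in var.genotypes:
            alleles = gt[:-1]  # trailing element is phasing
            if any(a < 0 for a in alleles):
                doses.append(np.nan)
                continue
            alt_count = sum(1 for a in alleles if a == 1)
            doses.append(float(alt_count if orient_alt else len(alleles) - alt_count))
        columns[vid] = doses
    if not columns:
        raise ValueError(f"{path}: no variant records")
    genotypes = pd.DataFrame(columns, index=samples)
    phenotype = pd.Series([phenotype_map[s] for s in samples], index=samples)
    return GenotypeCohort(genotypes=genotypes, phenotype=phenotype)


def read_weight_config(path) -> list[WeightSpec]:
    """Read a YAML/JSON weight configuration (list of variant weights)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, list) or not data:
        raise ValueError(f"{path}: expected a non-empty list of weight entries")
    specs = []
    for i, entry in enumerate(data):
        try:
            specs.append(
                WeightSpec(
                    variant_id=str(entry["variant_id"]),
                    risk_allele=str(entry["risk_allele"]),
                    or_weight=float(entry["or_weight"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: entry {i}: {exc}") from exc
    return specs


def write_weight_config(weights: Sequence[WeightSpec], path) -> None:
    path = Path(path)
    data = [
        {
            "variant_id": w.variant_id,
            "risk_allele": w.risk_allele,
            "or_weight": w.or_weight,
        }
        for w in weights
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def write_ct_csv(records: Iterable[CtRecord], path) -> None:
    """Write Ct records in the long CSV dialect."""
    rows = []
    for r in records:
        flags = dict(r.clinical_flags)
        base = {
            "sample_id": r.sample_id,
            "phenotype": r.phenotype,
            "genotype_class": r.genotype_class,
        }
        extra = {**flags}
        if r.sledai is not None:
            extra["sledai"] = r.sledai
        for gene, cts in (("target", r.target_cts), ("reference", r.reference_cts)):
            for i, ct in enumerate(cts, start=1):
                rows.append({**base, "gene": gene, "replicate_index": i, "ct": ct, **extra})
    pd.DataFrame(rows).to_csv(path, index=False)


_CT_CORE_LONG = {"sample_id", "phenotype", "genotype_class", "gene", "replicate_index", "ct"}


def read_ct_csv(path) -> list[CtRecord]:
    """Read a Ct table, accepting the long dialect or the wide per-sample form."""
    frame = pd.read_csv(path)
    cols = set(frame.columns)
    if _CT_CORE_LONG <= cols:
        return _ct_records_from_long(frame, Path(path))
    if any(c.startswith("target_ct_") for c in cols):
        return _ct_records_from_wide(frame, Path(path))
    raise ValueError(
        f"{path}: not a recognised Ct table (need long columns "
        f"{sorted(_CT_CORE_LONG)} or wide target_ct_*/reference_ct_* columns)"
    )


def _extras(sample_rows: pd.DataFrame, extra_cols: list[str]):
    flags: dict[str, int] = {}
    sledai = None
    for col in extra_cols:
        vals = sample_rows[col].dropna().unique()
        if len(vals) == 0:
            continue
        if len(vals) > 1:
            raise ValueError(f"column {col!r} is not constant within a sample")
        if col == "sledai":
            sledai = float(vals[0])
        else:
            flags[col] = int(vals[0])
    return flags, sledai


def _ct_records_from_long(frame: pd.DataFrame, path: Path) -> list[CtRecord]:
    extra_cols = [c for c in frame.columns if c not in _CT_CORE_LONG]
    records = []
    for sid, sub in frame.groupby("sample_id", sort=False):
        gene_cts = {}
        for gene in ("target", "reference"):
            sel = sub[sub["gene"] == gene].sort_values("replicate_index")
            if sel.empty:
                raise ValueError(f"{path}: sample {sid!r} has no {gene} replicates")
            gene_cts[gene] = tuple(float(x) for x in sel["ct"])
        flags, sledai = _extras(sub, extra_cols)
        records.append(
            CtRecord(
                sample_id=str(sid),
                phenotype=str(sub["phenotype"].iloc[0]),
                genotype_class=str(sub["genotype_class"].iloc[0]),
                target_cts=gene_cts["target"],
                reference_cts=gene_cts["reference"],
                clinical_flags=flags,
                sledai=sledai,
            )
        )
    return records


def _ct_records_from_wide(frame: pd.DataFrame, path: Path) -> list[CtRecord]:
    required = {"sample_id", "phenotype", "genotype_class"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: wide Ct table must carry columns {sorted(required)}")
    target_cols = sorted(
        (c for c in frame.columns if c.startswith("target_ct_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    ref_cols = sorted(
        (c for c in frame.columns if c.startswith("reference_ct_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    if not target_cols or not ref_cols:
        raise ValueError(f"{path}: wide Ct table needs target_ct_* and reference_ct_* columns")
    extra_cols = [
        c
        for c in frame.columns
        if c not in required and c not in target_cols and c not in ref_cols
    ]
    records = []
    for _, row in frame.iterrows():
        flags, sledai = _extras(row.to_frame().T, extra_cols)
        records.append(
            CtRecord(
                sample_id=str(row["sample_id"]),
                phenotype=str(row["phenotype"]),
                genotype_class=str(row["genotype_class"]),
                target_cts=tuple(float(row[c]) for c in target_cols if pd.notna(row[c])),
                reference_cts=tuple(float(row[c]) for c in ref_cols if pd.notna(row[c])),
                clinical_flags=flags,
                sledai=sledai,
            )
        )
    return records
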