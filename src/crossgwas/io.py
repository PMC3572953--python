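"""Readers and writers for the tab-delimited interchange formats.

All formats are plain TSV with a header row; positions are 1-based and
genotype calls use the inbred additive coding {0, 2} with ``NA`` for
missing.  Writers are deterministic: the same in-memory object always
produces byte-identical files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .emma import SNP_MAP_COLUMNS, GenotypeMatrix
from .errors import ValidationError
from .homology import HOMOLOGY_COLUMNS
from .phenotype import DOSE_RESPONSE_COLUMNS, StrainSummary

SUMMARY_STAT_COLUMNS = [
    "study", "ancestry", "snp_id", "chrom", "pos", "ref_allele", "other_allele",
    "p_two_sided", "effect", "effect_type", "n_samples",
]
ASSOCIATION_COLUMNS = ["snp_id", "chrom", "pos", "maf", "effect", "stat", "p"]
STRAIN_SUMMARY_COLUMNS = ["strain", "slope_mean", "slope_sem", "n_animals"]

_TSV = dict(sep="\t", index=False, na_rep="NA")


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    """SNP-per-row table: ``snp_id chrom pos allele_a allele_b <strain...>``."""
    table = genotypes.snp_map[SNP_MAP_COLUMNS].copy()
    calls = genotypes.calls.T  # SNPs x strains
    for i, strain in enumerate(genotypes.strain_ids):
        col = calls[:, i]
        table[strain] = pd.array(
            [int(v) if np.isfinite(v) else None for v in col], dtype="Int64"
        )
    table.to_csv(path, **_TSV)


def read_genotypes(path) -> GenotypeMatrix:
    table = pd.read_csv(path, sep="\t", na_values="NA", dtype={"chrom": str})
    missing = [c for c in SNP_MAP_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"genotype file missing columns: {missing}")
    strain_ids = [c for c in table.columns if c not in SNP_MAP_COLUMNS]
    calls = table[strain_ids].to_numpy(dtype=float).T
    return GenotypeMatrix(
        strain_ids=strain_ids,
        snp_map=table[SNP_MAP_COLUMNS].reset_index(drop=True),
        calls=calls,
    )


def write_dose_response(table: pd.DataFrame, path) -> None:
    missing = [c for c in DOSE_RESPONSE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"dose-response table missing columns: {missing}")
    table[DOSE_RESPONSE_COLUMNS].to_csv(path, **_TSV)


def read_dose_response(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", na_values="NA",
                        dtype={"strain": str, "sex": str, "animal_id": str})
    missing = [c for c in DOSE_RESPONSE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"dose-response file missing columns: {missing}")
    return table


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    missing = [c for c in SUMMARY_STAT_COLUMNS if c not in stats.columns]
    if missing:
        raise ValidationError(f"summary-stat table missing columns: {missing}")
    stats[SUMMARY_STAT_COLUMNS].to_csv(path, **_TSV)


def read_summary_stats(path) -> pd.DataFrame:
    stats = pd.read_csv(path, sep="\t", na_values="NA",
                        dtype={"study": str, "ancestry": str, "chrom": str})
    missing = [c for c in SUMMARY_STAT_COLUMNS if c not in stats.columns]
    if missing:
        raise ValidationError(f"summary-stat file missing columns: {missing}")
    return stats


def write_homology_map(homology: pd.DataFrame, path) -> None:
    missing = [c for c in HOMOLOGY_COLUMNS if c not in homology.columns]
    if missing:
        raise ValidationError(f"homology map missing columns: {missing}")
    homology[HOMOLOGY_COLUMNS].to_csv(path, **_TSV)


def read_homology_map(path) -> pd.DataFrame:
    homology = pd.read_csv(path, sep="\t", na_values="NA",
                           dtype={"mouse_chrom": str, "human_chrom": str})
    missing = [c for c in HOMOLOGY_COLUMNS if c not in homology.columns]
    if missing:
        raise ValidationError(f"homology file missing columns: {missing}")
    return homology


def write_strain_summaries(summaries: list[StrainSummary], path) -> None:
    table = pd.DataFrame(
        [
            {"strain": s.strain, "slope_mean": s.slope_mean,
             "slope_sem": s.slope_sem, "n_animals": s.n_animals}
            for s in summaries
        ],
        columns=STRAIN_SUMMARY_COLUMNS,
    )
    table.to_csv(path, **_TSV)


def read_strain_summaries(path) -> list[StrainSummary]:
    table = pd.read_csv(path, sep="\t", na_values="NA", dtype={"strain": str})
    return [
        StrainSummary(strain=row.strain, slope_mean=float(row.slope_mean),
                      slope_sem=float(row.slope_sem), n_animals=int(row.n_animals))
        for row in table.itertuples(index=False)
    ]


def write_association(assoc: pd.DataFrame, path) -> None:
    cols = [c for c in ASSOCIATION_COLUMNS + ["df", "flag"] if c in assoc.columns]
    missing = [c for c in ASSOCIATION_COLUMNS if c not in assoc.columns]
    if missing:
        raise ValidationError(f"association table missing columns: {missing}")
    assoc[cols].to_csv(path, **_TSV)


def read_association(path) -> pd.DataFrame:
    assoc = pd.read_csv(path, sep="\t", na_values="NA", dtype={"chrom": str})
    missing = [c for c in ASSOCIATION_COLUMNS if c not in assoc.columns]
    if missing:
        raise ValidationError(f"association file missing columns: {missing}")
    return assoc
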