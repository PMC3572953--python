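"""Screening of human GWAS summary statistics over ortholog gene windows.

A gene becomes a candidate when any ancestry/study stream contains a SNP
with p strictly below the screening threshold inside the gene window.  The
published follow-up criteria -- phenotype/genotype concordance across
strains, a minor-allele count bound on the supporting mouse SNPs, and
regional multi-SNP support -- are made explicit and quantitative here so
they can be tested and reused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pointbiserialr

from .errors import ValidationError
from .homology import GeneInterval
from .phenotype import StrainSummary

__all__ = [
    "CandidateGene",
    "screen_candidates",
    "mouse_maf_filter",
    "concordance_score",
    "regional_support",
]


@dataclass
class CandidateGene:
    """A human gene surviving the summary-statistic screen."""

    gene_id: str
    support_streams: list[str]
    min_p: float
    min_p_snp: str
    min_p_stream: str
    n_snps_in_window: int
    stream_min_p: dict = field(default_factory=dict)
    maf_pass: bool | None = None
    concordance: float | None = None
    concordance_rank_p: float | None = None
    regional_support_mouse: int | None = None
    regional_support_human: int | None = None


def _stream_label(study: str, ancestry: str) -> str:
    return f"{study}:{ancestry}" if ancestry else str(study)


def screen_candidates(
    stats: pd.DataFrame,
    ortholog_genes: list[GeneInterval],
    p_threshold: float = 1e-3,
    window_bp: int = 50_000,
) -> list[CandidateGene]:
    """Select genes with any sub-threshold SNP in any ancestry stream.

    ``stats`` is a long table with columns ``study ancestry snp_id chrom pos
    p_two_sided``; each distinct (study, ancestry) pair is an independent
    screen and streams are combined by union.  Selection uses strict
    ``p < p_threshold`` and a boundary-inclusive window of ``window_bp``
    around the gene body.
    """
    if not (0 < p_threshold <= 1):
        raise ValidationError(f"p_threshold must be in (0, 1], got {p_threshold}")
    if window_bp < 0:
        raise ValidationError(f"window_bp must be >= 0, got {window_bp}")
    chrom = stats["chrom"].astype(str).to_numpy()
    pos = stats["pos"].to_numpy(dtype=np.int64)
    p = stats["p_two_sided"].to_numpy(dtype=float)
    streams = np.array(
        [_stream_label(s, a) for s, a in zip(stats["study"], stats.get("ancestry", ""))]
    )
    snp_ids = stats["snp_id"].to_numpy()

    candidates: list[CandidateGene] = []
    n_zero_coverage = 0
    for gene in ortholog_genes:
        in_window = (
            (chrom == gene.chrom)
            & (pos >= gene.start - window_bp)
            & (pos <= gene.end + window_bp)
        )
        n_in_window = int(in_window.sum())
        if n_in_window == 0:
            n_zero_coverage += 1
            continue
        hit = in_window & (p < p_threshold) & np.isfinite(p)
        if not hit.any():
            continue
        support = sorted(set(streams[hit]))
        stream_min = {
            s: float(np.min(p[hit & (streams == s)])) for s in support
        }
        best = int(np.argmin(np.where(hit, p, np.inf)))
        candidates.append(
            CandidateGene(
                gene_id=gene.gene_id,
                support_streams=support,
                min_p=float(p[best]),
                min_p_snp=str(snp_ids[best]),
                min_p_stream=str(streams[best]),
                n_snps_in_window=n_in_window,
                stream_min_p=stream_min,
            )
        )
    if n_zero_coverage == len(ortholog_genes) and ortholog_genes:
        warnings.warn("no summary-statistic SNPs fall in any gene window")
    return candidates


def mouse_maf_filter(
    assoc: pd.DataFrame,
    region: GeneInterval,
    *,
    p_threshold: float = 1e-3,
    min_count: int = 2,
    n_strains: int = 31,
    window_bp: int = 0,
) -> bool | None:
    """Check that every supporting mouse SNP clears the minor-allele bound.

    True iff every SNP in the region (gene body +/- ``window_bp``) with
    ``p < p_threshold`` has minor-allele strain count strictly greater than
    ``min_count`` out of ``n_strains``.  Returns None (indeterminate, with a
    warning) when the region contains no mouse SNPs.
    """
    chrom = assoc["chrom"].astype(str).to_numpy()
    pos = assoc["pos"].to_numpy(dtype=np.int64)
    in_region = (
        (chrom == region.chrom)
        & (pos >= region.start - window_bp)
        & (pos <= region.end + window_bp)
    )
    if not in_region.any():
        warnings.warn(f"region {region.gene_id!r} contains no mouse SNPs; MAF filter indeterminate")
        return None
    sub = assoc.loc[in_region]
    supporting = sub.loc[sub["p"] < p_threshold]
    if supporting.empty:
        return True
    counts = np.rint(supporting["maf"].to_numpy(dtype=float) * n_strains).astype(int)
    return bool(np.all(counts > min_count))


def concordance_score(
    strain_summaries: list[StrainSummary],
    genotypes_at_snp: dict,
) -> tuple[float, float]:
    """Phenotype/genotype concordance across strains at one SNP.

    Returns the point-biserial correlation between genotype class (0 vs 2)
    and strain mean slope, plus a Wilcoxon rank-sum (Mann-Whitney) p-value
    between the two classes.  Requires at least 2 strains per class.
    """
    slopes, classes = [], []
    for summary in strain_summaries:
        if summary.strain not in genotypes_at_snp:
            continue
        call = genotypes_at_snp[summary.strain]
        if call is None or (isinstance(call, float) and np.isnan(call)):
            continue
        if call not in (0, 2, 0.0, 2.0):
            raise ValidationError(f"non-inbred call {call!r} for strain {summary.strain!r}")
        slopes.append(summary.slope_mean)
        classes.append(int(call) // 2)
    slopes_arr = np.asarray(slopes, dtype=float)
    classes_arr = np.asarray(classes, dtype=int)
    n0 = int(np.sum(classes_arr == 0))
    n1 = int(np.sum(classes_arr == 1))
    if n0 == 0 or n1 == 0:
        raise ValidationError("SNP is monomorphic across summarized strains")
    if n0 < 2 or n1 < 2:
        raise ValidationError("need >=2 strains per genotype class for concordance")
    if np.all(slopes_arr == slopes_arr[0]):
        return 0.0, 1.0
    r, _ = pointbiserialr(classes_arr, slopes_arr)
    group0 = slopes_arr[classes_arr == 0]
    group1 = slopes_arr[classes_arr == 1]
    if np.array_equal(np.sort(group0), np.sort(group1)):
        return float(r) if np.isfinite(r) else 0.0, 1.0
    rank = mannwhitneyu(group0, group1, alternative="two-sided")
    return float(r), float(rank.pvalue)


def regional_support(
    p_values,
    p_threshold: float,
) -> int:
    """Number of SNPs with p strictly below ``p_threshold`` in one region."""
    if not (0 <= p_threshold <= 1):
        raise ValidationError(f"p_threshold must be in [0, 1], got {p_threshold}")
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return 0
    return int(np.sum(p[np.isfinite(p)] < p_threshold))


def region_passes(
    mouse_count: int, human_count: int, *, min_snps: int = 2
) -> bool:
    """Regional-LD support rule: both species need >= ``min_snps`` sub-threshold SNPs."""
    return mouse_count >= min_snps and human_count >= min_snps
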