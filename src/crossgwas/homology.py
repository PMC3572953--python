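"""Gene-window annotation of association hits and mouse-to-human ortholog mapping.

Coordinates are 1-based inclusive throughout the external interfaces;
intervals printed in descending order (minus-strand genes) are normalized on
construction.  Window distance is measured from the SNP position to the
nearest gene edge, with the window boundary inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

HOMOLOGY_COLUMNS = [
    "mouse_gene", "mouse_chrom", "mouse_start", "mouse_end",
    "human_gene", "human_chrom", "human_start", "human_end",
]

__all__ = [
    "GeneInterval",
    "OrthologResult",
    "genes_near_snps",
    "map_orthologs",
    "gene_span_kb",
    "homology_to_intervals",
]


@dataclass(frozen=True)
class GeneInterval:
    """A gene locus; ``start <= end`` is enforced by normalizing on init."""

    gene_id: str
    species: str  # "mouse" or "human"
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.species not in ("mouse", "human"):
            raise ValidationError(f"species must be 'mouse' or 'human', got {self.species!r}")
        if self.start < 0 or self.end < 0:
            raise ValidationError(f"negative coordinate in gene {self.gene_id!r}")
        if self.strand not in ("+", "-", "unknown"):
            raise ValidationError(f"strand must be '+', '-' or 'unknown', got {self.strand!r}")
        if self.start > self.end:  # printed descending: normalize
            start, end = self.end, self.start
            object.__setattr__(self, "start", start)
            object.__setattr__(self, "end", end)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def distance_to(self, pos: int) -> int:
        """0 inside [start, end], base-pair gap to the nearest edge otherwise."""
        if pos < self.start:
            return self.start - pos
        if pos > self.end:
            return pos - self.end
        return 0


@dataclass
class OrthologResult:
    """Human intervals for mapped mouse genes plus genes dropped as unmapped."""

    human_genes: list[GeneInterval]
    dropped: list[str] = field(default_factory=list)
    pairs: list[tuple[str, str]] = field(default_factory=list)  # (mouse, human)


def genes_near_snps(
    assoc: pd.DataFrame,
    genes: list[GeneInterval],
    p_threshold: float,
    window_bp: int,
) -> set[str]:
    """Gene ids with at least one SNP at p < ``p_threshold`` (strict) within
    ``window_bp`` of the gene body (boundary inclusive; distance 0 inside).

    ``assoc`` needs columns ``chrom pos p``.  Raises if the chromosome label
    vocabularies of the two inputs are disjoint (e.g. 'chr1' vs '1').
    """
    if window_bp < 0:
        raise ValidationError(f"window_bp must be >= 0, got {window_bp}")
    if not (0 < p_threshold <= 1):
        raise ValidationError(f"p_threshold must be in (0, 1], got {p_threshold}")
    if not genes:
        return set()
    snp_chroms = set(assoc["chrom"].astype(str))
    gene_chroms = {g.chrom for g in genes}
    if snp_chroms and not (snp_chroms & gene_chroms):
        raise ValidationError(
            "no shared chromosome labels between SNPs and genes: "
            f"SNP labels {sorted(snp_chroms)[:5]} vs gene labels {sorted(gene_chroms)[:5]}"
        )
    hits = assoc.loc[assoc["p"] < p_threshold]
    selected: set[str] = set()
    for chrom, grp in hits.groupby(hits["chrom"].astype(str)):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        for g in genes:
            if g.chrom != chrom or g.gene_id in selected:
                continue
            near = (pos >= g.start - window_bp) & (pos <= g.end + window_bp)
            if near.any():
                selected.add(g.gene_id)
    return selected


def homology_to_intervals(homology: pd.DataFrame) -> list[tuple[GeneInterval, GeneInterval]]:
    """Parse a homology-map table into (mouse, human) interval pairs."""
    missing = [c for c in HOMOLOGY_COLUMNS if c not in homology.columns]
    if missing:
        raise ValidationError(f"homology map missing columns: {missing}")
    pairs = []
    seen: set[tuple] = set()
    for row in homology.itertuples(index=False):
        key = (row.mouse_gene, row.human_gene)
        if key in seen:
            continue  # no exact duplicate pairs
        seen.add(key)
        mouse = GeneInterval(str(row.mouse_gene), "mouse", str(row.mouse_chrom),
                             int(row.mouse_start), int(row.mouse_end))
        human = GeneInterval(str(row.human_gene), "human", str(row.human_chrom),
                             int(row.human_start), int(row.human_end))
        pairs.append((mouse, human))
    return pairs


def map_orthologs(mouse_genes: set[str], homology: pd.DataFrame) -> OrthologResult:
    """Human ortholog intervals for a set of mouse gene ids.

    One-to-many homology is retained in full.  Query genes absent from the
    map are returned in ``dropped`` (reason: no ortholog).
    """
    pairs = homology_to_intervals(homology) if len(homology) else []
    if not pairs:
        warnings.warn("empty homology map: no orthologs can be assigned")
    human: list[GeneInterval] = []
    mapped_pairs: list[tuple[str, str]] = []
    matched: set[str] = set()
    seen_human: set[tuple] = set()
    for mouse_iv, human_iv in pairs:
        if mouse_iv.gene_id in mouse_genes:
            matched.add(mouse_iv.gene_id)
            mapped_pairs.append((mouse_iv.gene_id, human_iv.gene_id))
            key = (human_iv.gene_id, human_iv.chrom, human_iv.start, human_iv.end)
            if key not in seen_human:
                seen_human.add(key)
                human.append(human_iv)
    dropped = sorted(mouse_genes - matched)
    return OrthologResult(human_genes=human, dropped=dropped, pairs=mapped_pairs)


def gene_span_kb(interval_as_printed: tuple[float, float]) -> float:
    """Genomic span in kb of a printed coordinate pair, normalizing order."""
    a, b = interval_as_printed
    if a < 0 or b < 0:
        raise ValidationError(f"negative coordinate in ({a}, {b})")
    return abs(a - b) / 1000.0
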