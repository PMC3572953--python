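"""Direction-aware replication testing and cross-study combination of evidence.

Replication studies are tested with one-sided alternatives fixed by the
effect direction in a reference (discovery) study, so that effects in
opposite directions cannot produce inappropriately small p-values:
p_one = p_two / 2 when directions agree, 1 - p_two / 2 otherwise.  Evidence
is combined with Fisher's method, X^2 = -2 sum(ln p_i) against chi-square
with 2k degrees of freedom, dropping unavailable studies and reducing the
degrees of freedom accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .errors import HarmonizationError, ValidationError
from .utils import format_sig

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

__all__ = [
    "DirectionReference",
    "MetaResult",
    "HarmonizedRecord",
    "harmonize_alleles",
    "one_sided_p",
    "fisher_combine",
    "weighted_z_meta",
    "build_table",
]


@dataclass(frozen=True)
class DirectionReference:
    """Effect direction of the discovery study at one SNP.

    ``direction`` is +1 if the reference allele is risk-increasing
    (OR > 1 / beta > 0) in the reference study, -1 otherwise.
    """

    snp_id: str
    study: str
    reference_allele: str
    direction: int

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValidationError(f"direction must be +1 or -1, got {self.direction}")
        if self.reference_allele not in COMPLEMENT:
            raise ValidationError(f"invalid allele {self.reference_allele!r}")


@dataclass
class MetaResult:
    """Fisher combination of per-study p-values for one SNP."""

    snp_id: str
    study_labels: list[str]
    p_values: list[float]
    n_studies_used: int
    fisher_chi2: float
    df: int
    combined_p: float
    log10_combined_p: float  # always finite; combined_p may underflow to 0.0


@dataclass
class HarmonizedRecord:
    """A study record re-oriented to the reference study's allele."""

    snp_id: str
    effect: float
    effect_type: str
    p_two_sided: float
    flipped: bool
    ambiguous: bool  # A/T or C/G SNP: strand cannot be resolved from alleles

    @property
    def direction(self) -> int:
        """Sign of the (oriented) effect: +1 risk-increasing, -1 protective."""
        value = math.log(self.effect) if self.effect_type == "OR" else self.effect
        if value == 0:
            raise ValidationError(f"effect direction undefined (null effect) at {self.snp_id}")
        return 1 if value > 0 else -1


def _is_ambiguous(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def harmonize_alleles(
    snp_id: str,
    ref_allele: str,
    other_allele: str,
    effect: float,
    effect_type: str,
    reference: DirectionReference,
) -> HarmonizedRecord:
    """Orient a study's effect to the reference study's reference allele.

    Matching tries, in order: identical alleles; swapped alleles (effect
    flipped, OR -> 1/OR, beta -> -beta); strand-complement alleles;
    strand-complement swapped (flipped once).  A/T and C/G SNPs are flagged
    ambiguous (complement equals swap, so strand is unresolvable) and kept
    in as-printed orientation via the exact-match rule.
    """
    if reference.snp_id != snp_id:
        raise ValidationError(
            f"snp_id mismatch: record {snp_id!r} vs reference {reference.snp_id!r}"
        )
    if effect_type not in ("OR", "beta"):
        raise ValidationError(f"effect_type must be 'OR' or 'beta', got {effect_type!r}")
    if effect_type == "OR" and effect <= 0:
        raise ValidationError(f"odds ratio must be > 0, got {effect}")
    for allele in (ref_allele, other_allele):
        if allele not in COMPLEMENT:
            raise HarmonizationError(f"invalid allele {allele!r} at {snp_id}")
    target = reference.reference_allele
    ambiguous = _is_ambiguous(ref_allele, other_allele)

    if ref_allele == target:
        flipped = False
    elif other_allele == target:
        flipped = True
    elif COMPLEMENT[ref_allele] == target:
        flipped = False
    elif COMPLEMENT[other_allele] == target:
        flipped = True
    else:
        raise HarmonizationError(
            f"alleles irreconcilable at {snp_id}: study ({ref_allele}/{other_allele}) "
            f"vs reference allele {target}"
        )
    if flipped:
        effect = 1.0 / effect if effect_type == "OR" else -effect
    return HarmonizedRecord(
        snp_id=snp_id,
        effect=effect,
        effect_type=effect_type,
        p_two_sided=np.nan,
        flipped=flipped,
        ambiguous=ambiguous,
    )


def one_sided_p(p_two: float, study_direction: int, reference_direction: int) -> float:
    """Convert a two-sided p to a one-sided p against the reference direction."""
    if not (0 < p_two <= 1):
        raise ValidationError(f"two-sided p must be in (0, 1], got {p_two}")
    if study_direction not in (+1, -1) or reference_direction not in (+1, -1):
        raise ValidationError("both directions must be +1 or -1")
    if study_direction == reference_direction:
        return p_two / 2.0
    return 1.0 - p_two / 2.0


def _log_chi2_sf_even_df(x: float, df: int) -> float:
    """log of the chi-square upper tail for even df, exact in log space.

    For df = 2k the survival function is exp(-x/2) * sum_{j<k} (x/2)^j / j!,
    which stays computable long after ``chi2.sf`` underflows.
    """
    if df % 2 != 0 or df <= 0:
        raise ValidationError(f"df must be a positive even integer, got {df}")
    if x <= 0:
        return 0.0
    k = df // 2
    j = np.arange(k)
    terms = j * math.log(x / 2.0) - gammaln(j + 1)
    return float(-x / 2.0 + logsumexp(terms))


def fisher_combine(
    p_list,
    *,
    snp_id: str = "",
    study_labels: list[str] | None = None,
    allow_missing: bool = True,
) -> MetaResult:
    """Fisher's combined probability test over available studies.

    X^2 = -2 sum(ln p_i) is referred to a chi-square with 2k degrees of
    freedom over the k non-missing p-values; the tail probability is
    computed on log scale so extreme inputs do not underflow.
    """
    p_arr = [np.nan if p is None else float(p) for p in p_list]
    labels = study_labels or [f"study{i+1}" for i in range(len(p_arr))]
    if len(labels) != len(p_arr):
        raise ValidationError("study_labels length must match p_list")
    kept_p, kept_labels = [], []
    for p, lab in zip(p_arr, labels):
        if np.isnan(p):
            if not allow_missing:
                raise ValidationError(f"missing p for {lab} with allow_missing=False")
            continue
        if p == 0:
            raise ValidationError(f"p = 0 for {lab}: log undefined")
        if not (0 < p <= 1):
            raise ValidationError(f"p must be in (0, 1], got {p} for {lab}")
        kept_p.append(p)
        kept_labels.append(lab)
    if not kept_p:
        raise ValidationError("no non-missing p-values to combine")
    k = len(kept_p)
    stat = float(-2.0 * np.sum(np.log(kept_p)))
    df = 2 * k
    log_p = _log_chi2_sf_even_df(stat, df)
    return MetaResult(
        snp_id=snp_id,
        study_labels=kept_labels,
        p_values=kept_p,
        n_studies_used=k,
        fisher_chi2=stat,
        df=df,
        combined_p=float(np.exp(log_p)),
        log10_combined_p=log_p / math.log(10.0),
    )


def weighted_z_meta(z_list, n_list) -> tuple[float, float]:
    """Sample-size weighted z-score meta-analysis.

    Z = sum(sqrt(n_i) z_i) / sqrt(sum n_i), with a two-sided standard-normal
    p-value.
    """
    z = np.asarray(z_list, dtype=float)
    n = np.asarray(n_list, dtype=float)
    if z.size == 0:
        raise ValidationError("no studies supplied")
    if z.shape != n.shape:
        raise ValidationError("z_list and n_list lengths differ")
    if np.any(n <= 0):
        raise ValidationError("all sample sizes must be > 0")
    Z = float(np.sum(np.sqrt(n) * z) / np.sqrt(np.sum(n)))
    p = float(2.0 * norm.sf(abs(Z)))
    return Z, p


def build_table(
    snp_ids: list[str],
    stats: pd.DataFrame,
    reference_study: str,
    *,
    nominal_alpha: float = 0.05,
    min_nominal: int = 3,
) -> pd.DataFrame:
    """Assemble a replication report table over candidate SNPs.

    ``stats`` is a long summary-statistic table (columns ``study snp_id
    chrom pos ref_allele other_allele p_two_sided effect effect_type
    n_samples``).  The reference study's p enters as reported (two-sided);
    every other study's p is converted to one-sided using its harmonized
    effect direction versus the reference direction.  Per SNP the row holds
    each study's p, the Fisher combined p over available studies, a
    per-study lowest-p flag, and a flag for nominally significant p <
    ``nominal_alpha`` in at least ``min_nominal`` studies.
    """
    studies = list(dict.fromkeys(stats["study"]))
    if reference_study not in studies:
        raise ValidationError(f"reference study {reference_study!r} absent from stats")
    ordered = [reference_study] + [s for s in studies if s != reference_study]
    by_study = {s: stats[stats["study"] == s].set_index("snp_id") for s in ordered}

    rows = []
    for snp in snp_ids:
        row: dict = {"snp_id": snp}
        ref_rows = by_study[reference_study]
        if snp not in ref_rows.index:
            row.update({f"p_{s}": np.nan for s in ordered})
            row.update({"p_combined": np.nan, "n_studies": 0, "flags": "no_reference"})
            rows.append(row)
            continue
        ref = ref_rows.loc[snp]
        row["chrom"] = ref["chrom"]
        row["pos"] = int(ref["pos"])
        row["a1"] = ref["ref_allele"]
        row["a2"] = ref["other_allele"]
        ref_effect = math.log(ref["effect"]) if ref["effect_type"] == "OR" else ref["effect"]
        ref_direction = 1 if ref_effect > 0 else -1
        reference = DirectionReference(
            snp_id=snp, study=reference_study,
            reference_allele=str(ref["ref_allele"]), direction=ref_direction,
        )
        p_per_study: list[float] = []
        for study in ordered:
            sub = by_study[study]
            if snp not in sub.index:
                row[f"p_{study}"] = np.nan
                p_per_study.append(np.nan)
                continue
            rec = sub.loc[snp]
            if study == reference_study:
                p_val = float(rec["p_two_sided"])
            else:
                harmonized = harmonize_alleles(
                    snp, str(rec["ref_allele"]), str(rec["other_allele"]),
                    float(rec["effect"]), str(rec["effect_type"]), reference,
                )
                harmonized.p_two_sided = float(rec["p_two_sided"])
                p_val = one_sided_p(
                    harmonized.p_two_sided, harmonized.direction, ref_direction
                )
            row[f"p_{study}"] = p_val
            p_per_study.append(p_val)
        result = fisher_combine(p_per_study, snp_id=snp, study_labels=ordered)
        row["p_combined"] = result.combined_p
        row["n_studies"] = result.n_studies_used
        n_nominal = int(np.nansum(np.array(p_per_study) < nominal_alpha))
        row["nominal_replications"] = n_nominal
        flags = []
        if n_nominal >= min_nominal:
            flags.append(f"nominal_{min_nominal}of{len(ordered)}")
        row["flags"] = ";".join(flags)
        rows.append(row)
    table = pd.DataFrame(rows)
    # mark the lowest p per study (the bolded entries of the report style)
    for study in ordered:
        col = f"p_{study}"
        if col in table.columns and table[col].notna().any():
            table[f"lowest_{study}"] = table[col] == table[col].min()
    return table


def render_p(p: float) -> str:
    """Report-style rendering of a p-value at 2 significant figures."""
    return format_sig(p, 2) if np.isfinite(p) else "-"
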