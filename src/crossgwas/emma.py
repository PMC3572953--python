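"""Mixed-model strain-survey association with kinship-based structure control.

The model for a phenotype vector ``y`` over inbred strains is

    y = X beta + u + eps,   Var(u) = sigma_g^2 * K,   Var(eps) = sigma_e^2 * I,

with ``K`` a strain-by-strain similarity matrix.  The single variance ratio
``delta = sigma_e^2 / sigma_g^2`` is profiled out by restricted maximum
likelihood on the eigenvalues of the projected kinship, after which each SNP
is tested by generalized least squares with a t statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.stats import chi2, t as t_dist

from .errors import DegenerateFitError, ValidationError

SNP_MAP_COLUMNS = ["snp_id", "chrom", "pos", "allele_a", "allele_b"]

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "VarianceComponents",
    "FilterResult",
    "filter_snps",
    "compute_kinship",
    "reml_fit",
    "snp_association",
    "bonferroni_threshold",
    "genomic_inflation",
]


@dataclass
class GenotypeMatrix:
    """Strains x SNPs additive genotype calls for an inbred panel.

    ``calls`` uses the additive coding {0, 2} with ``nan`` for missing; the
    heterozygote code 1 is reserved but never produced for inbred strains.
    ``snp_map`` has columns ``snp_id chrom pos allele_a allele_b`` with
    1-based positions, chromosome-contiguous and position-sorted.
    """

    strain_ids: list[str]
    snp_map: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        self.snp_map = self.snp_map.reset_index(drop=True)
        if self.calls.ndim != 2:
            raise ValidationError("calls must be a 2-D strains x SNPs array")
        n_strains, n_snps = self.calls.shape
        if n_strains != len(self.strain_ids):
            raise ValidationError(
                f"calls has {n_strains} rows but {len(self.strain_ids)} strain ids"
            )
        if n_snps != len(self.snp_map):
            raise ValidationError(
                f"calls has {n_snps} columns but snp_map has {len(self.snp_map)} rows"
            )
        missing = [c for c in SNP_MAP_COLUMNS if c not in self.snp_map.columns]
        if missing:
            raise ValidationError(f"snp_map missing columns: {missing}")
        if self.snp_map["snp_id"].duplicated().any():
            dups = self.snp_map.loc[self.snp_map["snp_id"].duplicated(), "snp_id"]
            raise ValidationError(f"duplicate snp_ids: {sorted(set(dups))[:5]}")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 2.0))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValidationError(f"genotype calls must be 0, 2 or missing; found {bad}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        chroms = self.snp_map["chrom"].astype(str).to_numpy()
        pos = self.snp_map["pos"].to_numpy()
        seen: set[str] = set()
        prev_chrom: str | None = None
        for i, c in enumerate(chroms):
            if c != prev_chrom:
                if c in seen:
                    raise ValidationError(f"snp_map chromosome {c!r} is not contiguous")
                seen.add(c)
                prev_chrom = c
            elif pos[i] < pos[i - 1]:
                raise ValidationError(
                    f"snp_map positions not sorted on chromosome {c!r} at row {i}"
                )

    @property
    def n_strains(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def minor_allele_counts(self) -> np.ndarray:
        """Number of non-missing strains carrying the minor allele, per SNP."""
        n_alt = np.nansum(self.calls == 2.0, axis=0)
        n_ref = np.nansum(self.calls == 0.0, axis=0)
        return np.minimum(n_alt, n_ref).astype(int)

    def maf(self) -> np.ndarray:
        """Strain-level minor allele fraction per SNP (nan if fully missing)."""
        n_alt = np.nansum(self.calls == 2.0, axis=0).astype(float)
        n_obs = np.sum(~np.isnan(self.calls), axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = n_alt / n_obs
        return np.where(np.isnan(freq), np.nan, np.minimum(freq, 1.0 - freq))

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            strain_ids=list(self.strain_ids),
            snp_map=self.snp_map.loc[np.asarray(mask)].reset_index(drop=True),
            calls=self.calls[:, np.asarray(mask)],
        )


@dataclass
class KinshipMatrix:
    """Symmetric PSD strain similarity matrix with unit diagonal."""

    strain_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.strain_ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"kinship shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("kinship matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise ValidationError("kinship diagonal must be exactly 1")
        eigmin = float(np.min(linalg.eigvalsh(self.values)))
        if eigmin < -1e-8:
            raise ValidationError(f"kinship not positive semidefinite (min eig {eigmin:.3g})")


@dataclass
class VarianceComponents:
    """REML variance components of the single-kinship mixed model."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    reml_loglik: float

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValidationError("variance components must be non-negative")

    @property
    def heritability(self) -> float:
        total = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / total if total > 0 else float("nan")


@dataclass
class FilterResult:
    genotypes: GenotypeMatrix
    n_monomorphic: int
    n_singleton: int
    n_kept: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_kept = self.genotypes.n_snps


def filter_snps(genotypes: GenotypeMatrix) -> FilterResult:
    """Drop monomorphic SNPs and SNPs whose minor allele is in a single strain."""
    if genotypes.n_snps == 0 or genotypes.n_strains == 0:
        raise ValidationError("cannot filter an empty genotype matrix")
    counts = genotypes.minor_allele_counts()
    monomorphic = counts == 0
    singleton = counts == 1
    keep = ~(monomorphic | singleton)
    return FilterResult(
        genotypes=genotypes.subset_snps(keep),
        n_monomorphic=int(monomorphic.sum()),
        n_singleton=int(singleton.sum()),
    )


def compute_kinship(genotypes: GenotypeMatrix, method: str = "ibs") -> KinshipMatrix:
    """Strain kinship from genotypes.

    ``method='ibs'`` (default): entry (i, j) is the mean identity-by-state
    sharing over SNPs non-missing in both strains -- 1 where calls agree,
    0 where they differ (inbred coding), so the diagonal is exactly 1.
    ``method='standardized'`` centres and scales each SNP by its allele
    frequency before forming the cross-product, then rescales to unit
    diagonal.
    """
    calls = genotypes.calls
    obs = ~np.isnan(calls)
    overlap = obs.astype(float) @ obs.astype(float).T
    if np.any(overlap == 0):
        i, j = np.argwhere(overlap == 0)[0]
        raise ValidationError(
            f"strains {genotypes.strain_ids[i]!r} and {genotypes.strain_ids[j]!r} "
            "share no genotyped SNPs"
        )
    if method == "ibs":
        is_ref = np.where(obs, calls == 0.0, False).astype(float)
        is_alt = np.where(obs, calls == 2.0, False).astype(float)
        matches = is_ref @ is_ref.T + is_alt @ is_alt.T
        k = matches / overlap
        np.fill_diagonal(k, 1.0)
    elif method == "standardized":
        freq = np.nansum(calls, axis=0) / (2.0 * obs.sum(axis=0))
        sd = np.sqrt(np.clip(2.0 * freq * (1.0 - freq), 1e-12, None))
        z = np.where(obs, (calls - 2.0 * freq) / sd, 0.0)
        k = (z @ z.T) / overlap
        d = np.sqrt(np.clip(np.diag(k), 1e-12, None))
        k = k / np.outer(d, d)
        np.fill_diagonal(k, 1.0)
    else:
        raise ValidationError(f"unknown kinship method {method!r}")
    # clip tiny negative eigenvalues from finite-SNP noise
    w, v = linalg.eigh((k + k.T) / 2.0)
    if w.min() < 0:
        w = np.clip(w, 0.0, None)
        k = (v * w) @ v.T
        d = np.sqrt(np.clip(np.diag(k), 1e-12, None))
        k = k / np.outer(d, d)
        np.fill_diagonal(k, 1.0)
    return KinshipMatrix(strain_ids=list(genotypes.strain_ids), values=(k + k.T) / 2.0)


def _projected_spectrum(y: np.ndarray, X: np.ndarray, K: np.ndarray):
    """Eigen-spectrum of the kinship projected off the fixed effects.

    Returns ``(lam, eta, n, q)`` where ``lam`` are the n - q informative
    eigenvalues of S K S (S the residual-forming projector of X) and ``eta``
    the rotated error contrasts of ``y``.
    """
    n = len(y)
    q = np.linalg.matrix_rank(X)
    if q != X.shape[1]:
        raise ValidationError("design matrix X is rank deficient")
    xtx_inv = linalg.inv(X.T @ X)
    S = np.eye(n) - X @ xtx_inv @ X.T
    w, v = linalg.eigh(S @ K @ S)
    order = np.argsort(w)[::-1]
    lam = w[order][: n - q]
    U = v[:, order][:, : n - q]
    lam = np.clip(lam, 0.0, None)
    eta = U.T @ y
    return lam, eta, n, q


def _reml_loglik(log_delta: float, lam: np.ndarray, eta: np.ndarray, nq: int) -> float:
    delta = np.exp(log_delta)
    denom = lam + delta
    rss = float(np.sum(eta**2 / denom))
    return 0.5 * (
        nq * (np.log(nq / (2.0 * np.pi)) - 1.0 - np.log(rss)) - float(np.sum(np.log(denom)))
    )


def _reml_dloglik(log_delta: float, lam: np.ndarray, eta: np.ndarray, nq: int) -> float:
    """Derivative of the restricted log-likelihood wrt log(delta)."""
    delta = np.exp(log_delta)
    denom = lam + delta
    s1 = float(np.sum(eta**2 / denom))
    s2 = float(np.sum(eta**2 / denom**2))
    s3 = float(np.sum(1.0 / denom))
    return 0.5 * delta * (nq * s2 / s1 - s3)


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    *,
    n_grid: int = 100,
    log_delta_bounds: tuple[float, float] = (-10.0, 10.0),
) -> VarianceComponents:
    """REML fit of the variance ratio delta = sigma_e^2 / sigma_g^2.

    The restricted likelihood is evaluated on a grid over ln(delta); every
    sign change of its derivative is refined by a bracketed root search and
    the global optimum over all candidates (including the bounds) is
    returned.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    if np.min(linalg.eigvalsh((Kv + Kv.T) / 2.0)) < -1e-8:
        raise ValidationError("kinship matrix is not positive semidefinite")
    lam, eta, n, q = _projected_spectrum(y, X, Kv)
    nq = n - q
    if nq < 2:
        raise DegenerateFitError("need at least 2 error contrasts for REML")
    if np.sum(eta**2) < 1e-12 * max(1.0, float(np.sum(y**2))):
        raise DegenerateFitError("phenotype is constant after projection; fit degenerate")

    lo, hi = log_delta_bounds
    grid = np.linspace(lo, hi, n_grid)
    # vectorized derivative over the whole grid (one pass, no python loop)
    deltas = np.exp(grid)[:, None]
    denom = lam[None, :] + deltas
    eta2 = eta**2
    s1 = (eta2 / denom).sum(axis=1)
    s2 = (eta2 / denom**2).sum(axis=1)
    s3 = (1.0 / denom).sum(axis=1)
    dvals = 0.5 * deltas[:, 0] * (nq * s2 / s1 - s3)
    candidates = [lo, hi]
    for i in range(n_grid - 1):
        if dvals[i] == 0.0:
            candidates.append(float(grid[i]))
        elif np.sign(dvals[i]) != np.sign(dvals[i + 1]):
            try:
                root = optimize.brentq(
                    _reml_dloglik, grid[i], grid[i + 1], args=(lam, eta, nq), xtol=1e-10
                )
                candidates.append(float(root))
            except ValueError:  # pragma: no cover - defensive
                candidates.append(float(grid[i]))
    lls = [_reml_loglik(c, lam, eta, nq) for c in candidates]
    best = int(np.argmax(lls))
    log_delta = candidates[best]
    delta = float(np.exp(log_delta))
    sigma_g2 = float(np.sum(eta**2 / (lam + delta)) / nq)
    sigma_e2 = delta * sigma_g2
    return VarianceComponents(
        sigma_g2=sigma_g2, sigma_e2=sigma_e2, delta=delta, reml_loglik=float(lls[best])
    )


def _gls_snp_test(
    y: np.ndarray, Xj: np.ndarray, Kv: np.ndarray, delta: float
) -> tuple[float, float, float, int]:
    """GLS t-test of the last column of ``Xj`` under Var = sigma^2 (K + delta I)."""
    n, p = Xj.shape
    H = Kv + delta * np.eye(n)
    cho = linalg.cho_factor((H + H.T) / 2.0 + 1e-10 * np.eye(n))
    Hi_X = linalg.cho_solve(cho, Xj)
    Hi_y = linalg.cho_solve(cho, y)
    xtHx = Xj.T @ Hi_X
    xtHy = Xj.T @ Hi_y
    xtHx_inv = linalg.inv(xtHx)
    beta = xtHx_inv @ xtHy
    resid = y - Xj @ beta
    df = n - p
    sigma2 = float(resid @ linalg.cho_solve(cho, resid)) / df
    se = float(np.sqrt(max(sigma2 * xtHx_inv[-1, -1], 0.0)))
    effect = float(beta[-1])
    stat = effect / se if se > 0 else np.nan
    p_value = float(2.0 * t_dist.sf(abs(stat), df)) if np.isfinite(stat) else np.nan
    return effect, stat, p_value, df


def snp_association(
    y: np.ndarray,
    X: np.ndarray | None,
    K: KinshipMatrix,
    genotypes: GenotypeMatrix,
    *,
    mode: str = "exact",
) -> pd.DataFrame:
    """Per-SNP mixed-model association scan.

    ``mode='exact'`` re-estimates the REML variance ratio for every SNP
    model; ``mode='approx'`` reuses the null-model ratio.  SNP genotype is
    coded per allele copy (calls / 2), so the effect is the difference
    between the two homozygote classes.  Strains with a missing call are
    dropped for that SNP only.

    Returns a data frame with columns
    ``snp_id chrom pos maf effect stat p df flag``; SNPs collinear with the
    covariates after missing-strain dropping get ``p = nan`` and
    ``flag='collinear'``.
    """
    if mode not in ("exact", "approx"):
        raise ValidationError(f"mode must be 'exact' or 'approx', got {mode!r}")
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != genotypes.n_strains:
        raise ValidationError("phenotype length does not match number of strains")
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    Kv = K.values
    mafs = genotypes.maf()

    null_delta: float | None = None
    if mode == "approx":
        null_delta = reml_fit(y, X, K).delta

    records = []
    for j in range(genotypes.n_snps):
        snp = genotypes.calls[:, j]
        keep = ~np.isnan(snp)
        yk, Xk = y[keep], X[keep]
        xj = (snp[keep] / 2.0)[:, None]
        Xj = np.hstack([Xk, xj])
        row = genotypes.snp_map.iloc[j]
        base = {
            "snp_id": row["snp_id"],
            "chrom": row["chrom"],
            "pos": int(row["pos"]),
            "maf": float(mafs[j]),
        }
        if np.linalg.matrix_rank(Xj) < Xj.shape[1]:
            records.append(
                {**base, "effect": np.nan, "stat": np.nan, "p": np.nan, "df": 0,
                 "flag": "collinear"}
            )
            continue
        Kk = Kv[np.ix_(keep, keep)]
        if mode == "exact":
            delta = reml_fit(yk, Xj, Kk).delta
        else:
            assert null_delta is not None
            delta = null_delta
        effect, stat, p_value, df = _gls_snp_test(yk, Xj, Kk, delta)
        records.append(
            {**base, "effect": effect, "stat": stat, "p": p_value, "df": df, "flag": ""}
        )
    return pd.DataFrame.from_records(records)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if m <= 0:
        raise ValidationError(f"number of tests must be positive, got {m}")
    if not (0 < alpha <= 1):
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    return alpha / m


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median chi2(1) quantile ratio of observed p."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValidationError("no finite p-values")
    observed = chi2.isf(np.median(p), df=1)
    return float(observed / chi2.isf(0.5, df=1))
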