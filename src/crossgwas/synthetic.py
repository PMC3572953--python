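"""Ground-truth simulators for every input the pipeline consumes.

The generator produces four coupled artifacts from one seeded configuration:

* an inbred strain panel in haplotype blocks (all calls homozygous, {0, 2});
* per-animal dose-response readings whose latent slopes follow
  ``mu + sum(x_j beta_j) + g`` plus animal-level noise, with
  ``g ~ N(0, sigma_g^2 K)`` for the panel's own kinship ``K``;
* multi-study human case-control summary statistics simulated at the
  z-score level, with AR(1) correlation between neighbouring SNPs and a
  planted mean of ``sqrt(N) * lambda`` inside signal genes;
* a mouse/human homology map tying the mouse causal gene to its human
  ortholog, plus a JSON truth record.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import norm

from . import io
from .emma import GenotypeMatrix, compute_kinship
from .errors import ConfigurationError
from .homology import GeneInterval

MOUSE_DOSES_MG_ML = (1.0, 3.0, 10.0, 30.0)
_BASES = np.array(["A", "C", "G", "T"])

__all__ = [
    "Study",
    "SimulationConfig",
    "TruthRecord",
    "SimulatedDataset",
    "simulate_strain_panel",
    "simulate_phenotypes",
    "simulate_summary_stats",
    "simulate_gene_maps",
    "simulate_dataset",
    "write_fixtures",
]


@dataclass(frozen=True)
class Study:
    """One human GWAS stream: a (study, ancestry) summary-statistic set."""

    name: str
    n_samples: int
    ancestry: str = "combined"
    shares_signal: bool = True


@dataclass
class SimulationConfig:
    n_strains: int = 31
    animals_per_strain: int = 8  # per strain and sex
    n_snps: int = 2_000
    block_length_snps: int = 20
    maf_distribution: tuple[float, float] = (0.15, 0.5)
    causal_snps: list[tuple[int, float]] = field(default_factory=list)
    heritability: float = 0.4
    residual_sd_within_animal: float = 0.05
    studies: list[Study] = field(default_factory=list)
    ld_decay_rho: float = 0.0
    seed: int = 0
    # plumbing knobs beyond the core contract
    base_slope: float = 1.0  # population mean latent slope
    strain_var: float = 0.04  # target variance of strain mean slopes
    n_families: int = 5  # ancestral lineages; gives kinship its structure
    family_concordance: float = 0.85  # P(strain allele = its lineage allele)
    baseline_resistance: float = 0.8
    n_chroms: int = 5
    snp_spacing_bp: int = 5_000
    n_genes: int = 20
    snps_per_human_gene: int = 25
    signal_snr: float = 5.0  # planted sqrt(N) * lambda in sharing studies

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_strains < 3:
            raise ConfigurationError(f"n_strains must be >= 3, got {self.n_strains}")
        if self.animals_per_strain < 1:
            raise ConfigurationError(
                f"animals_per_strain must be >= 1, got {self.animals_per_strain}"
            )
        if self.n_snps < 1:
            raise ConfigurationError(f"n_snps must be >= 1, got {self.n_snps}")
        if self.block_length_snps < 1:
            raise ConfigurationError(
                f"block_length_snps must be >= 1, got {self.block_length_snps}"
            )
        lo, hi = self.maf_distribution
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError(
                f"maf_distribution must satisfy 0 <= low <= high <= 1, got {self.maf_distribution}"
            )
        if not (0 <= self.heritability <= 1):
            raise ConfigurationError(
                f"heritability must be in [0, 1], got {self.heritability}"
            )
        for idx, _effect in self.causal_snps:
            if not (0 <= idx < self.n_snps):
                raise ConfigurationError(
                    f"causal_snps index {idx} out of range for n_snps={self.n_snps}"
                )
        if not (0 <= self.ld_decay_rho < 1):
            raise ConfigurationError(
                f"ld_decay_rho must be in [0, 1), got {self.ld_decay_rho}"
            )
        if self.residual_sd_within_animal < 0:
            raise ConfigurationError(
                f"residual_sd_within_animal must be >= 0, got {self.residual_sd_within_animal}"
            )
        if self.n_families < 1:
            raise ConfigurationError(f"n_families must be >= 1, got {self.n_families}")
        if not (0 <= self.family_concordance <= 1):
            raise ConfigurationError(
                f"family_concordance must be in [0, 1], got {self.family_concordance}"
            )
        for study in self.studies:
            if study.n_samples <= 0:
                raise ConfigurationError(
                    f"study {study.name!r} has n_samples={study.n_samples} (must be > 0)"
                )


@dataclass
class TruthRecord:
    """Ground truth serialized alongside each simulated dataset."""

    seed: int
    causal_mouse_snps: list[tuple[str, float]]  # (snp_id, effect in slope units)
    causal_mouse_genes: list[str]
    causal_human_genes: list[str]
    study_directions: dict  # study name -> +1 / -1 (0 when no shared signal)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["causal_mouse_snps"] = [list(t) for t in self.causal_mouse_snps]
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        data = json.loads(text)
        data["causal_mouse_snps"] = [
            (str(s), float(e)) for s, e in data["causal_mouse_snps"]
        ]
        return cls(**data)


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    dose_response: pd.DataFrame
    summary_stats: pd.DataFrame | None
    homology_map: pd.DataFrame
    mouse_genes: list[GeneInterval]
    human_genes: list[GeneInterval]
    truth: TruthRecord


def simulate_strain_panel(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a haplotype-block inbred panel.

    SNPs come in blocks of ``block_length_snps``; all SNPs inside a block
    share one ancestral strain partition, mimicking the large identical-by-
    descent haplotype blocks of laboratory strains.  Per-block minor allele
    frequency is drawn uniformly from ``maf_distribution``.  Strains belong
    to ``n_families`` ancestral lineages and copy each lineage allele with
    probability ``family_concordance`` (independent redraw otherwise), so
    related strains share haplotypes and the kinship matrix has real
    structure.
    """
    rng = np.random.default_rng([config.seed, 101])
    n_strains, n_snps = config.n_strains, config.n_snps
    n_blocks = int(np.ceil(n_snps / config.block_length_snps))
    lo, hi = config.maf_distribution
    freqs = rng.uniform(lo, hi, size=n_blocks)
    family_of = np.arange(n_strains) * config.n_families // n_strains
    family_alleles = rng.random((n_blocks, config.n_families)) < freqs[:, None]
    inherit = rng.random((n_blocks, n_strains)) < config.family_concordance
    own_alleles = rng.random((n_blocks, n_strains)) < freqs[:, None]
    patterns = np.where(inherit, family_alleles[:, family_of], own_alleles)
    calls = np.repeat(patterns.astype(float) * 2.0, config.block_length_snps, axis=0)[:n_snps].T

    block_of = np.arange(n_snps) // config.block_length_snps
    chrom_of_block = block_of // max(1, int(np.ceil(n_blocks / config.n_chroms)))
    chroms = (chrom_of_block % config.n_chroms) + 1
    pos = np.zeros(n_snps, dtype=np.int64)
    for c in np.unique(chroms):
        on_c = chroms == c
        pos[on_c] = (np.arange(int(on_c.sum())) + 1) * config.snp_spacing_bp
    allele_idx = rng.integers(0, 4, size=(n_snps, 2))
    allele_idx[:, 1] = (allele_idx[:, 0] + rng.integers(1, 4, size=n_snps)) % 4
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"msnp{i:06d}" for i in range(n_snps)],
            "chrom": [str(c) for c in chroms],
            "pos": pos,
            "allele_a": _BASES[allele_idx[:, 0]],
            "allele_b": _BASES[allele_idx[:, 1]],
        }
    )
    strain_ids = [f"strain{i:03d}" for i in range(n_strains)]
    return GenotypeMatrix(strain_ids=strain_ids, snp_map=snp_map, calls=calls)


def _psd_sqrt(matrix: np.ndarray) -> np.ndarray:
    w, v = linalg.eigh((matrix + matrix.T) / 2.0)
    return (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T


def animal_noise_sd(config: SimulationConfig) -> float:
    """Animal-to-animal latent slope SD implied by the variance partition.

    The target variance of strain mean slopes is ``strain_var``, split as
    ``heritability`` genetic vs. ``1 - heritability`` averaged animal noise
    (both sexes pooled), so heritability 0 leaves strain means differing by
    sampling noise only.
    """
    n_animals = 2 * config.animals_per_strain
    return float(np.sqrt((1.0 - config.heritability) * config.strain_var * n_animals))


def strain_latent_slopes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Latent strain slope means and the genetic values underlying them.

    Genetic values are drawn from N(0, sigma_g^2 K) with K the panel's own
    kinship and sigma_g^2 = heritability * strain_var; causal SNP effects
    shift the two homozygote classes apart by the configured amount.
    """
    rng = np.random.default_rng([config.seed, 202])
    n = genotypes.n_strains
    sigma_g2 = config.heritability * config.strain_var
    draw = rng.standard_normal(n)  # draw sequence stable across heritability
    if sigma_g2 > 0:
        K = compute_kinship(genotypes).values
        genetic = _psd_sqrt(K) @ draw * np.sqrt(sigma_g2)
    else:
        genetic = np.zeros(n)
    latent = config.base_slope + genetic
    for idx, effect in config.causal_snps:
        if not (0 <= idx < genotypes.n_snps):
            raise ConfigurationError(
                f"causal SNP index {idx} out of range for panel with {genotypes.n_snps} SNPs"
            )
        latent = latent + (genotypes.calls[:, idx] / 2.0) * effect
    return latent, genetic


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> pd.DataFrame:
    """Per-animal dose-response table for the panel.

    Each animal gets a saline reading (dose 0) and readings at the four
    methacholine doses; readings are linear in log10(dose) around the
    animal's latent slope plus per-reading instrument noise, so fitting the
    slope back recovers the latent value exactly in the noise-free limit.
    """
    latent, _genetic = strain_latent_slopes(genotypes, config)
    rng = np.random.default_rng([config.seed, 303])
    sigma_animal = animal_noise_sd(config)
    log_doses = np.log10(np.array(MOUSE_DOSES_MG_ML))
    rows = []
    for i, strain in enumerate(genotypes.strain_ids):
        for sex in ("f", "m"):
            for a in range(config.animals_per_strain):
                animal_id = f"{strain}_{sex}{a:02d}"
                slope = latent[i] + rng.standard_normal() * sigma_animal
                noise = rng.standard_normal(1 + len(log_doses)) * config.residual_sd_within_animal
                saline = max(config.baseline_resistance + noise[0], 1e-6)
                rows.append(
                    {"strain": strain, "sex": sex, "animal_id": animal_id,
                     "dose_mg_ml": 0.0, "resistance": saline}
                )
                for d, logd, eps in zip(MOUSE_DOSES_MG_ML, log_doses, noise[1:]):
                    resistance = max(
                        config.baseline_resistance + slope * logd + eps, 1e-6
                    )
                    rows.append(
                        {"strain": strain, "sex": sex, "animal_id": animal_id,
                         "dose_mg_ml": d, "resistance": resistance}
                    )
    return pd.DataFrame(rows)


def anchor_snp_indices(config: SimulationConfig) -> np.ndarray:
    """SNP index at the centre of each simulated mouse gene.

    Useful for planting a causal SNP inside gene ``g``:
    ``causal_snps=[(anchor_snp_indices(cfg)[g], effect)]``.
    """
    n_genes = min(config.n_genes, config.n_snps)
    return np.linspace(0, config.n_snps - 1, n_genes * 2 + 1)[1::2].astype(int)


def simulate_gene_maps(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[list[GeneInterval], list[GeneInterval], pd.DataFrame]:
    """Mouse genes tiled over the panel's SNP map, 1:1 human orthologs, and
    the homology-map table linking them."""
    n_genes = min(config.n_genes, genotypes.n_snps)
    anchors = np.linspace(0, genotypes.n_snps - 1, n_genes * 2 + 1)[1::2].astype(int)
    half_span = 5 * config.snp_spacing_bp
    mouse_genes: list[GeneInterval] = []
    human_genes: list[GeneInterval] = []
    rows = []
    for g, anchor in enumerate(anchors):
        row = genotypes.snp_map.iloc[int(anchor)]
        m_start = max(1, int(row["pos"]) - half_span)
        m_end = int(row["pos"]) + half_span
        mouse = GeneInterval(f"Mgene{g:03d}", "mouse", str(row["chrom"]), m_start, m_end)
        h_chrom = str((g % config.n_chroms) + 1)
        h_start = 1_000_000 + (g // config.n_chroms) * 2_000_000
        human = GeneInterval(f"HGENE{g:03d}", "human", h_chrom, h_start, h_start + 400_000)
        mouse_genes.append(mouse)
        human_genes.append(human)
        rows.append(
            {"mouse_gene": mouse.gene_id, "mouse_chrom": mouse.chrom,
             "mouse_start": mouse.start, "mouse_end": mouse.end,
             "human_gene": human.gene_id, "human_chrom": human.chrom,
             "human_start": human.start, "human_end": human.end}
        )
    return mouse_genes, human_genes, pd.DataFrame(rows)


def _human_snp_map(
    human_genes: list[GeneInterval], config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for gene in human_genes:
        offsets = np.linspace(gene.start, gene.end, config.snps_per_human_gene).astype(np.int64)
        for k, pos in enumerate(offsets):
            rows.append({"gene": gene.gene_id, "chrom": gene.chrom, "pos": int(pos)})
    table = pd.DataFrame(rows)
    table = table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    table["snp_id"] = [f"hsnp{i:06d}" for i in range(len(table))]
    ref_idx = rng.integers(0, 4, size=len(table))
    other_idx = (ref_idx + rng.integers(1, 4, size=len(table))) % 4
    table["ref_allele"] = _BASES[ref_idx]
    table["other_allele"] = _BASES[other_idx]
    return table


def _ar1_noise(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    eps = np.empty(n)
    eps[0] = rng.standard_normal()
    if n > 1:
        innovations = rng.standard_normal(n - 1) * np.sqrt(1.0 - rho**2)
        for k in range(1, n):
            eps[k] = rho * eps[k - 1] + innovations[k - 1]
    return eps


def simulate_summary_stats(
    human_genes: list[GeneInterval],
    config: SimulationConfig,
    *,
    signal_genes: set[str] | None = None,
    directions: dict | None = None,
) -> pd.DataFrame | None:
    """Per-study human summary statistics over a gene-anchored SNP map.

    Z-scores are standard normal with AR(1) correlation ``ld_decay_rho``
    between neighbouring SNPs in map order; inside signal genes the mean is
    ``signal_snr`` (i.e. sqrt(N) * lambda) with the study's true direction.
    Two-sided p-values and odds ratios are mutually consistent:
    sign(ln OR) = sign(z).  Returns None when the config has no studies.
    """
    if not config.studies:
        return None
    signal_genes = signal_genes or set()
    directions = directions or {}
    rng = np.random.default_rng([config.seed, 404])
    snp_map = _human_snp_map(human_genes, config, rng)
    in_signal = snp_map["gene"].isin(signal_genes).to_numpy()

    frames = []
    for study in config.studies:
        direction = int(directions.get(study.name, 1))
        mean = np.where(
            in_signal & study.shares_signal, config.signal_snr * direction, 0.0
        )
        z = mean + _ar1_noise(len(snp_map), config.ld_decay_rho, rng)
        p = 2.0 * norm.sf(np.abs(z))
        beta = z / np.sqrt(study.n_samples)
        frames.append(
            pd.DataFrame(
                {
                    "study": study.name,
                    "ancestry": study.ancestry,
                    "snp_id": snp_map["snp_id"],
                    "chrom": snp_map["chrom"],
                    "pos": snp_map["pos"],
                    "ref_allele": snp_map["ref_allele"],
                    "other_allele": snp_map["other_allele"],
                    "p_two_sided": np.clip(p, np.nextafter(0, 1), 1.0),
                    "effect": np.exp(beta),
                    "effect_type": "OR",
                    "n_samples": study.n_samples,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full coupled mouse + human dataset with ground truth."""
    genotypes = simulate_strain_panel(config)
    dose_response = simulate_phenotypes(genotypes, config)
    mouse_genes, human_genes, homology = simulate_gene_maps(genotypes, config)

    causal_ids: list[tuple[str, float]] = []
    causal_mouse_genes: list[str] = []
    causal_human_genes: list[str] = []
    human_of = {m.gene_id: h.gene_id for m, h in zip(mouse_genes, human_genes)}
    for idx, effect in config.causal_snps:
        row = genotypes.snp_map.iloc[idx]
        causal_ids.append((str(row["snp_id"]), float(effect)))
        for mouse in mouse_genes:
            if mouse.chrom == str(row["chrom"]) and mouse.distance_to(int(row["pos"])) == 0:
                if mouse.gene_id not in causal_mouse_genes:
                    causal_mouse_genes.append(mouse.gene_id)
                    causal_human_genes.append(human_of[mouse.gene_id])
    study_directions = {
        s.name: (1 if s.shares_signal else 0) for s in config.studies
    }
    truth = TruthRecord(
        seed=config.seed,
        causal_mouse_snps=causal_ids,
        causal_mouse_genes=causal_mouse_genes,
        causal_human_genes=causal_human_genes,
        study_directions=study_directions,
    )
    summary = simulate_summary_stats(
        human_genes, config,
        signal_genes=set(causal_human_genes),
        directions={k: v for k, v in study_directions.items() if v != 0},
    )
    return SimulatedDataset(
        genotypes=genotypes,
        dose_response=dose_response,
        summary_stats=summary,
        homology_map=homology,
        mouse_genes=mouse_genes,
        human_genes=human_genes,
        truth=truth,
    )


def write_fixtures(output_dir, config: SimulationConfig) -> dict[str, Path]:
    """Simulate a dataset and write all interchange files under ``output_dir``.

    Emits ``genotypes.tsv``, ``dose_response.tsv``, ``homology_map.tsv`` and
    ``truth.json`` always, plus ``summary_stats.tsv`` when the config has
    studies.  Same config (including seed) -> byte-identical files.
    """
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    dataset = simulate_dataset(config)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "dose_response": out / "dose_response.tsv",
        "homology_map": out / "homology_map.tsv",
        "truth": out / "truth.json",
    }
    io.write_genotypes(dataset.genotypes, paths["genotypes"])
    io.write_dose_response(dataset.dose_response, paths["dose_response"])
    io.write_homology_map(dataset.homology_map, paths["homology_map"])
    paths["truth"].write_text(dataset.truth.to_json() + "\n")
    if dataset.summary_stats is not None:
        paths["summary_stats"] = out / "summary_stats.tsv"
        io.write_summary_stats(dataset.summary_stats, paths["summary_stats"])
    return paths
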