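"""Synthetic genotype/phenotype panels for genomic-prediction experiments.

The generator emulates the structure of a crop GBS panel: thousands of
correlated biallelic markers (LD blocks via a shared latent factor),
population stratification (Balding–Nichols-style subpopulation allele
frequencies), and quantitative traits built from a sparse major-effect
layer plus a kinship-correlated polygenic background plus Gaussian noise —
the union of the generative assumptions of the models fitted elsewhere in
this package, so each model is well-specified under some configuration.
Ground truth (effects, indicators, polygenic values, noise variance) is
returned for parameter-recovery and coverage-calibration tests.

Dosages are drawn per haplotype by thresholding a blockwise-correlated
latent Gaussian at the quantile implied by the marker's subpopulation
allele frequency, which yields Hardy–Weinberg proportions within
subpopulations by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .types import GenotypeMatrix, PhenotypeVector, TruthRecord

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_dataset",
    "write_fixture",
]

_SKEW_TRANSFORMS = ("none", "exponential", "shifted_gamma")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic panel.

    Defaults emulate a rice GBS panel: ~2.3k individuals, ~12.5k SNPs,
    mild LD and stratification, a sparse-plus-polygenic trait at h2=0.5.
    """

    n_individuals: int = 2266
    n_markers: int = 12486
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 50
    ld_rho: float = 0.6
    n_subpops: int = 3
    fst_like_divergence: float = 0.05
    n_causal: int = 20
    causal_effect_sd: float = 1.0
    heritability_target: float = 0.5
    polygenic_fraction: float = 0.3
    skew_transform: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.ld_block_size < 1 or self.ld_block_size > self.n_markers:
            raise ValueError("ld_block_size must be in [1, n_markers]")
        if self.n_causal > self.n_markers:
            raise ValueError("n_causal cannot exceed n_markers")
        if not (0 <= self.heritability_target < 1):
            raise ValueError("heritability_target must be in [0, 1)")
        if not (0 <= self.polygenic_fraction <= 1):
            raise ValueError("polygenic_fraction must be in [0, 1]")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if self.fst_like_divergence < 0:
            raise ValueError("fst_like_divergence must be non-negative")
        if self.skew_transform not in _SKEW_TRANSFORMS:
            raise ValueError(f"skew_transform must be one of {_SKEW_TRANSFORMS}")


def _subpop_labels(n: int, k: int) -> np.ndarray:
    """Balanced assignment of n individuals to k subpopulations."""
    return np.arange(n) % k


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw an n x p dosage matrix with LD blocks and stratification.

    Per marker, an ancestral allele frequency is drawn uniformly on
    ``maf_range``; subpopulation frequencies are Balding–Nichols
    perturbations with divergence parameter F = ``fst_like_divergence``
    (Beta with mean the ancestral frequency, variance F p(1-p)).  Each
    haplotype's latent Gaussian shares a per-block factor with loading
    sqrt(ld_rho), inducing within-block dosage correlation.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_individuals, cfg.n_markers
    lo, hi = cfg.maf_range

    anc_freq = rng.uniform(lo, hi, size=p) if hi > lo else np.full(p, lo)
    labels = _subpop_labels(n, cfg.n_subpops)

    F = cfg.fst_like_divergence
    if F > 0 and cfg.n_subpops > 1:
        a = anc_freq * (1 - F) / F
        b = (1 - anc_freq) * (1 - F) / F
        sub_freq = rng.beta(
            np.tile(a, (cfg.n_subpops, 1)), np.tile(b, (cfg.n_subpops, 1))
        )
        sub_freq = np.clip(sub_freq, 1e-3, 1 - 1e-3)
    else:
        sub_freq = np.tile(anc_freq, (cfg.n_subpops, 1))

    dosages = np.empty((n, p), dtype=np.int8)
    rho = cfg.ld_rho
    # block-by-block to bound memory at n x 2 x block_size
    for start in range(0, p, cfg.ld_block_size):
        stop = min(start + cfg.ld_block_size, p)
        width = stop - start
        shared = rng.standard_normal((n, 2, 1))          # per block/haplotype
        noise = rng.standard_normal((n, 2, width))
        latent = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
        thresh = stats.norm.ppf(sub_freq[labels, start:stop])  # (n, width)
        alleles = latent < thresh[:, None, :]
        dosages[:, start:stop] = alleles.sum(axis=1)

    sample_ids = [f"ind{i:05d}" for i in range(n)]
    marker_ids = [f"snp{j:06d}" for j in range(p)]
    return GenotypeMatrix(dosages, sample_ids, marker_ids)


def simulate_phenotype(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[PhenotypeVector, TruthRecord]:
    """Build y = Xb + u + eps on top of a simulated dosage matrix.

    The sparse component Xb (``n_causal`` effects, sd ``causal_effect_sd``
    before rescaling) and the polygenic component u (covariance
    proportional to the realized kinship X_c X_c^T / p) are rescaled so the
    realized genetic variance fraction is ``heritability_target``, split
    per ``polygenic_fraction``; residual variance is 1 - h2, so y has unit
    variance up to sampling error.  If ``skew_transform`` is not "none" a
    monotone skewing map is applied to y afterwards; the truth record
    stays on the pre-skew (latent trait) scale.
    """
    cfg = config
    if cfg.n_causal > genotypes.p:
        raise ValueError("n_causal exceeds the number of markers")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n, p = genotypes.n, genotypes.p

    Xc = genotypes.dosages.astype(float)
    Xc -= Xc.mean(axis=0)

    h2 = cfg.heritability_target
    var_sparse = h2 * (1 - cfg.polygenic_fraction)
    var_poly = h2 * cfg.polygenic_fraction
    sigma_eps2 = 1.0 - h2

    beta = np.zeros(p)
    gamma = np.zeros(p, dtype=int)
    causal = rng.choice(p, size=cfg.n_causal, replace=False)
    gamma[causal] = 1
    g_sparse = np.zeros(n)
    if var_sparse > 0:
        if cfg.n_causal == 0:
            raise ValueError(
                "sparse genetic variance requested but n_causal is 0"
            )
        beta[causal] = rng.normal(0.0, cfg.causal_effect_sd, size=cfg.n_causal)
        g = Xc @ beta
        sd = g.std()
        if sd == 0:
            raise ValueError("no sparse genetic variance available (monomorphic causal markers)")
        beta *= np.sqrt(var_sparse) / sd
        g_sparse = Xc @ beta

    u = np.zeros(n)
    if var_poly > 0:
        K = Xc @ Xc.T / p
        jitter = 1e-8 * np.trace(K) / n + 1e-12
        L = np.linalg.cholesky(K + jitter * np.eye(n))
        u = L @ rng.standard_normal(n)
        sd = u.std()
        if sd == 0:
            raise ValueError("no polygenic variance available")
        u *= np.sqrt(var_poly) / sd

    eps = rng.normal(0.0, np.sqrt(sigma_eps2), size=n)
    y = g_sparse + u + eps

    genetic = g_sparse + u
    realized_h2 = float(np.var(genetic) / np.var(y)) if np.var(y) > 0 else 0.0

    if cfg.skew_transform != "none":
        z = (y - y.mean()) / y.std()
        if cfg.skew_transform == "exponential":
            y = np.exp(z)
        else:  # shifted_gamma
            uq = np.clip(stats.norm.cdf(z), 1e-12, 1 - 1e-12)
            y = stats.gamma.ppf(uq, a=2.0)

    pheno = PhenotypeVector(y, trait_name="sim_trait", transform_applied="none")
    truth = TruthRecord(
        beta_true=beta,
        gamma_true=gamma,
        u_true=u,
        sigma_eps2_true=sigma_eps2,
        realized_h2=realized_h2,
    )
    return pheno, truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PhenotypeVector, TruthRecord]:
    """Genotypes and phenotype in one call (shared config/seed)."""
    geno = simulate_genotypes(config)
    pheno, truth = simulate_phenotype(geno, config)
    return geno, pheno, truth


def write_fixture(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    truth: TruthRecord,
    directory: str | Path,
    config: SimulationConfig | None = None,
) -> dict:
    """Write the panel as tab-delimited text plus a YAML manifest.

    Files: ``genotypes.tsv`` (header of marker ids, first column
    sample_id), ``phenotypes.tsv`` (sample_id + trait column),
    ``truth_markers.tsv`` (one row per marker: beta, gamma),
    ``truth_individuals.tsv`` (one row per individual: u), and
    ``manifest.yaml`` recording scalars and the full config.
    Round-trips bit-exactly through :mod:`bayesgp.io`.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        geno_path = directory / "genotypes.tsv"
        genotypes.to_frame().rename_axis("sample_id").to_csv(geno_path, sep="\t")
        pheno_path = directory / "phenotypes.tsv"
        pd.DataFrame(
            {
                "sample_id": genotypes.sample_ids,
                phenotype.trait_name: phenotype.values,
            }
        ).to_csv(pheno_path, sep="\t", index=False)
        tm_path = directory / "truth_markers.tsv"
        pd.DataFrame(
            {
                "marker_id": genotypes.marker_ids,
                "beta_true": truth.beta_true,
                "gamma_true": truth.gamma_true,
            }
        ).to_csv(tm_path, sep="\t", index=False)
        ti_path = directory / "truth_individuals.tsv"
        pd.DataFrame(
            {"sample_id": genotypes.sample_ids, "u_true": truth.u_true}
        ).to_csv(ti_path, sep="\t", index=False)

        manifest = {
            "files": {
                "genotypes": geno_path.name,
                "phenotypes": pheno_path.name,
                "truth_markers": tm_path.name,
                "truth_individuals": ti_path.name,
            },
            "trait_name": phenotype.trait_name,
            "sigma_eps2_true": float(truth.sigma_eps2_true),
            "realized_h2": float(truth.realized_h2),
            "seed": None if config is None else config.seed,
        }
        if config is not None:
            cfg_dict = dataclasses.asdict(config)
            cfg_dict["maf_range"] = list(cfg_dict["maf_range"])
            manifest["config"] = cfg_dict
        with open(directory / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        return manifest
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
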