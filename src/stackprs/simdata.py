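"""Synthetic LD-blocked genotypes and phenotypes.

The generator stands in for cohort data so that the whole pipeline — QC, GWAS,
linear PRS baselines and the stacked networks — is exercisable end to end.

Genotypes: variants are partitioned into contiguous blocks.  Each gamete is a
latent AR(1) Gaussian process within a block (correlation ``within_block_r``
between adjacent variants, independent across blocks), thresholded at the
normal quantile of the variant's minor-allele frequency to give a Bernoulli
allele; a dosage is the sum of two independent gametes.  This yields valid
hard calls with tunable within-block r² and exactly independent blocks.
Blocks are placed >250 kb apart (block k starts at 1 + k*10^6 bp, 1 kb spacing
within a block, single chromosome) so physical clumping windows are meaningful.

Phenotypes: a genetic score sums additive terms over centred dosages plus
optional pairwise interaction terms (products of centred dosages, so the
interactions are near-orthogonal to the marginal effects and largely invisible
to marginal GWAS).  Environmental noise is residualised against the genetic
score and rescaled so the realised variance ratio equals ``h2_target``
exactly.  Binary traits threshold the liability at the empirical
(1 − prevalence) quantile.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import MISSING, GenotypeMatrix, VariantInfo

__all__ = ["TrueEffects", "simulate_genotypes", "simulate_phenotype", "write_truth_table"]

# non-ambiguous allele pairs cycled across variants (A/T and C/G never appear,
# so simulated variants survive the ambiguity filter)
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]

_BLOCK_START_BP = 1_000_000
_WITHIN_BLOCK_BP = 1_000


@dataclass
class TrueEffects:
    """Generative phenotype architecture.

    ``additive_betas`` maps causal vid -> per-allele effect on the liability
    scale (relative scale; the overall genetic variance is rescaled to hit
    ``h2_target``).  ``interaction_pairs`` lists (vid_a, vid_b, coefficient)
    epistatic terms over centred dosages.
    """

    additive_betas: dict[str, float] = field(default_factory=dict)
    interaction_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    h2_target: float = 0.5
    prevalence: float = 0.1
    liability_threshold: float | None = None

    @property
    def causal_vids(self) -> list[str]:
        vids = list(self.additive_betas)
        for a, b, _ in self.interaction_pairs:
            for v in (a, b):
                if v not in vids:
                    vids.append(v)
        return vids

    def validate(self, available_vids: set[str]) -> None:
        if not (0.0 < self.h2_target < 1.0):
            raise ValueError(f"h2_target must be in (0, 1), got {self.h2_target}")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        unknown = [v for v in self.causal_vids if v not in available_vids]
        if unknown:
            raise ValueError(f"causal vids not present in genotypes: {unknown[:5]}")


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    block_size: int = 10,
    within_block_r: float = 0.8,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int = 0,
    chrom: str = "1",
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Simulate an LD-blocked diploid genotype matrix.

    ``within_block_r`` is the latent AR(1) correlation between adjacent
    variants of one gamete; the induced genotype correlation is attenuated by
    the Bernoulli thresholding (see the Monte-Carlo oracle in the tests).
    ``missing_rate`` optionally masks entries at random for missingness-aware
    code paths.
    """
    if n_samples <= 0 or n_variants <= 0:
        raise ValueError("n_samples and n_variants must be positive")
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    if not (0.0 <= within_block_r < 1.0):
        raise ValueError(f"within_block_r must be in [0, 1), got {within_block_r}")
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError(f"need 0 < maf_low <= maf_high <= 0.5, got ({maf_low}, {maf_high})")

    rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_low, maf_high, size=n_variants)
    thresholds = stats.norm.ppf(mafs)  # allele present when latent < threshold

    dosage = np.zeros((n_samples, n_variants), dtype=np.int8)
    rho = within_block_r
    innov_sd = np.sqrt(1.0 - rho * rho)
    for _gamete in range(2):
        z = np.empty((n_samples, n_variants))
        for start in range(0, n_variants, block_size):
            stop = min(start + block_size, n_variants)
            z[:, start] = rng.standard_normal(n_samples)
            for j in range(start + 1, stop):
                z[:, j] = rho * z[:, j - 1] + innov_sd * rng.standard_normal(n_samples)
        dosage += (z < thresholds[None, :]).astype(np.int8)

    if missing_rate > 0.0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = MISSING

    variants = []
    for j in range(n_variants):
        block, offset = divmod(j, block_size)
        a1, a2 = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        variants.append(
            VariantInfo(
                chrom=chrom,
                pos=_BLOCK_START_BP * (block + 1) + 1 + offset * _WITHIN_BLOCK_BP,
                vid=f"snp{j:06d}",
                allele1=a1,
                allele2=a2,
            )
        )
    sample_ids = [f"id{i:06d}" for i in range(n_samples)]
    return GenotypeMatrix(genotypes=dosage, variants=variants, sample_ids=sample_ids)


def _centred_dosage(g: GenotypeMatrix, vid: str) -> np.ndarray:
    j = g.vid_index()[vid]
    x = g.genotypes[:, j].astype(float)
    obs = x != MISSING
    mean = x[obs].mean() if obs.any() else 0.0
    x = np.where(obs, x, mean)
    return x - mean


def simulate_phenotype(
    g: GenotypeMatrix,
    effects: TrueEffects,
    trait_type: str = "quantitative",
    noise_seed: int = 0,
) -> tuple[np.ndarray, TrueEffects, np.ndarray]:
    """Simulate a phenotype under ``effects``.

    Returns ``(phenotype, realised_effects, genetic_score)``.  For
    quantitative traits the realised variance ratio
    Var(genetic)/Var(phenotype) equals ``h2_target`` exactly: the noise is
    residualised against the genetic score and rescaled on the realised
    sample.  Binary traits additionally threshold the liability at the
    empirical (1 − prevalence) quantile, so the case fraction is the
    prevalence up to rounding.
    """
    if trait_type not in ("binary", "quantitative"):
        raise ValueError(f"trait_type must be 'binary' or 'quantitative', got {trait_type!r}")
    effects.validate(set(g.vids))

    n = g.n_samples
    genetic = np.zeros(n)
    for vid, beta in effects.additive_betas.items():
        genetic += beta * _centred_dosage(g, vid)
    for vid_a, vid_b, coef in effects.interaction_pairs:
        genetic += coef * _centred_dosage(g, vid_a) * _centred_dosage(g, vid_b)

    rng = np.random.default_rng(noise_seed)
    noise = rng.standard_normal(n)
    var_g = genetic.var()
    if var_g == 0.0:
        # pure-noise phenotype: a null calibration input
        y_cont = noise
    else:
        # make the noise exactly orthogonal to the genetic score, then scale
        gc = genetic - genetic.mean()
        noise = noise - noise.mean()
        noise = noise - (noise @ gc) / (gc @ gc) * gc
        noise *= np.sqrt(var_g * (1.0 - effects.h2_target) / effects.h2_target) / noise.std()
        y_cont = genetic + noise

    realised = TrueEffects(
        additive_betas=dict(effects.additive_betas),
        interaction_pairs=list(effects.interaction_pairs),
        h2_target=effects.h2_target,
        prevalence=effects.prevalence,
    )
    if trait_type == "quantitative":
        return y_cont, realised, genetic

    thr = float(np.quantile(y_cont, 1.0 - effects.prevalence))
    realised.liability_threshold = thr
    y = (y_cont > thr).astype(float)
    return y, realised, genetic


def write_truth_table(effects: TrueEffects, path: str | os.PathLike) -> None:
    """Tab-separated record of the generative architecture (one row per term)."""
    with open(path, "w") as fh:
        fh.write("vid\ttrue_beta\tpartner\tcoefficient\n")
        for vid, beta in effects.additive_betas.items():
            fh.write(f"{vid}\t{beta!r}\t.\t.\n")
        for a, b, c in effects.interaction_pairs:
            fh.write(f"{a}\t.\t{b}\t{c!r}\n")


def write_generation_config(path: str | os.PathLike, **params) -> None:
    """JSON record of the generator call, for reproducibility."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
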