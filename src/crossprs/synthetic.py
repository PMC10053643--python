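"""Synthetic two-population genotype, phenotype and discovery-GWAS simulator.

The simulator produces the minimal statistical structure the downstream
pipeline assumes, without any external data:

* two populations whose per-variant allele frequencies diverge around a
  shared ancestral frequency according to the Balding-Nichols model
  ``Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst)``;
* linkage disequilibrium inside independent blocks, induced by a
  first-order autoregressive latent Gaussian: variant ``i`` and ``j`` of a
  block have latent correlation ``rho^|i-j|``, and a haplotype carries the
  counted allele when its latent value falls below the frequency quantile;
* a binary phenotype from a liability-threshold model: liability is the
  standardized-genotype weighted sum of causal effects plus Gaussian noise,
  and an individual is a case when liability exceeds ``Phi^-1(1-K)``;
* discovery summary statistics from single-variant score tests in one
  population, optionally restricted to non-causal variants ("tag-only"
  mode) and with palindromic allele codings / strand flips injected to
  exercise harmonization.

All randomness derives from a user seed through named substreams, so the
same seed reproduces byte-identical outputs, and the two populations share
ancestral frequencies (identical frequencies at Fst = 0).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError, GenotypeMatrix, InputError, SummaryStatSet

# substream salts: ancestral draws are population-independent so both
# populations see the same ancestral frequencies and allele labels
_SALT_ANCESTRAL = 101
_SALT_POPFREQ = 202
_SALT_GENO = 303
_SALT_CAUSAL = 404
_SALT_INJECT = 505

#: non-palindromic ordered allele pairs used for simulated variants
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]

MHC_CHROM = "6"
MHC_START = 25_000_000
MHC_END = 35_000_000


def _pop_salt(population: str) -> int:
    return zlib.crc32(str(population).encode()) % (2 ** 16)


@dataclass
class PopulationModel:
    """Structure of the simulated genome and of population divergence.

    ``fst`` controls allele-frequency divergence between the two
    populations; ``within_block_rho`` controls LD decay inside a block
    (latent correlation ``rho^distance``); blocks are mutually independent.
    """

    n_blocks: int = 22
    snps_per_block: int = 12
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    fst: float = 0.1
    within_block_rho: float = 0.9
    block_span_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")
        if self.snps_per_block < 1:
            raise ConfigurationError("snps_per_block must be >= 1")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError(
                "ancestral_freq_range must be an interval inside (0, 1)"
            )
        if not (0.0 <= self.fst <= 0.5):
            raise ConfigurationError("fst must lie in [0, 0.5]")
        if not (0.0 <= self.within_block_rho <= 0.99):
            raise ConfigurationError("within_block_rho must lie in [0, 0.99]")
        if self.block_span_bp < self.snps_per_block:
            raise ConfigurationError("block_span_bp too small for snps_per_block")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.snps_per_block


@dataclass
class DiseaseModel:
    """Liability-threshold disease architecture.

    ``h2_liability`` is the liability-scale heritability; ``prevalence_K``
    the population prevalence setting the liability threshold
    ``Phi^-1(1-K)``. Causal effects are drawn zero-mean Gaussian and
    rescaled so the genetic liability component has variance exactly
    ``h2_liability`` in the simulated cohort.
    """

    causal_fraction: float = 0.3
    h2_liability: float = 0.3
    prevalence_K: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 <= self.causal_fraction <= 1.0):
            raise ConfigurationError("causal_fraction must lie in [0, 1]")
        if not (0.0 <= self.h2_liability < 1.0):
            raise ConfigurationError("h2_liability must lie in [0, 1)")
        if not (0.0 < self.prevalence_K <= 0.5):
            raise ConfigurationError("prevalence_K must lie in (0, 0.5]")


@dataclass
class SyntheticCohort:
    """Genotypes plus simulated phenotype, covariates and ground truth."""

    genotypes: GenotypeMatrix
    phenotype: np.ndarray           # 0/1 case status per individual
    covariates: pd.DataFrame        # age, sex, pc1..pc4, indexed like samples
    true_betas: np.ndarray          # per-variant liability effect (standardized scale)
    liability: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        n = self.genotypes.n_individuals
        self.phenotype = np.asarray(self.phenotype, dtype=int)
        if len(self.phenotype) != n or len(self.covariates) != n:
            raise InputError("phenotype/covariate length != individual count")
        if self.covariates.isna().any().any():
            raise InputError("covariates must be complete for every individual")

    @property
    def population_label(self) -> np.ndarray:
        return self.genotypes.populations


def _variant_metadata(model: PopulationModel) -> pd.DataFrame:
    """Block positions: round-robin chromosomes 1-22; the first chr6 block
    is pinned to overlap the 25-35 Mb MHC interval so region modes have
    something to act on."""
    chroms, positions, ids = [], [], []
    first_chr6 = None
    for b in range(model.n_blocks):
        chrom = (b % 22) + 1
        if chrom == 6 and first_chr6 is None:
            first_chr6 = b
            start = MHC_START
        else:
            start = 1_000_000 + (b // 22) * (model.block_span_bp + 500_000)
        step = max(model.block_span_bp // model.snps_per_block, 1)
        for k in range(model.snps_per_block):
            pos = start + k * step
            chroms.append(str(chrom))
            positions.append(pos)
            ids.append(f"var_{b}_{k}_chr{chrom}:{pos}")
    return pd.DataFrame({"chrom": chroms, "pos": positions, "id": ids})


def _ancestral_draws(model: PopulationModel, seed: int):
    rng = np.random.default_rng([seed, _SALT_ANCESTRAL])
    lo, hi = model.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, model.n_variants)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), model.n_variants)
    return p_anc, pair_idx


def _population_freqs(model: PopulationModel, p_anc: np.ndarray,
                      population: str, seed: int) -> np.ndarray:
    if model.fst == 0:
        return p_anc.copy()
    rng = np.random.default_rng([seed, _SALT_POPFREQ, _pop_salt(population)])
    a = p_anc * (1 - model.fst) / model.fst
    b = (1 - p_anc) * (1 - model.fst) / model.fst
    p = rng.beta(a, b)
    # keep every variant polymorphic in expectation; extreme draws are
    # clipped so downstream frequency-based code never divides by zero
    return np.clip(p, 1e-4, 1 - 1e-4)


def generate_haplotype_panel(model: PopulationModel, population: str,
                             n_individuals: int, seed: int,
                             freq_seed: int | None = None) -> GenotypeMatrix:
    """Simulate a diploid dosage panel for one population.

    Two independent haplotypes per individual are drawn per block from an
    AR(1) latent Gaussian (correlation ``rho^|i-j|`` between variants i, j);
    a haplotype carries the counted allele when its latent value is below
    ``Phi^-1(freq)``, so the counted-allele frequency is the Balding-Nichols
    population frequency. Dosage = sum of the two haplotypes.

    ``freq_seed`` pins the ancestral and population allele-frequency draws
    (and hence the population's LD structure). It defaults to ``seed``;
    pass one common value when several independent panels — a reference
    panel, a discovery cohort and a target cohort, say — must sample the
    same two populations, and vary ``seed`` to get independent individuals.
    """
    if n_individuals < 2:
        raise InputError("n_individuals must be >= 2")
    if freq_seed is None:
        freq_seed = seed
    p_anc, pair_idx = _ancestral_draws(model, freq_seed)
    p_pop = _population_freqs(model, p_anc, population, freq_seed)
    thresholds = stats.norm.ppf(p_pop)

    rng = np.random.default_rng([seed, _SALT_GENO, _pop_salt(population)])
    rho = model.within_block_rho
    k = model.snps_per_block
    dosage = np.empty((n_individuals, model.n_variants))
    for b in range(model.n_blocks):
        sl = slice(b * k, (b + 1) * k)
        thr = thresholds[sl]
        block = np.zeros((n_individuals, k))
        for _hap in range(2):
            z = rng.standard_normal((n_individuals, k))
            x = np.empty_like(z)
            x[:, 0] = z[:, 0]
            scale = np.sqrt(1.0 - rho * rho)
            for j in range(1, k):
                x[:, j] = rho * x[:, j - 1] + scale * z[:, j]
            block += (x < thr).astype(float)
        dosage[:, sl] = block

    variants = _variant_metadata(model)
    variants["a1"] = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    variants["a2"] = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    samples = np.array([f"{population}_{i:06d}" for i in range(n_individuals)])
    populations = np.array([population] * n_individuals)
    return GenotypeMatrix(dosage, variants, samples, populations)


def inject_missingness(genotypes: GenotypeMatrix, rate: float,
                       seed: int) -> GenotypeMatrix:
    """Set a random fraction of genotype entries to missing (NaN)."""
    if not (0.0 <= rate < 1.0):
        raise ConfigurationError("missingness rate must lie in [0, 1)")
    rng = np.random.default_rng([seed, 606])
    d = genotypes.dosages.copy()
    mask = rng.random(d.shape) < rate
    d[mask] = np.nan
    out = GenotypeMatrix(d, genotypes.variants.copy(), genotypes.samples,
                         genotypes.populations)
    return out


def generate_phenotypes(cohort_genotypes: GenotypeMatrix, disease: DiseaseModel,
                        seed: int,
                        architecture_seed: int | None = None) -> SyntheticCohort:
    """Attach a liability-threshold phenotype and covariates to genotypes.

    Liability = standardized-genotype weighted causal burden (variance
    rescaled to exactly ``h2_liability``) + Normal(0, 1 - h2) noise; case
    iff liability > ``Phi^-1(1 - K)``. Covariates: age ~ Normal(41, 14)
    truncated to [18, 90], sex ~ Bernoulli(0.5) and the top four principal
    components of the genotype matrix. Age and sex are independent of
    disease; the analysis adjusts for them, it does not model their effect.
    ``true_betas`` (per-variant, zero for non-causal) are retained for
    parameter-recovery tests.

    ``architecture_seed`` selects the causal-variant set and raw effect
    draws; leave it at its default (= ``seed``) for a standalone cohort,
    and pass one common value when several cohorts (discovery, matched
    target, diverged target) must share a single disease architecture
    while keeping independent environmental noise and covariates.
    """
    g = cohort_genotypes
    if np.isnan(g.dosages).any():
        raise InputError("genotypes must be complete; inject missingness after "
                         "phenotype generation")
    n, m = g.dosages.shape
    if architecture_seed is None:
        architecture_seed = seed

    rng_causal = np.random.default_rng([architecture_seed, _SALT_CAUSAL])
    betas = np.zeros(m)
    n_causal = int(round(disease.causal_fraction * m))
    if disease.h2_liability > 0 and n_causal == 0:
        raise ConfigurationError(
            "h2_liability > 0 requires a nonzero causal_fraction")
    if n_causal > 0 and disease.h2_liability > 0:
        causal_idx = rng_causal.choice(m, size=n_causal, replace=False)
        raw = rng_causal.normal(0.0, 1.0, n_causal)
        gs = g.standardized()
        genetic = gs[:, causal_idx] @ raw
        sd = genetic.std()
        if sd == 0:
            raise InputError("causal variants carry no genotypic variance")
        scale = np.sqrt(disease.h2_liability) / sd
        genetic *= scale
        betas[causal_idx] = raw * scale
    else:
        genetic = np.zeros(n)

    rng = np.random.default_rng([seed, 707])
    noise = rng.normal(0.0, np.sqrt(1.0 - disease.h2_liability), n)
    liability = genetic + noise
    threshold = stats.norm.ppf(1.0 - disease.prevalence_K)
    case = (liability > threshold).astype(int)

    a, b = (18 - 41) / 14, (90 - 41) / 14
    age = stats.truncnorm.rvs(a, b, loc=41, scale=14, size=n, random_state=rng)
    sex = rng.integers(0, 2, n)
    pcs = _genotype_pcs(g, n_pcs=4, seed=seed)
    covariates = pd.DataFrame(
        {"age": age, "sex": sex,
         **{f"pc{i + 1}": pcs[:, i] for i in range(pcs.shape[1])}},
        index=pd.Index(g.samples, name="id"),
    )
    return SyntheticCohort(g, case, covariates, betas, liability)


def _genotype_pcs(genotypes: GenotypeMatrix, n_pcs: int, seed: int) -> np.ndarray:
    from sklearn.decomposition import PCA

    gs = genotypes.standardized()
    k = min(n_pcs, min(gs.shape) - 1)
    k = max(k, 1)
    pca = PCA(n_components=k, random_state=seed % (2 ** 31))
    scores = pca.fit_transform(gs)
    if scores.shape[1] < n_pcs:  # rank-deficient toy matrices: pad with zeros
        pad = np.zeros((scores.shape[0], n_pcs - scores.shape[1]))
        scores = np.hstack([scores, pad])
    return scores


def generate_discovery_sumstats(discovery_cohort: SyntheticCohort, seed: int,
                                palindromic_fraction: float = 0.05,
                                strand_flip_fraction: float = 0.05,
                                mask_causal: bool = False) -> SummaryStatSet:
    """Single-variant association scan of the discovery cohort.

    Per variant a logistic score test of case status on dosage is computed
    under the intercept-only null: ``U = sum (y - ybar) g``,
    ``V = ybar (1 - ybar) sum (g - gbar)^2``, z = U/sqrt(V), with the
    one-step effect estimate ``beta = U/V`` and ``se = 1/sqrt(V)`` — the
    standard fast approximation to the per-variant logistic Wald fit.

    Monomorphic variants (V = 0) are flagged and excluded from the output.
    With ``mask_causal`` the truly causal variants are withheld, so any
    downstream score must rely on LD tags — the mechanism behind
    cross-ancestry attenuation. A fraction of emitted variants has its
    allele pair rewritten as palindromic (A/T or C/G) and a disjoint
    fraction is strand-complemented, to exercise harmonization; the
    affected variant ids are recorded in ``meta``.
    """
    cohort = discovery_cohort
    g = cohort.genotypes
    pops = g.populations
    if pops is not None and len(np.unique(pops)) > 1:
        raise InputError("discovery cohort must come from a single population")
    y = cohort.phenotype.astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise InputError("discovery cohort needs both cases and controls")
    if not (0 <= palindromic_fraction <= 1 and 0 <= strand_flip_fraction <= 1):
        raise ConfigurationError("injection fractions must lie in [0, 1]")

    d = g.mean_imputed()
    ybar = y.mean()
    resid = y - ybar
    u = resid @ d
    centered = d - d.mean(axis=0)
    v = ybar * (1 - ybar) * np.einsum("ij,ij->j", centered, centered)

    monomorphic = v <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(monomorphic, np.nan, u / v)
        se = np.where(monomorphic, np.nan, 1.0 / np.sqrt(v))
        chi2 = np.where(monomorphic, np.nan, u * u / v)
    p = stats.chi2.sf(chi2, df=1)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    table = g.variants[["chrom", "pos", "id", "a1", "a2"]].copy()
    table["beta"] = beta
    table["se"] = se
    table["p"] = p

    keep = ~monomorphic
    if mask_causal:
        keep &= cohort.true_betas == 0
    monomorphic_ids = list(table.loc[monomorphic, "id"])
    table = table[keep].reset_index(drop=True)

    rng = np.random.default_rng([seed, _SALT_INJECT])
    m = len(table)
    n_pal = int(round(palindromic_fraction * m))
    n_flip = int(round(strand_flip_fraction * m))
    perm = rng.permutation(m)
    pal_idx = perm[:n_pal]
    flip_idx = perm[n_pal:n_pal + n_flip]

    a1 = table["a1"].to_numpy(dtype=object)
    a2 = table["a2"].to_numpy(dtype=object)
    pal_pairs = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
    for i in pal_idx:
        a1[i], a2[i] = pal_pairs[rng.integers(0, 4)]
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for i in flip_idx:
        a1[i], a2[i] = comp[a1[i]], comp[a2[i]]
    table["a1"] = a1
    table["a2"] = a2

    meta = {
        "palindromic_ids": sorted(table["id"].iloc[pal_idx]),
        "strand_flipped_ids": sorted(table["id"].iloc[flip_idx]),
        "monomorphic_ids": monomorphic_ids,
        "masked_causal": bool(mask_causal),
    }
    out = SummaryStatSet(table, meta)
    out.validate()
    return out
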