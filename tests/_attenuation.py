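"""Shared two-population attenuation study used by property and acceptance
tests.

One disease architecture is shared by a discovery cohort, a matched-ancestry
target (same population as discovery) and an LD-diverged target. Discovery
summary statistics are estimated with the causal variants withheld
("tag-only"), so any predictive power must travel through LD tags; the
diverged population's perturbed allele frequencies reshuffle tag-causal
correlations, which is the mechanism behind cross-ancestry PRS attenuation.

Study conditions (fixed): 60 independent LD blocks of 10 SNPs, Fst 0.3,
within-block latent correlation 0.9, ancestral frequencies U(0.2, 0.8);
10% causal variants, liability h² 0.25, prevalence 0.1 (high enough that
cohorts of a few thousand carry hundreds of cases); clumping r² 0.1. The
effect size was chosen so the matched-ancestry target's liability R² is
near 0.05.
"""

import numpy as np
import pandas as pd

import crossprs as cp

POP_MODEL = dict(n_blocks=60, snps_per_block=10, fst=0.3,
                 within_block_rho=0.9, ancestral_freq_range=(0.2, 0.8))
DISEASE = dict(causal_fraction=0.1, h2_liability=0.25, prevalence_K=0.1)
K = DISEASE["prevalence_K"]
CLUMP_R2 = 0.1
CANDIDATE_P = (0.01, 0.05, 0.5)


def make_models():
    return cp.PopulationModel(**POP_MODEL), cp.DiseaseModel(**DISEASE)


def discovery_and_reference(seed, n_disc=8000):
    """Discovery cohort, tag-only sumstats and an LD reference panel."""
    pm, dm = make_models()
    disc_g = cp.generate_haplotype_panel(pm, "POP1", n_disc, seed + 11,
                                         freq_seed=seed)
    disc = cp.generate_phenotypes(disc_g, dm, seed + 11,
                                  architecture_seed=seed)
    sumstats = cp.generate_discovery_sumstats(
        disc, seed, palindromic_fraction=0.0, strand_flip_fraction=0.0,
        mask_causal=True)
    reference = cp.generate_haplotype_panel(pm, "POP1", 503, seed + 91,
                                            freq_seed=seed)
    return disc, sumstats, reference


def target_cohort(seed, population, n, cohort_seed_offset):
    pm, dm = make_models()
    g = cp.generate_haplotype_panel(pm, population, n,
                                    seed + cohort_seed_offset, freq_seed=seed)
    cohort = cp.generate_phenotypes(g, dm, seed + cohort_seed_offset,
                                    architecture_seed=seed)
    return cohort


def score_candidates(sumstats, reference, genotypes,
                     p_thresholds=CANDIDATE_P) -> pd.DataFrame:
    """Clump once at the fixed r² and score at each candidate threshold."""
    hset = cp.harmonize(sumstats, genotypes)
    index_ids = cp.ld_clump(hset, reference, CLUMP_R2, 250_000)
    matched = hset.matched
    clumped = matched[matched["id"].isin(index_ids)]
    return pd.DataFrame({
        f"p{pt:g}": cp.compute_prs(genotypes, clumped[clumped["p"] <= pt]).scores
        for pt in p_thresholds
    })


def optimal_r2(scores: pd.DataFrame, cohort) -> float:
    """Liability R² of the best-fitting candidate in this cohort."""
    evals = [
        cp.evaluate_prs(scores[c].to_numpy(), cohort.phenotype,
                        cohort.covariates, K=K, config_label=c, minimal=True)
        for c in scores.columns
    ]
    return cp.select_optimal(evals).r2_liability_adjusted


def matched_vs_diverged_r2(seed, n_target=6000, p_threshold=0.05):
    """Liability R² of the fixed-configuration score in a matched-ancestry
    and an LD-diverged target sharing the discovery's disease."""
    _, sumstats, reference = discovery_and_reference(seed)
    out = {}
    for offset, pop in ((21, "POP1"), (22, "POP2")):
        cohort = target_cohort(seed, pop, n_target, offset)
        scores = score_candidates(sumstats, reference, cohort.genotypes,
                                  p_thresholds=(p_threshold,))
        ev = cp.evaluate_prs(scores.iloc[:, 0].to_numpy(), cohort.phenotype,
                             cohort.covariates, K=K, minimal=True)
        out[pop] = ev.r2_liability_adjusted
    return out["POP1"], out["POP2"]
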