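"""Clumping-and-thresholding PRS construction.

The score for individual *i* is the weighted allelic burden
``PRS_i = sum_j G_ij * beta_j`` over the variants surviving LD clumping
against a reference panel and a p-value threshold, where ``G_ij`` is the
effect-allele dosage (missing genotypes contribute the variant's sample
mean, so an untyped genotype adds 0 after centring around the mean) and
``beta_j`` the harmonized log-odds effect.

Clumping is greedy: variants are visited in order of ascending p-value
(ties broken by chromosome, position, then alleles, for determinism); each
visited unassigned variant becomes an index and removes every unassigned
variant within the physical window whose squared dosage correlation with it
in the reference exceeds the r² threshold. Region modes build scores with
the MHC interval (chr6:25-35 Mb), without it, or from it alone; the region
filter is applied before clumping so each score's clumps are internally
consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .containers import ConfigurationError, GenotypeMatrix
from .harmonize import HarmonizedSet

#: the field-standard clumping r² grid
DEFAULT_CLUMP_R2 = (0.001, 0.01, 0.05, 0.1, 0.2, 0.4, 0.6)
#: the field-standard p-value threshold grid
DEFAULT_P_THRESHOLDS = (
    1e-8, 5e-8, 1e-7, 5e-7, 1e-6, 5e-6, 1e-5, 5e-5,
    1e-4, 5e-4, 1e-3, 5e-3, 0.01, 0.05, 0.1, 0.5,
)
MODE_WITH_MHC = "with_mhc"
MODE_WITHOUT_MHC = "without_mhc"
MODE_MHC_ONLY = "mhc_only"
ALL_MODES = (MODE_WITH_MHC, MODE_WITHOUT_MHC, MODE_MHC_ONLY)

DEFAULT_MHC_REGION = ("6", 25_000_000, 35_000_000)


@dataclass
class PrsGridSpec:
    """Enumeration of (clumping r², p-threshold, region mode) configurations."""

    clump_r2_values: tuple = DEFAULT_CLUMP_R2
    p_thresholds: tuple = DEFAULT_P_THRESHOLDS
    mhc_modes: tuple = ALL_MODES
    clump_window_bp: int = 250_000
    mhc_region: tuple = DEFAULT_MHC_REGION

    def __post_init__(self) -> None:
        for r2 in self.clump_r2_values:
            if not (0.0 < r2 <= 1.0):
                raise ConfigurationError(f"clump r2 {r2} outside (0, 1]")
        for p in self.p_thresholds:
            if not (0.0 < p <= 1.0):
                raise ConfigurationError(f"p threshold {p} outside (0, 1]")
        bad = [m for m in self.mhc_modes if m not in ALL_MODES]
        if bad:
            raise ConfigurationError(f"unknown region modes {bad}")
        if self.clump_window_bp <= 0:
            raise ConfigurationError("clump_window_bp must be positive")

    @property
    def n_configurations(self) -> int:
        return (len(self.clump_r2_values) * len(self.p_thresholds)
                * len(self.mhc_modes))

    def configurations(self):
        """Deterministic enumeration order: mode, then r², then p."""
        return list(product(self.mhc_modes, self.clump_r2_values,
                            self.p_thresholds))


@dataclass
class PrsResult:
    """Per-individual scores for one grid configuration."""

    mhc_mode: str
    clump_r2: float
    p_threshold: float
    n_snps_included: int
    scores: np.ndarray
    sample_ids: np.ndarray
    all_missing_variants: int = 0
    empty: bool = False

    @property
    def config_label(self) -> str:
        return f"{self.mhc_mode}|r2={self.clump_r2}|p={self.p_threshold}"


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric-first chromosome ordering (1..22 then lexicographic)."""
    num = pd.to_numeric(chrom, errors="coerce")
    return num.fillna(1000)


def ld_clump(variants: HarmonizedSet | pd.DataFrame, reference: GenotypeMatrix,
             r2_threshold: float, window_bp: int = 250_000) -> set:
    """Greedy LD clumping; returns the set of index-variant ids.

    ``variants`` must carry ``chrom``, ``pos``, ``id``, ``a1``, ``a2`` and
    ``p`` columns (a :class:`HarmonizedSet`'s matched rows qualify). r² is
    the squared Pearson correlation of mean-imputed dosages in the
    reference panel, matched on chromosome + position. Variants absent from
    the reference cannot be clumped and are retained as indices, with a
    warning reporting how many.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ConfigurationError(f"r2_threshold {r2_threshold} outside (0, 1]")
    table = variants.matched if isinstance(variants, HarmonizedSet) else variants
    if len(table) == 0:
        return set()
    t = table.copy()
    t["_ckey"] = _chrom_sort_key(t["chrom"])
    t = t.sort_values(["p", "_ckey", "pos", "a1", "a2"], kind="mergesort")

    ref_lookup = {}
    rv = reference.variants
    for j, (chrom, pos) in enumerate(zip(rv["chrom"], rv["pos"].astype(int))):
        ref_lookup[(chrom, int(pos))] = j
    ref_cols = np.array([
        ref_lookup.get((c, int(p)), -1)
        for c, p in zip(t["chrom"], t["pos"].astype(int))
    ])
    n_absent = int((ref_cols == -1).sum())
    if n_absent:
        warnings.warn(
            f"{n_absent} variants absent from the LD reference are retained "
            "unclumped", stacklevel=2)

    d = reference.mean_imputed()
    centered = d - d.mean(axis=0)
    norms = np.sqrt((centered ** 2).sum(axis=0))

    chroms = t["chrom"].to_numpy()
    positions = t["pos"].to_numpy(dtype=int)
    ids = t["id"].to_numpy()
    m = len(t)
    assigned = np.zeros(m, dtype=bool)
    index_ids = set()
    for i in range(m):
        if assigned[i]:
            continue
        assigned[i] = True
        index_ids.add(ids[i])
        ji = ref_cols[i]
        if ji == -1:
            continue
        cand = np.flatnonzero(
            (~assigned)
            & (chroms == chroms[i])
            & (np.abs(positions - positions[i]) <= window_bp)
            & (ref_cols != -1)
        )
        if cand.size == 0:
            continue
        xi = centered[:, ji]
        ni = norms[ji]
        jc = ref_cols[cand]
        denom = norms[jc] * ni
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (centered[:, jc].T @ xi) / denom
        r2 = np.where(denom == 0, 0.0, r * r)
        assigned[cand[r2 > r2_threshold]] = True
    return index_ids


def apply_region_mode(variants: pd.DataFrame, mode: str,
                      mhc_region: tuple = DEFAULT_MHC_REGION) -> pd.DataFrame:
    """Filter a variant table by MHC membership (closed interval)."""
    if mode not in ALL_MODES:
        raise ConfigurationError(f"unknown region mode {mode!r}")
    chrom, start, end = mhc_region
    in_mhc = (
        (variants["chrom"].astype(str) == str(chrom))
        & (variants["pos"].astype(int) >= start)
        & (variants["pos"].astype(int) <= end)
    )
    if mode == MODE_WITH_MHC:
        return variants
    if mode == MODE_WITHOUT_MHC:
        return variants[~in_mhc]
    return variants[in_mhc]


def compute_prs(target: GenotypeMatrix, weights: pd.DataFrame,
                mhc_mode: str = MODE_WITH_MHC, clump_r2: float = np.nan,
                p_threshold: float = np.nan) -> PrsResult:
    """Score the target cohort with harmonized weights.

    ``weights`` rows need ``target_index``, ``beta`` and ``flip``. Missing
    dosages are replaced by the variant's sample mean, so they contribute 0
    after centring; a ``flip`` row is scored on the effect-allele dosage
    ``2 - g``, which leaves the score's dependence on genotype identical to
    negating the effect (up to a constant shared by all individuals) while
    keeping region-wise additivity exact. Variants with every dosage
    missing contribute 0 to everyone and are counted.
    """
    n = target.n_individuals
    if len(weights) == 0:
        return PrsResult(mhc_mode, clump_r2, p_threshold, 0, np.zeros(n),
                         np.asarray(target.samples), empty=True)
    cols = weights["target_index"].to_numpy(dtype=int)
    if (cols < 0).any():
        raise ConfigurationError("weights contain unmatched variants")
    d = target.dosages[:, cols]
    all_missing = np.isnan(d).all(axis=0)
    with np.errstate(invalid="ignore"):
        col_means = np.nanmean(np.where(all_missing, 0.0, d), axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    d = np.where(np.isnan(d), col_means, d)
    flip = weights["flip"].to_numpy(dtype=bool)
    d = np.where(flip, 2.0 - d, d)
    betas = weights["beta"].to_numpy(dtype=float)
    scores = d @ betas
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} scored variants have no observed "
            "genotypes and contribute 0", stacklevel=2)
    return PrsResult(mhc_mode, clump_r2, p_threshold, int(len(weights)),
                     scores, np.asarray(target.samples),
                     all_missing_variants=int(all_missing.sum()))


def run_grid(spec: PrsGridSpec, sumstats: HarmonizedSet,
             target: GenotypeMatrix, reference: GenotypeMatrix) -> list:
    """One :class:`PrsResult` per (mode, r², p-threshold) configuration.

    Clumping runs once per (mode, r²) pair on the full region-filtered
    harmonized set and is reused across p-thresholds (clump-then-threshold).
    Output order is deterministic: modes, then r² values, then thresholds,
    each in the order given by the grid specification.
    """
    results = []
    matched = sumstats.matched
    for mode in spec.mhc_modes:
        region_variants = apply_region_mode(matched, mode, spec.mhc_region)
        for r2 in spec.clump_r2_values:
            index_ids = ld_clump(region_variants, reference, r2,
                                 spec.clump_window_bp)
            clumped = region_variants[region_variants["id"].isin(index_ids)]
            for p_thr in spec.p_thresholds:
                sel = clumped[clumped["p"] <= p_thr]
                res = compute_prs(target, sel, mode, r2, p_thr)
                if res.n_snps_included == 0:
                    res.empty = True
                results.append(res)
    return results
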