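"""Core in-memory containers shared across the pipeline.

Two containers travel through every stage: :class:`GenotypeMatrix`, an
individuals x variants dosage matrix with per-variant metadata, and
:class:`SummaryStatSet`, a table of per-variant GWAS association results
(effect sizes on the log-odds scale). Both are thin wrappers around numpy
arrays / pandas frames so that downstream code can rely on a validated,
consistently-named surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical variant metadata columns for a GenotypeMatrix
VARIANT_COLUMNS = ("chrom", "pos", "id", "a1", "a2")

AUTOSOMES = frozenset(str(c) for c in range(1, 23))


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G pairs cannot be oriented from allele labels alone."""
    return a2 == COMPLEMENT.get(a1, "")


def complement_allele(a: str) -> str:
    return COMPLEMENT[a]


class ConfigurationError(ValueError):
    """A model / threshold / grid parameter is outside its valid range."""


class InputError(ValueError):
    """An input table or matrix violates a precondition of an operation."""


@dataclass
class GenotypeMatrix:
    """Dosage matrix for a cohort.

    Parameters
    ----------
    dosages:
        float array of shape ``(n_individuals, n_variants)``; entries are
        expected alternate-allele (``a1``) counts in ``[0, 2]``, with
        ``numpy.nan`` marking missing genotypes.
    variants:
        per-variant metadata with columns ``chrom`` (str), ``pos`` (1-based
        int), ``id``, ``a1`` (counted/effect allele), ``a2``; an optional
        ``info`` column carries imputation quality.
    samples:
        individual identifiers, one per row of ``dosages``.
    populations:
        optional per-individual ancestry label.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: np.ndarray
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.samples = np.asarray(self.samples)
        if self.dosages.ndim != 2:
            raise InputError("dosages must be a 2-D individuals x variants array")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise InputError(
                f"sample count {len(self.samples)} != dosage rows {n}"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise InputError(f"variant table lacks columns {missing}")
        if len(self.variants) != m:
            raise InputError(
                f"variant table rows {len(self.variants)} != dosage columns {m}"
            )
        self.variants = self.variants.reset_index(drop=True)
        self.variants["chrom"] = self.variants["chrom"].astype(str)
        if self.populations is not None:
            self.populations = np.asarray(self.populations)
            if len(self.populations) != n:
                raise InputError("populations length != individual count")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_missingness(self) -> np.ndarray:
        """Fraction of missing genotypes per variant."""
        return np.isnan(self.dosages).mean(axis=0)

    def variant_call_rate(self) -> np.ndarray:
        return 1.0 - self.variant_missingness()

    def individual_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Counted-allele (a1) frequency from non-missing dosages.

        Variants with no observed genotypes get frequency ``nan``.
        """
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def mean_imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the variant mean.

        A variant with all genotypes missing imputes to 0 (it carries no
        information and contributes nothing to scores).
        """
        d = self.dosages.copy()
        mask = np.isnan(d)
        if mask.any():
            with np.errstate(invalid="ignore"):
                col_means = np.nanmean(d, axis=0)
            col_means = np.where(np.isnan(col_means), 0.0, col_means)
            d[mask] = np.broadcast_to(col_means, d.shape)[mask]
        return d

    def standardized(self) -> np.ndarray:
        """Mean-imputed, per-variant standardized dosages.

        Zero-variance variants standardize to all-zero columns.
        """
        d = self.mean_imputed()
        mu = d.mean(axis=0)
        sd = d.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return (d - mu) / sd

    def subset_variants(self, index) -> "GenotypeMatrix":
        """New matrix keeping the variants at positional ``index``."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            dosages=self.dosages[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
        )

    def subset_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            dosages=self.dosages[index, :],
            variants=self.variants.copy(),
            samples=self.samples[index],
            populations=None if self.populations is None else self.populations[index],
        )


#: canonical summary-statistic columns (internal names)
SUMSTAT_COLUMNS = ("chrom", "pos", "id", "a1", "a2", "beta", "se", "p")


@dataclass
class SummaryStatSet:
    """Per-variant discovery-GWAS association results.

    ``table`` columns: ``chrom``, ``pos``, ``id``, ``a1`` (effect allele),
    ``a2`` (other allele), ``beta`` (log-odds per a1 copy), ``se``, ``p``.
    ``meta`` records provenance bookkeeping such as which variant ids had a
    strand flip injected by the simulator.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"summary statistics lack columns {missing}")
        self.table = self.table.reset_index(drop=True)
        self.table["chrom"] = self.table["chrom"].astype(str)

    def validate(self) -> None:
        """Enforce biallelic-SNP invariants: A/C/G/T alleles, a1 != a2, p in (0, 1]."""
        t = self.table
        bad_allele = ~(t["a1"].isin(VALID_BASES) & t["a2"].isin(VALID_BASES))
        if bad_allele.any():
            raise InputError(
                f"{int(bad_allele.sum())} variants with non-ACGT alleles "
                f"(first: {t.loc[bad_allele, 'id'].iloc[0]!r})"
            )
        same = t["a1"] == t["a2"]
        if same.any():
            raise InputError(
                f"{int(same.sum())} variants with identical alleles"
            )
        bad_p = ~((t["p"] > 0) & (t["p"] <= 1))
        if bad_p.any():
            raise InputError(f"{int(bad_p.sum())} variants with p outside (0, 1]")

    @property
    def n_variants(self) -> int:
        return len(self.table)
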