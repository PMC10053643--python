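"""Readers and writers for the pipeline's on-disk formats.

Summary statistics travel as tab-delimited text with header columns
CHR, BP, SNP, A1 (effect allele), A2, BETA, SE, P (an OR column is
accepted in place of BETA and converted to the log scale). Genotypes are
read from VCF (DS dosage field preferred, GT fallback) via cyvcf2 or from
a plain dosage-matrix TSV whose first column is the individual id and
whose remaining columns are variants named ``chrom:pos:a1:a2`` with
missing entries encoded as NA; the same two formats are written.
Simulation configuration is YAML mirroring the population/disease model
fields, with a mandatory seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .containers import GenotypeMatrix, InputError, SummaryStatSet
from .synthetic import DiseaseModel, PopulationModel

SUMSTAT_HEADER = ["CHR", "BP", "SNP", "A1", "A2", "BETA", "SE", "P"]
_TO_INTERNAL = {"CHR": "chrom", "BP": "pos", "SNP": "id", "A1": "a1",
                "A2": "a2", "BETA": "beta", "SE": "se", "P": "p"}
_TO_EXTERNAL = {v: k for k, v in _TO_INTERNAL.items()}


# ----------------------------------------------------------------------
# summary statistics
# ----------------------------------------------------------------------

def write_sumstats(sumstats: SummaryStatSet, path) -> None:
    out = sumstats.table[list(_TO_INTERNAL.values())].rename(
        columns=_TO_EXTERNAL)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sumstats(path, strict: bool = True) -> SummaryStatSet:
    """Read a summary-statistics TSV; an OR column is converted to log-odds."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    cols = {c.upper(): c for c in df.columns}
    if "BETA" not in cols and "OR" in cols:
        df["BETA"] = np.log(df[cols["OR"]].astype(float))
        df = df.drop(columns=[cols["OR"]])
        cols["BETA"] = "BETA"
    missing = [c for c in SUMSTAT_HEADER if c not in cols]
    if missing:
        raise InputError(f"summary statistics file lacks columns {missing}")
    df = df.rename(columns={cols[c]: _TO_INTERNAL[c] for c in SUMSTAT_HEADER})
    out = SummaryStatSet(df[list(_TO_INTERNAL.values())])
    if strict:
        out.validate()
    return out


# ----------------------------------------------------------------------
# dosage TSV dialect
# ----------------------------------------------------------------------

def variant_key(chrom, pos, a1, a2) -> str:
    return f"{chrom}:{pos}:{a1}:{a2}"


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    keys = [variant_key(c, p, a1, a2) for c, p, a1, a2 in zip(
        genotypes.variants["chrom"], genotypes.variants["pos"],
        genotypes.variants["a1"], genotypes.variants["a2"])]
    df = pd.DataFrame(genotypes.dosages, columns=keys)
    df.insert(0, "id", genotypes.samples)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.columns[0] != "id":
        raise InputError("dosage TSV must have 'id' as its first column")
    samples = df["id"].astype(str).to_numpy()
    keys = list(df.columns[1:])
    meta = []
    for k in keys:
        parts = k.split(":")
        if len(parts) != 4:
            raise InputError(
                f"dosage TSV variant column {k!r} is not chrom:pos:a1:a2")
        meta.append({"chrom": parts[0], "pos": int(parts[1]), "id": k,
                     "a1": parts[2], "a2": parts[3]})
    dosages = df[keys].to_numpy(dtype=float)
    return GenotypeMatrix(dosages, pd.DataFrame(meta), samples)


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write an uncompressed VCF 4.2 with GT (rounded hard call) and DS."""
    g = genotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = list(dict.fromkeys(g.variants["chrom"]))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.samples)) + "\n")
        for j, row in g.variants.iterrows():
            # a1 is the counted (dosage) allele, i.e. the VCF ALT
            fields = [str(row["chrom"]), str(int(row["pos"])), str(row["id"]),
                      str(row["a2"]), str(row["a1"]), ".", "PASS", ".", "GT:DS"]
            col = g.dosages[:, j]
            for d in col:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    hard = int(round(min(max(d, 0.0), 2.0)))
                    gt = ["0/0", "0/1", "1/1"][hard]
                    fields.append(f"{gt}:{d:.4g}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF; DS dosages preferred, GT otherwise."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    meta, columns = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # multiallelic records are not scoreable here
        try:
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            ds = None
        if ds is None:
            gts = np.asarray(var.genotype.array())[:, :2].astype(float)
            gts[gts < 0] = np.nan
            ds = gts.sum(axis=1)
        else:
            ds = np.where((ds < 0) | (ds > 2), np.nan, ds)
        meta.append({"chrom": str(var.CHROM), "pos": int(var.POS),
                     "id": var.ID or variant_key(var.CHROM, var.POS,
                                                 var.ALT[0], var.REF),
                     "a1": var.ALT[0], "a2": var.REF})
        columns.append(ds)
    if not meta:
        raise InputError(f"no biallelic variants found in {path}")
    dosages = np.column_stack(columns)
    return GenotypeMatrix(dosages, pd.DataFrame(meta), samples)


def read_genotypes(path) -> GenotypeMatrix:
    """Dispatch on extension: .vcf -> VCF reader, otherwise dosage TSV."""
    s = str(path)
    if s.endswith((".vcf", ".vcf.gz")):
        return read_vcf(path)
    return read_dosage_tsv(path)


# ----------------------------------------------------------------------
# phenotype / covariate table
# ----------------------------------------------------------------------

PHENO_COLUMNS = ["id", "case", "age", "sex", "pc1", "pc2", "pc3", "pc4"]


def write_phenotypes(phenotype, covariates: pd.DataFrame, path) -> None:
    df = covariates.copy()
    df.insert(0, "case", np.asarray(phenotype, dtype=int))
    df.index.name = "id"
    df.reset_index().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"phenotype table lacks columns {missing}")
    return df.set_index("id")


# ----------------------------------------------------------------------
# YAML simulation config
# ----------------------------------------------------------------------

def load_config(path) -> tuple[PopulationModel, DiseaseModel, int]:
    """Load a simulation config; the seed is mandatory."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "seed" not in cfg:
        raise InputError("simulation config must set an explicit seed")
    pop = PopulationModel(**(cfg.get("population") or {}))
    if "ancestral_freq_range" in (cfg.get("population") or {}):
        pop.ancestral_freq_range = tuple(pop.ancestral_freq_range)
    disease = DiseaseModel(**(cfg.get("disease") or {}))
    return pop, disease, int(cfg["seed"])
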