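"""Tab-delimited readers and writers for every pipeline artifact.

Missing values are empty cells.  Round trips are exact: reading a written
cohort or genotype table reproduces the original values (floats are
written at full precision).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .genetics import GenotypeMatrix, PRSModel
from .synthetic import CANCERS, Cohort, FactorSpec

COHORT_REQUIRED = ("participant_id", "current_age")


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="",
              float_format="%.17g")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_cohort(cohort: Cohort, path) -> Path:
    return write_table(cohort.table, path)


def read_cohort(path, factors: Optional[Sequence[FactorSpec]] = None) \
        -> Cohort:
    """Read a cohort table, checking the mandatory schema.

    Unknown columns are preserved.  Missing mandatory columns raise a
    schema error naming them; malformed numeric cells raise with the
    (1-based) row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str},
                     float_precision="round_trip")
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    missing += [f"case_{c}" for c in CANCERS
                if f"case_{c}" not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks mandatory columns: "
                         f"{missing}")
    numeric_like = [c for c in df.columns
                    if c not in ("participant_id",)
                    and not (factors and any(
                        f.name == c and f.kind == "categorical"
                        for f in factors))]
    for c in numeric_like:
        if pd.api.types.is_numeric_dtype(df[c]):
            continue
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df[c].notna() & coerced.isna()
        if bad.any():
            row = int(np.where(bad)[0][0]) + 1
            raise ValueError(f"malformed numeric cell in column {c!r}, "
                             f"row {row}")
        df[c] = coerced
    if factors:
        for f in factors:
            if f.kind == "categorical" and f.name in df.columns:
                df[f.name] = pd.Categorical(
                    df[f.name], categories=f.params["levels"])
    return Cohort(table=df, factors=list(factors) if factors else [])


def write_genotypes(genotypes: GenotypeMatrix, matrix_path,
                    variants_path) -> tuple:
    mat = pd.DataFrame(genotypes.dosages,
                       columns=genotypes.variants["variant_id"])
    mat.insert(0, "participant_id", genotypes.participant_ids)
    return (write_table(mat, matrix_path),
            write_table(genotypes.variants, variants_path))


def read_genotypes(matrix_path, variants_path) -> GenotypeMatrix:
    mat = pd.read_csv(matrix_path, sep="\t", dtype={"participant_id": str},
                      float_precision="round_trip")
    variants = pd.read_csv(variants_path, sep="\t")
    ids = mat["participant_id"].tolist()
    dosages = mat.drop(columns=["participant_id"]).to_numpy(dtype=float)
    order = [list(mat.columns[1:]).index(v)
             for v in variants["variant_id"]]
    return GenotypeMatrix(dosages=dosages[:, order], participant_ids=ids,
                          variants=variants)


def read_vcf_dosages(path) -> GenotypeMatrix:
    """Read a VCF into the internal dosage matrix.

    Uses per-genotype ``DS`` (imputed dosage) FORMAT fields when present,
    otherwise counts alternate alleles from the hard genotypes.  The ALT
    allele is the effect allele; MAF comes from the dosages themselves.
    """
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, rows = [], []
    for v in vcf:
        ds = v.format("DS")
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(len(samples))
        else:
            gts = np.asarray(v.genotypes, dtype=object)
            dose = np.array([
                sum(int(a) for a in g[:-1] if int(a) >= 0) for g in gts],
                dtype=float)
        rows.append({"variant_id": v.ID or f"{v.CHROM}:{v.POS}",
                     "chrom": str(v.CHROM).removeprefix("chr"),
                     "pos": int(v.POS),
                     "effect_allele": v.ALT[0] if v.ALT else "."})
        cols.append(dose)
    if not cols:
        raise ValueError(f"no variants in VCF {path}")
    dosages = np.column_stack(cols)
    variants = pd.DataFrame(rows)
    try:
        variants["chrom"] = pd.to_numeric(variants["chrom"])
    except (ValueError, TypeError):
        pass  # non-numeric contig names stay strings
    freq = dosages.mean(axis=0) / 2.0
    variants["maf"] = np.minimum(freq, 1.0 - freq)
    return GenotypeMatrix(dosages=dosages, participant_ids=samples,
                          variants=variants)


def write_prs_model(model: PRSModel, assoc: pd.DataFrame, path) -> Path:
    sel = assoc[assoc["variant_id"].isin(model.variant_ids)].copy()
    sel = sel.set_index("variant_id").loc[model.variant_ids].reset_index()
    sel["weight"] = model.weights
    return write_table(sel[["variant_id", "chrom", "pos", "effect_allele",
                            "maf", "beta", "se", "p_value", "weight"]],
                       path)


def read_survival_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if "age" not in df.columns or "survival" not in df.columns:
        raise ValueError("survival table needs columns: age, survival")
    return df[["age", "survival"]]


def write_report(report: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    path.write_text(json.dumps(report, indent=2, sort_keys=True,
                               default=default) + "\n")
    return path


def write_config(config: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config, sort_keys=True))
    return path


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
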