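"""Readers and writers for pedigrees, genotypes, phenotypes and matrices.

All text formats are tab-delimited (comma accepted on read) with
mandatory headers.  Ids are opaque, case-sensitive strings; matrices are
always written with id header row and column so order mistakes surface
as id mismatches rather than silent misalignment.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .relmat import GenotypeMatrix, Pedigree, RelationshipMatrix

_SEP = "\t"


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def read_pedigree(path) -> Pedigree:
    """3-column pedigree (id, sire, dam); '0' or empty means unknown."""
    df = _read_table(path)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: pedigree needs 3 columns (id, sire, dam)")
    df = df.iloc[:, :3].fillna("0")
    return Pedigree([tuple(r) for r in df.itertuples(index=False)])


def write_pedigree(ped: Pedigree, path) -> None:
    pd.DataFrame(ped.records, columns=["id", "sire", "dam"]).to_csv(
        path, sep=_SEP, index=False
    )


def read_genotypes(path, fmt: str | None = None, impute_missing: bool = False) -> GenotypeMatrix:
    """Genotypes from VCF (biallelic diploid) or a delimited 0/1/2 matrix.

    ``fmt`` is inferred from the extension when omitted.  Missing
    genotypes are rejected unless ``impute_missing`` (per-SNP mean,
    rounded to the nearest code).
    """
    path = str(path)
    if fmt is None:
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "matrix"
    if fmt == "vcf":
        return _read_vcf(path, impute_missing)
    df = _read_table(path)
    ids = df.iloc[:, 0].tolist()
    snp_ids = df.columns[1:].tolist()
    vals = df.iloc[:, 1:].to_numpy()
    codes = np.full(vals.shape, -1, dtype=float)
    mask = (vals != "") & (vals != "NA") & pd.notna(vals)
    codes[mask] = vals[mask].astype(float)
    return _finalize_codes(ids, codes, snp_ids, impute_missing, path)


def _read_vcf(path, impute_missing):
    from cyvcf2 import VCF

    vcf = VCF(path)
    ids = list(vcf.samples)
    snp_ids, cols = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"{path}: non-biallelic record {rec.CHROM}:{rec.POS} "
                f"(ALT={rec.ALT}); only biallelic SNPs are supported"
            )
        gts = rec.genotype.array()
        if gts.shape[1] < 2:
            raise ValueError(f"{path}: non-diploid record {rec.CHROM}:{rec.POS}")
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan
        # code counts REF allele (A) copies: 2 - sum(ALT alleles)
        col = 2.0 - np.nansum(alleles, axis=1)
        col[np.isnan(alleles).any(axis=1)] = -1
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        cols.append(col)
    if not cols:
        raise ValueError(f"{path}: no usable records")
    codes = np.column_stack(cols)
    return _finalize_codes(ids, codes, snp_ids, impute_missing, path)


def _finalize_codes(ids, codes, snp_ids, impute_missing, path):
    missing = codes < 0
    if missing.all(axis=0).any():
        j = int(np.flatnonzero(missing.all(axis=0))[0])
        raise ValueError(f"{path}: SNP {snp_ids[j]!r} has no called genotypes")
    if missing.any():
        if not impute_missing:
            n_miss = int(missing.sum())
            raise ValueError(
                f"{path}: {n_miss} missing genotype call(s); pass "
                "impute_missing=True for per-SNP mean imputation"
            )
        means = np.where(missing, np.nan, codes)
        col_mean = np.nanmean(means, axis=0)
        fill = np.clip(np.rint(col_mean), 0, 2)
        codes = np.where(missing, fill[None, :], codes)
    return GenotypeMatrix(ids, codes.astype(np.int8), snp_ids=snp_ids)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.codes, index=geno.ids, columns=geno.snp_ids)
    df.index.name = "id"
    df.to_csv(path, sep=_SEP)


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype table with id, site, block headers plus trait columns.

    Blocks are nested within site: a block label occurring at two sites
    is an error.  Empty trait columns are dropped with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = ("id", "site", "block")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df["id"] = df["id"].astype(str)
    df["site"] = df["site"].astype(str)
    df["block"] = df["block"].astype(str)
    if df.duplicated(["id", "site"]).any():
        dup = df.loc[df.duplicated(["id", "site"]), "id"].iloc[0]
        raise ValueError(f"{path}: duplicate record for id {dup!r}")
    sites_per_block = df.groupby("block")["site"].nunique()
    bad = sites_per_block[sites_per_block > 1]
    if not bad.empty:
        raise ValueError(
            f"{path}: block label(s) {list(bad.index)[:5]} appear in more than "
            "one site; post-blocks are nested within site"
        )
    import warnings

    for col in [c for c in df.columns if c not in required]:
        if df[col].isna().all():
            warnings.warn(f"{path}: trait column {col!r} is empty; skipped")
            df = df.drop(columns=[col])
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_SEP, index=False)


def read_matrix(path, kind: str | None = None) -> RelationshipMatrix:
    df = pd.read_csv(path, sep=_SEP, index_col=0)
    if kind is None:
        kind = Path(path).stem.split(".")[-1]
    return RelationshipMatrix(df.index.astype(str).tolist(), df.to_numpy(float), kind)


def write_matrix(mat: RelationshipMatrix, path) -> None:
    df = pd.DataFrame(mat.values, index=mat.ids, columns=mat.ids)
    df.index.name = mat.kind
    df.to_csv(path, sep=_SEP, float_format="%.10g")


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir, config: dict, seed: int, outputs: list[str]) -> Path:
    """JSON run manifest: seed, config hash, package versions, file list."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "versions": {
            "metgblup": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": outputs,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def write_fit_report(fit, outdir) -> list[Path]:
    """Delimited varcomp + BLUP tables and a JSON model summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vc = pd.DataFrame(
        {
            "component": list(fit.varcomps),
            "estimate": list(fit.varcomps.values()),
            "se": [fit.varcomp_se[k] for k in fit.varcomps],
        }
    )
    paths = []
    p = outdir / "varcomps.tsv"
    vc.to_csv(p, sep=_SEP, index=False)
    paths.append(p)
    for name, df in fit.blups.items():
        p = outdir / f"blup_{name}.tsv"
        df.rename_axis("id").to_csv(p, sep=_SEP)
        paths.append(p)
    if fit.seps is not None:
        p = outdir / "seps.tsv"
        fit.seps.rename_axis("id").to_csv(p, sep=_SEP)
        paths.append(p)
    summary = {
        "model": fit.spec.name,
        "trait": fit.trait,
        "sites": fit.sites,
        "logL": fit.logL,
        "aic": fit.aic,
        "n_variance_params": fit.n_params,
        "converged": fit.converged,
        "iterations": fit.iterations,
        "fixed": fit.fixed,
    }
    p = outdir / "fit_summary.json"
    p.write_text(json.dumps(summary, indent=2))
    paths.append(p)
    return paths
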