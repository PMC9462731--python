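"""File interchange: TSV cohorts, YAML configs, estimate tables, VCF import.

TSV with header rows is the canonical interchange format.  Genotype and
phenotype tables are joined by individual identifier, never by row order,
so misaligned files fail loudly.  Dosages round-trip exactly (integers);
phenotypes are written at full ``repr`` precision.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .simdata import SimulatedDataset, SimulationConfig

__all__ = [
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_cohort",
    "read_cohort",
    "write_config_yaml",
    "read_config_yaml",
    "write_estimates_tsv",
    "read_vcf_dosages",
]

_ID_COL = "individual"


def _default_ids(n: int) -> np.ndarray:
    return np.array([f"ind_{i}" for i in range(n)])


def _default_variants(p: int) -> np.ndarray:
    return np.array([f"var_{j}" for j in range(p)])


def write_genotypes_tsv(path, genotypes, individual_ids=None, variant_ids=None):
    g = np.asarray(genotypes)
    ids = _default_ids(g.shape[0]) if individual_ids is None else individual_ids
    variants = (
        _default_variants(g.shape[1]) if variant_ids is None else variant_ids
    )
    df = pd.DataFrame(g.astype(np.int64), columns=list(variants))
    df.insert(0, _ID_COL, ids)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (individual_ids, variant_ids, dosage matrix int8)."""
    df = pd.read_csv(path, sep="\t", dtype={_ID_COL: str})
    if _ID_COL not in df.columns:
        raise ConfigurationError(
            f"{path}: missing required '{_ID_COL}' column"
        )
    ids = df[_ID_COL].to_numpy()
    variants = np.array([c for c in df.columns if c != _ID_COL])
    g = df[variants].to_numpy()
    if not np.isin(np.unique(g), [0, 1, 2]).all():
        raise ConfigurationError(f"{path}: dosages must be 0, 1 or 2")
    return ids, variants, g.astype(np.int8)


def write_phenotypes_tsv(
    path,
    exposure,
    outcome,
    individual_ids=None,
    covariates: Optional[pd.DataFrame] = None,
    population: Optional[Sequence[str]] = None,
):
    n = len(exposure)
    ids = _default_ids(n) if individual_ids is None else individual_ids
    df = pd.DataFrame({_ID_COL: ids, "exposure": exposure, "outcome": outcome})
    if covariates is not None:
        for col in covariates.columns:
            df[col] = np.asarray(covariates[col])
    if population is not None:
        df["population"] = list(population)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_phenotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={_ID_COL: str}, float_precision="round_trip"
    )
    for col in (_ID_COL, "exposure", "outcome"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing required '{col}' column")
    return df


def write_cohort(prefix, dataset: SimulatedDataset, individual_ids=None,
                 variant_ids=None):
    """Write <prefix>.genotypes.tsv / <prefix>.phenotypes.tsv (+ config)."""
    prefix = str(prefix)
    ids = (
        _default_ids(dataset.n) if individual_ids is None else individual_ids
    )
    write_genotypes_tsv(
        f"{prefix}.genotypes.tsv", dataset.genotypes, ids, variant_ids
    )
    write_phenotypes_tsv(
        f"{prefix}.phenotypes.tsv", dataset.exposure, dataset.outcome, ids
    )
    if dataset.config is not None:
        write_config_yaml(f"{prefix}.config.yaml", dataset.config)


def read_cohort(genotypes_path, phenotypes_path):
    """Join genotype and phenotype tables by individual identifier.

    Returns ``(genotypes, phenotypes_frame, variant_ids)`` with rows in the
    genotype file's order; raises when the ID sets differ.
    """
    ids, variants, g = read_genotypes_tsv(genotypes_path)
    pheno = read_phenotypes_tsv(phenotypes_path)
    pheno_ids = pheno[_ID_COL].to_numpy()
    missing = np.setdiff1d(ids, pheno_ids)
    extra = np.setdiff1d(pheno_ids, ids)
    if len(missing) or len(extra):
        raise ConfigurationError(
            f"genotype/phenotype ID mismatch: {len(missing)} genotyped "
            f"individuals lack phenotypes, {len(extra)} phenotyped "
            f"individuals lack genotypes"
        )
    pheno = pheno.set_index(_ID_COL).loc[ids].reset_index()
    return g, pheno, variants


def write_config_yaml(path, config, extra: Optional[dict] = None):
    """Write a config (dataclass or dict) with the package version stamped."""
    from . import __version__

    payload = asdict(config) if not isinstance(config, dict) else dict(config)
    payload = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in payload.items()
        if not isinstance(v, (SimulationConfig,))
    }
    payload["cfmr_version"] = __version__
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_estimates_tsv(path, estimates, extra_columns: Optional[dict] = None):
    """One row per estimate, mirroring the standard reporting columns."""
    rows = []
    for est in estimates:
        row = est.to_row() if hasattr(est, "to_row") else dict(est)
        if extra_columns:
            row.update(extra_columns)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_vcf_dosages(path):
    """Alternate-allele dosages from a VCF's GT field.

    Returns ``(sample_ids, variant_ids, dosage matrix int8)``.  Multiallelic
    records are rejected; missing genotypes are not supported.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "VCF import requires the optional cyvcf2 dependency "
            "(pip install cfmr[vcf])"
        ) from exc

    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    variants, rows = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ConfigurationError(
                f"{path}: multiallelic record at {rec.CHROM}:{rec.POS} rejected"
            )
        gts = rec.genotype.array()[:, :2]
        if (gts < 0).any():
            raise ConfigurationError(
                f"{path}: missing genotype at {rec.CHROM}:{rec.POS}"
            )
        rows.append(gts.sum(axis=1))
        variants.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
    if not rows:
        raise ConfigurationError(f"{path}: no usable records")
    return samples, np.array(variants), np.array(rows, dtype=np.int8).T
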