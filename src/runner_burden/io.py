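"""Readers and writers for the formats the pipeline touches.

VCF genotypes are read through cyvcf2 (htslib), split per alternate
allele; annotation and variant-resource tables are plain TSV with a
header; results go out as a TSV plus a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SchemaError

ANNOTATION_REQUIRED = ("gene_id", "length_kb", "gc", "oe_mis", "mu_mis",
                       "oe_lof", "mu_lof")
RESOURCES_REQUIRED = ("chrom", "pos", "ref", "alt", "gene_id", "consequence",
                      "score")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

@dataclass
class SiteAlt:
    """One (site, alternate allele) after multi-allelic splitting."""

    chrom: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alt: str
    n_alleles: int          # REF + ALTs at the original site
    alt_dosage: np.ndarray  # per-sample count of this ALT (0/1/2)
    missing: np.ndarray     # per-sample missing-genotype mask
    gq: np.ndarray | None
    dp: np.ndarray | None

    @property
    def genotyping_rate(self) -> float:
        return float(1.0 - self.missing.mean())


def read_vcf_minimal(path: str, samples: list[str] | None = None) -> list[SiteAlt]:
    """Read GT (plus GQ/DP when present) for every split alternate allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=samples)
    sites: list[SiteAlt] = []
    for v in vcf:
        gts = np.array([g[:2] for g in v.genotypes], dtype=np.int64)
        missing = np.any(gts < 0, axis=1)
        gq = dp = None
        try:
            raw = v.format("GQ")
            gq = None if raw is None else raw.reshape(-1).astype(float)
        except KeyError:
            pass
        try:
            raw = v.format("DP")
            dp = None if raw is None else raw.reshape(-1).astype(float)
        except KeyError:
            pass
        n_alleles = 1 + len(v.ALT)
        for k, alt in enumerate(v.ALT, start=1):
            dosage = np.where(missing, 0, (gts == k).sum(axis=1))
            sites.append(SiteAlt(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                n_alleles=n_alleles, alt_dosage=dosage.astype(np.int64),
                missing=missing.copy(), gq=gq, dp=dp,
            ))
    return sites


@dataclass
class QCThresholds:
    """Genotype/variant quality filters; set a field to None to disable."""

    min_gq: float | None = 20.0
    min_dp: float | None = 8.0
    max_alleles: int | None = 4
    min_rate: float | None = 0.90
    hwe_p: float | None = 0.001


def hwe_pvalue(dosage: np.ndarray, missing: np.ndarray) -> float:
    """Pearson 1-df Hardy-Weinberg test on called diploid genotypes."""
    d = dosage[~missing]
    n = d.size
    if n == 0:
        return 1.0
    n_aa, n_ab, n_bb = np.sum(d == 0), np.sum(d == 1), np.sum(d == 2)
    p = (2 * n_bb + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
    x2 = np.sum((np.array([n_aa, n_ab, n_bb]) - exp) ** 2 / exp)
    return float(stats.chi2.sf(x2, df=1))


def apply_genotype_qc(sites: list[SiteAlt],
                      thresholds: QCThresholds | None = None) -> list[SiteAlt]:
    """Drop failing genotypes/variants and recompute allele counts.

    Genotypes below the GQ or depth thresholds are set missing; variants
    with more than ``max_alleles`` alleles, a genotyping rate below
    ``min_rate`` or a Hardy-Weinberg p-value at or below ``hwe_p`` are
    removed.  Filters whose annotations are absent are skipped.
    """
    thresholds = thresholds or QCThresholds()
    out = []
    for s in sites:
        if thresholds.max_alleles is not None and s.n_alleles > thresholds.max_alleles:
            continue
        missing = s.missing.copy()
        if thresholds.min_gq is not None and s.gq is not None:
            missing |= np.where(np.isnan(s.gq), False, s.gq < thresholds.min_gq)
        if thresholds.min_dp is not None and s.dp is not None:
            missing |= np.where(np.isnan(s.dp), False, s.dp < thresholds.min_dp)
        dosage = np.where(missing, 0, s.alt_dosage)
        rate = 1.0 - missing.mean()
        if thresholds.min_rate is not None and rate < thresholds.min_rate:
            continue
        if thresholds.hwe_p is not None and hwe_pvalue(dosage, missing) <= thresholds.hwe_p:
            continue
        out.append(SiteAlt(s.chrom, s.pos, s.ref, s.alt, s.n_alleles,
                           dosage.astype(np.int64), missing, s.gq, s.dp))
    return out


def sites_to_counts(sites: list[SiteAlt], prefix: str = "case") -> pd.DataFrame:
    """Cohort allele-count table (one row per split alternate allele)."""
    return pd.DataFrame({
        "chrom": [s.chrom for s in sites],
        "pos": [s.pos for s in sites],
        "ref": [s.ref for s in sites],
        "alt": [s.alt for s in sites],
        f"{prefix}_ac": [int(s.alt_dosage.sum()) for s in sites],
        f"{prefix}_an": [int(2 * (~s.missing).sum()) for s in sites],
    })


def build_variant_table(case_counts: pd.DataFrame, resources: pd.DataFrame,
                        control_counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join cohort counts with the variant resource annotations.

    Variants absent from the resource table are dropped (they cannot be
    mapped to a gene); a variant overlapping several genes yields one row
    per gene.
    """
    key = ["chrom", "pos", "ref", "alt"]
    table = case_counts.merge(resources, on=key, how="inner")
    if control_counts is not None:
        table = table.merge(control_counts, on=key, how="left")
        table["ctrl_ac"] = table["ctrl_ac"].fillna(0).astype(np.int64)
        table["ctrl_an"] = table["ctrl_an"].fillna(0).astype(np.int64)
    return table


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def _read_tsv(path, required, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{name} table lacks column(s): {sorted(missing)}")
    return df


def read_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV; errors on missing columns or duplicate genes."""
    df = _read_tsv(path, ANNOTATION_REQUIRED, "annotation")
    dup = df["gene_id"][df["gene_id"].duplicated()].tolist()
    if dup:
        raise SchemaError(f"duplicate gene_id in annotation: {dup}")
    return df


def read_resources(path, panels: list[str] | None = None) -> pd.DataFrame:
    """Variant resource TSV (gene, consequence, score, per-panel AFs)."""
    df = _read_tsv(path, RESOURCES_REQUIRED, "resources")
    af_cols = [c for c in df.columns if c.startswith("af_")]
    if panels is not None:
        wanted = [f"af_{p}" for p in panels]
        missing = set(wanted) - set(af_cols)
        if missing:
            raise SchemaError(f"resources table lacks panel column(s): {sorted(missing)}")
        df = df[[c for c in df.columns if not c.startswith("af_")] + wanted]
    return df


# ---------------------------------------------------------------------------
# Results and manifest
# ---------------------------------------------------------------------------

def config_hash(options: dict, input_paths: list | None = None) -> str:
    """SHA-256 over canonical options JSON and the bytes of every input."""
    h = hashlib.sha256(json.dumps(options, sort_keys=True, default=str).encode())
    for path in input_paths or []:
        with open(path, "rb") as fh:
            h.update(fh.read())
    return h.hexdigest()


def write_results(results: pd.DataFrame, path, manifest: dict | None = None,
                  manifest_path=None) -> None:
    """Write the per-gene results TSV (p/q in >= 3-digit scientific form)."""
    out = results.copy()
    for col in ("p", "q"):
        if col in out:
            out[col] = out[col].map(lambda v: f"{v:.4e}")
    out.to_csv(path, sep="\t", index=False)
    if manifest is not None and manifest_path is not None:
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
            fh.write("\n")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
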