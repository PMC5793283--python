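"""File formats: phenotype tables, genotype matrices, minimal VCF, config.

All tabular outputs are tab-delimited with a single header row.  The VCF
writer emits a minimal VCF 4.2 with one record per SNP and one sample
column per subject: GT for hard-called SNPs, DS for imputed ones.
Reading goes through pysam.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .simulate import ENDPOINTS, CohortTable, GeneratorConfig
from .snps import SnpDefinition

__all__ = [
    "write_phenotypes",
    "read_phenotypes",
    "write_genotype_matrix",
    "read_genotype_matrix",
    "write_vcf",
    "read_genotype_vcf",
    "read_config",
    "write_config",
]

# plausible coordinates used for synthetic VCF records (GRCh37-like)
_VCF_SITES = {
    "rs12794714": ("11", 14913575),
    "rs10741657": ("11", 14914878),
    "rs11234027": ("11", 71167449),
    "rs7944926": ("11", 71168073),
    "rs2282679": ("4", 72608383),
}

_PHENO_COLUMNS = ["id", "age", "bmi", "ohd"] + [
    f"{kind}_{e}" for e in ENDPOINTS for kind in ("event", "time")
]


def write_phenotypes(cohort: CohortTable | pd.DataFrame, path: str | Path) -> Path:
    """Tab-delimited phenotype table, one row per subject.

    Columns: id, age, bmi, ohd (empty when unmeasured), then
    event_<endpoint>/time_<endpoint> for each endpoint.  The latent
    ground-truth 25OHD is deliberately not written.
    """
    data = cohort.data if isinstance(cohort, CohortTable) else cohort
    path = Path(path)
    data[_PHENO_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
    return df


def write_genotype_matrix(
    cohort: CohortTable, path: str | Path
) -> Path:
    """Tab-delimited dosage matrix: id plus one column per rsid."""
    path = Path(path)
    out = pd.DataFrame({"id": cohort.data["id"]})
    for s in cohort.snps:
        out[s.rsid] = cohort.data[f"dosage_{s.rsid}"]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_genotype_matrix(
    path: str | Path, snps: Sequence[SnpDefinition]
) -> pd.DataFrame:
    """Read a delimited dosage matrix; returns id + one dosage column per
    configured rsid (panel order)."""
    df = pd.read_csv(path, sep="\t")
    missing = [s.rsid for s in snps if s.rsid not in df.columns]
    if missing:
        raise ValueError(f"genotype matrix lacks SNP columns {missing}")
    return df[["id"] + [s.rsid for s in snps]]


def write_vcf(cohort: CohortTable, path: str | Path) -> Path:
    """Minimal VCF 4.2: GT records for hard-called SNPs, DS for imputed.

    The ALT allele is the higher-25OHD (counted) allele, so GT/DS values
    translate directly into score contributions.
    """
    path = Path(path)
    ids = cohort.data["id"].astype(str).tolist()
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    records = []
    for s in cohort.snps:
        chrom, pos = _VCF_SITES.get(s.rsid, ("1", 1000))
        if s.imputed:
            fmt = "DS"
            vals = [
                f"{v:.4g}" for v in cohort.data[f"dosage_{s.rsid}"].to_numpy()
            ]
        else:
            fmt = "GT"
            vals = [gt_map[int(v)] for v in cohort.data[f"count_{s.rsid}"]]
        records.append((chrom, pos, s.rsid, fmt, vals))
    records.sort(key=lambda r: (r[0], r[1]))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({r[0] for r in records}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,'
            'Description="Imputed dosage of the higher-25OHD allele">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ids)
            + "\n"
        )
        for chrom, pos, rsid, fmt, vals in records:
            fh.write(
                f"{chrom}\t{pos}\t{rsid}\tA\tG\t.\t.\t.\t{fmt}\t"
                + "\t".join(vals)
                + "\n"
            )
    return path


def read_genotype_vcf(
    path: str | Path, snps: Sequence[SnpDefinition]
) -> pd.DataFrame:
    """Read dosages from a VCF keyed by the ID column.

    GT calls become exact dosages 0/1/2; DS fields are taken as-is.
    Returns id + one dosage column per configured rsid.
    """
    wanted = {s.rsid for s in snps}
    found: dict[str, np.ndarray] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.id not in wanted:
                continue
            vals = np.empty(len(samples))
            for i, sample in enumerate(samples):
                call = rec.samples[sample]
                if "DS" in call and call["DS"] is not None:
                    vals[i] = float(call["DS"])
                else:
                    gt = call.get("GT")
                    if gt is None or any(a is None for a in gt):
                        vals[i] = np.nan
                    else:
                        vals[i] = float(sum(gt))
            found[rec.id] = vals
    missing = wanted - set(found)
    if missing:
        raise ValueError(f"VCF lacks records for {sorted(missing)}")
    out = pd.DataFrame({"id": samples})
    try:
        out["id"] = out["id"].astype(int)
    except ValueError:
        pass
    for s in snps:
        out[s.rsid] = found[s.rsid]
    return out


# ---------------------------------------------------------------------------
# config files (TOML-style key = value sections)


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    return repr(v)


def write_config(config: GeneratorConfig, path: str | Path) -> Path:
    """Write a generator config as flat key = value sections."""
    path = Path(path)
    lines = ["[cohort]"]
    scalars = (
        "n_cohort n_subcohort ohd_mean ohd_sd target_r2 age_mean age_sd "
        "age_min bmi_mean bmi_sd bmi_min followup_years imputation_noise_sd "
        "age_log_hr target_events_reference_n"
    ).split()
    for key in scalars:
        lines.append(f"{key} = {_toml_scalar(getattr(config, key))}")
    if config.seed is not None:
        lines.append(f"seed = {config.seed}")
    lines.append("")
    lines.append("[target_events]")
    for e in ENDPOINTS:
        lines.append(f"{e} = {config.target_events[e]}")
    lines.append("")
    lines.append("[causal_log_hr_per_nmol]")
    for e in ENDPOINTS:
        lines.append(f"{e} = {_toml_scalar(config.causal_log_hr_per_nmol[e])}")
    if config.baseline_hazards is not None:
        lines.append("")
        lines.append("[baseline_hazards]")
        for e in ENDPOINTS:
            lines.append(f"{e} = {_toml_scalar(config.baseline_hazards[e])}")
    for s in config.snps:
        lines.append("")
        lines.append("[[snp]]")
        for f in dataclasses.fields(s):
            lines.append(f"{f.name} = {_toml_scalar(getattr(s, f.name))}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_config(path: str | Path) -> GeneratorConfig:
    """Read a generator config written by :func:`write_config` (any
    default may be overridden; omitted sections keep their defaults)."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    kwargs = dict(raw.get("cohort", {}))
    if "target_events" in raw:
        kwargs["target_events"] = raw["target_events"]
    if "causal_log_hr_per_nmol" in raw:
        kwargs["causal_log_hr_per_nmol"] = raw["causal_log_hr_per_nmol"]
    if "baseline_hazards" in raw:
        kwargs["baseline_hazards"] = raw["baseline_hazards"]
    if "snp" in raw:
        kwargs["snps"] = [SnpDefinition(**s) for s in raw["snp"]]
    return GeneratorConfig(**kwargs)
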