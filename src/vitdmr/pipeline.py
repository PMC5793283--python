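"""End-to-end orchestration: simulate -> GRS -> association -> MR.

`run_full_analysis` produces a reproducible report bundle: the
category/continuous hazard-ratio table per endpoint, a per-SNP
association table, a quintile mean-25OHD table with trend test, the IV
table for both score variants, and a run manifest with content digests.
Two runs with the same config and seed produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import io as io_mod
from .model import MendelianRandomization
from .simulate import ENDPOINTS, CohortTable, GeneratorConfig, generate_cohort

__all__ = ["run_full_analysis", "trend_test_across_quintiles", "RunManifest"]

logger = logging.getLogger(__name__)


def trend_test_across_quintiles(
    ohd: Sequence[float], quintiles: Sequence[int]
) -> tuple[float, float]:
    """Linear trend of 25OHD across quintile index (1..5).

    OLS of 25OHD on the quintile label; returns (slope, Wald p for zero
    slope).  Requires at least two non-empty quintiles.
    """
    ohd = np.asarray(ohd, dtype=float)
    q = np.asarray(quintiles, dtype=float)
    keep = ~(np.isnan(ohd) | np.isnan(q))
    ohd, q = ohd[keep], q[keep]
    if len(np.unique(q)) < 2:
        raise ValueError("trend test needs at least 2 non-empty quintiles")
    res = sm.OLS(ohd, sm.add_constant(q)).fit()
    return float(res.params[1]), float(res.pvalues[1])


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    seed: int
    config: dict
    outputs: dict[str, str]  # filename -> sha256
    counts: dict[str, int]
    warnings: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_snapshot(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["snps"] = [dataclasses.asdict(s) for s in config.snps]
    return d


def run_full_analysis(
    config: GeneratorConfig,
    out_dir: str | Path,
    seed: int | None = None,
    scale: float = 20.0,
    adjust: tuple[str, ...] = ("age",),
    write_vcf: bool = True,
) -> RunManifest:
    """Simulate a cohort and run the whole analysis, writing the bundle.

    Outputs under ``out_dir``: phenotypes.tsv, genotypes.vcf (optional),
    grs.tsv, endpoints_table.tsv (continuous + category rows per
    endpoint), snp_associations.tsv, quintile_ohd.tsv, iv_estimates.tsv,
    and manifest.json.  Any stage error removes partial outputs and
    re-raises with the stage named.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (argument or config.seed)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    warnings_log: list[str] = []

    def emit(name: str, text: str) -> Path:
        p = out_dir / name
        p.write_text(text)
        written.append(p)
        return p

    stage = "simulate"
    try:
        cohort = generate_cohort(config, seed)
        cohort.validate()
        if cohort.truncation_fraction > 0:
            warnings_log.append(
                f"25OHD truncation at 0 for {cohort.truncation_fraction:.2%} of subjects"
            )
        written.append(io_mod.write_phenotypes(cohort, out_dir / "phenotypes.tsv"))
        if write_vcf:
            written.append(io_mod.write_vcf(cohort, out_dir / "genotypes.vcf"))

        stage = "grs"
        model = MendelianRandomization.from_cohort(cohort)
        scores = model.scores
        emit("grs.tsv", scores.to_csv(sep="\t", index=False))

        stage = "association"
        rows = []
        for endpoint in ENDPOINTS:
            res = model.fit(endpoint, adjust=adjust, scale=scale)
            if res.iv.weak_instrument:
                warnings_log.append(f"{endpoint}: weak instrument")
            if not res.cox.converged:
                warnings_log.append(f"{endpoint}: Cox fit did not converge")
            cat_fit, rates = model.fit_categories(endpoint, adjust=adjust)
            cases_by = dict(zip(rates["group"], rates["cases"]))
            total_cases = int(sum(cases_by.values()))
            if total_cases != res.cox.n_events:
                raise RuntimeError(
                    f"{endpoint}: category case counts ({total_cases}) do not "
                    f"match the continuous fit ({res.cox.n_events})"
                )
            rows.append(
                {
                    "endpoint": endpoint, "row": "continuous",
                    "cases": res.cox.n_events, "n": res.cox.n,
                    "rate_per_1000": "",
                    "hr": round(res.cox.hr, 2),
                    "lo": round(res.cox.ci95[0], 2),
                    "hi": round(res.cox.ci95[1], 2),
                    "p": f"{res.cox.p:.3g}",
                }
            )
            for _, rr in rates.iterrows():
                if rr["group"] == "0-5":
                    hr, lo, hi, p = 1.0, "", "", ""
                else:
                    name = "grs_6_7" if rr["group"] == "6-7" else "grs_8_10"
                    coef, se = cat_fit.term(name)
                    from .association import Z975
                    from scipy import stats as _st

                    hr = round(float(np.exp(coef)), 2)
                    lo = round(float(np.exp(coef - Z975 * se)), 2)
                    hi = round(float(np.exp(coef + Z975 * se)), 2)
                    p = f"{2 * _st.norm.sf(abs(coef / se)):.3g}"
                rows.append(
                    {
                        "endpoint": endpoint, "row": f"GRS {rr['group']}",
                        "cases": int(rr["cases"]), "n": int(rr["n"]),
                        "rate_per_1000": f"{rr['rate_per_1000']:.2f}",
                        "hr": hr, "lo": lo, "hi": hi, "p": p,
                    }
                )
        emit(
            "endpoints_table.tsv",
            pd.DataFrame(rows).to_csv(sep="\t", index=False),
        )

        snp_rows = []
        for s in cohort.snps:
            for endpoint in ENDPOINTS:
                fit = model.fit_outcome(endpoint, f"snp:{s.rsid}", adjust=adjust)
                snp_rows.append(
                    {
                        "rsid": s.rsid, "gene": s.gene, "endpoint": endpoint,
                        "events": fit.n_events, "coef": fit.coef,
                        "se": fit.coef_se, "hr": fit.hr,
                        "lo": fit.ci95[0], "hi": fit.ci95[1], "p": fit.p,
                    }
                )
        emit(
            "snp_associations.tsv",
            pd.DataFrame(snp_rows).to_csv(sep="\t", index=False),
        )

        stage = "quintiles"
        sub = cohort.data["ohd"].notna().to_numpy()
        qtab = (
            pd.DataFrame(
                {
                    "quintile": scores.loc[sub, "quintile"],
                    "ohd": cohort.data.loc[sub, "ohd"],
                }
            )
            .groupby("quintile")["ohd"]
            .agg(["count", "mean", "std"])
            .reset_index()
        )
        slope, trend_p = trend_test_across_quintiles(
            cohort.data.loc[sub, "ohd"], scores.loc[sub, "quintile"]
        )
        qtab["trend_slope"] = slope
        qtab["trend_p"] = trend_p
        emit("quintile_ohd.tsv", qtab.to_csv(sep="\t", index=False))

        stage = "mr"
        iv_rows = []
        for exposure in ("grs", "grs_no_gc"):
            for endpoint in ENDPOINTS:
                res = model.fit(endpoint, exposure=exposure, adjust=adjust,
                                scale=scale, check_ph=False)
                frame = res.summary_frame()
                iv_rows.append(frame.iloc[0].to_dict())
        iv_df = pd.DataFrame(iv_rows)
        emit("iv_estimates.tsv", iv_df.to_csv(sep="\t", index=False))
        emit(
            "iv_estimates.json",
            iv_df.to_json(orient="records", indent=2, double_precision=15),
        )
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        logger.error("pipeline failed during stage %r", stage)
        raise

    stage = "manifest"
    counts = {"n_cohort": cohort.n, "n_subcohort": int(sub.sum())}
    for e in ENDPOINTS:
        counts[f"events_{e}"] = int(cohort.data[f"event_{e}"].sum())
    manifest = RunManifest(
        seed=int(seed),
        config=_config_snapshot(config),
        outputs={p.name: _sha256(p) for p in written},
        counts=counts,
        warnings=warnings_log,
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
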