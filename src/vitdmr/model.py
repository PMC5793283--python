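"""Model/results interface for the one-sample Mendelian-randomization fit.

`MendelianRandomization` wraps a phenotype table and genotype dosages;
each `fit()` runs the three-stage analysis for one endpoint — first
stage (25OHD on the score, measured subcohort), Cox outcome model on
the full cohort, and the scaled Wald-ratio IV estimate — and returns an
`MRResults` with estimates, standard errors, diagnostics and a
`summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import grs as grs_mod
from .association import (
    CoxFit,
    FirstStageFit,
    check_proportionality,
    fit_cox,
    fit_linear,
    jackknife_slope_se,
    rate_table,
)
from .mr import IvEstimate, wald_iv, rescale_simple
from .simulate import ENDPOINTS, CohortTable
from .snps import SnpDefinition, default_panel

__all__ = ["MendelianRandomization", "MRResults"]


@dataclass
class MRResults:
    """Results of one endpoint's instrumented analysis."""

    endpoint: str
    exposure: str
    first_stage: FirstStageFit
    cox: CoxFit
    iv: IvEstimate
    proportionality: dict[str, float] = field(default_factory=dict)
    adjust: tuple[str, ...] = ()

    def summary(self) -> str:
        fs, cx, iv = self.first_stage, self.cox, self.iv
        lo, hi = cx.ci95
        ilo, ihi = iv.ci95
        lines = [
            f"Mendelian randomization: {self.endpoint}",
            "=" * 58,
            f"exposure score: {self.exposure}    adjusted for: "
            + (", ".join(self.adjust) or "(none)"),
            f"cohort n = {cx.n}, events = {cx.n_events}; "
            f"first-stage n = {fs.n}",
            "-" * 58,
            "First stage (25OHD ~ score):",
            f"  slope = {fs.slope:.4f} nmol/L per point (SE {fs.slope_se:.4f})",
            f"  R2 = {fs.r2:.4f}   F = {fs.f_stat:.1f}",
            "Cox outcome model (per score point):",
            f"  HR = {cx.hr:.3f} ({lo:.3f}-{hi:.3f})   p = {cx.p:.3g}"
            f"   [{cx.ties} ties, converged={cx.converged}]",
            f"Wald IV ({iv.method}) per {iv.scale:g} nmol/L 25OHD:",
            f"  ratio = {iv.or_:.3f} ({ilo:.3f}-{ihi:.3f})   p = {iv.p:.3g}",
        ]
        if iv.weak_instrument:
            lines.append("  WARNING: weak instrument (first-stage strength low)")
        if self.proportionality:
            worst = min(self.proportionality.values())
            lines.append(f"proportional-hazards check: min p = {worst:.3f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def summary_frame(self) -> pd.DataFrame:
        """One-row DataFrame with the headline numbers (full precision)."""
        return pd.DataFrame(
            [
                {
                    "endpoint": self.endpoint,
                    "exposure": self.exposure,
                    "n": self.cox.n,
                    "events": self.cox.n_events,
                    "fs_slope": self.first_stage.slope,
                    "fs_slope_se": self.first_stage.slope_se,
                    "fs_r2": self.first_stage.r2,
                    "fs_f": self.first_stage.f_stat,
                    "cox_coef": self.cox.coef,
                    "cox_se": self.cox.coef_se,
                    "hr": self.cox.hr,
                    "hr_lo": self.cox.ci95[0],
                    "hr_hi": self.cox.ci95[1],
                    "cox_p": self.cox.p,
                    "iv_beta": self.iv.beta_iv,
                    "iv_se": self.iv.se_iv,
                    "iv_or": self.iv.or_,
                    "iv_lo": self.iv.ci95[0],
                    "iv_hi": self.iv.ci95[1],
                    "iv_p": self.iv.p,
                    "iv_method": self.iv.method,
                    "iv_scale": self.iv.scale,
                    "weak_instrument": self.iv.weak_instrument,
                }
            ]
        )


class MendelianRandomization:
    """One-sample MR of a 5-SNP 25OHD score against survival endpoints.

    Parameters
    ----------
    phenotypes : DataFrame
        Per-subject table with ``id``, ``age``, ``bmi``, ``ohd`` (NaN
        where unmeasured) and ``event_<e>``/``time_<e>`` per endpoint.
    genotypes : DataFrame
        ``id`` plus one dosage column per rsid (hard calls or dosages in
        [0, 2]); rows are aligned to ``phenotypes`` by ``id``.
    snps : sequence of SnpDefinition, optional
        The score panel; defaults to the standard five-SNP panel.
    """

    def __init__(
        self,
        phenotypes: pd.DataFrame,
        genotypes: pd.DataFrame,
        snps: Sequence[SnpDefinition] | None = None,
    ) -> None:
        self.snps = list(snps) if snps is not None else default_panel()
        self.phenotypes = phenotypes.reset_index(drop=True)
        geno = genotypes.set_index("id").reindex(self.phenotypes["id"])
        if geno.isna().all(axis=1).any():
            raise ValueError("genotype table is missing subjects present in phenotypes")
        self.dosages = geno[[s.rsid for s in self.snps]].to_numpy(float)
        self.scores = grs_mod.grs_table(
            self.dosages, self.snps, ids=self.phenotypes["id"]
        )

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_cohort(cls, cohort: CohortTable) -> "MendelianRandomization":
        geno = pd.DataFrame({"id": cohort.data["id"]})
        for s in cohort.snps:
            geno[s.rsid] = cohort.data[f"dosage_{s.rsid}"]
        pheno_cols = ["id", "age", "bmi", "ohd"] + [
            c
            for c in cohort.data.columns
            if c.startswith(("event_", "time_"))
        ]
        return cls(cohort.data[pheno_cols], geno, cohort.snps)

    @classmethod
    def from_files(
        cls,
        phenotypes: str | Path,
        genotypes: str | Path,
        snps: Sequence[SnpDefinition] | None = None,
    ) -> "MendelianRandomization":
        """Build from a phenotype TSV and a genotype file (.vcf or TSV)."""
        from . import io as io_mod

        snps = list(snps) if snps is not None else default_panel()
        pheno = io_mod.read_phenotypes(phenotypes)
        gpath = Path(genotypes)
        if gpath.suffix == ".vcf":
            geno = io_mod.read_genotype_vcf(gpath, snps)
        else:
            geno = io_mod.read_genotype_matrix(gpath, snps)
        return cls(pheno, geno, snps)

    # -- pieces ------------------------------------------------------------
    def _exposure_vector(self, exposure: str) -> np.ndarray:
        if exposure == "grs":
            return self.scores["score"].to_numpy(float)
        if exposure == "grs_no_gc":
            return self.scores["score_no_gc"].to_numpy(float)
        if exposure.startswith("snp:"):
            rsid = exposure.split(":", 1)[1]
            if rsid not in [s.rsid for s in self.snps]:
                raise ValueError(f"unknown SNP {rsid!r}")
            j = [s.rsid for s in self.snps].index(rsid)
            return grs_mod.round_dosage(self.dosages[:, j]).astype(float)
        raise ValueError(f"unknown exposure {exposure!r}")

    def _covariates(self, adjust: Sequence[str]) -> pd.DataFrame | None:
        if not adjust:
            return None
        missing = set(adjust) - set(self.phenotypes.columns)
        if missing:
            raise ValueError(f"unknown covariates {sorted(missing)}")
        return self.phenotypes[list(adjust)]

    def first_stage(
        self, exposure: str = "grs", adjust: Sequence[str] = ()
    ) -> FirstStageFit:
        """OLS of measured 25OHD on the score over the measured subcohort."""
        return fit_linear(
            self.phenotypes["ohd"],
            self._exposure_vector(exposure),
            self._covariates(adjust),
        )

    def fit_outcome(
        self,
        endpoint: str,
        exposure: str = "grs",
        adjust: Sequence[str] = ("age",),
        ties: str = "breslow",
    ) -> CoxFit:
        """Cox model of one endpoint on the (continuous) exposure."""
        if endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {endpoint!r}")
        return fit_cox(
            self.phenotypes[f"time_{endpoint}"],
            self.phenotypes[f"event_{endpoint}"],
            self._exposure_vector(exposure),
            self._covariates(adjust),
            ties=ties,
            exposure_name=exposure,
            covariate_names=list(adjust),
        )

    # -- the headline fit --------------------------------------------------
    def fit(
        self,
        endpoint: str,
        exposure: str = "grs",
        adjust: Sequence[str] = ("age",),
        scale: float = 20.0,
        method: str = "delta",
        ties: str = "breslow",
        check_ph: bool = True,
        jackknife_first_stage: bool = False,
    ) -> MRResults:
        """First stage + Cox + scaled Wald IV for one endpoint.

        ``jackknife_first_stage`` swaps the model-based first-stage slope
        SE for a delete-one jackknife over the measured subcohort before
        the delta-method propagation (comparison flag).
        """
        fs = self.first_stage(exposure)
        if jackknife_first_stage:
            sub = self.phenotypes["ohd"].notna().to_numpy()
            fs.slope_se = jackknife_slope_se(
                self.phenotypes.loc[sub, "ohd"],
                self._exposure_vector(exposure)[sub],
            )
        cx = self.fit_outcome(endpoint, exposure, adjust, ties)
        if method == "delta":
            iv = wald_iv(cx.coef, cx.coef_se, fs.slope, fs.slope_se, scale)
        elif method == "simple":
            iv = rescale_simple(cx.coef, cx.coef_se, fs.slope, scale)
        else:
            raise ValueError(f"unknown IV method {method!r}")
        if fs.f_stat < 10:
            iv.weak_instrument = True
        ph = {}
        if check_ph and cx.converged:
            ph = check_proportionality(
                cx,
                self.phenotypes[f"time_{endpoint}"],
                self.phenotypes[f"event_{endpoint}"],
                self._exposure_vector(exposure),
                self._covariates(adjust),
            )
        return MRResults(
            endpoint=endpoint,
            exposure=exposure,
            first_stage=fs,
            cox=cx,
            iv=iv,
            proportionality=ph,
            adjust=tuple(adjust),
        )

    def fit_all(
        self,
        endpoints: Sequence[str] = ENDPOINTS,
        **kwargs,
    ) -> dict[str, MRResults]:
        return {e: self.fit(e, **kwargs) for e in endpoints}

    # -- categorical / descriptive pieces ----------------------------------
    def fit_categories(
        self,
        endpoint: str,
        adjust: Sequence[str] = ("age",),
        ties: str = "breslow",
    ) -> tuple[CoxFit, pd.DataFrame]:
        """Category HRs (6-7 and 8-10 vs 0-5) plus per-category rates.

        Returns one joint fit with indicator terms ``grs_6_7`` and
        ``grs_8_10`` (0-5 as reference; use ``fit.term(name)`` for each)
        and a rate table with cases/n/person-years per category.
        """
        cats = self.scores["category"]
        d67 = (cats == "6-7").to_numpy(float)
        d810 = (cats == "8-10").to_numpy(float)
        cov = pd.DataFrame({"grs_8_10": d810})
        if adjust:
            cov = pd.concat(
                [cov, self._covariates(adjust).reset_index(drop=True)], axis=1
            )
        fit_joint = fit_cox(
            self.phenotypes[f"time_{endpoint}"],
            self.phenotypes[f"event_{endpoint}"],
            d67,
            cov,
            ties=ties,
            exposure_name="grs_6_7",
            covariate_names=list(cov.columns),
        )
        rows = []
        for label in ("0-5", "6-7", "8-10"):
            mask = (cats == label).to_numpy()
            rows.append(
                {
                    "group": label,
                    "cases": int(self.phenotypes.loc[mask, f"event_{endpoint}"].sum()),
                    "n": int(mask.sum()),
                    "person_years": float(
                        self.phenotypes.loc[mask, f"time_{endpoint}"].sum()
                    ),
                }
            )
        rates = pd.DataFrame(
            [r.__dict__ for r in rate_table(
                [r["group"] for r in rows],
                [r["cases"] for r in rows],
                [r["person_years"] for r in rows],
                [r["n"] for r in rows],
            )]
        )
        return fit_joint, rates
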