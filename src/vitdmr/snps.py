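"""Definitions of the five 25OHD-associated SNPs used to build the score.

The score sums counts of the allele associated with *higher* circulating
25-hydroxyvitamin D, across two DHCR7 variants, two CYP2R1 variants and
one GC (vitamin D binding protein) variant.  Per-SNP minor-allele
frequencies and per-allele 25OHD effects are generator ground truth and
are configurable; the shipped defaults lie inside the frequency range
reported for cohorts of European ancestry (16-44%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SnpDefinition",
    "GC_RSID",
    "default_panel",
    "grs_variance",
    "solve_per_allele_effect",
]

#: rsid of the GC-gene variant excluded in the sensitivity score (range 0-8).
GC_RSID = "rs2282679"


@dataclass(frozen=True)
class SnpDefinition:
    """Identity and generator truth for one score SNP.

    Parameters
    ----------
    rsid : str
        dbSNP identifier.
    gene : str
        Gene label; one of ``DHCR7``, ``CYP2R1``, ``GC``.
    maf : float
        Minor-allele frequency, in (0, 0.5].
    per_allele_effect : float
        nmol/L increase in 25OHD per copy of the high-25OHD allele
        (non-negative by the orientation convention of the score).
    imputed : bool
        Whether the generator emits noisy dosages for this SNP (emulating
        genotype imputation) rather than exact hard calls.
    risk_is_minor : bool
        Whether the higher-25OHD ("risk") allele is the minor allele.
        For the five score SNPs the minor allele is the 25OHD-lowering
        one, so the counted allele runs at frequency 1 - maf by default;
        that orientation reproduces the observed score distribution
        (~28%/41%/31% in categories 0-5/6-7/8-10).
    """

    rsid: str
    gene: str
    maf: float
    per_allele_effect: float = 0.0
    imputed: bool = False
    risk_is_minor: bool = False

    @property
    def risk_allele_frequency(self) -> float:
        """Population frequency of the counted (higher-25OHD) allele."""
        return self.maf if self.risk_is_minor else 1.0 - self.maf

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(
                f"{self.rsid}: maf must be in (0, 0.5], got {self.maf}"
            )
        if self.per_allele_effect < 0:
            raise ValueError(
                f"{self.rsid}: per_allele_effect must be >= 0 "
                "(risk allele is oriented to higher 25OHD)"
            )
        if self.gene not in ("DHCR7", "CYP2R1", "GC"):
            raise ValueError(f"{self.rsid}: unknown gene {self.gene!r}")


# (rsid, gene, default maf, imputed?) — rs11234027/rs7944926 are hard-called,
# the other three imputed.  MAFs are documented stand-ins inside the
# reported 16-44% range.
_DEFAULTS = (
    ("rs11234027", "DHCR7", 0.21, False),
    ("rs12794714", "DHCR7", 0.42, True),
    ("rs10741657", "CYP2R1", 0.38, True),
    ("rs7944926", "CYP2R1", 0.40, False),
    ("rs2282679", "GC", 0.28, True),
)


def grs_variance(mafs: Sequence[float]) -> float:
    """Population variance of the allele-count score under HWE, no LD.

    Each SNP contributes Binomial(2, p) variance 2p(1-p).
    """
    p = np.asarray(mafs, dtype=float)
    return float(np.sum(2.0 * p * (1.0 - p)))


def solve_per_allele_effect(
    mafs: Sequence[float], target_r2: float, ohd_sd: float
) -> float:
    """Common per-allele 25OHD effect giving the score a target R-squared.

    With a shared effect ``b`` per allele, the score explains
    ``b^2 Var(GRS) / ohd_sd^2`` of the 25OHD variance, so
    ``b = ohd_sd * sqrt(target_r2 / Var(GRS))``.
    """
    if not (0.0 <= target_r2 < 1.0):
        raise ValueError(f"target_r2 must be in [0, 1), got {target_r2}")
    return float(ohd_sd * np.sqrt(target_r2 / grs_variance(mafs)))


def default_panel(
    target_r2: float = 0.026, ohd_sd: float = 26.1
) -> list[SnpDefinition]:
    """The default five-SNP panel, first-stage calibrated.

    Per-allele effects are shared across SNPs and solved so the score
    explains ``target_r2`` of a 25OHD distribution with SD ``ohd_sd``
    (defaults: 2.6% of variance, SD 26.1 nmol/L, giving ~2.85 nmol/L
    per allele).
    """
    panel = [SnpDefinition(r, g, m, 0.0, imp) for r, g, m, imp in _DEFAULTS]
    beta = solve_per_allele_effect([s.maf for s in panel], target_r2, ohd_sd)
    return [replace(s, per_allele_effect=beta) for s in panel]
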