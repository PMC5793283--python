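"""The unweighted vitamin-D genetic risk score.

The score sums counts (0/1/2) of the higher-25OHD allele over five SNPs,
so it ranges 0-10; the GC-excluded sensitivity score drops rs2282679
(range 0-8).  Categories use the fixed cuts 0-5 (reference), 6-7, 8-10.
Imputed dosages are hard-called by rounding to the nearest genotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .snps import GC_RSID, SnpDefinition

__all__ = [
    "GrsResult",
    "round_dosage",
    "compute_grs",
    "grs_category",
    "assign_quintiles",
    "grs_table",
]

_DOSAGE_TOL = 1e-8


@dataclass(frozen=True)
class GrsResult:
    """Score, category, GC-excluded score and (optional) quintile for one
    subject."""

    score: int
    category: str
    score_no_gc: int
    quintile: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 10:
            raise ValueError(f"score {self.score} outside [0, 10]")
        if not 0 <= self.score_no_gc <= min(self.score, 8):
            raise ValueError("score_no_gc outside [0, min(score, 8)]")
        if self.category != grs_category(self.score):
            raise ValueError(
                f"category {self.category!r} inconsistent with score {self.score}"
            )


def round_dosage(dosage):
    """Hard-call a dosage in [0, 2] to the nearest genotype 0/1/2.

    Exact half-way points (0.5, 1.5) round away from zero — a documented
    convention; ties have probability ~0 for continuous dosages.  Values
    outside [0, 2] by more than a small numerical tolerance are rejected.
    """
    arr = np.asarray(dosage, dtype=float)
    if np.any(arr < -_DOSAGE_TOL) or np.any(arr > 2.0 + _DOSAGE_TOL):
        bad = arr[(arr < -_DOSAGE_TOL) | (arr > 2.0 + _DOSAGE_TOL)]
        raise ValueError(f"dosage outside [0, 2]: {bad.ravel()[:5]}")
    out = np.floor(np.clip(arr, 0.0, 2.0) + 0.5).astype(np.int8)
    out = np.minimum(out, 2)  # dosage exactly 2.0 floors to 2, keep bound
    if np.ndim(dosage) == 0:
        return int(out)
    return out


def grs_category(score: int) -> str:
    """Fixed category cuts: 0-5 (reference), 6-7, 8-10."""
    if score <= 5:
        return "0-5"
    if score <= 7:
        return "6-7"
    return "8-10"


def compute_grs(
    allele_counts: Sequence[int], snps: Sequence[SnpDefinition]
) -> GrsResult:
    """Score one subject from five allele counts in SNP-panel order."""
    counts = np.asarray(allele_counts)
    if counts.shape != (len(snps),) or len(snps) != 5:
        raise ValueError(
            f"expected 5 allele counts matching the SNP panel, got shape {counts.shape}"
        )
    if not np.isin(counts, (0, 1, 2)).all():
        raise ValueError(f"allele counts must be in {{0,1,2}}: {counts}")
    rsids = [s.rsid for s in snps]
    if GC_RSID not in rsids:
        raise ValueError(f"SNP panel lacks the GC variant {GC_RSID}")
    score = int(counts.sum())
    score_no_gc = score - int(counts[rsids.index(GC_RSID)])
    return GrsResult(score, grs_category(score), score_no_gc)


def _quintile_cuts(values: np.ndarray, counts: np.ndarray, n: int) -> list[int]:
    """Exhaustive search for non-splitting cut points.

    ``values``/``counts`` describe the distinct sorted score values; the
    return is, for each of up to 5 bins, the index one past its last
    value.  Minimizes sum |bin size - n/5|; among minimizers prefers the
    lexicographically smallest cut positions (lower cut values).
    """
    from itertools import combinations

    k = len(values)
    n_bins = min(5, k)
    target = n / 5.0
    csum = np.concatenate([[0], np.cumsum(counts)])
    best, best_dev = None, np.inf
    for inner in combinations(range(1, k), n_bins - 1):
        edges = (0,) + inner + (k,)
        sizes = np.diff(csum[list(edges)])
        dev = float(np.abs(sizes - target).sum())
        if dev < best_dev - 1e-12:
            best, best_dev = list(edges[1:]), dev
    return best if best is not None else [k]


def assign_quintiles(scores: Sequence[int]) -> np.ndarray:
    """Rank-based quintile labels (1..5) that never split tied scores.

    All subjects sharing a score value land in the same quintile; cut
    points are chosen by exhaustive search to minimize total deviation
    from 20% per bin.  With fewer than 5 distinct values, fewer groups
    are produced; a single distinct value yields one group with a warning.
    """
    arr = np.asarray(scores)
    if arr.size < 5:
        raise ValueError(f"need at least 5 subjects, got {arr.size}")
    values, counts = np.unique(arr, return_counts=True)
    if len(values) == 1:
        warnings.warn(
            "all scores identical; a single quantile group is returned",
            UserWarning,
            stacklevel=2,
        )
        return np.ones(arr.size, dtype=np.int8)
    edges = _quintile_cuts(values, counts, arr.size)
    label_of_value = np.empty(len(values), dtype=np.int8)
    start = 0
    for label, stop in enumerate(edges, start=1):
        label_of_value[start:stop] = label
        start = stop
    return label_of_value[np.searchsorted(values, arr)]


def grs_table(
    dosages: np.ndarray,
    snps: Sequence[SnpDefinition],
    ids: Sequence | None = None,
    quintiles: bool = True,
) -> pd.DataFrame:
    """Per-subject GRS table from a dosage (or hard-call) matrix.

    Dosages are rounded to hard calls first.  Columns: id, score,
    category, score_no_gc and (optionally) quintile.
    """
    counts = round_dosage(np.atleast_2d(dosages))
    if counts.shape[1] != len(snps):
        raise ValueError("dosage matrix width does not match the SNP panel")
    rsids = [s.rsid for s in snps]
    score = counts.sum(axis=1).astype(int)
    score_no_gc = score - counts[:, rsids.index(GC_RSID)]
    out = pd.DataFrame(
        {
            "id": np.arange(1, len(score) + 1) if ids is None else list(ids),
            "score": score,
            "category": [grs_category(s) for s in score],
            "score_no_gc": score_no_gc,
        }
    )
    if quintiles:
        out["quintile"] = assign_quintiles(score)
    return out
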