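"""Genotype quality control and misplaced-SNP screening.

Four criteria are applied, animals first and then markers in a fixed
order so that every excluded marker is attributed to exactly one
criterion: animal call rate >= 90%, then per marker MAF >= 0.05,
SNP call rate >= 90% and a chi-square Hardy-Weinberg test at p >= 1e-6.
Monomorphic markers pass HWE by convention (there is nothing to test;
MAF removes them anyway).

The misplaced-SNP screen looks for markers whose mapped position is
inconsistent with the LD they show: high r2 with many distant markers
on the same chromosome combined with weak r2 with their immediate
neighbours.  The published analysis did this partly by eye on LD-decay
plots; here the statistic is explicit and every threshold is exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypePanel
from .ld import pairwise_r2_matrix

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Per-criterion exclusion counts and surviving ids."""

    n_excluded_maf: int
    n_excluded_snp_call_rate: int
    n_excluded_hwe: int
    n_excluded_animals: int
    surviving_markers: np.ndarray
    surviving_animals: np.ndarray
    thresholds: dict

    def to_frame(self) -> pd.DataFrame:
        """One-row table mirroring a per-population QC summary."""
        return pd.DataFrame(
            {
                "excluded_maf": [self.n_excluded_maf],
                "excluded_snp_cr": [self.n_excluded_snp_call_rate],
                "excluded_hwe": [self.n_excluded_hwe],
                "excluded_animals": [self.n_excluded_animals],
                "remaining_snps": [len(self.surviving_markers)],
            }
        )


def hwe_chisq_test(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test for Hardy-Weinberg proportions.

    Expected counts are ``n*(p^2, 2pq, q^2)`` with ``p`` estimated from
    the same genotype counts.  Monomorphic input returns ``(0.0, 1.0)``
    (no test possible).  No continuity correction.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 0.0, 1.0
    exp = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _marker_stats(dosages: np.ndarray):
    """Return per-marker (call_rate, maf, hwe_p) over non-missing calls."""
    miss = np.isnan(dosages)
    n_called = (~miss).sum(axis=0)
    call_rate = n_called / dosages.shape[0]
    n_AA = ((dosages == 2) & ~miss).sum(axis=0)
    n_Aa = ((dosages == 1) & ~miss).sum(axis=0)
    n_aa = ((dosages == 0) & ~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n_AA + n_Aa) / (2 * np.maximum(n_called, 1))
    p = np.where(n_called == 0, np.nan, p)
    maf = np.minimum(p, 1 - p)
    hwe_p = np.ones(dosages.shape[1])
    for j in range(dosages.shape[1]):
        if n_called[j] == 0:
            continue
        _, hwe_p[j] = hwe_chisq_test(int(n_AA[j]), int(n_Aa[j]), int(n_aa[j]))
    return call_rate, maf, hwe_p


def apply_qc(
    panel: GenotypePanel,
    snp_cr_min: float = 0.90,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
    animal_cr_min: float = 0.90,
) -> tuple[GenotypePanel, QCReport]:
    """Filter a panel by the four QC criteria; return survivors and a report.

    Animals below ``animal_cr_min`` call rate are removed first; marker
    statistics are then computed on the surviving animals and markers
    failing MAF, SNP call rate or HWE (attributed in that order) are
    dropped.  A marker failing several criteria counts once, under the
    first it fails.
    """
    if panel.n_animals == 0 or panel.n_markers == 0:
        raise ValueError("cannot QC an empty panel")
    miss = np.isnan(panel.dosages)
    animal_cr = 1 - miss.mean(axis=1)
    keep_animals = np.flatnonzero(animal_cr >= animal_cr_min)
    n_excl_animals = panel.n_animals - len(keep_animals)
    work = panel.subset(animal_idx=keep_animals) if n_excl_animals else panel

    if work.n_animals == 0:
        report = QCReport(0, 0, 0, n_excl_animals, np.array([]), np.array([]),
                          _thresholds(snp_cr_min, maf_min, hwe_p_min, animal_cr_min))
        logger.warning("QC removed every animal")
        return work, report

    call_rate, maf, hwe_p = _marker_stats(work.dosages)
    fail_maf = ~(maf >= maf_min)  # NaN maf (no calls) fails here
    fail_cr = call_rate < snp_cr_min
    fail_hwe = hwe_p < hwe_p_min
    excl_maf = fail_maf
    excl_cr = fail_cr & ~excl_maf
    excl_hwe = fail_hwe & ~excl_maf & ~excl_cr
    keep = ~(excl_maf | excl_cr | excl_hwe)
    if not keep.any():
        logger.warning("QC removed every marker")
    out = work.subset(marker_idx=np.flatnonzero(keep))
    report = QCReport(
        n_excluded_maf=int(excl_maf.sum()),
        n_excluded_snp_call_rate=int(excl_cr.sum()),
        n_excluded_hwe=int(excl_hwe.sum()),
        n_excluded_animals=n_excl_animals,
        surviving_markers=out.map.marker_ids.copy(),
        surviving_animals=out.animal_ids.copy(),
        thresholds=_thresholds(snp_cr_min, maf_min, hwe_p_min, animal_cr_min),
    )
    return out, report


def _thresholds(snp_cr_min, maf_min, hwe_p_min, animal_cr_min) -> dict:
    return {
        "snp_cr_min": snp_cr_min,
        "maf_min": maf_min,
        "hwe_p_min": hwe_p_min,
        "animal_cr_min": animal_cr_min,
    }


@dataclass
class MisplacedFlag:
    marker_id: str
    chromosome: int
    position_bp: int
    far_high_ld_fraction: float
    near_mean_r2: float
    flagged: bool


def detect_misplaced_snps(
    panel: GenotypePanel,
    d_far_mbp: float = 10.0,
    d_near_mbp: float = 1.0,
    r2_high: float = 0.3,
    far_fraction_min: float = 0.05,
    near_r2_max: float = 0.1,
    max_near: int = 10,
) -> list[MisplacedFlag]:
    """Flag markers whose LD profile contradicts their mapped position.

    For every marker, ``far_high_ld_fraction`` is the share of
    same-chromosome pairs beyond ``d_far_mbp`` with r2 >= ``r2_high``,
    and ``near_mean_r2`` the mean r2 with its up-to-``max_near`` nearest
    neighbours within ``d_near_mbp``.  A marker is flagged when it is in
    strong LD with many distant markers yet weak LD with its neighbours.
    """
    flags: list[MisplacedFlag] = []
    mt = panel.map.table
    for chrom in pd.unique(mt["chromosome"]):
        idx = np.flatnonzero(mt["chromosome"].to_numpy() == chrom)
        if len(idx) < 2:
            logger.info("chromosome %s has a single marker; skipped", chrom)
            continue
        sub = panel.dosages[:, idx]
        pos = mt["position_bp"].to_numpy()[idx] / 1e6
        r2 = pairwise_r2_matrix(sub)
        dist = np.abs(pos[:, None] - pos[None, :])
        np.fill_diagonal(r2, np.nan)
        for k in range(len(idx)):
            rk, dk = r2[k], dist[k]
            ok = ~np.isnan(rk)
            far = ok & (dk > d_far_mbp)
            near = ok & (dk <= d_near_mbp) & (dk > 0)
            far_frac = float((rk[far] >= r2_high).mean()) if far.any() else 0.0
            if near.any():
                near_idx = np.flatnonzero(near)
                nearest = near_idx[np.argsort(dk[near_idx])][:max_near]
                near_r2 = float(np.mean(rk[nearest]))
            else:
                near_r2 = np.nan
            flagged = bool(
                far.any()
                and far_frac >= far_fraction_min
                and (np.isnan(near_r2) or near_r2 <= near_r2_max)
            )
            flags.append(
                MisplacedFlag(
                    marker_id=str(mt["marker_id"].to_numpy()[idx[k]]),
                    chromosome=int(chrom),
                    position_bp=int(mt["position_bp"].to_numpy()[idx[k]]),
                    far_high_ld_fraction=far_frac,
                    near_mean_r2=near_r2,
                    flagged=flagged,
                )
            )
    return flags


def misplaced_flags_frame(flags: list[MisplacedFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker_id": [f.marker_id for f in flags],
            "chromosome": [f.chromosome for f in flags],
            "position_bp": [f.position_bp for f in flags],
            "far_high_ld_fraction": [f.far_high_ld_fraction for f in flags],
            "near_mean_r2": [f.near_mean_r2 for f in flags],
            "flagged": [f.flagged for f in flags],
        }
    )
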