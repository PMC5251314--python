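"""Per-population heterozygosity, MAF and pairwise IBS genetic distance."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class AlleleStats:
    """Per-marker counted-allele frequency p, MAF, H_O and H_E.

    H_O is the fraction of non-missing heterozygous calls at the marker;
    H_E = 2 p (1 - p).  Markers with no calls carry NaN and are excluded
    from the summary means.
    """

    marker_ids: np.ndarray
    p: np.ndarray
    maf: np.ndarray
    h_obs: np.ndarray
    h_exp: np.ndarray

    def summary(self) -> pd.Series:
        """Unweighted marker means (and SDs) over markers with data."""
        ok = ~np.isnan(self.p)
        return pd.Series(
            {
                "mean_H_E": float(np.mean(self.h_exp[ok])),
                "sd_H_E": float(np.std(self.h_exp[ok], ddof=1)),
                "mean_H_O": float(np.mean(self.h_obs[ok])),
                "sd_H_O": float(np.std(self.h_obs[ok], ddof=1)),
                "mean_MAF": float(np.mean(self.maf[ok])),
                "sd_MAF": float(np.std(self.maf[ok], ddof=1)),
            }
        )


def allele_stats(panel: GenotypePanel) -> AlleleStats:
    """Counted-allele frequency, MAF and per-marker heterozygosity."""
    if panel.n_animals == 0 or panel.n_markers == 0:
        raise ValueError("empty panel")
    dos = panel.dosages
    miss = np.isnan(dos)
    n_called = (~miss).sum(axis=0)
    if (n_called == 0).any():
        logger.info(
            "%d markers have no calls; excluded from summaries",
            int((n_called == 0).sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dos, axis=0) / (2 * n_called)
        h_obs = (dos == 1).sum(axis=0) / n_called
    p = np.where(n_called == 0, np.nan, p)
    h_obs = np.where(n_called == 0, np.nan, h_obs)
    maf = np.minimum(p, 1 - p)
    h_exp = 2 * p * (1 - p)
    return AlleleStats(
        marker_ids=panel.map.marker_ids.copy(),
        p=p,
        maf=maf,
        h_obs=h_obs,
        h_exp=h_exp,
    )


@dataclass
class DistanceMatrix:
    """Pairwise genetic distance D = 1 - D_ST between animals.

    D_ST = (IBS2 + 0.5 * IBS1) / N is the allele-sharing proportion over
    the N loci non-missing in both animals; identical genotypes share
    both alleles (IBS2), a dosage difference of 1 shares exactly one.
    """

    animal_ids: np.ndarray
    values: np.ndarray  # symmetric, diagonal 0, NaN where no shared loci

    def mean_off_diagonal(self) -> float:
        iu = np.triu_indices(len(self.animal_ids), k=1)
        vals = self.values[iu]
        return float(np.nanmean(vals))


def ibs_distance(panel: GenotypePanel) -> DistanceMatrix:
    """IBS-sharing distance matrix D = 1 - (IBS2 + 0.5*IBS1)/N.

    Uses dosage differences: |d_i - d_j| = 0 means both alleles shared,
    1 means one shared, 2 means opposite homozygotes.  Pairwise-complete
    loci only; a pair with no shared loci gets NaN (logged).
    """
    if panel.n_animals < 2:
        raise ValueError("need at least 2 animals")
    dos = panel.dosages
    miss = np.isnan(dos)
    M = (~miss).astype(float)
    V = np.where(miss, 0.0, dos)
    N = M @ M.T
    # sum over shared loci of |d_i - d_j| via expansion: E[|x-y|] lacks a
    # bilinear form, so accumulate the three indicator matmuls instead.
    is0 = ((dos == 0) & ~miss).astype(float)
    is1 = ((dos == 1) & ~miss).astype(float)
    is2 = ((dos == 2) & ~miss).astype(float)
    ibs2 = is0 @ is0.T + is1 @ is1.T + is2 @ is2.T
    ibs0 = is0 @ is2.T + is2 @ is0.T
    ibs1 = N - ibs2 - ibs0
    with np.errstate(invalid="ignore", divide="ignore"):
        dst = (ibs2 + 0.5 * ibs1) / N
    d = 1.0 - dst
    d[N == 0] = np.nan
    if np.isnan(d[np.triu_indices(len(d), k=1)]).any():
        logger.warning("some animal pairs share no called loci")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(animal_ids=panel.animal_ids.copy(), values=d)


def diversity_summary(panel: GenotypePanel) -> pd.DataFrame:
    """Per-population H_E/H_O/MAF/D_ST summary table."""
    rows = []
    for pop, sub in panel.split_by_population().items():
        s = allele_stats(sub).summary()
        s["mean_D"] = ibs_distance(sub).mean_off_diagonal() if sub.n_animals > 1 else np.nan
        s["n_animals"] = sub.n_animals
        s["population"] = pop
        rows.append(s)
    return pd.DataFrame(rows).set_index("population")
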