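"""Composite linkage disequilibrium from unphased genotypes.

Phase is never inferred: disequilibrium between two SNPs is estimated
directly from the 3x3 diploid genotype table (the composite measure of
Hill & Robertson / Lynch & Walsh).  Writing ``c_a`` and ``c_b`` for the
dosages of the counted alleles A and B, the joint-count term

    4*N_AABB + 2*(N_AABb + N_AaBB) + N_AaBb  =  sum_k c_a[k] * c_b[k]

so the composite disequilibrium with its small-sample factor is

    D  = N/(N-1) * [ sum(c_a*c_b)/(2N) - 2*f(A)*f(B) ]
    r2 = D^2 / (f(A) f(a) f(B) f(b)),   clamped at 1
    signed r = sign(D) * sqrt(r2),      sign(0) := +1

with every count and frequency computed on the animals where both
markers are called (complete pairs), and N the complete-pair count.
The dosage-product identity is what lets whole marker blocks be
computed with three matrix products; the per-pair function
:func:`composite_ld_pair` and the blocked scan share these formulas.

Distances are bp differences / 1e6 (Mbp).  Pairs where either marker is
monomorphic among the complete pairs are undefined and skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GenotypePanel

logger = logging.getLogger(__name__)

#: Table-5-style distance classes in Mbp, half-open [lo, hi).
DEFAULT_DISTANCE_CLASSES: tuple[tuple[float, float], ...] = (
    (0.0, 0.01),
    (0.01, 0.05),
    (0.05, 0.10),
    (0.10, 0.50),
    (0.50, 1.00),
    (1.00, 2.00),
    (2.00, 3.00),
    (3.00, 4.00),
    (4.00, 5.00),
)


@dataclass
class LDRecord:
    chromosome: int
    id_a: str
    id_b: str
    bp_a: int
    bp_b: int
    distance_mbp: float
    D: float
    r2: float
    signed_r: float
    n_animals: int


def composite_ld_pair(
    dosages_a: Sequence[float], dosages_b: Sequence[float]
) -> tuple[float, float, float]:
    """Composite (D, r2, signed_r) for one marker pair.

    Raises ``ValueError`` when fewer than 2 complete pairs remain or a
    marker is monomorphic among them (the pair is undefined).
    """
    ca = np.asarray(dosages_a, dtype=float)
    cb = np.asarray(dosages_b, dtype=float)
    ok = ~np.isnan(ca) & ~np.isnan(cb)
    ca, cb = ca[ok], cb[ok]
    n = ca.size
    if n < 2:
        raise ValueError("need >= 2 animals with both markers called")
    fA = ca.sum() / (2 * n)
    fB = cb.sum() / (2 * n)
    if fA in (0.0, 1.0) or fB in (0.0, 1.0):
        raise ValueError("marker monomorphic among complete pairs")
    D = (n / (n - 1)) * ((ca @ cb) / (2 * n) - 2 * fA * fB)
    denom = fA * (1 - fA) * fB * (1 - fB)
    r2 = min(D * D / denom, 1.0)
    sign = 1.0 if D >= 0 else -1.0
    return float(D), float(r2), float(sign * np.sqrt(r2))


def _block_ld(dos: np.ndarray):
    """All-pairs composite LD within a dosage block (animals x markers).

    Returns (D, r2, signed_r, N, valid) square matrices; ``valid`` is
    False where a pair is undefined (too few complete pairs or a marker
    monomorphic among them).  Missing-data handling is exact: all sums
    are per-pair over the animals where both markers are called.
    """
    miss = np.isnan(dos)
    M = (~miss).astype(float)
    V = np.where(miss, 0.0, dos)
    N = M.T @ M  # complete pairs per marker pair
    Sab = V.T @ V  # sum of dosage products over complete pairs
    Sa = V.T @ M  # Sa[i, j] = sum of c_i over pairs complete with j
    Sb = Sa.T
    with np.errstate(invalid="ignore", divide="ignore"):
        fA = Sa / (2 * N)
        fB = Sb / (2 * N)
        D = (N / (N - 1)) * (Sab / (2 * N) - 2 * fA * fB)
        denom = fA * (1 - fA) * fB * (1 - fB)
        r2 = np.minimum(D * D / denom, 1.0)
    valid = (N >= 2) & (fA > 0) & (fA < 1) & (fB > 0) & (fB < 1)
    sign = np.where(D < 0, -1.0, 1.0)
    signed_r = sign * np.sqrt(np.where(valid, r2, np.nan))
    return D, r2, signed_r, N, valid


def pairwise_r2_matrix(dos: np.ndarray) -> np.ndarray:
    """Square r2 matrix for a dosage block; NaN where undefined."""
    _, r2, _, _, valid = _block_ld(dos)
    return np.where(valid, r2, np.nan)


def ld_scan(
    panel: GenotypePanel,
    max_distance_mbp: float = 5.0,
    adjacent_only: bool = False,
) -> pd.DataFrame:
    """All within-chromosome LD pairs up to ``max_distance_mbp``.

    Returns a DataFrame with one row per pair in deterministic order
    (chromosome, left marker, right marker); columns chromosome, id_a,
    id_b, bp_a, bp_b, distance_mbp, D, r2, signed_r, n_animals.  With
    ``adjacent_only`` only consecutive-marker pairs are computed (the
    "adjacent SNP" summaries).  Undefined pairs are dropped and counted
    in the log.
    """
    mt = panel.map.table
    chroms = mt["chromosome"].to_numpy()
    frames = []
    n_skipped = 0
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if len(idx) < 2:
            continue
        pos = mt["position_bp"].to_numpy()[idx]
        ids = mt["marker_id"].to_numpy()[idx]
        D, r2, signed_r, N, valid = _block_ld(panel.dosages[:, idx])
        k = len(idx)
        if adjacent_only:
            ii = np.arange(k - 1)
            jj = ii + 1
        else:
            ii, jj = np.triu_indices(k, k=1)
        dist = (pos[jj] - pos[ii]) / 1e6
        keep = dist <= max_distance_mbp
        ii, jj, dist = ii[keep], jj[keep], dist[keep]
        ok = valid[ii, jj]
        n_skipped += int((~ok).sum())
        ii, jj, dist = ii[ok], jj[ok], dist[ok]
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "id_a": ids[ii],
                    "id_b": ids[jj],
                    "bp_a": pos[ii],
                    "bp_b": pos[jj],
                    "distance_mbp": dist,
                    "D": D[ii, jj],
                    "r2": r2[ii, jj],
                    "signed_r": signed_r[ii, jj],
                    "n_animals": N[ii, jj].astype(int),
                }
            )
        )
    if n_skipped:
        logger.info("ld_scan skipped %d undefined pairs", n_skipped)
    if not frames:
        return pd.DataFrame(
            columns=[
                "chromosome", "id_a", "id_b", "bp_a", "bp_b",
                "distance_mbp", "D", "r2", "signed_r", "n_animals",
            ]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class LDSummary:
    """Binned decay curve, distance-class means and useful-LD fractions."""

    bins: pd.DataFrame  # bin_lo, bin_hi, mean_r2, mean_signed_r, n_pairs
    class_means: pd.DataFrame  # class_lo, class_hi, mean_r2, n_pairs
    useful_fractions: dict[float, float]  # threshold -> fraction of pairs


def summarize_ld(
    records: pd.DataFrame,
    bin_width_mbp: float = 0.01,
    distance_classes: Iterable[tuple[float, float]] = DEFAULT_DISTANCE_CLASSES,
    useful_thresholds: Sequence[float] = (0.2, 0.3),
) -> LDSummary:
    """Bin LD records by distance (half-open [lo, hi) bins anchored at 0).

    ``bins`` is the 0.01-Mbp decay curve, ``class_means`` the coarse
    distance-class table, and ``useful_fractions`` the share of input
    pairs with r2 >= each threshold (meaningful when ``records`` comes
    from an adjacent-only scan).  Empty bins are omitted.
    """
    if records.empty:
        raise ValueError("no LD records to summarize")
    d = records["distance_mbp"].to_numpy()
    r2 = records["r2"].to_numpy()
    sr = records["signed_r"].to_numpy()

    bin_idx = np.floor(d / bin_width_mbp).astype(int)
    rows = []
    for b in np.unique(bin_idx):
        sel = bin_idx == b
        rows.append(
            (
                b * bin_width_mbp,
                (b + 1) * bin_width_mbp,
                r2[sel].mean(),
                sr[sel].mean(),
                int(sel.sum()),
            )
        )
    bins = pd.DataFrame(
        rows, columns=["bin_lo", "bin_hi", "mean_r2", "mean_signed_r", "n_pairs"]
    )

    crows = []
    for lo, hi in distance_classes:
        sel = (d >= lo) & (d < hi)
        if sel.any():
            crows.append((lo, hi, r2[sel].mean(), int(sel.sum())))
    class_means = pd.DataFrame(
        crows, columns=["class_lo", "class_hi", "mean_r2", "n_pairs"]
    )

    useful = {float(t): float((r2 >= t).mean()) for t in useful_thresholds}
    return LDSummary(bins=bins, class_means=class_means, useful_fractions=useful)
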