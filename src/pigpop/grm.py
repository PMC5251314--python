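"""VanRaden genomic relationship matrix and principal components.

G = Z Z' / (2 * sum_i p_i (1 - p_i)), with Z the dosage matrix whose
columns are centered by twice the counted-allele frequency and missing
dosages imputed at 2 p_i (zero contribution).  The diagonal of G minus
one is the VanRaden genomic inbreeding coefficient; the off-diagonals
are genomic relationships.  Principal components are taken from the
eigendecomposition of the double-centered G, the standard population-
structure construction (scores = eigenvector * sqrt(eigenvalue)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import AlleleStats
from .io import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    animal_ids: np.ndarray
    values: np.ndarray  # symmetric animals x animals
    n_markers: int
    freqs: np.ndarray  # counted-allele frequencies used


@dataclass
class PCResult:
    animal_ids: np.ndarray
    scores: np.ndarray  # animals x k
    variance_fractions: np.ndarray  # length k, non-increasing

    def to_frame(self, populations=None) -> pd.DataFrame:
        cols = {f"PC{i+1}": self.scores[:, i] for i in range(self.scores.shape[1])}
        df = pd.DataFrame({"animal_id": self.animal_ids, **cols})
        if populations is not None:
            df.insert(1, "population", populations)
        return df


def build_grm(panel: GenotypePanel, freqs: AlleleStats | None = None) -> GRM:
    """VanRaden G from a post-QC panel.

    ``freqs`` defaults to frequencies estimated from the panel itself;
    supply reference (e.g. base-population) frequencies to override.
    Monomorphic markers contribute nothing and are dropped from the
    denominator; a panel with no polymorphic markers is an error.
    """
    from .diversity import allele_stats

    p = (freqs or allele_stats(panel)).p
    poly = ~np.isnan(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers; GRM undefined")
    p = p[poly]
    dos = panel.dosages[:, poly]
    Z = np.where(np.isnan(dos), 0.0, dos - 2 * p)  # missing -> 2p (zero term)
    denom = 2.0 * np.sum(p * (1 - p))
    G = (Z @ Z.T) / denom
    return GRM(
        animal_ids=panel.animal_ids.copy(),
        values=G,
        n_markers=int(poly.sum()),
        freqs=p,
    )


def f_vanraden_from_grm(grm: GRM) -> pd.Series:
    """F_VR = diag(G) - 1, the animal's genomic self-relationship excess."""
    return pd.Series(np.diag(grm.values) - 1.0, index=grm.animal_ids, name="F_VR")


def principal_components(grm: GRM, k: int = 2) -> PCResult:
    """Top-k principal components of the double-centered GRM.

    Variance fractions are eigenvalues over the sum of positive
    eigenvalues; if fewer than ``k`` positive eigenvalues exist the
    result is truncated (logged).  A degenerate GRM (all animals
    identical) has no positive eigenvalues and raises.
    """
    n = len(grm.animal_ids)
    if k > n:
        raise ValueError("k exceeds number of animals")
    G = grm.values
    J = np.eye(n) - np.ones((n, n)) / n
    Gc = J @ G @ J
    Gc = (Gc + Gc.T) / 2
    w, v = np.linalg.eigh(Gc)
    w, v = w[::-1], v[:, ::-1]
    pos = w > max(1e-12, 1e-9 * abs(w[0]))
    total = w[pos].sum()
    if not pos.any() or total <= 0:
        raise ValueError("degenerate GRM: no positive eigenvalues")
    kk = min(k, int(pos.sum()))
    if kk < k:
        logger.warning("requested %d components, rank supports %d", k, kk)
    scores = v[:, :kk] * np.sqrt(w[:kk])
    return PCResult(
        animal_ids=grm.animal_ids.copy(),
        scores=scores,
        variance_fractions=w[:kk] / total,
    )
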