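"""Individual inbreeding coefficients: F_EH, F_VR, F_PED, and their
cross-estimator correlations.

F_EH (excess homozygosity), per animal over its non-missing markers:

    F_EH = (1/m) * sum_i [ 1 - c_i (2 - c_i) / (2 p_i (1 - p_i)) ]

F_VR (VanRaden) is the genomic self-relationship minus one, computed
through the GRM code path so the identity F_VR = diag(G) - 1 is exact.

F_PED is Wright's pedigree inbreeding coefficient, computed by the
recursive tabular (numerator-relationship) method: the animal's F is
half the additive relationship between its parents.  The tabular method
gives results identical to Colleau's indirect method, which is an
efficiency device for very large pedigrees.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .diversity import AlleleStats, allele_stats
from .grm import build_grm, f_vanraden_from_grm
from .io import NULL_PARENT, GenotypePanel, Pedigree

logger = logging.getLogger(__name__)

COEFFICIENTS = ("F_EH", "F_VR", "F_ROH", "F_PED")


def f_excess_homozygosity(
    panel: GenotypePanel, freqs: AlleleStats | None = None
) -> pd.Series:
    """Excess-homozygosity inbreeding coefficient per animal.

    Markers with p in {0, 1} (or unknown p) are excluded; m is the
    animal's count of usable non-missing markers.  An animal with no
    usable markers gets NaN.
    """
    p = (freqs or allele_stats(panel)).p
    usable = ~np.isnan(p) & (p > 0) & (p < 1)
    p = p[usable]
    dos = panel.dosages[:, usable]
    with np.errstate(invalid="ignore"):
        term = 1.0 - dos * (2.0 - dos) / (2.0 * p * (1.0 - p))
    m = (~np.isnan(term)).sum(axis=1)
    f = np.where(m > 0, np.nansum(term, axis=1) / np.maximum(m, 1), np.nan)
    if (m == 0).any():
        logger.warning("%d animals have no usable markers for F_EH", int((m == 0).sum()))
    return pd.Series(f, index=panel.animal_ids, name="F_EH")


def f_vanraden(
    panel: GenotypePanel, freqs: AlleleStats | None = None
) -> pd.Series:
    """VanRaden inbreeding coefficient: diag of the genomic relationship
    matrix minus one (shared code path with :func:`pigpop.grm.build_grm`)."""
    return f_vanraden_from_grm(build_grm(panel, freqs)).rename("F_VR")


def f_pedigree(ped: Pedigree) -> pd.Series:
    """Wright's inbreeding coefficient for every pedigree animal.

    Tabular method on the numerator relationship matrix restricted to
    recorded animals; unknown parents are unrelated non-inbred founders.
    """
    order = ped.topological_order
    parents = ped.parents_of()
    idx = {a: i for i, a in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, animal in enumerate(order):
        s, d = parents[animal]
        si = idx.get(s) if s != NULL_PARENT else None
        di = idx.get(d) if d != NULL_PARENT else None
        # relationship with every earlier animal (row recursion, vectorized)
        row = np.zeros(i)
        if si is not None:
            row += 0.5 * A[si, :i]
        if di is not None:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        a_sd = A[si, di] if (si is not None and di is not None) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
    f = pd.Series({a: A[idx[a], idx[a]] - 1.0 for a in ped.table["animal"]})
    return f.rename("F_PED")


def inbreeding_table(
    panel: GenotypePanel,
    f_roh: pd.Series | None = None,
    pedigree: Pedigree | None = None,
    freqs: AlleleStats | None = None,
) -> pd.DataFrame:
    """Assemble the per-animal table of all available coefficients."""
    df = pd.DataFrame(
        {
            "F_EH": f_excess_homozygosity(panel, freqs),
            "F_VR": f_vanraden(panel, freqs),
        }
    )
    if f_roh is not None:
        df["F_ROH"] = f_roh.reindex(df.index).fillna(0.0)
    if pedigree is not None:
        df["F_PED"] = f_pedigree(pedigree).reindex(df.index)
    df.insert(0, "population", panel.populations)
    df.index.name = "animal_id"
    return df


def inbreeding_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-population mean/SD/min/max for each coefficient."""
    cols = [c for c in COEFFICIENTS if c in table.columns]
    return table.groupby("population")[cols].agg(["mean", "std", "min", "max"])


def inbreeding_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations among coefficients, per population.

    Complete cases only.  A coefficient with zero variance in a
    population (e.g. F_PED identically 0 in an F1 cross) yields
    correlation 0.0 with ``degenerate=True`` in the output.
    """
    cols = [c for c in COEFFICIENTS if c in table.columns]
    rows = []
    for pop, grp in table.groupby("population"):
        sub = grp[cols].dropna()
        if len(sub) < 3:
            logger.warning("population %s has < 3 complete cases", pop)
            continue
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                x, y = sub[a].to_numpy(), sub[b].to_numpy()
                degenerate = np.std(x) == 0 or np.std(y) == 0
                r = 0.0 if degenerate else float(np.corrcoef(x, y)[0, 1])
                rows.append(
                    {
                        "population": pop,
                        "coef_a": a,
                        "coef_b": b,
                        "pearson_r": r,
                        "degenerate": degenerate,
                        "n": len(sub),
                    }
                )
    return pd.DataFrame(rows)
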