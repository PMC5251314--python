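"""Runs of homozygosity: detection, F_ROH and summaries.

A run is a maximal marker interval in which the animal has at least
``min_snps`` SNPs with at most one heterozygote and at most two missing
calls, and whose first and last SNP are homozygous non-missing.  The
scan is a direct left-to-right maximal-interval search over the sorted
map — not a sliding-window heuristic — so the reported segments are
exactly the maximal intervals satisfying the stated constraints, with
overlapping candidates resolved greedily left to right.  F_ROH divides
the summed segment bp lengths by the SNP-covered genome length (last
minus first SNP position summed over autosomes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypePanel, MarkerMap

logger = logging.getLogger(__name__)

HOM, HET, MISS = 0, 1, 2  # per-call classification codes


@dataclass
class ROHSegment:
    animal_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


def classify_calls(dosages_1d: np.ndarray) -> np.ndarray:
    """Map a dosage vector to HOM/HET/MISS codes."""
    calls = np.full(dosages_1d.shape, HOM, dtype=np.int8)
    calls[dosages_1d == 1] = HET
    calls[np.isnan(dosages_1d)] = MISS
    return calls


def scan_runs(
    calls: np.ndarray,
    min_snps: int = 40,
    max_het: int = 1,
    max_missing: int = 2,
) -> list[tuple[int, int]]:
    """Greedy left-to-right maximal homozygous runs in a call vector.

    Returns (start, end) index pairs (inclusive).  From each candidate
    start (leftmost homozygous SNP not yet covered) the run is extended
    as far right as the het/missing budgets allow, then trimmed so it
    ends on a homozygous SNP; it is reported if it reaches ``min_snps``
    markers, and scanning resumes after its end.
    """
    n = len(calls)
    is_het = calls == HET
    is_miss = calls == MISS
    is_hom = calls == HOM
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not is_hom[i]:
            i += 1
            continue
        # extend right while budgets hold
        het = miss = 0
        j = i
        last_hom = i
        while j < n:
            if is_het[j]:
                if het + 1 > max_het:
                    break
                het += 1
            elif is_miss[j]:
                if miss + 1 > max_missing:
                    break
                miss += 1
            else:
                last_hom = j
            j += 1
        end = last_hom
        if end - i + 1 >= min_snps:
            runs.append((i, end))
            i = end + 1
        else:
            i += 1
    return runs


def detect_roh(
    panel: GenotypePanel,
    min_snps: int = 40,
    max_het: int = 1,
    max_missing: int = 2,
) -> list[ROHSegment]:
    """Detect ROH segments for every animal on every chromosome."""
    mt = panel.map.table
    chroms = mt["chromosome"].to_numpy()
    pos = mt["position_bp"].to_numpy()
    segments: list[ROHSegment] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        cpos = pos[idx]
        block = panel.dosages[:, idx]
        for a, animal in enumerate(panel.animal_ids):
            calls = classify_calls(block[a])
            for s, e in scan_runs(calls, min_snps, max_het, max_missing):
                seg = calls[s : e + 1]
                segments.append(
                    ROHSegment(
                        animal_id=str(animal),
                        chromosome=int(chrom),
                        start_bp=int(cpos[s]),
                        end_bp=int(cpos[e]),
                        n_snps=int(e - s + 1),
                        n_het=int((seg == HET).sum()),
                        n_missing=int((seg == MISS).sum()),
                    )
                )
    return segments


def segments_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [s.animal_id for s in segments],
            "chromosome": [s.chromosome for s in segments],
            "start_bp": [s.start_bp for s in segments],
            "end_bp": [s.end_bp for s in segments],
            "n_snps": [s.n_snps for s in segments],
            "n_het": [s.n_het for s in segments],
            "n_missing": [s.n_missing for s in segments],
            "length_kb": [s.length_kb for s in segments],
        }
    )


def f_roh(
    segments: list[ROHSegment],
    marker_map: MarkerMap,
    animal_ids: np.ndarray | None = None,
) -> pd.Series:
    """F_ROH = summed segment bp / SNP-covered genome bp, per animal.

    The genome length is the sum over chromosomes of (last SNP bp -
    first SNP bp) on the map the segments were called against.  Animals
    in ``animal_ids`` without segments get 0.
    """
    if len(marker_map) == 0:
        raise ValueError("empty marker map")
    genome_bp = float(marker_map.chromosome_spans_bp().sum())
    if genome_bp <= 0:
        raise ValueError("map covers zero genome length")
    totals: dict[str, float] = {}
    for s in segments:
        totals[s.animal_id] = totals.get(s.animal_id, 0.0) + (s.end_bp - s.start_bp)
    index = (
        pd.Index([str(a) for a in animal_ids])
        if animal_ids is not None
        else pd.Index(sorted(totals))
    )
    return pd.Series(
        [totals.get(a, 0.0) / genome_bp for a in index], index=index, name="F_ROH"
    )


def summarize_roh(
    segments: list[ROHSegment],
    panel: GenotypePanel,
    length_bins_kb: tuple[float, ...] = (0, 1000, 2000, 4000, 8000, 16000, np.inf),
) -> dict:
    """Per-animal and per-population ROH summaries plus a length histogram.

    Per animal: NSEG (segment count), KB (total kb), KB_AVG (mean kb per
    segment; NaN when NSEG = 0), NSNP (mean SNPs per segment) and
    density (mean kb per SNP within runs, KB_AVG / NSNP).
    """
    df = segments_frame(segments)
    per_animal = []
    for a, pop in zip(panel.animal_ids, panel.populations):
        sub = df[df["animal_id"] == str(a)] if not df.empty else df
        nseg = len(sub)
        kb = float(sub["length_kb"].sum()) if nseg else 0.0
        kb_avg = kb / nseg if nseg else np.nan
        nsnp = float(sub["n_snps"].mean()) if nseg else np.nan
        per_animal.append(
            {
                "animal_id": str(a),
                "population": pop,
                "NSEG": nseg,
                "KB": kb,
                "KB_AVG": kb_avg,
                "NSNP": nsnp,
                "density": kb_avg / nsnp if nseg else np.nan,
            }
        )
    per_animal = pd.DataFrame(per_animal).set_index("animal_id")
    per_pop = per_animal.groupby("population")[
        ["NSEG", "KB", "KB_AVG", "NSNP", "density"]
    ].agg(["mean", "std", "min", "max"])

    if df.empty:
        hist = pd.DataFrame(columns=["bin_lo_kb", "bin_hi_kb", "n_segments"])
    else:
        lo = np.asarray(length_bins_kb[:-1])
        hi = np.asarray(length_bins_kb[1:])
        counts = [
            int(((df["length_kb"] >= l) & (df["length_kb"] < h)).sum())
            for l, h in zip(lo, hi)
        ]
        hist = pd.DataFrame({"bin_lo_kb": lo, "bin_hi_kb": hi, "n_segments": counts})
    return {"per_animal": per_animal, "per_population": per_pop, "histogram": hist}
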