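"""Genotype-panel and pedigree I/O plus the project-wide data model.

The package works on diploid biallelic SNP genotypes stored as allele
dosages: for every marker one allele is designated the *counted allele*
and each genotype is the number of copies (0, 1 or 2) an animal carries,
with ``NaN`` marking a missing call.  All downstream statistics
(heterozygosity, inbreeding, LD, GRM, ROH) are defined on this dosage
representation, so the counted-allele convention is fixed once at read
time and recorded on the panel.

Input/output dialect is whitespace-delimited PLINK text (PED/MAP) for
genotypes and a headered CSV/TSV for pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

MISSING = np.nan
#: Null parent code used in pedigree files.
NULL_PARENT = "0"


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass
class MarkerMap:
    """Marker positions: one row per SNP with chromosome and bp coordinate.

    Markers must be unique by id and strictly sorted by position within
    each chromosome; positions are 1-based bp.  Distances used elsewhere
    are ``|bp_i - bp_j| / 1e6`` Mbp.
    """

    table: pd.DataFrame  # columns: marker_id, chromosome, position_bp

    def __post_init__(self) -> None:
        t = self.table
        required = ["marker_id", "chromosome", "position_bp"]
        missing_cols = [c for c in required if c not in t.columns]
        if missing_cols:
            raise ValueError(f"marker map missing columns {missing_cols}")
        if t["marker_id"].duplicated().any():
            dup = t.loc[t["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        if (t["position_bp"] < 1).any():
            raise ValueError("position_bp must be >= 1")
        for chrom, grp in t.groupby("chromosome", sort=False):
            pos = grp["position_bp"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"markers on chromosome {chrom} not strictly sorted by bp"
                )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions_bp(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy()

    def chromosome_spans_bp(self) -> pd.Series:
        """Covered length per chromosome: last SNP bp minus first SNP bp."""
        g = self.table.groupby("chromosome")["position_bp"]
        return g.max() - g.min()


@dataclass
class GenotypePanel:
    """Animals x markers dosage matrix with map and population labels.

    ``dosages`` is float64 with values in {0, 1, 2, NaN}; entry [i, j]
    counts copies of the counted allele of marker j in animal i.
    """

    animals: pd.DataFrame  # columns: animal_id, population, herd
    dosages: np.ndarray
    map: MarkerMap
    counted_allele: np.ndarray  # per-marker allele symbol that dosage counts
    other_allele: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.other_allele is None:
            self.other_allele = np.full(len(self.map), "B", dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.animals):
            raise ValueError("dosage rows != number of animals")
        if m != len(self.map):
            raise ValueError("dosage columns != number of markers")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosages must be in {0, 1, 2, NaN}")
        if (self.animals["population"].astype(str) == "").any():
            raise ValueError("population labels must be non-empty")

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_markers(self) -> int:
        return len(self.map)

    @property
    def animal_ids(self) -> np.ndarray:
        return self.animals["animal_id"].to_numpy()

    @property
    def populations(self) -> np.ndarray:
        return self.animals["population"].to_numpy()

    def subset(
        self,
        animal_idx: np.ndarray | None = None,
        marker_idx: np.ndarray | None = None,
    ) -> "GenotypePanel":
        """Return a new panel restricted to the given animal/marker indices."""
        a = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        m = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypePanel(
            animals=self.animals.iloc[a].reset_index(drop=True),
            dosages=self.dosages[np.ix_(a, m)],
            map=MarkerMap(self.map.table.iloc[m].reset_index(drop=True)),
            counted_allele=self.counted_allele[m],
            other_allele=self.other_allele[m],
        )

    def split_by_population(self) -> dict[str, "GenotypePanel"]:
        out = {}
        for pop in pd.unique(self.animals["population"]):
            idx = np.flatnonzero(self.animals["population"].to_numpy() == pop)
            out[str(pop)] = self.subset(animal_idx=idx)
        return out


@dataclass
class Pedigree:
    """Pedigree records (animal, sire, dam, population); acyclic by construction.

    Unknown parents are ``NULL_PARENT`` ("0").  ``topological_order``
    lists every animal after both of its (known) parents, which is the
    order the tabular relationship recursion requires.
    """

    table: pd.DataFrame  # columns: animal, sire, dam, population

    def __post_init__(self) -> None:
        t = self.table
        for col in ("animal", "sire", "dam"):
            if col not in t.columns:
                raise ValueError(f"pedigree missing column {col!r}")
        if "population" not in t.columns:
            t = t.assign(population="ALL")
            self.table = t
        if t["animal"].duplicated().any():
            dup = t.loc[t["animal"].duplicated(), "animal"].iloc[0]
            raise ValueError(f"duplicate pedigree record for {dup!r}")
        self._order = self._toposort()

    def _toposort(self) -> list[str]:
        t = self.table
        parents = {
            r.animal: [p for p in (r.sire, r.dam) if p != NULL_PARENT]
            for r in t.itertuples()
        }
        # parents not listed as animals are implicit founders
        known = set(parents)
        order: list[str] = []
        state: dict[str, int] = {}  # 1 = visiting, 2 = done

        for root in parents:
            if state.get(root):
                continue
            stack = [(root, iter(parents[root]))]
            state[root] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if p not in known:
                        continue
                    s = state.get(p)
                    if s == 1:
                        raise ValueError(
                            f"pedigree cycle detected involving animal {p!r}"
                        )
                    if s is None:
                        state[p] = 1
                        stack.append((p, iter(parents[p])))
                        advanced = True
                        break
                if not advanced:
                    stack.pop()
                    state[node] = 2
                    order.append(node)
        return order

    @property
    def topological_order(self) -> list[str]:
        return list(self._order)

    def parents_of(self) -> dict[str, tuple[str, str]]:
        return {
            r.animal: (r.sire, r.dam) for r in self.table.itertuples()
        }

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# PLINK text I/O


def _choose_counted(
    a_counts: dict[str, int], policy: str
) -> tuple[str, str]:
    """Pick (counted, other) allele symbols from observed allele counts."""
    alleles = sorted(a_counts)  # lexicographic tie-break
    if len(alleles) == 1:
        return alleles[0], "?"
    if policy == "first_listed":
        return alleles[0], alleles[1]
    # minor: least frequent allele counted, lexicographic on ties
    a, b = alleles
    if a_counts[a] <= a_counts[b]:
        return a, b
    return b, a


def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    allele_policy: str = "minor",
) -> GenotypePanel:
    """Read a whitespace-delimited PED/MAP pair into a :class:`GenotypePanel`.

    PED rows are ``fid iid sire dam sex pheno`` followed by two allele
    columns per marker; ``0`` codes a missing allele.  The family id
    column is used as the population label (herd defaults to the same).
    ``allele_policy`` fixes which allele the dosage counts: ``minor``
    (default; ties broken lexicographically) or ``first_listed`` (the
    lexicographically first observed allele).
    """
    map_path, ped_path = Path(map_path), Path(ped_path)
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{map_path}:{ln}: expected 4 MAP columns")
            chrom, mid, _cm, bp = parts
            try:
                rows.append((mid, int(chrom), int(bp)))
            except ValueError as e:
                raise ParseError(f"{map_path}:{ln}: {e}") from None
    mtab = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"])
    # present markers sorted per chromosome by bp (stable across chromosomes)
    order = np.lexsort((mtab["position_bp"], mtab["chromosome"]))
    # keep original chromosome grouping order if already grouped; use sort
    mtab = mtab.iloc[order].reset_index(drop=True)
    marker_map = MarkerMap(mtab)
    m = len(marker_map)

    animals = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            fid, iid = parts[0], parts[1]
            animals.append((iid, fid, fid))
            allele_rows.append(parts[6:])
    if not animals:
        raise ParseError(f"{ped_path}: no animals")
    atab = pd.DataFrame(animals, columns=["animal_id", "population", "herd"])

    # alleles as (n, m, 2) array in MAP file order, then reordered with map
    arr = np.array(allele_rows, dtype=object).reshape(len(animals), m, 2)
    arr = arr[:, order, :]

    dosages = np.full((len(animals), m), np.nan)
    counted = np.empty(m, dtype=object)
    other = np.empty(m, dtype=object)
    for j in range(m):
        col = arr[:, j, :]
        obs = col[col != "0"]
        uniq, cnt = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise ParseError(
                f"marker {marker_map.marker_ids[j]!r} has >2 alleles: {list(uniq)}"
            )
        counts = dict(zip(uniq.tolist(), cnt.tolist()))
        if not counts:
            counted[j], other[j] = "A", "B"
            continue
        counted[j], other[j] = _choose_counted(counts, allele_policy)
        a1, a2 = col[:, 0], col[:, 1]
        ok = (a1 != "0") & (a2 != "0")
        dosages[ok, j] = (a1[ok] == counted[j]).astype(float) + (
            a2[ok] == counted[j]
        ).astype(float)
    return GenotypePanel(
        animals=atab,
        dosages=dosages,
        map=marker_map,
        counted_allele=counted,
        other_allele=other,
    )


def write_plink_text(
    panel: GenotypePanel, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write a panel as PED/MAP readable by :func:`read_plink_text`.

    The counted allele is written with its recorded symbol ("A" when the
    original letters are unknown, the other allele "B"); missing dosage
    becomes "0 0".  Re-reading with ``allele_policy="first_listed"``
    reproduces the panel exactly (the A/B coding puts the counted allele
    lexicographically first); the ``minor`` policy instead re-derives
    the counted allele from the data, complementing any marker whose
    counted allele has sample frequency above one half.  A counted
    allele entirely absent from the panel cannot be recovered from PED
    text at all (the format only records observed alleles).
    """
    if panel.n_animals == 0:
        raise ValueError("refusing to write a panel with no animals")
    out_prefix = Path(out_prefix)
    ped_path = out_prefix.with_suffix(".ped")
    map_path = out_prefix.with_suffix(".map")
    mt = panel.map.table
    with open(map_path, "w") as fh:
        for r in mt.itertuples():
            fh.write(f"{r.chromosome} {r.marker_id} 0 {r.position_bp}\n")
    counted = panel.counted_allele
    other = panel.other_allele
    with open(ped_path, "w") as fh:
        for i, r in enumerate(panel.animals.itertuples()):
            fields = [str(r.population), str(r.animal_id), "0", "0", "0", "-9"]
            row = panel.dosages[i]
            for j in range(panel.n_markers):
                d = row[j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [counted[j], counted[j]]
                elif d == 1:
                    fields += [counted[j], other[j]]
                else:
                    fields += [other[j], other[j]]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a delimited pedigree file (animal, sire, dam[, population]).

    Accepts comma-, tab- or whitespace-delimited text with a header row.
    Cycles (including self-parenting) raise with an offending animal named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    ren = {}
    for want, pats in {
        "animal": ("animal", "id", "iid"),
        "sire": ("sire", "father"),
        "dam": ("dam", "mother"),
        "population": ("population", "breed", "pop"),
    }.items():
        for c in df.columns:
            if c in pats:
                ren[c] = want
                break
    df = df.rename(columns=ren)
    if "population" not in df.columns:
        df["population"] = "ALL"
    for col in ("animal", "sire", "dam"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing pedigree column {col!r}")
        df[col] = df[col].fillna(NULL_PARENT).astype(str)
    return Pedigree(df[["animal", "sire", "dam", "population"]])


def write_pedigree(ped: Pedigree, path: str | Path) -> Path:
    path = Path(path)
    ped.table.to_csv(path, sep="\t", index=False)
    return path
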