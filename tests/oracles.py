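"""Independent brute-force oracles used to cross-check the implementation.

Each oracle takes the most literal route available — contingency
tables, path enumeration, exhaustive subinterval search — and shares no
code with the library paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

# --- composite LD from the explicit 3x3 genotype contingency table ---


def ld_oracle(dosages_a, dosages_b):
    """(D, r2, signed_r) via the printed joint-count formula on the 3x3 table."""
    ca = np.asarray(dosages_a, dtype=float)
    cb = np.asarray(dosages_b, dtype=float)
    ok = ~np.isnan(ca) & ~np.isnan(cb)
    ca, cb = ca[ok].astype(int), cb[ok].astype(int)
    n = len(ca)
    table = np.zeros((3, 3))
    for x, y in zip(ca, cb):
        table[x, y] += 1
    N_AABB = table[2, 2]
    N_AABb = table[2, 1]
    N_AaBB = table[1, 2]
    N_AaBb = table[1, 1]
    fA = (2 * table[2, :].sum() + table[1, :].sum()) / (2 * n)
    fB = (2 * table[:, 2].sum() + table[:, 1].sum()) / (2 * n)
    if fA in (0.0, 1.0) or fB in (0.0, 1.0):
        raise ValueError("monomorphic")
    joint = (4 * N_AABB + 2 * (N_AABb + N_AaBB) + N_AaBb) / (2 * n)
    D = (n / (n - 1)) * (joint - 2 * fA * fB)
    r2 = min(D * D / (fA * (1 - fA) * fB * (1 - fB)), 1.0)
    sign = 1.0 if D >= 0 else -1.0
    return D, r2, sign * np.sqrt(r2)


# --- pedigree inbreeding by common-ancestor path counting ---


def _ancestor_paths(animal, parents):
    """All upward paths (as tuples, starting at ``animal``) to every ancestor."""
    paths = [(animal,)]
    out = [(animal,)]
    while paths:
        nxt = []
        for p in paths:
            for parent in parents.get(p[-1], ()):  # unknown -> founder
                if parent == "0":
                    continue
                q = p + (parent,)
                out.append(q)
                nxt.append(q)
        paths = nxt
    return out


def f_pedigree_oracle(animal, parents, _cache=None):
    """Wright's path-counting F: sum over common ancestors A and pairs of
    parent-to-A paths meeting only at A of (1/2)^(n1+n2+1) * (1 + F_A)."""
    if _cache is None:
        _cache = {}
    if animal in _cache:
        return _cache[animal]
    pars = [p for p in parents.get(animal, ()) if p != "0"]
    if len(pars) < 2:
        _cache[animal] = 0.0
        return 0.0
    s, d = pars
    paths_s = _ancestor_paths(s, parents)
    paths_d = _ancestor_paths(d, parents)
    f = 0.0
    for ps in paths_s:
        for pd_ in paths_d:
            if ps[-1] != pd_[-1]:
                continue
            a = ps[-1]
            if set(ps) & set(pd_) != {a}:
                continue  # paths must meet only at the common ancestor
            n1, n2 = len(ps) - 1, len(pd_) - 1
            fa = f_pedigree_oracle(a, parents, _cache)
            f += 0.5 ** (n1 + n2 + 1) * (1.0 + fa)
    _cache[animal] = f
    return f


# --- ROH by exhaustive valid-subinterval enumeration ---


def roh_oracle(calls, min_snps=40, max_het=1, max_missing=2):
    """All (start, end) runs via brute force over every subinterval, with
    the same left-to-right maximal overlap resolution the scanner defines."""
    from pigpop.roh import HET, HOM, MISS

    n = len(calls)
    valid = []
    for i in range(n):
        if calls[i] != HOM:
            continue
        for j in range(i + min_snps - 1, n):
            if calls[j] != HOM:
                continue
            window = calls[i : j + 1]
            if (window == HET).sum() <= max_het and (
                window == MISS
            ).sum() <= max_missing:
                valid.append((i, j))
    out = []
    cursor = 0
    while True:
        cands = [(i, j) for i, j in valid if i >= cursor]
        if not cands:
            break
        i0 = min(i for i, _ in cands)
        j0 = max(j for i, j in cands if i == i0)
        out.append((i0, j0))
        cursor = j0 + 1
    return out


# --- allele-level IBS sharing for one genotype pair ---


def ibs_shared_alleles(g1: int, g2: int) -> int:
    """Size of the multiset intersection of the two allele pairs."""
    alleles = {0: ("B", "B"), 1: ("A", "B"), 2: ("A", "A")}
    a = list(alleles[g1])
    shared = 0
    for x in alleles[g2]:
        if x in a:
            a.remove(x)
            shared += 1
    return shared
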