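"""Independent oracles used by the test suite.

These deliberately re-derive quantities by different algorithms than the
package (recursive kinship and Wright's path counting instead of the
tabular method; exact rational arithmetic instead of floats) so that
agreement is evidence, not tautology.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache

import numpy as np

from floaterqg.pedigree import Pedigree


def kinship_oracle(ped: Pedigree):
    """Recursive coancestry phi(i, j) with exact rational arithmetic.

    phi(i, i) = 1/2 (1 + phi(s_i, d_i)); for i != j with i not an
    ancestor of j, phi(i, j) = 1/2 (phi(i, s_j) + phi(i, d_j)) taking j
    as the later-born individual.  Missing parents contribute 0.
    """
    order = {iid: k for k, iid in enumerate(_topo(ped))}

    @lru_cache(maxsize=None)
    def phi(i: str | None, j: str | None) -> Fraction:
        if i is None or j is None:
            return Fraction(0)
        if i == j:
            s, d = ped.parents(i)
            return Fraction(1, 2) * (1 + phi(s, d))
        # recurse on the individual later in the topological order
        if order[i] > order[j]:
            i, j = j, i
        s, d = ped.parents(j)
        return Fraction(1, 2) * (phi(i, s) + phi(i, d))

    return phi


def inbreeding_oracle_kinship(ped: Pedigree) -> dict[str, Fraction]:
    """f_i = phi(sire_i, dam_i), exactly."""
    phi = kinship_oracle(ped)
    out = {}
    for i in ped.ids:
        s, d = ped.parents(i)
        out[i] = Fraction(0) if s is None or d is None else phi(s, d)
    return out


def wright_paths_inbreeding(ped: Pedigree) -> dict[str, Fraction]:
    """Wright's path-counting inbreeding coefficients, exactly.

    f_X = sum over common ancestors CA and over pairs of ascending paths
    sire->CA and dam->CA that share only CA of (1/2)^(n + n' + 1)
    (1 + F_CA), with F_CA computed by the same rule.
    """
    anc_cache: dict[str, dict[str, list[tuple[str, ...]]]] = {}

    def paths_up(x: str) -> dict[str, list[tuple[str, ...]]]:
        """All ascending paths from x to each ancestor, as vertex tuples
        (x excluded, ancestor included)."""
        if x in anc_cache:
            return anc_cache[x]
        out: dict[str, list[tuple[str, ...]]] = {x: [()]}
        for p in ped.parents(x):
            if p is None:
                continue
            for anc, plist in paths_up(p).items():
                out.setdefault(anc, [])
                for path in plist:
                    out[anc].append((p,) + path)
        anc_cache[x] = out
        return out

    memo: dict[str, Fraction] = {}

    def F(x: str) -> Fraction:
        if x in memo:
            return memo[x]
        s, d = ped.parents(x)
        if s is None or d is None:
            memo[x] = Fraction(0)
            return memo[x]
        sp, dp = paths_up(s), paths_up(d)
        total = Fraction(0)
        for ca in set(sp) & set(dp):
            for p1 in sp[ca]:
                v1 = {s} | set(p1)
                for p2 in dp[ca]:
                    # the two ascending paths may share only CA itself
                    v2 = {d} | set(p2)
                    if v1 & v2 != {ca}:
                        continue
                    total += Fraction(1, 2) ** (len(p1) + len(p2) + 1) * (1 + F(ca))
        memo[x] = total
        return total

    return {i: F(i) for i in ped.ids}


def _topo(ped: Pedigree) -> list[str]:
    from graphlib import TopologicalSorter

    ts = TopologicalSorter({i: [p for p in ped.parents(i) if p is not None] for i in ped.ids})
    return list(ts.static_order())


def random_pedigree(rng: np.random.Generator, n: int, *, n_founders: int = 8,
                    missing_rate: float = 0.1) -> Pedigree:
    """Generation-structured random pedigree of about n individuals."""
    recs = []
    males, females = [], []
    for k in range(n_founders):
        iid = f"P{k:03d}"
        sex = "M" if k % 2 == 0 else "F"
        recs.append((iid, None, None, 0, sex))
        (males if sex == "M" else females).append(iid)
    k = n_founders
    gen = 0
    while k < n:
        gen += 1
        new_m, new_f = [], []
        n_children = int(rng.integers(2, max(3, n // 4)))
        for _ in range(n_children):
            if k >= n:
                break
            iid = f"P{k:03d}"
            s = males[rng.integers(len(males))] if rng.random() > missing_rate else None
            d = females[rng.integers(len(females))] if rng.random() > missing_rate else None
            sex = "M" if rng.random() < 0.5 else "F"
            recs.append((iid, s, d, gen, sex))
            (new_m if sex == "M" else new_f).append(iid)
            k += 1
        males = (males + new_m)[-12:]
        females = (females + new_f)[-12:]
    return Pedigree.from_records(recs)
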