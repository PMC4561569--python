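"""Pedigree validation, additive relationships and inbreeding coefficients.

The pedigree is the sole source of genetic information here: the additive
(numerator) relationship matrix **A** is built by the recursive tabular
method, with founders assumed unrelated and non-inbred, and the inbreeding
coefficient of individual *i* recovered as ``f_i = A_ii - 1``.  A missing
parent is treated as a unique, unrelated phantom founder, so individuals
with one or both parents unknown get ``f = 0``; analyses that need a
well-defined *f* restrict to individuals whose four grandparents are all
known (:func:`four_grandparent_filter`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from graphlib import CycleError, TopologicalSorter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "PedigreeError",
    "ValidationReport",
    "RelatednessResult",
    "validate_pedigree",
    "additive_relationship",
    "four_grandparent_filter",
    "read_pedigree",
    "write_pedigree",
    "write_relatedness",
    "read_relatedness_long",
    "write_inbreeding",
]

#: tokens accepted as "unknown parent" on input
_MISSING_TOKENS = {"", "na", "n/a", "nan", "0", "none", "*"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


def _norm_token(x) -> str | None:
    """Normalize an id cell; return None for any missing-value spelling."""
    if x is None:
        return None
    if isinstance(x, float) and np.isnan(x):
        return None
    s = str(x).strip()
    if s.lower() in _MISSING_TOKENS:
        return None
    return s


@dataclass
class Pedigree:
    """An ordered collection of (id, sire, dam, birth_year, sex) records.

    Ids are opaque case-sensitive tokens.  ``sire``/``dam`` are ``None``
    when unknown; ``birth_year`` is ``None`` when unknown; ``sex`` is one
    of ``"M"``, ``"F"``, ``"unknown"``.
    """

    ids: list[str]
    sire: dict[str, str | None]
    dam: dict[str, str | None]
    birth_year: dict[str, int | None]
    sex: dict[str, str]
    #: optional per-id death year (simulation metadata; not written to CSV)
    death_year: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
    ) -> "Pedigree":
        """Build from an iterable of (id, sire, dam, birth_year, sex) tuples."""
        ids: list[str] = []
        sire: dict[str, str | None] = {}
        dam: dict[str, str | None] = {}
        by: dict[str, int | None] = {}
        sex: dict[str, str] = {}
        for rec in records:
            iid, s, d, y, x = (list(rec) + [None] * 5)[:5]
            iid = _norm_token(iid)
            if iid is None:
                raise PedigreeError("record with missing individual id")
            ids.append(iid)
            sire[iid] = _norm_token(s)
            dam[iid] = _norm_token(d)
            by[iid] = None if y is None or (isinstance(y, float) and np.isnan(y)) else int(y)
            x = _norm_token(x)
            sex[iid] = x if x in ("M", "F") else "unknown"
        return cls(ids, sire, dam, by, sex)

    def __len__(self) -> int:
        return len(self.ids)

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        return self.sire.get(iid), self.dam.get(iid)

    def grandparents(self, iid: str) -> tuple[str | None, ...]:
        """The four grandparents (paternal GS, GD, maternal GS, GD); None when unknown."""
        out: list[str | None] = []
        for p in self.parents(iid):
            if p is None or p not in self.sire:
                out.extend([None, None])
            else:
                out.extend([self.sire[p], self.dam[p]])
        return tuple(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [self.sire[i] for i in self.ids],
                "dam": [self.dam[i] for i in self.ids],
                "birth_year": [self.birth_year[i] for i in self.ids],
                "sex": [self.sex[i] for i in self.ids],
            }
        )


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_fatal(self) -> None:
        if self.errors:
            raise PedigreeError("; ".join(self.errors))


@dataclass
class RelatednessResult:
    """Additive relationship matrix and per-individual inbreeding coefficients."""

    ids: list[str]
    A: np.ndarray
    f: np.ndarray
    #: convention note carried into output metadata
    unknown_parent_convention: str = "phantom founder (unrelated, non-inbred)"

    def f_of(self, iid: str) -> float:
        return float(self.f[self.ids.index(iid)])

    def submatrix(self, subset: Sequence[str]) -> "RelatednessResult":
        idx = [self.ids.index(i) for i in subset]
        return RelatednessResult(
            list(subset), np.asarray(self.A[np.ix_(idx, idx)], dtype=float),
            np.asarray(self.f[idx], dtype=float),
            self.unknown_parent_convention,
        )

    def f_table(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "f": np.asarray(self.f, dtype=float)})


def validate_pedigree(ped: Pedigree) -> ValidationReport:
    """Check structural invariants; a clean report is required downstream.

    Fatal: duplicated ids, self-parentage, ancestry cycles, parents named
    but absent from the id list, and parent birth years that do not
    strictly precede the offspring's.  Missing birth years are warnings.
    """
    rep = ValidationReport()
    seen: set[str] = set()
    for i in ped.ids:
        if i in seen:
            rep.errors.append(f"duplicated id {i!r}")
        seen.add(i)
    idset = set(ped.ids)
    for i in ped.ids:
        for role, p in zip(("sire", "dam"), ped.parents(i)):
            if p is None:
                continue
            if p == i:
                rep.errors.append(f"{i!r} is its own {role}")
            elif p not in idset:
                rep.errors.append(f"{role} {p!r} of {i!r} absent from pedigree")
            else:
                py, iy = ped.birth_year.get(p), ped.birth_year.get(i)
                if py is not None and iy is not None and py >= iy:
                    rep.errors.append(
                        f"{role} {p!r} (born {py}) not older than offspring {i!r} (born {iy})"
                    )
        if ped.birth_year.get(i) is None:
            rep.warnings.append(f"missing birth year for {i!r}")
    # cycle detection on the parent graph (only if links resolve)
    if not rep.errors:
        ts = TopologicalSorter(
            {i: [p for p in ped.parents(i) if p is not None] for i in ped.ids}
        )
        try:
            ts.prepare()
        except CycleError as e:
            rep.errors.append(f"ancestry cycle: {e.args[1]}")
    return rep


def _topo_order(ped: Pedigree) -> list[str]:
    ts = TopologicalSorter(
        {i: [p for p in ped.parents(i) if p is not None] for i in ped.ids}
    )
    try:
        return list(ts.static_order())
    except CycleError as e:  # pragma: no cover - validate() catches earlier
        raise PedigreeError(f"ancestry cycle: {e.args[1]}") from e


def additive_relationship(ped: Pedigree, *, exact: bool = False) -> RelatednessResult:
    """Compute **A** and inbreeding coefficients by the tabular method.

    Individuals are processed parents-before-offspring; for individual *j*
    with parents *s*, *d*::

        A[j, i] = (A[s, i] + A[d, i]) / 2      (i already processed)
        A[j, j] = 1 + A[s, d] / 2

    with a missing parent contributing zero relationship.  Founders are
    unrelated and non-inbred, so ``f = 0`` for them by construction.

    Parameters
    ----------
    exact : bool
        Compute with exact rational arithmetic (``fractions.Fraction``);
        intended for small pedigrees and cross-validation.
    """
    validate_pedigree(ped).raise_if_fatal()
    order = _topo_order(ped)
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    if exact:
        A = np.empty((n, n), dtype=object)
        A[:] = Fraction(0)
        half = Fraction(1, 2)
        one = Fraction(1)
    else:
        A = np.zeros((n, n))
        half, one = 0.5, 1.0
    for j, iid in enumerate(order):
        s, d = ped.parents(iid)
        si = pos[s] if s is not None else None
        di = pos[d] if d is not None else None
        row = A[si, :j] if si is not None else 0
        row = row + (A[di, :j] if di is not None else 0)
        if si is not None or di is not None:
            A[j, :j] = half * row
            A[:j, j] = A[j, :j]
        A[j, j] = one + (half * A[si, di] if si is not None and di is not None else 0)
    # report in the pedigree's own id order
    perm = [pos[i] for i in ped.ids]
    A = A[np.ix_(perm, perm)]
    f = np.array([A[k, k] - one for k in range(n)])
    return RelatednessResult(list(ped.ids), A, f)


def four_grandparent_filter(ped: Pedigree, ids: Iterable[str] | None = None) -> set[str]:
    """Subset of ids whose sire, dam and all four grandparents are known.

    Inbreeding coefficients are only comparable among individuals with
    equally complete ancestry; restricting to fully known grandparentage
    is the standard guard against depth-driven downward bias in *f*.
    """
    pool = list(ids) if ids is not None else list(ped.ids)
    out: set[str] = set()
    for i in pool:
        s, d = ped.parents(i)
        if s is None or d is None:
            continue
        if all(g is not None for g in ped.grandparents(i)):
            out.add(i)
    return out


# ---------------------------------------------------------------------------
# file formats: CSV with header id,sire,dam,birth_year,sex; missing as ""/NA/0


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam", "birth_year", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree file {path} lacks columns: {sorted(missing)}")
    recs = []
    for row in df.itertuples(index=False):
        y = str(row.birth_year).strip()
        year = None if y.lower() in ("", "na", "nan", "none") else int(float(y))
        recs.append((row.id, row.sire, row.dam, year, row.sex))
    return Pedigree.from_records(recs)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    df = ped.to_frame()
    df = df.where(pd.notna(df), "NA")
    df = df.fillna("NA").replace({None: "NA"})
    df.to_csv(path, index=False, na_rep="NA")


def write_relatedness(res: RelatednessResult, path: str | Path, *, fmt: str = "auto") -> None:
    """Write A as a dense matrix CSV (small n) or long-format triplets."""
    path = Path(path)
    n = len(res.ids)
    if fmt == "auto":
        fmt = "dense" if n <= 200 else "long"
    if fmt == "dense":
        pd.DataFrame(np.asarray(res.A, dtype=float), index=res.ids, columns=res.ids).to_csv(
            path, index_label="id"
        )
    elif fmt == "long":
        iu = np.triu_indices(n)
        A = np.asarray(res.A, dtype=float)
        pd.DataFrame(
            {
                "id_i": [res.ids[i] for i in iu[0]],
                "id_j": [res.ids[j] for j in iu[1]],
                "a_ij": A[iu],
            }
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown relatedness format {fmt!r}")


def read_relatedness_long(path: str | Path) -> RelatednessResult:
    """Read long-format triplets back into a dense RelatednessResult."""
    df = pd.read_csv(path, dtype={"id_i": str, "id_j": str})
    ids = list(pd.unique(pd.concat([df["id_i"], df["id_j"]])))
    pos = {iid: k for k, iid in enumerate(ids)}
    A = np.zeros((len(ids), len(ids)))
    for r in df.itertuples(index=False):
        i, j = pos[r.id_i], pos[r.id_j]
        A[i, j] = A[j, i] = r.a_ij
    return RelatednessResult(ids, A, np.diag(A) - 1.0)


def write_inbreeding(res: RelatednessResult, path: str | Path) -> None:
    res.f_table().to_csv(path, index=False)
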