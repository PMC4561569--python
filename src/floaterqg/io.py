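"""Phenotype-table and configuration file plumbing.

The male-season phenotype table is a flat CSV with header
``male_id,year,age,status,tarsus,f,ars,epars`` (UTF-8, comma separated,
``NA`` for missing).  Reading applies row-level validation — unknown
status tokens, negative counts, extra-pair counts exceeding totals,
non-incrementing ages — and reports every bad row with its line number
rather than stopping at the first.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MaleSeasonRecord",
    "PhenotypeFormatError",
    "read_phenotypes",
    "write_phenotypes",
    "records_to_frame",
    "frame_to_records",
    "read_config",
    "write_config",
    "run_manifest",
]

_STATUS = ("floater", "territorial")
PHENOTYPE_COLUMNS = ["male_id", "year", "age", "status", "tarsus", "f", "ars", "epars"]


class PhenotypeFormatError(ValueError):
    """Raised with an aggregated, line-numbered report of bad rows."""


@dataclass(frozen=True)
class MaleSeasonRecord:
    """One male's season: mating status, size, inbreeding and success."""

    male_id: str
    year: int
    age: int
    status: str
    tarsus: float
    f: float | None
    ars: int
    epars: int

    def check(self) -> list[str]:
        errs = []
        if self.status not in _STATUS:
            errs.append(f"unknown status {self.status!r}")
        if self.age < 1:
            errs.append(f"age {self.age} < 1")
        if self.ars < 0:
            errs.append(f"negative ARS {self.ars}")
        if self.epars < 0:
            errs.append(f"negative EPARS {self.epars}")
        if self.epars > self.ars:
            errs.append(f"EPARS {self.epars} > ARS {self.ars}")
        if self.f is not None and not np.isnan(self.f) and not -0.01 <= self.f <= 0.75:
            errs.append(f"implausible inbreeding coefficient {self.f}")
        return errs


def frame_to_records(df: pd.DataFrame) -> list[MaleSeasonRecord]:
    recs = []
    for row in df.itertuples(index=False):
        f = getattr(row, "f", None)
        recs.append(
            MaleSeasonRecord(
                male_id=str(row.male_id),
                year=int(row.year),
                age=int(row.age),
                status=str(row.status),
                tarsus=float(row.tarsus),
                f=None if f is None or (isinstance(f, float) and np.isnan(f)) else float(f),
                ars=int(row.ars),
                epars=int(row.epars),
            )
        )
    return recs


def records_to_frame(records: list[MaleSeasonRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df["f"] = df["f"].astype(float)
    return df[PHENOTYPE_COLUMNS]


def _validate_frame(df: pd.DataFrame) -> None:
    errors: list[str] = []
    seen: set[tuple] = set()
    recs = frame_to_records(df)
    for lineno, rec in enumerate(recs, start=2):  # header is line 1
        for e in rec.check():
            errors.append(f"line {lineno}: {e}")
        key = (rec.male_id, rec.year)
        if key in seen:
            errors.append(f"line {lineno}: duplicate (male_id, year) {key}")
        seen.add(key)
    # ages must advance by exactly one season per year within a male
    for mid, sub in pd.DataFrame(
        {"male_id": [r.male_id for r in recs], "year": [r.year for r in recs],
         "age": [r.age for r in recs]}
    ).groupby("male_id"):
        sub = sub.sort_values("year")
        dy, da = np.diff(sub["year"]), np.diff(sub["age"])
        if np.any((dy == 1) & (da != 1)):
            errors.append(f"male {mid}: age does not increment by 1 across consecutive years")
    if errors:
        raise PhenotypeFormatError("; ".join(errors[:50]))


def read_phenotypes(path: str | Path, *, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise PhenotypeFormatError(f"{path} lacks columns: {sorted(missing)}")
    df = df[PHENOTYPE_COLUMNS].copy()
    df["male_id"] = df["male_id"].astype(str)
    if validate:
        _validate_frame(df)
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df[PHENOTYPE_COLUMNS].to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# flat key=value config files


def _parse_scalar(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def read_config(path: str | Path) -> dict:
    """Flat ``key = value`` file; '#' starts a comment."""
    out: dict = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {raw!r}")
        k, v = (t.strip() for t in line.split("=", 1))
        out[k] = _parse_scalar(v)
    return out


def write_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{k} = {v}\n" for k, v in cfg.items()), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# run manifests


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_manifest(
    out_dir: str | Path,
    *,
    analysis: str,
    seed: int | None,
    config: dict,
    inputs: dict[str, str | Path] | None = None,
    timestamp: str | None = None,
) -> Path:
    """Write a JSON manifest describing one CLI run (inputs' checksums,
    configuration, seed, package version); returns its path."""
    from . import __version__

    inputs = inputs or {}
    manifest = {
        "analysis": analysis,
        "seed": seed,
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": _checksum(Path(p))}
            for name, p in inputs.items()
            if Path(p).exists()
        },
        "version": __version__,
        "timestamp": timestamp,
    }
    out = Path(out_dir) / f"manifest_{analysis}.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return out
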