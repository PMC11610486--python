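"""Nanomaterial data model and I/O for the shared feature table.

The canonical schema follows the descriptor symbols of the source dataset:
``ID, CF, Dsph, Shape, CT, DLS, MW, A11, A132, Nmetal, Noxygen, Metals_SumIP,
ZP, Split``.  A user-supplied ``column_map`` adapts other headers.  The table
is held as a :class:`NMDataset`, a thin validated wrapper around a pandas
DataFrame so that every downstream stage can use ordinary DataFrame idioms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import DomainError, IntegrityError, ParseError, SchemaError
from .features import SHAPES, UNCOATED

ID = "ID"
NUMERIC_COLUMNS = ("Dsph", "DLS", "MW", "A11", "A132", "Nmetal", "Noxygen",
                   "Metals_SumIP", "ZP")
REQUIRED_COLUMNS = (ID, "CF", "Dsph", "Shape", "CT", "DLS", "MW", "A11",
                    "A132", "Nmetal", "Noxygen", "Metals_SumIP", "ZP")
OPTIONAL_COLUMNS = ("Split",)

_POSITIVE = ("Dsph", "DLS", "MW")


@dataclass
class NMDataset:
    """An ordered table of nanomaterial records with optional train/test flags."""

    df: pd.DataFrame
    provenance: str = ""
    composition: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        ids = self.df[ID]
        dup = ids[ids.duplicated()].tolist()
        if dup:
            raise IntegrityError(f"duplicate record id(s): {dup}")
        bad_shape = sorted(set(self.df["Shape"]) - set(SHAPES))
        if bad_shape:
            raise SchemaError(f"unknown shape group(s): {bad_shape}; expected {SHAPES}")
        for col in _POSITIVE:
            bad = self.df.loc[self.df[col] <= 0, ID].tolist()
            if bad:
                raise DomainError(f"non-positive {col} for record(s): {bad}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return self.df[ID].tolist()

    def subset(self, mask: np.ndarray | pd.Series, provenance: str | None = None) -> "NMDataset":
        return NMDataset(
            self.df[np.asarray(mask)].reset_index(drop=True),
            provenance=provenance if provenance is not None else self.provenance,
            composition=self.composition,
        )


def _normalize_coating(v: object) -> str:
    s = "" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v).strip()
    return UNCOATED if not s or s.lower() == UNCOATED else s


def read_nm_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> NMDataset:
    """Read the shared feature table from CSV/TSV into an :class:`NMDataset`.

    ``column_map`` maps file headers to canonical names; delimiter is derived
    from the extension (``.tsv`` -> tab) unless overridden.  Coating strings
    equal to "uncoated" (any case) or empty collapse to the UNCOATED sentinel;
    split flags, when present, are read verbatim (lower-cased).
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                      na_values=[""])
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {missing}")
    df = raw.copy()
    for col in NUMERIC_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[parsed.isna() & df[col].notna(), ID].tolist()
        if bad:
            raise ParseError(f"non-numeric value in column {col!r} for record(s): {bad}")
        if parsed.isna().any():
            empty = df.loc[parsed.isna(), ID].tolist()
            raise ParseError(f"missing value in column {col!r} for record(s): {empty}")
        df[col] = parsed
    df["CT"] = [_normalize_coating(v) for v in df["CT"]]
    if "Split" in df.columns:
        df["Split"] = df["Split"].astype(str).str.strip().str.lower()
        bad = sorted(set(df["Split"]) - {"train", "test", "", "nan"})
        if bad:
            raise SchemaError(f"unknown split flag(s): {bad}; expected train/test")
    return NMDataset(df, provenance=f"read from {path.name}")


def write_nm_table(ds: NMDataset, path: str | Path, delimiter: str | None = None) -> None:
    """Write the table back out; a read of the result is field-identical."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    ds.df.to_csv(path, sep=delimiter, index=False)


def apply_split(
    ds: NMDataset,
    mode: str = "flags",
    ratio: float = 0.75,
    seed: int | None = None,
) -> tuple[NMDataset, NMDataset]:
    """Partition into (train, test).

    ``flags`` mode reproduces the stored Split column exactly; ``random`` mode
    draws a seeded permutation (numpy PCG64) and takes the first
    ``round(ratio * n)`` records as training.  Union equals the input and the
    id sets are disjoint in both modes.
    """
    if mode == "flags":
        if "Split" not in ds.df.columns:
            raise IntegrityError("flags mode requires a Split column")
        flags = ds.df["Split"]
        unflagged = ds.df.loc[~flags.isin(["train", "test"]), ID].tolist()
        if unflagged:
            raise IntegrityError(f"record(s) without a train/test flag: {unflagged}")
        train = ds.subset(flags == "train", provenance=ds.provenance + " | split=flags")
        test = ds.subset(flags == "test", provenance=ds.provenance + " | split=flags")
        return train, test
    if mode == "random":
        if not 0 < ratio < 1:
            raise DomainError(f"ratio must be in (0, 1), got {ratio}")
        rng = np.random.default_rng(seed)
        n = len(ds)
        perm = rng.permutation(n)
        n_train = int(round(ratio * n))
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n_train]] = True
        prov = ds.provenance + f" | split=random(PCG64, seed={seed}, ratio={ratio})"
        df = ds.df.copy()
        df["Split"] = np.where(mask, "train", "test")
        tagged = NMDataset(df, provenance=ds.provenance, composition=ds.composition)
        return tagged.subset(mask, prov), tagged.subset(~mask, prov)
    raise DomainError(f"unknown split mode {mode!r}; expected 'flags' or 'random'")


def load_reference_dataset(path: str | Path | None = None) -> NMDataset:
    """Load the published 71-nanomaterial reference table.

    The measured table (71 records, 53 train / 18 test) is distributed as the
    source publication's supplementary dataset and is not redistributed here;
    place it, converted to the canonical CSV schema, at
    ``data/reference_dataset.csv`` under the repository root (or pass a path).
    """
    p = Path(path) if path is not None else Path("data/reference_dataset.csv")
    if not p.exists():
        raise FileNotFoundError(
            f"reference dataset not found at {p}; obtain the published "
            "supplementary table, convert it to the canonical schema "
            "(ID, CF, Dsph, Shape, CT, DLS, MW, A11, A132, Nmetal, Noxygen, "
            "Metals_SumIP, ZP, Split) and place it there"
        )
    ds = read_nm_table(p)
    if len(ds) != 71:
        raise IntegrityError(f"reference table must have 71 records, found {len(ds)}")
    train, test = apply_split(ds, mode="flags")
    if (len(train), len(test)) != (53, 18):
        raise IntegrityError(
            f"reference split must be 53 train / 18 test, found {len(train)}/{len(test)}"
        )
    return ds
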