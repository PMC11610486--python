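"""Descriptor computation and encoding for nanomaterial feature tables.

Covers formula parsing, composition-derived descriptors (MW, atom counts, sum
of metal ionization potentials), the equivalent-sphere diameter, categorical
encodings (binary core class, coating groups, one-hot shape), z-score scaling
with train-fitted parameters, the log hydrodynamic diameter, and a Pearson
correlation filter for near-collinear descriptor pairs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .elements import ELEMENT_PROPERTIES, KNOWN_SYMBOLS, get_property
from .exceptions import ConfigurationError, DomainError, ParseError

UNCOATED = "uncoated"

#: canonical coating groups; anything else maps to "other"
COATING_GROUPS = ("sodium citrate", "L-arginine", "PVP", UNCOATED, "other")

SHAPES = ("spherical", "square_plate", "rod")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)_?(\d+(?:\.\d+)?)?")


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def parse_formula(cf: str) -> dict[str, float]:
    """Parse a core chemical formula into an element -> count map.

    Counts default to 1; fractional subscripts written with an underscore
    (doped cores such as ``"Ce_0.75Zr_0.25O2"``) are accepted.  Repeated
    element symbols accumulate.
    """
    if not cf or not cf.strip():
        raise ParseError("empty chemical formula")
    s = cf.strip()
    comp: dict[str, float] = {}
    pos = 0
    while pos < len(s):
        m = _FORMULA_TOKEN.match(s, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ParseError(f"cannot parse formula {cf!r} at position {pos}")
        sym, count = m.group(1), m.group(2)
        if sym not in KNOWN_SYMBOLS:
            raise ParseError(f"unknown element symbol {sym!r} in formula {cf!r}")
        n = float(count) if count else 1.0
        if n <= 0:
            raise ParseError(f"non-positive count for {sym} in formula {cf!r}")
        comp[sym] = comp.get(sym, 0.0) + n
        pos = m.end()
    return comp


def _default_valence_electron_potential(comp: Mapping[str, float]) -> float:
    # documented plug-in default: valence electrons per unit atomic number,
    # summed over metal atoms.  Swap via composition_descriptors(vep=...).
    return sum(
        n * get_property(el, "valence_electrons") / get_property(el, "atomic_number")
        for el, n in comp.items()
        if el != "O"
    )


def composition_descriptors(
    comp: Mapping[str, float],
    table: Mapping[str, Mapping[str, float]] | None = None,
    vep: Callable[[Mapping[str, float]], float] | None = None,
) -> dict[str, float]:
    """Descriptors derived from the core composition.

    Returns ``mw`` (g/mol), ``n_metal``, ``n_oxygen``, ``tot_num_atoms``,
    ``metals_sum_ip`` (kJ/mol, first ionization energy summed over metal
    atoms), per-element ``amount_<El>`` entries, and the pluggable
    ``valence_electron_potential``.  All quantities are linear in the counts.
    """
    if not comp:
        raise ParseError("empty composition")
    tab = ELEMENT_PROPERTIES if table is None else table
    for el in comp:
        if el not in tab:
            raise ParseError(f"element {el!r} missing from the property table")
    mw = sum(n * tab[el]["atomic_weight"] for el, n in comp.items())
    n_oxygen = comp.get("O", 0.0)
    n_metal = sum(n for el, n in comp.items() if el != "O")
    metals_sum_ip = sum(
        n * tab[el]["ionization_kj_mol"] for el, n in comp.items() if el != "O"
    )
    out = {
        "mw": mw,
        "n_metal": n_metal,
        "n_oxygen": n_oxygen,
        "tot_num_atoms": float(sum(comp.values())),
        "metals_sum_ip": metals_sum_ip,
        "valence_electron_potential": (vep or _default_valence_electron_potential)(comp),
    }
    for el, n in comp.items():
        out[f"amount_{el}"] = float(n)
    return out


def amount_of(comp: Mapping[str, float], element: str) -> float:
    """Count of ``element`` in the composition (0 if absent)."""
    return float(comp.get(element, 0.0))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def equivalent_sphere_diameter(shape: str, **dims: float) -> float:
    """Diameter of the sphere whose surface area equals the particle's.

    Shapes: ``spherical`` (d), ``rod`` modelled as a closed cylinder
    (diameter d, length length), ``square_plate`` (side a, thickness t).
    Solves pi * D**2 = area.
    """
    for name, v in dims.items():
        if v <= 0:
            raise DomainError(f"dimension {name} must be positive, got {v}")
    if shape == "spherical":
        return dims["d"]
    if shape == "rod":
        d, length = dims["d"], dims["length"]
        area = math.pi * d * length + math.pi * d * d / 2.0
    elif shape == "square_plate":
        a, t = dims["a"], dims["t"]
        area = 2.0 * a * a + 4.0 * a * t
    else:
        raise DomainError(f"unknown shape {shape!r}; expected one of {SHAPES}")
    return math.sqrt(area / math.pi)


# ---------------------------------------------------------------------------
# categorical encodings
# ---------------------------------------------------------------------------

def core_is_metal(cf: str) -> int:
    """1 for a pure metal core (no oxygen), 0 for an oxide."""
    return int(parse_formula(cf).get("O", 0.0) == 0.0)


def group_coating(coating: str) -> str:
    """Collapse the raw coating label to the five canonical groups."""
    c = (coating or "").strip()
    if not c or c.lower() == UNCOATED:
        return UNCOATED
    norm = c.lower().replace("ʟ", "l").replace("-", " ").replace("_", " ")
    if "citrate" in norm and "sodium" in norm:
        return "sodium citrate"
    if norm in {"l arginine", "arginine"}:
        return "L-arginine"
    if norm == "pvp" or "polyvinylpyrrolidone" in norm:
        return "PVP"
    return "other"


@dataclass
class EncodingSpec:
    """Per-column encoding recipe, serializable alongside model artifacts.

    ``encoders`` maps a source column to one of:
      - ``("binary_core",)`` 0 = oxide, 1 = metal, from the formula column
      - ``("binary_coated",)`` 0 = coated, 1 = uncoated
      - ``("onehot", categories)`` explicit category list, no implicit bucket
      - ``("coating_group",)`` 5-group coating one-hot with an "other" bucket
    """

    encoders: dict[str, tuple] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {col: list(enc) for col, enc in self.encoders.items()}


def encode_categoricals(df: pd.DataFrame, spec: EncodingSpec) -> pd.DataFrame:
    """Apply the encoding recipe, returning a new frame with encoded columns.

    One-hot groups always contain exactly one 1 per row; a category outside an
    explicit one-hot list (with no "other" bucket) raises
    :class:`ConfigurationError` so that a fitted vocabulary can never silently
    absorb unseen test categories.
    """
    out = df.copy()
    for col, enc in spec.encoders.items():
        if col not in out.columns:
            raise ConfigurationError(f"encoding refers to missing column {col!r}")
        kind = enc[0]
        if kind == "binary_core":
            out[col] = [core_is_metal(v) for v in out[col]]
        elif kind == "binary_coated":
            out[col] = [
                1 if group_coating(v) == UNCOATED else 0 for v in out[col]
            ]
        elif kind == "coating_group":
            groups = [group_coating(v) for v in out[col]]
            for g in COATING_GROUPS:
                out[f"{col}={g}"] = [int(x == g) for x in groups]
            out = out.drop(columns=[col])
        elif kind == "onehot":
            cats = list(enc[1])
            for v in out[col]:
                if v not in cats:
                    raise ConfigurationError(
                        f"category {v!r} of column {col!r} absent from the "
                        f"fitted vocabulary {cats} and no 'other' bucket exists"
                    )
            for c in cats:
                out[f"{col}={c}"] = [int(v == c) for v in out[col]]
            out = out.drop(columns=[col])
        else:
            raise ConfigurationError(f"unknown encoder {kind!r} for column {col!r}")
    return out


# ---------------------------------------------------------------------------
# scaling and transforms
# ---------------------------------------------------------------------------

@dataclass
class ScalerParams:
    """Column means and population standard deviations fitted on training rows."""

    mean: pd.Series
    std: pd.Series

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        cols = list(self.mean.index)
        out[cols] = (out[cols] - self.mean) / self.std
        return out

    def invert(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        cols = list(self.mean.index)
        out[cols] = out[cols] * self.std + self.mean
        return out


def zscore_fit(train: pd.DataFrame, columns: Sequence[str]) -> ScalerParams:
    """Fit per-column mean/sd (population, divide-by-n) on training rows only."""
    cols = list(columns)
    mean = train[cols].mean()
    std = train[cols].std(ddof=0)
    zero = [c for c in cols if std[c] == 0 or not np.isfinite(std[c])]
    if zero:
        raise DomainError(f"zero-variance column(s) cannot be z-scored: {zero}")
    return ScalerParams(mean=mean, std=std)


def zscore_fit_apply(
    train: pd.DataFrame, test: pd.DataFrame | None, columns: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame | None, ScalerParams]:
    """Z-score selected columns; test reuses the train-fitted parameters."""
    params = zscore_fit(train, columns)
    train_t = params.apply(train)
    test_t = params.apply(test) if test is not None else None
    return train_t, test_t, params


def log_transform_dls(dls_nm: float) -> float:
    """Base-10 log of the hydrodynamic diameter (QSAR convention)."""
    if np.any(np.asarray(dls_nm) <= 0):
        raise DomainError(f"DLS diameter must be positive, got {dls_nm}")
    return np.log10(dls_nm)


def correlation_filter(
    df: pd.DataFrame,
    threshold: float = 0.95,
    prefer_keep: Sequence[str] = ("A132",),
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Drop one column of every |Pearson r| >= threshold pair.

    By default the later column (in frame order) of an offending pair is
    dropped, except that columns in ``prefer_keep`` survive their partner —
    the convention here keeps the in-water Hamaker constant A132 and discards
    the in-vacuum A11 when the two are near-collinear.  Returns the filtered
    frame and ``(dropped, kept, r)`` triples.
    """
    if not 0 < threshold <= 1:
        raise DomainError(f"threshold must be in (0, 1], got {threshold}")
    if len(df) < 2:
        raise DomainError("correlation filter needs at least 2 rows")
    stds = df.std(ddof=0)
    constant = [c for c in df.columns if stds[c] == 0]
    if constant:
        raise DomainError(f"correlation undefined for constant column(s): {constant}")
    corr = df.corr(method="pearson")
    dropped: list[tuple[str, str, float]] = []
    gone: set[str] = set()
    cols = list(df.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if a in gone or b in gone:
                continue
            r = corr.loc[a, b]
            if abs(r) >= threshold:
                drop, keep = (b, a)
                if b in prefer_keep and a not in prefer_keep:
                    drop, keep = a, b
                gone.add(drop)
                dropped.append((drop, keep, float(r)))
    return df.drop(columns=sorted(gone, key=cols.index)), dropped
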