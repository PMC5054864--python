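"""Nested sampling design: isolate identifiers, spatial-scale categories and
representative metric distances.

Isolates are sampled in a five-level nested hierarchy: clones within a
fruiting body (micrometre scale), fruiting bodies within a soil core
(millimetre), cores within a transect (centimetre), transects within a site
(metre), and km-separated sites.  An isolate identifier such as ``KF3.2.8A``
encodes site KF, transect 3, core 2, fruiting body 8, clone A.

The distance between two isolates is summarised categorically by the deepest
hierarchy level at which their addresses differ, and each category maps to a
single representative metric distance.  For the two smallest scales that
distance is one-third of the diameter of the containing unit (fruiting body
or soil core); the larger scales use field-measured constants.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Scale",
    "SCALES",
    "HierarchicalAddress",
    "ScaleGeometry",
    "IsolateIdError",
    "parse_isolate_id",
    "pair_scale",
    "scale_distance",
    "round_sig",
    "sample_sheet_from_ids",
    "read_sample_sheet",
    "write_sample_sheet",
]


class Scale(enum.Enum):
    """Spatial-scale category, ordered by increasing representative distance."""

    MICROMETRE = 0
    MILLIMETRE = 1
    CENTIMETRE = 2
    METRE = 3
    KILOMETRE = 4

    @property
    def rank(self) -> int:
        return self.value

    @property
    def label(self) -> str:
        return self.name.lower()

    def __lt__(self, other: "Scale") -> bool:
        if not isinstance(other, Scale):
            return NotImplemented
        return self.value < other.value

    @classmethod
    def from_label(cls, label: str) -> "Scale":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown scale category: {label!r}") from None


#: The five categories in rank order.
SCALES: tuple[Scale, ...] = tuple(Scale)


class IsolateIdError(ValueError):
    """Raised when an isolate identifier cannot be parsed."""


_ID_RE = re.compile(
    r"^(?P<site>[A-Z]+)"
    r"(?P<transect>[1-9]\d*)"
    r"\.(?P<core>[1-9]\d*)"
    r"\.(?P<fruiting_body>[1-9]\d*)"
    r"(?P<clone>[A-Z])$"
)


@dataclass(frozen=True, order=True)
class HierarchicalAddress:
    """Nested spatial coordinates of one isolate.

    ``KF3.2.8A`` -> site ``KF``, transect 3, core 2, fruiting body 8,
    clone ``A``.  Formatting round-trips losslessly through
    :func:`parse_isolate_id`.
    """

    site: str
    transect: int
    core: int
    fruiting_body: int
    clone: str

    def __post_init__(self) -> None:
        if not self.site or not self.site.isalpha() or not self.site.isupper():
            raise IsolateIdError(f"site label must be uppercase letters, got {self.site!r}")
        for name in ("transect", "core", "fruiting_body"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise IsolateIdError(f"{name} must be a positive integer, got {v!r}")
        if not (len(self.clone) == 1 and "A" <= self.clone <= "Z"):
            raise IsolateIdError(f"clone must be a single letter A-Z, got {self.clone!r}")

    def __str__(self) -> str:
        return f"{self.site}{self.transect}.{self.core}.{self.fruiting_body}{self.clone}"

    # Unit labels at each enclosing level, used for grouping.
    @property
    def site_label(self) -> str:
        return self.site

    @property
    def transect_label(self) -> str:
        return f"{self.site}{self.transect}"

    @property
    def core_label(self) -> str:
        return f"{self.site}{self.transect}.{self.core}"

    @property
    def fruiting_body_label(self) -> str:
        return f"{self.site}{self.transect}.{self.core}.{self.fruiting_body}"


def parse_isolate_id(name: str) -> HierarchicalAddress:
    """Parse an isolate identifier like ``KF3.2.8A``.

    Raises :class:`IsolateIdError` naming the offending token for malformed
    input.
    """
    if not isinstance(name, str):
        raise IsolateIdError(f"isolate id must be a string, got {type(name).__name__}")
    m = _ID_RE.match(name.strip())
    if m is None:
        _diagnose_bad_id(name.strip())
        raise IsolateIdError(f"malformed isolate id: {name!r}")
    return HierarchicalAddress(
        site=m.group("site"),
        transect=int(m.group("transect")),
        core=int(m.group("core")),
        fruiting_body=int(m.group("fruiting_body")),
        clone=m.group("clone"),
    )


def _diagnose_bad_id(name: str) -> None:
    """Raise a targeted error for the first malformed token of ``name``."""
    if not name:
        raise IsolateIdError("empty isolate id")
    if not name[0].isalpha():
        raise IsolateIdError(f"isolate id {name!r}: missing site label prefix")
    body = name.lstrip("A-Z") if False else re.sub(r"^[A-Za-z]+", "", name)
    site = name[: len(name) - len(body)]
    if not site.isupper():
        raise IsolateIdError(f"isolate id {name!r}: site label {site!r} must be uppercase")
    parts = body.split(".")
    if len(parts) != 3:
        raise IsolateIdError(
            f"isolate id {name!r}: expected transect.core.fruiting-body, got {body!r}"
        )
    if not parts[2] or parts[2][-1].isdigit():
        raise IsolateIdError(f"isolate id {name!r}: missing clone letter")


def pair_scale(a: HierarchicalAddress, b: HierarchicalAddress) -> Scale:
    """Spatial-scale category of an isolate pair: the deepest differing level.

    Same fruiting body -> micrometre; same core, different fruiting body ->
    millimetre; same transect, different core -> centimetre; same site,
    different transect -> metre; different site -> kilometre.  Symmetric in
    its arguments; a self-pair is an error.
    """
    if a == b:
        raise ValueError(f"self-pair: {a} compared with itself")
    if a.site != b.site:
        return Scale.KILOMETRE
    if a.transect != b.transect:
        return Scale.METRE
    if a.core != b.core:
        return Scale.CENTIMETRE
    if a.fruiting_body != b.fruiting_body:
        return Scale.MILLIMETRE
    return Scale.MICROMETRE


@dataclass(frozen=True)
class ScaleGeometry:
    """Metric geometry of the nested design, all lengths in metres.

    The micrometre- and millimetre-scale representative distances derive from
    the one-third-of-diameter convention: isolates within a unit are assumed
    maximally separated by a third of the unit's diameter (fruiting bodies
    ~100 um across, soil cores ~0.9 cm).  The centimetre, metre and kilometre
    distances are field-averaged constants and are taken as configuration.
    """

    fruiting_body_diameter: float = 100e-6
    core_diameter: float = 0.009
    centimetre_distance: float = 0.036
    metre_distance: float = 18.0
    kilometre_distance: float = 11000.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"{f.name} must be strictly positive, got {v!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ScaleGeometry":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown geometry keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


def scale_distance(category: Scale, geometry: ScaleGeometry | None = None) -> float:
    """Representative inter-isolate distance for a scale category, in metres.

    micrometre -> fruiting_body_diameter / 3, millimetre -> core_diameter / 3;
    the remaining categories use the configured constants.  Strictly
    increasing in scale rank under any valid geometry of the default shape.
    """
    geometry = geometry or ScaleGeometry()
    if category is Scale.MICROMETRE:
        return geometry.fruiting_body_diameter / 3.0
    if category is Scale.MILLIMETRE:
        return geometry.core_diameter / 3.0
    if category is Scale.CENTIMETRE:
        return geometry.centimetre_distance
    if category is Scale.METRE:
        return geometry.metre_distance
    return geometry.kilometre_distance


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention: 0.000033)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


# ---------------------------------------------------------------------------
# Sample sheet I/O

_SHEET_COLUMNS = ["isolate_id", "site", "transect", "core", "fruiting_body", "clone"]


def sample_sheet_from_ids(ids: Iterable[str]) -> pd.DataFrame:
    """Build a sample sheet (one row per isolate) from bare isolate IDs."""
    rows = []
    seen: set[str] = set()
    for name in ids:
        if name in seen:
            raise IsolateIdError(f"duplicate isolate id: {name!r}")
        seen.add(name)
        a = parse_isolate_id(name)
        rows.append(
            {
                "isolate_id": name,
                "site": a.site,
                "transect": a.transect,
                "core": a.core,
                "fruiting_body": a.fruiting_body,
                "clone": a.clone,
            }
        )
    if not rows:
        raise ValueError("no isolate ids supplied")
    return pd.DataFrame(rows, columns=_SHEET_COLUMNS)


def addresses_from_sheet(sheet: pd.DataFrame) -> dict[str, HierarchicalAddress]:
    """Map isolate_id -> :class:`HierarchicalAddress` from a sample sheet."""
    out: dict[str, HierarchicalAddress] = {}
    for row in sheet.itertuples(index=False):
        out[row.isolate_id] = HierarchicalAddress(
            site=str(row.site),
            transect=int(row.transect),
            core=int(row.core),
            fruiting_body=int(row.fruiting_body),
            clone=str(row.clone),
        )
    return out


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {sorted(missing)}")
    return sheet[_SHEET_COLUMNS]
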