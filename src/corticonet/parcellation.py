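"""Cortical parcellation and functional-subsystem configuration.

The analysis operates on 64 gyral-based cortical regions (32 per
hemisphere, Desikan–Killiany scheme), each assigned to one of five
intrinsic structural subsystems: strategic/executive control, language,
mnemonic/emotional processing, sensorimotor and visual function.  The
region order defined here fixes the row/column order of every matrix
downstream, so all modules share a single ``ParcellationMap``.

The default map ships as a TSV data file; users can supply their own map
with the same columns (the five-subsystem partition of the default atlas
is a reconstruction from published region lists and anatomical anchors,
so swapping in an alternative assignment is explicitly supported).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "SUBSYSTEMS",
    "CANONICAL_SUBSYSTEM_SIZES",
    "Region",
    "ParcellationMap",
    "ParcellationError",
    "load_parcellation",
    "default_parcellation",
]

#: Canonical subsystem names, in reporting order.
SUBSYSTEMS = (
    "strategic_executive",
    "language",
    "mnemonic_emotional",
    "sensorimotor",
    "visual",
)

#: Region counts per subsystem for the canonical 64-region map.
CANONICAL_SUBSYSTEM_SIZES = {
    "strategic_executive": 14,
    "language": 14,
    "mnemonic_emotional": 18,
    "sensorimotor": 10,
    "visual": 8,
}

_HEMISPHERES = ("left", "right")
_COLUMNS = ["region_id", "hemisphere", "abbreviation", "full_name", "subsystem"]


class ParcellationError(ValueError):
    """Raised when a parcellation file violates the map invariants."""


@dataclass(frozen=True)
class Region:
    region_id: int
    hemisphere: str
    abbreviation: str
    full_name: str
    subsystem: str

    @property
    def label(self) -> str:
        """Hemisphere-qualified label used as matrix row/column name."""
        return f"{'L' if self.hemisphere == 'left' else 'R'}_{self.abbreviation}"


@dataclass(frozen=True)
class ParcellationMap:
    """Ordered set of regions with their subsystem assignment.

    Region order is positional and stable: index ``i`` in every thickness,
    correlation and adjacency matrix refers to ``regions[i]``.
    """

    regions: tuple[Region, ...]
    _subsystem_index: dict[str, tuple[int, ...]] = field(
        init=False, repr=False, compare=False, default=None
    )

    def __post_init__(self) -> None:
        by_system: dict[str, list[int]] = {}
        for i, r in enumerate(self.regions):
            by_system.setdefault(r.subsystem, []).append(i)
        object.__setattr__(
            self,
            "_subsystem_index",
            {k: tuple(v) for k, v in by_system.items()},
        )

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.regions]

    @property
    def subsystems(self) -> list[str]:
        """Subsystem names present, in canonical order first."""
        seen = set(self._subsystem_index)
        ordered = [s for s in SUBSYSTEMS if s in seen]
        ordered += sorted(seen.difference(SUBSYSTEMS))
        return ordered

    def subsystem_members(self, name: str) -> tuple[int, ...]:
        """Region indices belonging to subsystem ``name``."""
        try:
            return self._subsystem_index[name]
        except KeyError:
            raise KeyError(
                f"unknown subsystem {name!r}; available: {self.subsystems}"
            ) from None

    def subsystem_sizes(self) -> dict[str, int]:
        return {s: len(self.subsystem_members(s)) for s in self.subsystems}

    def subsystem_of(self, index: int) -> str:
        return self.regions[index].subsystem

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.region_id, r.hemisphere, r.abbreviation, r.full_name, r.subsystem)
                for r in self.regions
            ],
            columns=_COLUMNS,
        )

    def write(self, path: str | Path) -> None:
        """Write the map as TSV (or JSON when the suffix is .json)."""
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(
                json.dumps(self.to_frame().to_dict(orient="records"), indent=1)
            )
        else:
            self.to_frame().to_csv(path, sep="\t", index=False)


def _validate(df: pd.DataFrame, *, strict: bool, source: str) -> ParcellationMap:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ParcellationError(f"{source}: missing columns {missing}")
    df = df[_COLUMNS].copy()
    if df[_COLUMNS].isna().any().any():
        raise ParcellationError(f"{source}: empty fields present")

    ids = df["region_id"].astype(int).tolist()
    if sorted(ids) != list(range(len(ids))):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ParcellationError(
            f"{source}: region_id must be 0..N-1 without gaps; "
            f"duplicates/gaps around {dupes or ids[:5]}"
        )
    df = df.sort_values("region_id")

    bad_hemi = sorted(set(df["hemisphere"]).difference(_HEMISPHERES))
    if bad_hemi:
        raise ParcellationError(f"{source}: unknown hemisphere values {bad_hemi}")

    # one subsystem per region is structural (one row per region, one value);
    # duplicated region rows would already have failed the id check above.
    for hemi in _HEMISPHERES:
        sub = df[df["hemisphere"] == hemi]
        dup = sub["abbreviation"][sub["abbreviation"].duplicated()].tolist()
        if dup:
            raise ParcellationError(
                f"{source}: duplicate abbreviation(s) within {hemi} hemisphere: {dup}"
            )

    regions = tuple(
        Region(int(t.region_id), t.hemisphere, t.abbreviation, t.full_name, t.subsystem)
        for t in df.itertuples(index=False)
    )
    pmap = ParcellationMap(regions)

    if strict:
        if pmap.n_regions != 64:
            raise ParcellationError(
                f"{source}: expected 64 regions, found {pmap.n_regions}"
            )
        counts = df["hemisphere"].value_counts().to_dict()
        if counts.get("left") != 32 or counts.get("right") != 32:
            raise ParcellationError(
                f"{source}: expected 32 regions per hemisphere, found {counts}"
            )
        sizes = pmap.subsystem_sizes()
        if sizes != CANONICAL_SUBSYSTEM_SIZES:
            raise ParcellationError(
                f"{source}: subsystem sizes {sizes} do not match the canonical "
                f"partition {CANONICAL_SUBSYSTEM_SIZES}"
            )
    return pmap


def load_parcellation(path: str | Path, *, strict: bool = True) -> ParcellationMap:
    """Load a parcellation map from TSV or JSON.

    Parameters
    ----------
    path
        TSV with header ``region_id hemisphere abbreviation full_name
        subsystem``, or a JSON array of records with the same keys.
    strict
        Enforce the canonical 64-region / five-subsystem invariants
        (region count 64, 32 per hemisphere, subsystem sizes
        14/14/18/10/8).  Set ``False`` to accept alternative atlases; the
        structural checks (contiguous ids, unique abbreviations, valid
        hemispheres) always apply.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "region_id" in df.columns:
            df["region_id"] = df["region_id"].astype(int)
    return _validate(df, strict=strict, source=str(path))


def default_parcellation() -> ParcellationMap:
    """The packaged 64-region Desikan–Killiany map with five subsystems."""
    ref = resources.files("corticonet.data").joinpath("desikan64_subsystems.tsv")
    with resources.as_file(ref) as p:
        return load_parcellation(p, strict=True)


def from_records(records: Iterable[dict], *, strict: bool = False) -> ParcellationMap:
    """Build a map from an iterable of dicts (mainly for tests)."""
    return _validate(pd.DataFrame(list(records)), strict=strict, source="<records>")
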