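"""Domain types and tabular I/O for multi-core stratigraphic abundance data.

The sample table is a wide CSV with one row per sampled horizon:
``core, depth_m, gamma_uRh, <species 1>, <species 2>, ...``.  Depth is
measured downhole in meters (larger = older), gamma-ray intensity in
μR/h and may be missing, counts are non-negative integers (blank = 0,
i.e. species absent).  Series handed to the statistics layer are always
oriented oldest-first (deepest-first), since depth is the time axis.

The predictor table is a species-level CSV:
``species, survival, a_bar, cv_bar, hurst, nu, skew_a, extirpation,
colonization, gamma_mean, gamma_sd, gamma_skew``; empty cells encode
statistically undefined (missing) values, carried as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PREDICTOR_COLUMNS = [
    "a_bar",
    "cv_bar",
    "hurst",
    "nu",
    "skew_a",
    "extirpation",
    "colonization",
    "gamma_mean",
    "gamma_sd",
    "gamma_skew",
]

_META_COLUMNS = ("core", "depth_m", "gamma_uRh")


@dataclass(frozen=True)
class StratigraphicSample:
    """One sampled horizon in one core."""

    core_id: str
    depth: float  # meters, measured downhole
    gamma: float | None  # μR/h; None if not logged
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth <= 0 or not math.isfinite(self.depth):
            raise ValueError(f"depth must be positive and finite, got {self.depth}")
        if self.gamma is not None and (self.gamma < 0 or not math.isfinite(self.gamma)):
            raise ValueError(f"gamma must be non-negative, got {self.gamma}")
        for sp, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count {c} for species {sp!r}")


@dataclass(frozen=True)
class AbundanceSeries:
    """One species' ordered count series in one core, zeros included.

    Depths are strictly decreasing: index 0 is the deepest (oldest)
    sample, so the series reads forward in time.
    """

    core_id: str
    species_id: str
    depths: tuple[float, ...]
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.depths) != len(self.values):
            raise ValueError("depths and values must be the same length")
        d = np.asarray(self.depths)
        if len(d) > 1 and not np.all(np.diff(d) < 0):
            raise ValueError("depths must be strictly decreasing (oldest/deepest first)")
        if any(v < 0 for v in self.values):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def span(self) -> float:
        """Total depth span in meters (0 for series of length < 2)."""
        if len(self.depths) < 2:
            return 0.0
        return float(self.depths[0] - self.depths[-1])


@dataclass(frozen=True)
class SpeciesRecord:
    """A species' survival label plus its per-core abundance series."""

    species_id: str
    survival: int  # 0 = victim, 1 = survivor
    series: tuple[AbundanceSeries, ...]

    def __post_init__(self) -> None:
        if self.survival not in (0, 1):
            raise ValueError("survival must be 0 or 1")
        if not any(v > 0 for s in self.series for v in s.values):
            raise ValueError(f"species {self.species_id!r} has no positive count in any core")


@dataclass
class PredictorVector:
    """The ten species-level predictors; NaN marks an undefined value."""

    species_id: str
    a_bar: float = math.nan
    cv_bar: float = math.nan
    hurst: float = math.nan
    nu: float = math.nan
    skew_a: float = math.nan
    extirpation: float = math.nan
    colonization: float = math.nan
    gamma_mean: float = math.nan
    gamma_sd: float = math.nan
    gamma_skew: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in PREDICTOR_COLUMNS}


def load_sample_table(path) -> dict[str, list[StratigraphicSample]]:
    """Read a wide sample CSV (or .xlsx with the same sheet layout).

    Returns samples grouped by core id, each group sorted by depth
    descending (oldest first).  Blank count cells are read as 0; blank
    gamma cells as missing.  Duplicate (core, depth) pairs, negative
    counts and unparseable numerics raise ``ValueError``.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("core", "depth_m") if c not in df.columns]
    if missing:
        raise ValueError(f"sample table lacks required columns: {missing}")
    species_cols = [c for c in df.columns if c not in _META_COLUMNS]
    by_core: dict[str, list[StratigraphicSample]] = {}
    seen: set[tuple[str, float]] = set()
    for idx, row in df.iterrows():
        core = str(row["core"])
        try:
            depth = float(row["depth_m"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {idx}: unparseable depth {row['depth_m']!r}") from exc
        key = (core, depth)
        if key in seen:
            raise ValueError(f"duplicate sample at core={core} depth={depth}")
        seen.add(key)
        gamma = None
        if "gamma_uRh" in df.columns and not pd.isna(row["gamma_uRh"]):
            gamma = float(row["gamma_uRh"])
        counts = {}
        for sp in species_cols:
            cell = row[sp]
            if pd.isna(cell) or cell == "":
                counts[sp] = 0
                continue
            try:
                c = float(cell)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"row {idx}: unparseable count {cell!r} for {sp!r}") from exc
            if c < 0:
                raise ValueError(f"row {idx}: negative count for {sp!r}")
            counts[sp] = int(round(c))
        by_core.setdefault(core, []).append(
            StratigraphicSample(core_id=core, depth=depth, gamma=gamma, counts=counts)
        )
    for core in by_core:
        by_core[core].sort(key=lambda s: -s.depth)
    return dict(sorted(by_core.items()))


def write_sample_table(samples: dict[str, list[StratigraphicSample]], path) -> None:
    """Write grouped samples back to the wide CSV layout (round-trip safe)."""
    species = sorted({sp for ss in samples.values() for s in ss for sp in s.counts})
    rows = []
    for core in sorted(samples):
        for s in sorted(samples[core], key=lambda s: -s.depth):
            row = {"core": core, "depth_m": s.depth, "gamma_uRh": s.gamma}
            for sp in species:
                row[sp] = s.counts.get(sp, 0)
            rows.append(row)
    pd.DataFrame(rows, columns=["core", "depth_m", "gamma_uRh", *species]).to_csv(
        path, index=False
    )


def species_in_table(samples: dict[str, list[StratigraphicSample]]) -> list[str]:
    """Sorted list of all species ids appearing in the table."""
    return sorted({sp for ss in samples.values() for s in ss for sp in s.counts})


def extract_series(
    samples: dict[str, list[StratigraphicSample]], species_id: str, core_id: str
) -> AbundanceSeries:
    """Full per-core series for one species, zeros included, oldest first.

    An unknown species yields an all-zero series; an unknown core is an
    error.
    """
    if core_id not in samples:
        raise KeyError(f"unknown core {core_id!r}")
    ordered = sorted(samples[core_id], key=lambda s: -s.depth)
    return AbundanceSeries(
        core_id=core_id,
        species_id=species_id,
        depths=tuple(s.depth for s in ordered),
        values=tuple(s.counts.get(species_id, 0) for s in ordered),
    )


def range_window(series: AbundanceSeries) -> AbundanceSeries:
    """Restrict a series to its first-through-last appearance, inclusive.

    Empty series if the species never occurs in the core.
    """
    pos = [i for i, v in enumerate(series.values) if v > 0]
    if not pos:
        return AbundanceSeries(series.core_id, series.species_id, (), ())
    lo, hi = pos[0], pos[-1]
    return AbundanceSeries(
        series.core_id,
        series.species_id,
        series.depths[lo : hi + 1],
        series.values[lo : hi + 1],
    )


def trim_range(series: AbundanceSeries) -> AbundanceSeries:
    """Samples strictly between the first and last positive sample.

    Both range endpoints are removed (gap-analysis convention: the first
    and last appearances are excluded so the interior gaps alone carry
    the occupancy-turnover signal).  Result is empty when fewer than
    three samples lie in the first-to-last-appearance window, or when
    there is no positive sample at all.
    """
    win = range_window(series)
    if len(win) < 3:
        return AbundanceSeries(series.core_id, series.species_id, (), ())
    return AbundanceSeries(
        series.core_id, series.species_id, win.depths[1:-1], win.values[1:-1]
    )


def longest_series(record: SpeciesRecord) -> AbundanceSeries:
    """The species' longest first-to-last-appearance window over its cores.

    Length is counted in samples, zeros included.  Ties break toward the
    larger total element count, then the lexicographically smaller core
    id.  Raises if the species has no positive count anywhere.
    """
    windows = [range_window(s) for s in record.series]
    windows = [w for w in windows if len(w) > 0]
    if not windows:
        raise ValueError(f"species {record.species_id!r} has no occurrences")
    return min(windows, key=lambda w: (-len(w), -sum(w.values), w.core_id))


def load_predictor_table(path) -> pd.DataFrame:
    """Read a species-level predictor CSV (or .xlsx); empty cell = NaN.

    Returns a DataFrame indexed by species with a ``survival`` column
    (0/1 int) and the ten predictor columns as floats.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if "species" not in df.columns or "survival" not in df.columns:
        raise ValueError("predictor table needs 'species' and 'survival' columns")
    df = df.set_index("species")
    bad = set(df["survival"].dropna()) - {0, 1}
    if bad:
        raise ValueError(f"survival must be 0/1, found {sorted(bad)}")
    df["survival"] = df["survival"].astype(int)
    for c in PREDICTOR_COLUMNS:
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="raise")
    return df


def write_predictor_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="species")
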