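"""Gamma-ray habitat-affinity metrics.

Downhole gamma-ray intensity (μR/h) tracks clay/organic content and
hence, to first order, the water depth at which the sediment formed.
The gamma values at a species' positive occurrences therefore summarize
its habitat preference: the mean γ̄ is the preferred depth, the standard
deviation σ(γ) the breadth of occupied depths, and the skewness G(γ)
the shape of the occupied-depth distribution.
"""

from __future__ import annotations

import math

import numpy as np

from paleosel.core_data import SpeciesRecord, StratigraphicSample
from paleosel.series_stats import _skewness


def gamma_at_occurrences(
    record: SpeciesRecord, samples: dict[str, list[StratigraphicSample]]
) -> list[float]:
    """Gamma values at every positive occurrence, pooled over cores.

    Samples without a gamma reading are skipped.  Raises if no positive
    occurrence carries a gamma value.
    """
    out: list[float] = []
    for core_id, core_samples in samples.items():
        by_depth = {s.depth: s for s in core_samples}
        for series in record.series:
            if series.core_id != core_id:
                continue
            for depth, value in zip(series.depths, series.values):
                if value > 0:
                    s = by_depth.get(depth)
                    if s is not None and s.gamma is not None:
                        out.append(s.gamma)
    if not out:
        raise ValueError(
            f"{record.species_id!r}: no positive occurrence with a gamma reading"
        )
    return out


def affinity_metrics(values: list[float]) -> tuple[float, float, float]:
    """(mean, sample sd, adjusted G1 skewness) of occurrence gamma values.

    Each metric needs progressively more data (1, 2, 3 values); an
    underpowered metric is NaN rather than an error.
    """
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("no gamma values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if len(x) >= 2 else math.nan
    skew = _skewness(x) if len(x) >= 3 else math.nan
    return mean, sd, skew
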