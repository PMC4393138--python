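"""Orchestration: sample table → predictor table → selectivity report.

``compute_predictors`` turns a multi-core sample table into the
species-level predictor table (ten statistics per species, NaN where a
statistic is undefined); ``run_selectivity`` runs the full modelling
stage on a predictor table.  Every culling decision (species dropped,
per-predictor n) is logged at INFO, because the varying per-predictor
sample sizes are the main reproducibility trap of this kind of
analysis.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from paleosel.core_data import (
    PREDICTOR_COLUMNS,
    SpeciesRecord,
    StratigraphicSample,
    extract_series,
    longest_series,
    species_in_table,
    trim_range,
)
from paleosel.env_affinity import affinity_metrics, gamma_at_occurrences
from paleosel.occupancy import colonization_rate, extirpation_rate, summarize_transitions
from paleosel.selectivity import SelectivityResults, SurvivalSelectivityModel
from paleosel.series_stats import (
    abundance_skewness,
    averaged_cv,
    hurst_exponent,
    lomb_periodogram,
    mean_abundance,
    spectral_exponent,
)

logger = logging.getLogger(__name__)


def build_record(
    samples: dict[str, list[StratigraphicSample]], species_id: str, survival: int = 0
) -> SpeciesRecord:
    """Assemble a SpeciesRecord with one full series per core."""
    series = tuple(extract_series(samples, species_id, core) for core in sorted(samples))
    return SpeciesRecord(species_id=species_id, survival=survival, series=series)


def predictors_for_record(
    record: SpeciesRecord, samples: dict[str, list[StratigraphicSample]]
) -> dict[str, float]:
    """All ten predictors for one species; NaN where undefined.

    Mean abundance, CV̄ and G(a) pool positive counts over all cores;
    the Hurst and spectral exponents and the extirpation/colonization
    rates use the species' longest first-to-last-appearance series (the
    rates on its trimmed interior); the gamma metrics pool gamma values
    at positive occurrences.
    """
    out: dict[str, float] = dict.fromkeys(PREDICTOR_COLUMNS, math.nan)
    out["a_bar"] = mean_abundance(record)
    out["cv_bar"] = averaged_cv(record)
    out["skew_a"] = abundance_skewness(record)
    longest = longest_series(record)
    out["hurst"] = hurst_exponent(longest)
    try:
        out["nu"] = spectral_exponent(lomb_periodogram(longest))
    except ValueError:
        pass
    trimmed = trim_range(longest)
    if len(trimmed) >= 2:
        summary = summarize_transitions(trimmed)
        out["extirpation"] = extirpation_rate(summary)
        out["colonization"] = colonization_rate(summary)
    try:
        gammas = gamma_at_occurrences(record, samples)
    except ValueError:
        pass
    else:
        out["gamma_mean"], out["gamma_sd"], out["gamma_skew"] = affinity_metrics(gammas)
    return out


def compute_predictors(
    samples: dict[str, list[StratigraphicSample]],
    survival: dict[str, int] | pd.Series | None = None,
) -> pd.DataFrame:
    """Species-level predictor table from a multi-core sample table.

    Species with no positive count anywhere are excluded with a
    warning.  If ``survival`` labels are given, they become the first
    column of the result.
    """
    rows = {}
    for sp in species_in_table(samples):
        try:
            record = build_record(samples, sp)
        except ValueError:
            logger.warning("species %r has no occurrences; excluded", sp)
            continue
        rows[sp] = predictors_for_record(record, samples)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=PREDICTOR_COLUMNS)
    df.index.name = "species"
    for col in PREDICTOR_COLUMNS:
        logger.info("predictor %s defined for n=%d species", col, int(df[col].notna().sum()))
    if survival is not None:
        labels = pd.Series(survival)
        df.insert(0, "survival", labels.reindex(df.index).astype("Int64"))
    return df


def run_selectivity(
    predictor_table: pd.DataFrame,
    alpha: float = 0.1,
    tree_control: dict | None = None,
) -> SelectivityResults:
    """Screen → model ranking → regression tree on a predictor table.

    With fewer than two screened candidates the multivariate stage is
    skipped and the results carry the bivariate fits and the tree only.
    """
    table = predictor_table.dropna(subset=["survival"]).copy()
    table["survival"] = table["survival"].astype(int)
    model = SurvivalSelectivityModel(table, alpha=alpha, tree_control=tree_control)
    results = model.fit()
    logger.info(
        "screen kept %d of %d predictors: %s",
        len(results.screen.candidates),
        len(results.screen.fits),
        results.screen.candidates,
    )
    if results.ranking is None:
        logger.info("fewer than 2 candidates: multivariate stage skipped")
    else:
        logger.info("ranked %d models on culled n=%d", len(results.ranking.table), results.ranking.n)
    return results
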