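"""Synthetic multi-core stratigraphic datasets with controllable structure.

Generates data with the statistical anatomy the selectivity analysis
assumes: a handful of deep cores, each a few tens of samples at
roughly regular (jittered) depth spacing; a gamma-ray log per core with
a baseline, a gentle trend, an abrupt regression-event drop and
Gaussian noise; and per-species zero-inflated, overdispersed count
series whose occupancy follows a persistence chain modulated by a
Gaussian habitat-affinity kernel on gamma and whose positive counts are
negative-binomial with a colored-noise log-mean (spectral synthesis,
amplitude ∝ f^(−ν_gen/2)), so both the spectral exponent and the
abundance skewness of the output are steerable.

Survival labels are drawn from a logistic model on the predictors
computed from the generated series themselves, which makes full
parameter-recovery experiments possible without any real data.

All randomness flows from one integer seed; per-core and per-species
substreams are spawned deterministically from it, so a fixed config is
bit-reproducible.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from paleosel.core_data import StratigraphicSample


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate a five-core, 34-species survey."""

    n_cores: int = 5
    samples_per_core: tuple[int, int] = (22, 36)
    n_species: int = 34
    # depth grid: mean spacing (m) with jitter, per-core top depth offsets
    depth_spacing: float = 1.5
    depth_jitter: float = 0.3
    depth_top: float = 700.0
    # gamma model (μR/h)
    gamma_baseline_range: tuple[float, float] = (8.0, 22.0)
    gamma_trend: float = 0.05  # per meter of depth
    gamma_step_drop: float = 4.0  # regression-event drop in the upper part
    gamma_step_fraction: float = 0.6  # fraction of samples below the step
    gamma_noise_sd: float = 1.5
    # species count model
    nb_mean_log_mu: float = 1.0  # lognormal hyperprior on the NB mean
    nb_mean_log_sd: float = 0.8
    nb_dispersion: float = 1.0
    nu_gen_range: tuple[float, float] = (0.0, 2.0)
    noise_log_sd: float = 0.7  # sd of the colored log-mean noise
    persistence: float = 0.75  # P(positive stays positive), before affinity
    colonize: float = 0.45  # P(zero turns positive), before affinity
    affinity_tolerance: float = 6.0  # μR/h width of the habitat kernel
    # survival model: coefficients on z-scored predictors (+ intercept)
    survival_beta: dict[str, float] = field(
        default_factory=lambda: {"intercept": 0.2, "gamma_mean": -1.0, "skew_a": 1.0}
    )
    seed: int = 0


@dataclass
class SynthDataset:
    """A generated dataset plus the truth needed for recovery tests."""

    samples: dict[str, list[StratigraphicSample]]
    predictors: pd.DataFrame  # computed predictors + survival column
    survival: pd.Series
    truth: dict  # per-species generating parameters and survival betas


def _stable_key(x) -> int:
    if isinstance(x, (int, np.integer)):
        return int(x) % (2**31)
    return zlib.crc32(str(x).encode()) % (2**31)


def _substream(seed: int, *ids) -> np.random.Generator:
    """Deterministic child generator keyed on (seed, ids); process-stable."""
    ss = np.random.SeedSequence([seed % (2**31), *(_stable_key(i) for i in ids)])
    return np.random.default_rng(ss)


def colored_noise(n: int, nu_gen: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-sd colored noise via spectral synthesis.

    Fourier amplitudes ∝ f^(−ν_gen/2) with uniform random phases give a
    power spectrum ∝ f^(−ν_gen): ν_gen=0 is white, 1 pink, 2 red.
    """
    if n < 2:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-nu_gen / 2.0)
    phases = rng.uniform(0, 2 * math.pi, size=len(freqs))
    spectrum = amp * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    return x / sd if sd > 0 else np.zeros(n)


def synth_gamma_log(config: SynthConfig, core_index: int, seed: int | None = None):
    """Depth grid and gamma-ray log for one core.

    Returns (depths, gamma): depths strictly decreasing (oldest first),
    gamma = baseline + trend·(depth below top) − step drop in the upper
    (younger) ``1−gamma_step_fraction`` of samples + noise, floored at 0.
    """
    seed = config.seed if seed is None else seed
    rng = _substream(seed, "gamma", core_index)
    n = int(rng.integers(config.samples_per_core[0], config.samples_per_core[1] + 1))
    spacing = np.clip(
        rng.normal(config.depth_spacing, config.depth_jitter, size=n - 1),
        config.depth_spacing * 0.2,
        None,
    )
    top = config.depth_top + 40.0 * core_index
    depths_up = top + np.concatenate([[0.0], np.cumsum(spacing)])  # increasing downhole
    depths = depths_up[::-1].copy()  # deepest (oldest) first
    lo, hi = config.gamma_baseline_range
    baseline = lo + (hi - lo) * core_index / max(config.n_cores - 1, 1)
    below = depths - depths[-1]
    step = np.where(
        np.arange(n) >= int(config.gamma_step_fraction * n), config.gamma_step_drop, 0.0
    )
    gamma = (
        baseline
        + config.gamma_trend * below
        - step
        + rng.normal(0.0, config.gamma_noise_sd, size=n)
    )
    return depths, np.clip(gamma, 0.0, None)


@dataclass
class SpeciesParams:
    """True generating parameters of one synthetic species."""

    preferred_gamma: float
    nb_mean: float
    nu_gen: float


def draw_species_params(config: SynthConfig, species_index: int) -> SpeciesParams:
    rng = _substream(config.seed, "species-params", species_index)
    lo, hi = config.gamma_baseline_range
    nu_lo, nu_hi = config.nu_gen_range
    return SpeciesParams(
        preferred_gamma=float(rng.uniform(lo - 2.0, hi + config.gamma_trend * 40.0)),
        nb_mean=float(np.exp(rng.normal(config.nb_mean_log_mu, config.nb_mean_log_sd))),
        nu_gen=float(rng.uniform(nu_lo, nu_hi)),
    )


def synth_species_series(
    config: SynthConfig,
    params: SpeciesParams,
    core_index: int,
    gamma: np.ndarray,
    seed: int | None = None,
) -> np.ndarray:
    """Count series for one species in one core.

    Occupancy: two-state chain with stay/colonize probabilities scaled
    by the Gaussian affinity kernel exp(−(γ−pref)²/(2·tol²)).  Where
    occupied, counts are 1 + NegBin with a log-mean carrying colored
    noise of exponent ν_gen.
    """
    seed = config.seed if seed is None else seed
    rng = _substream(seed, "series", core_index, round(params.preferred_gamma * 1e6))
    n = len(gamma)
    tol = max(config.affinity_tolerance, 1e-9)
    affinity = np.exp(-((gamma - params.preferred_gamma) ** 2) / (2.0 * tol**2))
    occupied = np.zeros(n, dtype=bool)
    state = rng.random() < config.colonize * affinity[0]
    occupied[0] = state
    for i in range(1, n):
        p = (config.persistence if state else config.colonize) * affinity[i]
        state = rng.random() < p
        occupied[i] = state
    noise = colored_noise(n, params.nu_gen, rng) * config.noise_log_sd
    mu = params.nb_mean * np.exp(noise - config.noise_log_sd**2 / 2.0)
    k = config.nb_dispersion
    counts = np.zeros(n, dtype=int)
    idx = np.flatnonzero(occupied)
    if len(idx):
        counts[idx] = 1 + rng.negative_binomial(k, k / (k + mu[idx]), size=len(idx))
    return counts


def synth_assembly(config: SynthConfig) -> SynthDataset:
    """Generate a full multi-core dataset with survival labels.

    Predictors are computed from the generated series with the same
    pipeline used for real data; survival is then Bernoulli on the
    logistic link of the z-scored predictors named in
    ``config.survival_beta`` (NaN predictor values are mean-imputed for
    label generation only, so every species gets a label).
    """
    from paleosel.pipeline import compute_predictors

    species_ids = [f"sp{idx:03d}" for idx in range(config.n_species)]
    params = {sp: draw_species_params(config, i) for i, sp in enumerate(species_ids)}
    samples: dict[str, list[StratigraphicSample]] = {}
    series_cache: dict[str, dict[str, np.ndarray]] = {sp: {} for sp in species_ids}
    for c in range(config.n_cores):
        core_id = f"core{c}"
        depths, gamma = synth_gamma_log(config, c)
        counts_by_species = {
            sp: synth_species_series(config, params[sp], c, gamma) for sp in species_ids
        }
        for sp in species_ids:
            series_cache[sp][core_id] = counts_by_species[sp]
        samples[core_id] = [
            StratigraphicSample(
                core_id=core_id,
                depth=float(depths[i]),
                gamma=float(gamma[i]),
                counts={sp: int(counts_by_species[sp][i]) for sp in species_ids},
            )
            for i in range(len(depths))
        ]
    # guarantee every species occurs at least once (re-seat absentees)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))
    for sp in species_ids:
        if not any(arr.any() for arr in series_cache[sp].values()):
            core_id = f"core{int(rng.integers(config.n_cores))}"
            pos = int(rng.integers(len(samples[core_id])))
            s = samples[core_id][pos]
            s.counts[sp] = 1 + int(rng.negative_binomial(1, 0.5))
    predictors = compute_predictors(samples)
    linpred = np.full(len(predictors), config.survival_beta.get("intercept", 0.0))
    for name, beta in config.survival_beta.items():
        if name == "intercept":
            continue
        col = predictors[name].to_numpy(dtype=float)
        col = np.where(np.isnan(col), np.nanmean(col), col)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        linpred = linpred + beta * z
    prob = 1.0 / (1.0 + np.exp(-linpred))
    rng_s = np.random.default_rng(np.random.SeedSequence([config.seed, 2**21]))
    survival = pd.Series(
        (rng_s.random(len(prob)) < prob).astype(int), index=predictors.index, name="survival"
    )
    predictors.insert(0, "survival", survival)
    truth = {
        "survival_beta": dict(config.survival_beta),
        "species": {
            sp: {
                "preferred_gamma": params[sp].preferred_gamma,
                "nb_mean": params[sp].nb_mean,
                "nu_gen": params[sp].nu_gen,
            }
            for sp in species_ids
        },
    }
    return SynthDataset(samples=samples, predictors=predictors, survival=survival, truth=truth)
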