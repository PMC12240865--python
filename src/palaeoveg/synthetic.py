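"""Synthetic cores, driver series and calibration sites with ground truth.

The generator emulates the statistical structure of a long alpine pollen
record: a 3,500-kyr axis sampled every ~0.7 kyr, taxon abundances driven by
a single latent "effective temperature" axis composed of superposed ~20, 41
and 100-kyr orbital cycles (the 41/100-kyr terms strengthening toward the
present), a long-term cooling trend that shifts dominance from forest
toward meadow, and AR(1) millennial noise. Counts are multinomial at
300–600 terrestrial grains per sample. Every generated object is a valid
instance of the core data types, and the exact generative equations are
exported as :class:`GroundTruth` so each downstream stage has a
parameter-recovery oracle.

The generator emulates composition, cyclicity and noise only — not sediment
taphonomy, differential preservation or pollen transport.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from palaeoveg.biomization import BiomeScheme, affinity_scores, assign_biome, default_scheme
from palaeoveg.core import PollenCore, SampleRecord, Series, TaxonInfo

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "DriverSet",
    "make_drivers",
    "simulate_core",
    "make_calibration_sites",
    "simulate_path_data",
]

#: Gaussian response (optimum, tolerance, max abundance) of each taxon along
#: the latent effective-temperature axis (arbitrary °C-like units; ~+4 in the
#: warm Pliocene end falling to ~−4 in late-Pleistocene glacials).
DEFAULT_TAXON_RESPONSES: dict[str, tuple[float, float, float]] = {
    # trees → forest biomes
    "Picea": (2.5, 2.0, 40.0),
    "Abies": (2.8, 2.0, 30.0),
    "Pinus": (3.5, 2.5, 25.0),
    "Tsuga": (5.0, 1.8, 12.0),
    "Betula": (1.5, 2.0, 10.0),
    "Quercus": (4.0, 2.0, 8.0),
    # steppe herbs
    "Artemisia": (0.0, 1.6, 25.0),
    "Amaranthaceae": (-0.3, 1.6, 10.0),
    "Poaceae": (-0.8, 2.2, 25.0),
    # shrubs
    "Hippophae": (0.5, 1.4, 12.0),
    "Rosaceae": (0.3, 1.4, 8.0),
    "Salix": (-0.5, 1.5, 6.0),
    # meadow herbs
    "Cyperaceae": (-3.0, 2.0, 35.0),
    "Ranunculaceae": (-3.5, 1.8, 15.0),
    "Thalictrum": (-3.2, 1.5, 8.0),
    "Polygonum": (-3.8, 1.5, 8.0),
    "Asteraceae": (-2.5, 1.8, 12.0),
    "Gentianaceae": (-4.0, 1.5, 6.0),
    "Caryophyllaceae": (-4.5, 1.5, 5.0),
}

_GROUP_OF = {
    "Picea": "tree", "Abies": "tree", "Pinus": "tree", "Tsuga": "tree",
    "Betula": "tree", "Quercus": "tree",
    "Hippophae": "shrub", "Rosaceae": "shrub", "Salix": "shrub",
    "Artemisia": "herb", "Amaranthaceae": "herb", "Poaceae": "herb",
    "Cyperaceae": "herb", "Ranunculaceae": "herb", "Thalictrum": "herb",
    "Polygonum": "herb", "Asteraceae": "herb", "Gentianaceae": "herb",
    "Caryophyllaceae": "herb",
}


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic record."""

    span: float = 3500.0  # kyr
    dt_sample: float = 0.7  # kyr between pollen samples
    dt_driver: float = 1.0  # kyr driver grid
    orbital_amplitudes: dict[float, float] = field(
        default_factory=lambda: {20.0: 1.2, 41.0: 0.9, 100.0: 0.7}
    )
    #: 41/100-kyr amplitudes ramp linearly from this fraction (oldest end) to 1
    glacial_ramp_start: float = 0.25
    cooling_total: float = 7.0  # latent-axis drop old → young
    latent_warm_end: float = 3.5  # latent value at the oldest sample
    ar1_phi: float = 0.6
    ar1_sigma: float = 0.45
    taxon_responses: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TAXON_RESPONSES)
    )
    count_target: tuple[int, int] = (300, 600)
    sed_rate_m_per_kyr: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.dt_sample <= 0 or self.dt_driver <= 0:
            raise ValueError("sampling steps must be positive")
        if not 0 <= self.ar1_phi < 1:
            raise ValueError("ar1_phi must lie in [0, 1)")
        for taxon, (_, tol, mx) in self.taxon_responses.items():
            if tol <= 0 or mx <= 0:
                raise ValueError(f"taxon {taxon!r}: tolerance and max must be > 0")


@dataclass
class DriverSet:
    """Age-aligned exogenous series on a common grid (ages ascending, ka)."""

    insolation: Series
    ice: Series
    co2: Series
    gmst: Series
    latent: Series  # the true effective-temperature forcing
    weights: dict[str, float]  # latent = w·(standardized drivers) + trend + noise


@dataclass
class GroundTruth:
    latent: Series  # latent forcing at the sample ages
    megabiome: np.ndarray  # true label per sample (old→young)
    ages: np.ndarray  # sample ages old→young (ka)
    expected_pct: pd.DataFrame  # noise-free percentages (old→young)
    change_points: list[float]  # ages where the trend-only megabiome flips
    taxon_optima: dict[str, float]
    weights: dict[str, float]


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    innov = rng.standard_normal(n) * sigma
    out = np.empty(n)
    out[0] = innov[0] / np.sqrt(max(1 - phi**2, 1e-12))
    for i in range(1, n):
        out[i] = phi * out[i - 1] + innov[i]
    return out


def make_drivers(cfg: GeneratorConfig, seed: int | None = None) -> DriverSet:
    """Generate coupled synthetic driver series and the latent forcing.

    Deterministic given (config, seed). In forward time (decreasing age):
    insolation is a sum of fixed-phase sinusoids; ice volume is a ramped,
    softly saturating transform of lagged inverse insolation plus AR(1)
    noise; CO₂ anti-correlates with ice; the latent effective temperature is
    the exported linear combination plus the cooling trend and AR(1)
    millennial noise; GMST is a noisy affine image of the latent axis.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    age = np.arange(0.0, cfg.span + cfg.dt_driver / 2, cfg.dt_driver)
    frac_young = 1.0 - age / cfg.span  # 0 at the old end, 1 at present

    phases = {20.0: 0.3, 41.0: 1.1, 100.0: 2.0}
    insol = np.zeros_like(age)
    for period, amp in cfg.orbital_amplitudes.items():
        ramp = (
            cfg.glacial_ramp_start + (1 - cfg.glacial_ramp_start) * frac_young
            if period >= 40
            else 1.0
        )
        insol += amp * ramp * np.sin(2 * np.pi * age / period + phases.get(period, 0.0))

    lag = int(round(2.0 / cfg.dt_driver))  # ice lags insolation by ~2 kyr
    insol_lagged = np.roll(insol, -lag)
    insol_lagged[-lag:] = insol[-lag:]
    ice = (
        1.5 * frac_young
        + np.tanh(-0.8 * insol_lagged) * (0.5 + 0.8 * frac_young)
        + _ar1(rng, len(age), 0.7, 0.15)
    )
    co2 = 260.0 - 35.0 * ice + _ar1(rng, len(age), 0.5, 4.0)

    w = {"insolation": 0.9, "ice": -1.2, "co2": 0.35}

    def z(v):
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    trend = cfg.latent_warm_end - cfg.cooling_total * frac_young
    noise = _ar1(rng, len(age), cfg.ar1_phi, cfg.ar1_sigma)
    latent = trend + w["insolation"] * z(insol) + w["ice"] * z(ice) + w["co2"] * z(co2) + noise
    gmst = 0.8 * latent - 0.5 + _ar1(rng, len(age), 0.4, 0.2)

    return DriverSet(
        insolation=Series(age, insol, "insolation"),
        ice=Series(age, ice, "ice"),
        co2=Series(age, co2, "co2"),
        gmst=Series(age, gmst, "gmst"),
        latent=Series(age, latent, "latent"),
        weights=w,
    )


def expected_percentages(
    latent_values: np.ndarray, responses: dict[str, tuple[float, float, float]]
) -> pd.DataFrame:
    """Noise-free taxon percentages from Gaussian responses, renormalized."""
    taxa = list(responses)
    raw = np.empty((len(latent_values), len(taxa)))
    for j, t in enumerate(taxa):
        opt, tol, mx = responses[t]
        raw[:, j] = mx * np.exp(-0.5 * ((latent_values - opt) / tol) ** 2)
    raw /= raw.sum(axis=1, keepdims=True)
    return pd.DataFrame(raw * 100.0, columns=taxa)


def _true_megabiomes(pct: pd.DataFrame, scheme: BiomeScheme) -> np.ndarray:
    out = []
    for _, row in pct.iterrows():
        out.append(assign_biome(affinity_scores(row.to_dict(), scheme), scheme).megabiome)
    return np.array(out, dtype=object)


def simulate_core(
    cfg: GeneratorConfig,
    drivers: DriverSet | None = None,
    scheme: BiomeScheme | None = None,
    seed: int | None = None,
    exact_counts: bool = False,
) -> tuple[PollenCore, GroundTruth]:
    """Simulate a pollen core along the latent forcing.

    Counts are multinomial draws at 300–600 grains (``exact_counts=True``
    instead rounds the expected proportions at 10⁵ grains — the zero-noise
    limit). The true megabiome per sample is the biomization of the
    *noise-free* expected percentages; change points are the transitions of
    the trend-only (noise- and orbit-free) megabiome sequence.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    if drivers is None:
        drivers = make_drivers(cfg, seed=None if seed is None else seed)
    if scheme is None:
        scheme = default_scheme()
    missing = set(cfg.taxon_responses) - set(scheme.pft_of_taxon)
    if missing == set(cfg.taxon_responses):
        raise ValueError("taxon responses cover no taxon of the scheme")

    ages = np.arange(cfg.span, -cfg.dt_sample / 2, -cfg.dt_sample)  # old → young
    ages = np.round(ages, 6) + 0.0  # snap float-accumulation dust at the young end
    latent = np.interp(ages, drivers.latent.age, drivers.latent.value)
    pct = expected_percentages(latent, cfg.taxon_responses)
    truth_mega = _true_megabiomes(pct, scheme)

    # trend-only change points (long-term transformation ages)
    frac_young = 1.0 - ages / cfg.span
    trend_latent = cfg.latent_warm_end - cfg.cooling_total * frac_young
    trend_pct = expected_percentages(trend_latent, cfg.taxon_responses)
    trend_mega = _true_megabiomes(trend_pct, scheme)
    cps = [
        float(0.5 * (ages[i - 1] + ages[i]))
        for i in range(1, len(ages))
        if trend_mega[i] != trend_mega[i - 1]
    ]

    taxa_names = list(pct.columns)
    probs = pct.to_numpy() / 100.0
    lo, hi = cfg.count_target
    samples = []
    # build samples young → shallow first (PollenCore orders by depth)
    for i in range(len(ages) - 1, -1, -1):
        if exact_counts:
            counts = np.round(probs[i] * 100_000).astype(int)
        else:
            n_grains = int(rng.integers(lo, hi + 1))
            counts = rng.multinomial(n_grains, probs[i] / probs[i].sum())
        spike = int(rng.poisson(60)) + 1
        samples.append(
            SampleRecord(
                depth=float(ages[i] * cfg.sed_rate_m_per_kyr + 1e-6),
                counts={t: int(c) for t, c in zip(taxa_names, counts) if c > 0},
                spike_counted=spike,
                spike_added=20_848,
                volume=2.0,
                age=float(ages[i]),
                sample_id=f"s{len(ages) - 1 - i:05d}",
            )
        )
    taxa = [TaxonInfo(t, _GROUP_OF.get(t, "other")) for t in taxa_names]
    core = PollenCore(samples, taxa)
    truth = GroundTruth(
        latent=Series(ages[::-1].copy(), latent[::-1].copy(), "latent"),
        megabiome=truth_mega,
        ages=ages,
        expected_pct=pct,
        change_points=cps,
        taxon_optima={t: r[0] for t, r in cfg.taxon_responses.items()},
        weights=drivers.weights,
    )
    return core, truth


def make_calibration_sites(
    cfg: GeneratorConfig,
    n_sites: int = 1448,
    noise_sd: float = 0.3,
    gradient: tuple[float, float] = (-8.0, 8.0),
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict[str, float]]:
    """Modern calibration set: site × taxon % plus site climate.

    Sites are spread uniformly along a temperature gradient. Each taxon's
    *percentage* follows its Gaussian response curve directly (the classical
    unimodal percentage-response model of weighted-averaging calibration)
    with multiplicative lognormal noise (``noise_sd`` on the log scale;
    0 = noise-free). Site rows are therefore not closed to a 100 % sum —
    compositional closure is deliberately not emulated, so the exported
    optima are exact response-curve truths. Returns
    (pollen %, site temperature, true optima).
    """
    if n_sites < 30:
        raise ValueError("need at least 30 sites")
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    temps = np.linspace(gradient[0], gradient[1], n_sites)
    taxa = list(cfg.taxon_responses)
    raw = np.empty((n_sites, len(taxa)))
    for j, t in enumerate(taxa):
        opt, tol, mx = cfg.taxon_responses[t]
        raw[:, j] = mx * np.exp(-0.5 * ((temps - opt) / tol) ** 2)
    if noise_sd > 0:
        raw = raw * rng.lognormal(0.0, noise_sd, raw.shape)
    sites = pd.DataFrame(raw, columns=taxa,
                         index=[f"site{i:04d}" for i in range(n_sites)])
    climate = pd.Series(temps, index=sites.index, name="temperature")
    optima = {t: r[0] for t, r in cfg.taxon_responses.items()}
    return sites, climate, optima


def simulate_path_data(
    coeffs: dict[str, float] | None = None,
    n: int = 3000,
    rho: float = 0.0,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Standardized driver→response system with known path coefficients.

    Predictors are unit-variance Gaussians (pairwise correlation ``rho``);
    the response is their linear combination plus Gaussian noise scaled so
    the response has unit variance. Returns (data with columns of the
    coefficient names plus ``ap``, true coefficients).
    """
    if coeffs is None:
        coeffs = {"insolation": 0.6, "ice": 0.3, "co2": 0.1}
    rng = np.random.default_rng(seed)
    names = list(coeffs)
    k = len(names)
    cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
    X = rng.multivariate_normal(np.zeros(k), cov, size=n)
    b = np.array([coeffs[nm] for nm in names])
    signal_var = float(b @ cov @ b)
    if signal_var >= 1:
        raise ValueError("coefficients imply variance >= 1; no room for noise")
    y = X @ b + rng.standard_normal(n) * np.sqrt(1 - signal_var)
    data = pd.DataFrame(X, columns=names)
    data["ap"] = y
    return data, dict(coeffs)
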