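"""Synthetic generators for gridded winter climate and effect-size datasets.

Both generators exist so that every downstream stage of the pipeline —
event detection, trend estimation, effect-size computation and the
multilevel meta-analysis — can be exercised against a known ground truth
without any reanalysis download.  The climate generator produces daily
maximum temperature, rainfall, snowfall and snow-water-equivalent fields
on a regular lat/lon grid; the effect-size generator produces a table of
control/response group summaries whose true underlying standardized mean
differences, variance components and phylogeny are returned alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import signal

__all__ = [
    "ClimateSimConfig",
    "MetaSimConfig",
    "simulate_climate",
    "simulate_effect_sizes",
    "random_ultrametric_tree",
    "balanced_ultrametric_tree",
    "paired_ultrametric_tree",
]

#: day-of-year at which the seasonal temperature cycle peaks (mid-July)
_PEAK_DOY = 197.0
_DAYS_PER_YEAR = 365.2425


@dataclass
class ClimateSimConfig:
    """Configuration of the gridded daily climate simulator.

    Temperatures are daily maxima in degrees Celsius, rain and snowfall are
    daily totals in mm, snow depth is mm of snow-water-equivalent (SWE).
    Defaults emulate a maritime low-Arctic cell: a strong seasonal cycle
    around a mean below freezing, red (AR(1)) day-to-day noise, and enough
    winter temperature variability that rare above-freezing rainy days —
    the rain-on-snow ingredients — occur a few times per decade per cell.
    """

    lat_min: float = 66.0
    lat_max: float = 70.0
    lon_min: float = 20.0
    lon_max: float = 24.0
    cell_size: float = 1.0
    year_start: int = 1950
    year_end: int = 1959
    #: annual-mean daily maximum temperature (°C)
    mean_temp: float = -6.0
    #: half peak-to-trough amplitude of the seasonal cycle (°C)
    seasonal_amplitude: float = 14.0
    #: SD of the per-cell constant temperature offset (°C)
    cell_offset_sd: float = 2.0
    #: secular warming trend applied to tmax (°C per year)
    trend: float = 0.0
    #: lag-1 autocorrelation of the tmax noise, in [0, 1)
    ar1: float = 0.65
    #: SD of the AR(1) innovations (°C)
    noise_sd: float = 3.5
    #: per-day probability that any precipitation falls
    precip_prob: float = 0.30
    #: gamma-distribution shape/scale of daily precipitation totals (mm)
    precip_shape: float = 0.7
    precip_scale: float = 5.0
    #: precipitation falls as snow when daily tmax is below this (°C)
    snow_temp: float = 0.5
    #: snowpack melt per degree-day above 0 °C (mm SWE / °C / day)
    melt_rate: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("lat", "lon"):
            lo = getattr(self, f"{name}_min")
            hi = getattr(self, f"{name}_max")
            if hi <= lo:
                raise ValueError(f"{name}_max must exceed {name}_min")
            span = hi - lo
            n = span / self.cell_size
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"cell_size {self.cell_size} does not evenly divide the "
                    f"{name} extent {span}"
                )
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("ar1 must lie in [0, 1)")
        if not 0.0 <= self.precip_prob <= 1.0:
            raise ValueError("precip_prob must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.precip_shape <= 0 or self.precip_scale <= 0:
            raise ValueError("precip_shape and precip_scale must be > 0")
        if self.melt_rate < 0:
            raise ValueError("melt_rate must be >= 0")


def _grid_centers(lo: float, hi: float, size: float) -> np.ndarray:
    n = int(round((hi - lo) / size))
    return lo + size * (np.arange(n) + 0.5)


def simulate_climate(config: ClimateSimConfig) -> xr.Dataset:
    """Simulate a daily climate cube.

    tmax is the sum of a cosine seasonal cycle (peaking in mid-July), a
    per-cell constant offset, a linear secular trend in whole calendar
    years since ``year_start``, and stationary AR(1) noise.  Precipitation
    occurs on random days with gamma-distributed totals and falls as snow
    when tmax is below ``snow_temp``; the snowpack is a simple bucket that
    accumulates snowfall and melts at ``melt_rate`` per degree-day above
    freezing.

    Returns an :class:`xarray.Dataset` with variables ``tasmax`` (°C),
    ``pr`` (mm/day rain), ``prsn`` (mm/day snowfall) and ``swe`` (mm SWE)
    on dimensions ``(time, lat, lon)``.  Bit-reproducible under a fixed
    seed; seed substreams are allocated per field so that adding a new
    field cannot perturb existing ones.
    """
    config.validate()
    lats = _grid_centers(config.lat_min, config.lat_max, config.cell_size)
    lons = _grid_centers(config.lon_min, config.lon_max, config.cell_size)
    time = pd.date_range(
        f"{config.year_start}-01-01", f"{config.year_end}-12-31", freq="D"
    )
    nt, ny, nx = len(time), len(lats), len(lons)

    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng_offset = np.random.default_rng(ss[0])
    rng_noise = np.random.default_rng(ss[1])
    rng_occ = np.random.default_rng(ss[2])
    rng_amt = np.random.default_rng(ss[3])

    doy = time.dayofyear.to_numpy(dtype=float)
    seasonal = config.mean_temp + config.seasonal_amplitude * np.cos(
        2.0 * math.pi * (doy - _PEAK_DOY) / _DAYS_PER_YEAR
    )
    trend = config.trend * (time.year.to_numpy() - config.year_start)
    offsets = rng_offset.normal(0.0, config.cell_offset_sd, size=(ny, nx))

    if config.noise_sd > 0:
        eps = rng_noise.normal(0.0, config.noise_sd, size=(nt, ny, nx))
        if config.ar1 > 0:
            # stationary start, then x_t = ar1 * x_{t-1} + eps_t via lfilter
            x0 = rng_noise.normal(
                0.0, config.noise_sd / math.sqrt(1.0 - config.ar1**2), size=(ny, nx)
            )
            zi = (config.ar1 * x0)[None, :, :]
            noise, _ = signal.lfilter(
                [1.0], [1.0, -config.ar1], eps, axis=0, zi=zi
            )
        else:
            noise = eps
    else:
        noise = np.zeros((nt, ny, nx))

    tasmax = (
        seasonal[:, None, None]
        + trend[:, None, None]
        + offsets[None, :, :]
        + noise
    )

    occurs = rng_occ.random(size=(nt, ny, nx)) < config.precip_prob
    amounts = rng_amt.gamma(
        config.precip_shape, config.precip_scale, size=(nt, ny, nx)
    )
    precip = np.where(occurs, amounts, 0.0)
    is_snow = tasmax < config.snow_temp
    prsn = np.where(is_snow, precip, 0.0)
    pr = np.where(~is_snow, precip, 0.0)

    swe = np.zeros((nt, ny, nx))
    melt_potential = config.melt_rate * np.maximum(tasmax, 0.0)
    pack = np.zeros((ny, nx))
    for t in range(nt):
        pack = np.maximum(pack + prsn[t] - melt_potential[t], 0.0)
        swe[t] = pack

    ds = xr.Dataset(
        {
            "tasmax": (("time", "lat", "lon"), tasmax, {"units": "degC"}),
            "pr": (("time", "lat", "lon"), pr, {"units": "mm/day"}),
            "prsn": (("time", "lat", "lon"), prsn, {"units": "mm/day"}),
            "swe": (("time", "lat", "lon"), swe, {"units": "mm"}),
        },
        coords={
            "time": time,
            "lat": ("lat", lats, {"units": "degrees_north"}),
            "lon": ("lon", lons, {"units": "degrees_east"}),
        },
        attrs={
            "source": "arcex.synthetic_data.simulate_climate",
            "cell_size_deg": config.cell_size,
            "seed": config.seed,
        },
    )
    return ds


# ---------------------------------------------------------------------------
# effect-size simulator
# ---------------------------------------------------------------------------


def _default_moderators() -> dict:
    return {
        "event_type": {"warming": 0.0, "rain-on-snow": 0.0},
        "study_type": {"experimental": 0.0, "observational": 0.0},
        "response_category": {"quantity": 0.0, "energetic": 0.0},
    }


@dataclass
class MetaSimConfig:
    """Configuration of the effect-size table simulator.

    The generative model mirrors the random-effect structure of the
    multilevel meta-analysis: every record's true standardized mean
    difference is

        theta_i = mu + moderator offsets + u_study + u_effect
                  + b_species + p_species,

    where ``u_study ~ N(0, sigma2_study)`` is shared within a study,
    ``u_effect ~ N(0, sigma2_effect)`` is record-specific, ``b_species ~
    N(0, sigma2_species)`` is an independent species effect and the vector
    of ``p_species`` across species is multivariate normal with covariance
    ``sigma2_phylo * A`` for the tree correlation matrix A.  Observed group
    summaries are then drawn from exact normal sampling distributions:
    group mean ~ N(mu_g, sd_g^2/n_g) and group variance ~
    sd_g^2 * chi2(n_g - 1) / (n_g - 1).
    """

    true_effect: float = -0.9
    sigma2_study: float = 0.4
    sigma2_effect: float = 0.3
    sigma2_species: float = 0.05
    sigma2_phylo: float = 0.1
    n_studies: int = 17
    effects_per_study: int = 11
    n_species: int = 49
    #: inclusive range of per-group sample sizes (years or replicates)
    n_range: tuple[int, int] = (4, 20)
    #: range of within-group population SDs (response units)
    sd_range: tuple[float, float] = (0.5, 2.0)
    moderators: dict = field(default_factory=_default_moderators)
    #: phylum labels cycled over species; kingdom derived from phylum
    phyla: tuple[str, ...] = (
        "Angiosperms",
        "Bryophyta",
        "Ascomycota",
        "Chordata",
        "Arthropoda",
    )
    #: "groups": emit control/response summaries to be run through the
    #: SMDH estimator (the full pipeline, with its estimated sampling
    #: variances).  "direct": observe d_i = theta_i + N(0, v_i) with the
    #: known v_i ~ U(v_range) reported in the table — the exact
    #: generative counterpart of the multilevel model, for estimator
    #: recovery studies.
    observation: str = "groups"
    v_range: tuple[float, float] = (0.05, 0.3)
    #: "random": seeded coalescent-style tree; "balanced": deterministic
    #: balanced tree; "paired": deterministic sister-pair ("cherries")
    #: tree used by estimator-recovery studies
    tree_shape: str = "random"
    #: "random": each record draws its species uniformly; "stratified":
    #: species are spread as evenly as possible over records (recovery
    #: studies — removes design noise from the species-level variance)
    species_assignment: str = "random"
    seed: int = 0

    def validate(self) -> None:
        for name in ("sigma2_study", "sigma2_effect", "sigma2_species", "sigma2_phylo"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_studies < 1 or self.effects_per_study < 1:
            raise ValueError("counts must be >= 1")
        if self.n_species < 1:
            if self.sigma2_phylo > 0:
                raise ValueError(
                    "zero species with nonzero phylogenetic variance"
                )
            raise ValueError("n_species must be >= 1")
        if self.n_range[0] < 2:
            raise ValueError("group sample sizes must be >= 2 (SD undefined below)")
        if self.sd_range[0] <= 0:
            raise ValueError("within-group SDs must be > 0")


_KINGDOM_OF = {
    "Angiosperms": "Plantae",
    "Bryophyta": "Plantae",
    "Ascomycota": "Fungi",
    "Chordata": "Animalia",
    "Arthropoda": "Animalia",
}


def random_ultrametric_tree(
    species: list[str], rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    """Build a random bifurcating ultrametric tree over ``species``.

    Lineages are merged pairwise at strictly increasing coalescent-style
    ages, then the root age is rescaled to 1 so tip depths are exactly 1.
    Returns the newick string (with branch lengths) and the corresponding
    correlation matrix ``A`` with ``A[i, j]`` = shared root-to-tip path
    fraction of species i and j.
    """
    k = len(species)
    if k == 1:
        return f"({species[0]}:1.0);", np.ones((1, 1))
    nodes = [(f"{s}", 0.0, [i]) for i, s in enumerate(species)]
    age = 0.0
    a_shared = np.zeros((k, k))  # MRCA age per pair
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        # coalescent-style waiting time: merge rate grows with lineage count
        age += rng.exponential(1.0 / len(nodes))
        (nwk_i, age_i, tips_i) = nodes[i]
        (nwk_j, age_j, tips_j) = nodes[j]
        for a in tips_i:
            for b in tips_j:
                a_shared[a, b] = a_shared[b, a] = age
        merged = (
            f"({nwk_i}:{age - age_i:.10f},{nwk_j}:{age - age_j:.10f})",
            age,
            tips_i + tips_j,
        )
        nodes = [n for t, n in enumerate(nodes) if t not in (i, j)]
        nodes.append(merged)
    root_age = age
    corr = 1.0 - a_shared / root_age
    np.fill_diagonal(corr, 1.0)
    return f"{nodes[0][0]};", corr


def paired_ultrametric_tree(species: list[str]) -> tuple[str, np.ndarray]:
    """Deterministic "cherries" tree: sister pairs joined at half depth.

    Consecutive species form sister pairs splitting at age 0.5; all pairs
    attach to the root (a polytomy), so A is block-diagonal with 0.5
    within pairs and 0 elsewhere.  With k species this yields k/2
    independent pair contrasts — the maximum-degrees-of-freedom design
    for separating the phylogenetic variance from the independent
    species variance, used by estimator-recovery studies.
    """
    k = len(species)
    if k == 1:
        return f"({species[0]}:1.0);", np.ones((1, 1))
    a = np.eye(k)
    parts = []
    i = 0
    while i < k:
        if i + 1 < k:
            a[i, i + 1] = a[i + 1, i] = 0.5
            parts.append(f"({species[i]}:0.5,{species[i + 1]}:0.5):0.5")
            i += 2
        else:
            parts.append(f"{species[i]}:1.0")
            i += 1
    return f"({','.join(parts)});", a


def balanced_ultrametric_tree(species: list[str]) -> tuple[str, np.ndarray]:
    """Deterministic balanced binary tree with equal split depths.

    Splits occur at evenly spaced ages, so pairwise shared-ancestry
    fractions take the graded values {0, 1/D, 2/D, ...} for tree depth
    D = ceil(log2 k).  This maximally even design separates the
    phylogenetic variance from the independent species variance and is
    the tree used for estimator-recovery studies; the random coalescent
    shape of :func:`random_ultrametric_tree` is the general-purpose
    default.
    """
    k = len(species)
    if k == 1:
        return f"({species[0]}:1.0);", np.ones((1, 1))
    depth = int(math.ceil(math.log2(k)))
    a = np.eye(k)
    idx = {s: i for i, s in enumerate(species)}

    def build(tips: list[str], level: int) -> tuple[str, float]:
        if len(tips) == 1:
            return tips[0], 0.0
        mid = len(tips) // 2
        share = 1.0 - (depth - level) / depth
        for x in tips[:mid]:
            for y in tips[mid:]:
                a[idx[x], idx[y]] = a[idx[y], idx[x]] = share
        left, age_l = build(tips[:mid], level + 1)
        right, age_r = build(tips[mid:], level + 1)
        age = (depth - level) / depth
        return f"({left}:{age - age_l:.10f},{right}:{age - age_r:.10f})", age

    nwk, _ = build(list(species), 0)
    return f"{nwk};", a


def simulate_effect_sizes(
    config: MetaSimConfig,
) -> tuple[pd.DataFrame, str, dict]:
    """Simulate a control/response summary table with known truth.

    Returns ``(table, newick, truth)`` where ``table`` has one row per
    effect size with study/species/moderator metadata and the six group
    summaries (n, mean, SD for control and response), ``newick`` is the
    simulated species tree, and ``truth`` carries the configured overall
    effect, variance components, per-record true effects and the tree
    correlation matrix for recovery tests.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed).spawn(3)
    rng_tree = np.random.default_rng(ss[0])
    rng_effects = np.random.default_rng(ss[1])
    rng_data = np.random.default_rng(ss[2])

    species = [f"sp_{i:03d}" for i in range(config.n_species)]
    if config.tree_shape == "balanced":
        newick, a_matrix = balanced_ultrametric_tree(species)
    elif config.tree_shape == "paired":
        newick, a_matrix = paired_ultrametric_tree(species)
    else:
        newick, a_matrix = random_ultrametric_tree(species, rng_tree)
    phylum_of = {
        s: config.phyla[i % len(config.phyla)] for i, s in enumerate(species)
    }

    # species-level random effects
    if config.sigma2_phylo > 0:
        chol = np.linalg.cholesky(
            config.sigma2_phylo * a_matrix
            + 1e-10 * np.eye(config.n_species)
        )
        phylo_fx = chol @ rng_effects.normal(size=config.n_species)
    else:
        phylo_fx = np.zeros(config.n_species)
    species_fx = rng_effects.normal(
        0.0, math.sqrt(config.sigma2_species), size=config.n_species
    )
    study_fx = rng_effects.normal(
        0.0, math.sqrt(config.sigma2_study), size=config.n_studies
    )

    n_records = config.n_studies * config.effects_per_study
    if config.species_assignment == "stratified":
        reps = -(-n_records // config.n_species)  # ceil
        pool = np.tile(np.arange(config.n_species), reps)[:n_records]
        species_sequence = rng_effects.permutation(pool)
    else:
        species_sequence = None

    mod_names = list(config.moderators)
    rows = []
    theta_true = []
    eid = 0
    for s_idx in range(config.n_studies):
        study_type = rng_effects.choice(
            list(config.moderators.get("study_type", {"experimental": 0.0}))
        )
        for _ in range(config.effects_per_study):
            if species_sequence is not None:
                sp_idx = int(species_sequence[eid])
            else:
                sp_idx = int(rng_effects.integers(config.n_species))
            levels = {}
            offset = 0.0
            for m in mod_names:
                table = config.moderators[m]
                if m == "study_type":
                    lev = study_type
                else:
                    lev = rng_effects.choice(list(table))
                levels[m] = lev
                offset += table[lev]
            u_effect = rng_effects.normal(
                0.0, math.sqrt(config.sigma2_effect)
            )
            theta = (
                config.true_effect
                + offset
                + study_fx[s_idx]
                + u_effect
                + phylo_fx[sp_idx]
                + species_fx[sp_idx]
            )
            phylum = phylum_of[species[sp_idx]]
            row = {
                "effect_id": f"es_{eid:04d}",
                "study_id": f"study_{s_idx:03d}",
                "species": species[sp_idx],
                "phylum": phylum,
                "kingdom": _KINGDOM_OF.get(phylum, "other"),
                **levels,
                "first_author": "Bokhorst" if s_idx % 2 == 0 else "other",
                "direction": 1,
            }
            if config.observation == "direct":
                v_i = rng_data.uniform(*config.v_range)
                row["smdh"] = theta + rng_data.normal(0.0, math.sqrt(v_i))
                row["variance"] = v_i
            else:
                n_c, n_r = rng_data.integers(
                    config.n_range[0], config.n_range[1] + 1, size=2
                )
                sd_c, sd_r = rng_data.uniform(*config.sd_range, size=2)
                s_pool = math.sqrt((sd_c**2 + sd_r**2) / 2.0)
                mu_c = rng_data.normal(0.0, 1.0)
                mu_r = mu_c + theta * s_pool
                mean_c = rng_data.normal(mu_c, sd_c / math.sqrt(n_c))
                mean_r = rng_data.normal(mu_r, sd_r / math.sqrt(n_r))
                obs_sd_c = sd_c * math.sqrt(
                    rng_data.chisquare(n_c - 1) / (n_c - 1)
                )
                obs_sd_r = sd_r * math.sqrt(
                    rng_data.chisquare(n_r - 1) / (n_r - 1)
                )
                row.update(
                    n_control=int(n_c),
                    mean_control=mean_c,
                    sd_control=obs_sd_c,
                    n_response=int(n_r),
                    mean_response=mean_r,
                    sd_response=obs_sd_r,
                )
            rows.append(row)
            theta_true.append(theta)
            eid += 1

    table = pd.DataFrame(rows)
    truth = {
        "true_effect": config.true_effect,
        "sigma2": {
            "study": config.sigma2_study,
            "effect": config.sigma2_effect,
            "species": config.sigma2_species,
            "phylo": config.sigma2_phylo,
        },
        "theta": np.asarray(theta_true),
        "species": species,
        "A": a_matrix,
        "phylo_effects": phylo_fx,
        "species_effects": species_fx,
        "study_effects": study_fx,
    }
    return table, newick, truth
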