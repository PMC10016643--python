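"""Synthetic inputs for the whole analysis.

Generates every input the pipeline consumes, with the statistical structure
the downstream methods assume:

* two diverged parental allele-frequency pools (wild and game-farm) under a
  Balding-Nichols-style model, plus reference genotypes from each;
* a cohort of known filial class (pure, F1, backcrosses) with per-sample
  sequencing-depth profiles reflecting ZW/ZZ sex chromosomes;
* a latitudinal precipitation-deuterium (d2H_p) isoscape on a regular grid
  with a breeding-range mask and two population polygons;
* feather d2H values tied to a drawn natal latitude with individual noise;
* banding-effort / direct-recovery counts for two source populations.

Everything is driven by a single :class:`SimConfig`; identical configs
(including the seed) give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .genodata import MISSING, DepthProfile, SnpMatrix
from .hybridsim import FILIAL_LABEL_RE, simulate_pedigree_individual
from .isoassign import BandingData, Isoscape

FEATHER_CALIB_INTERCEPT = -27.4  # feather-scale calibration: d2H_f = a + b * d2H_p
FEATHER_CALIB_SLOPE = 1.28


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the real study's shape at desk scale: a few thousand
    unlinked bi-allelic SNPs, two well-diverged parental pools, a harvest
    cohort dominated by wild and wild-backcrossed birds, a ~20-degree
    latitudinal d2H gradient and 12.8 permil individual feather noise.
    """

    n_loci: int = 2000
    divergence: float = 0.3  # F_ST-like separation of the parental pools
    n_ref_wild: int = 30
    n_ref_gfm: int = 30
    # wild reference birds carry residual game-farm ancestry U(0, bound):
    # wild populations are not perfectly pure, which is what makes a <=5%
    # alternative-assignment cutoff the natural pure-wild definition
    ref_wild_admixture: float = 0.05
    cohort_mix: Mapping[str, int] = field(
        default_factory=lambda: {
            "WILD": 40,
            "F1": 10,
            "F2_WMA": 10,
            "F3_WMA": 10,
            "FX_WMA": 40,
        }
    )
    missing_rate: float = 0.02
    # isoscape: d2H_p = iso_intercept + iso_slope * latitude (permil VSMOW)
    iso_intercept: float = 81.0
    iso_slope: float = -3.0  # permil per degree latitude
    iso_sd: float = 12.8  # individual feather noise, permil
    grid_shape: tuple[int, int] = (21, 41)  # rows (lat) x cols (lon)
    lat_range: tuple[float, float] = (40.0, 60.0)
    lon_range: tuple[float, float] = (-100.0, -60.0)
    pop_split_lon: float = -80.0  # west of this: mid-continent, east: eastern
    # natal-latitude model: truncated normal per class, mean shifted by class
    natal_lat_mean: float = 47.0
    natal_lat_sd: float = 4.0
    natal_lat_shift: Mapping[str, float] = field(
        default_factory=lambda: {"WILD": 3.0, "F1": -3.0}
    )
    # facultative migration: birds harvested later in the season come from
    # farther north, ~2.5 degrees across the 76-day season by default
    migration_trend: float = 0.033  # degrees natal latitude per harvest day
    harvest_day_max: int = 76  # 4 Oct (day 0) .. 19 Dec
    depth_mean: float = 118.0
    depth_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci <= 0 or self.n_ref_wild <= 0 or self.n_ref_gfm <= 0:
            raise ValueError("counts must be positive")
        if not 0 < self.divergence < 1:
            raise ValueError("divergence must be in (0, 1)")
        if self.iso_sd <= 0:
            raise ValueError("iso_sd must be > 0")
        if any(c <= 0 for c in self.cohort_mix.values()):
            raise ValueError("cohort_mix counts must be positive")
        if self.grid_shape[0] <= 0 or self.grid_shape[1] <= 0:
            raise ValueError("grid_shape must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort_mix"] = dict(self.cohort_mix)
        d["natal_lat_shift"] = dict(self.natal_lat_shift)
        return d


def _autosomal_meta(n_loci: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(n_loci)],
            "chrom_class": "autosome",
            "pos": np.arange(1, n_loci + 1) * 100,
        }
    )


def gen_parental_pools(
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray, SnpMatrix, pd.Series]:
    """Draw wild and game-farm allele-frequency pools and reference genotypes.

    Pool frequencies follow a Balding-Nichols-style model: a shared ancestral
    frequency p0 ~ Uniform(0.05, 0.95) per locus, then each pool draws
    independently from Beta(p0 (1-F)/F, (1-p0)(1-F)/F) with F = ``divergence``.

    Returns (wild_freqs, gfm_freqs, reference SnpMatrix, labels), where labels
    is a Series over reference sample ids with values "WILD"/"GFM".
    """
    rng = np.random.default_rng(config.seed)
    F = config.divergence
    p0 = rng.uniform(0.05, 0.95, size=config.n_loci)
    a = p0 * (1 - F) / F
    b = (1 - p0) * (1 - F) / F
    wild = rng.beta(a, b)
    gfm = rng.beta(a, b)
    n_w, n_g = config.n_ref_wild, config.n_ref_gfm
    # per-bird residual game-farm fraction in the wild reference panel
    admix = rng.uniform(0.0, config.ref_wild_admixture, size=n_w)
    mix = (1 - admix[:, None]) * wild[None, :] + admix[:, None] * gfm[None, :]
    geno = np.vstack(
        [
            rng.binomial(2, mix),
            rng.binomial(2, gfm, size=(n_g, config.n_loci)),
        ]
    ).astype(np.int8)
    ids = [f"refW{i}" for i in range(n_w)] + [f"refG{i}" for i in range(n_g)]
    labels = pd.Series(["WILD"] * n_w + ["GFM"] * n_g, index=ids, name="pool")
    _inject_missing(geno, config.missing_rate, rng)
    ref = SnpMatrix(geno, _autosomal_meta(config.n_loci), ids)
    return wild, gfm, ref, labels


def _inject_missing(geno: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if rate > 0:
        geno[rng.random(geno.shape) < rate] = MISSING


def gen_isoscape(config: SimConfig) -> Isoscape:
    """Linear latitudinal d2H_p surface with range mask and population polygons."""
    rows, cols = config.grid_shape
    # row 0 = northernmost (raster convention)
    lats = np.linspace(config.lat_range[1], config.lat_range[0], rows)
    lons = np.linspace(config.lon_range[0], config.lon_range[1], cols)
    values = config.iso_intercept + config.iso_slope * lats[:, None]
    values = np.broadcast_to(values, (rows, cols)).copy()
    mask = np.ones((rows, cols), dtype=bool)
    pop = np.where(lons[None, :] < config.pop_split_lon, "mid-continent", "eastern")
    pop = np.broadcast_to(pop, (rows, cols)).copy()
    return Isoscape(values=values, mask=mask, lats=lats, lons=lons, pop_labels=pop)


def gen_cohort(
    config: SimConfig,
    wild_freqs: np.ndarray,
    gfm_freqs: np.ndarray,
    isoscape: Isoscape | None = None,
) -> tuple[SnpMatrix, pd.Series, DepthProfile, pd.DataFrame]:
    """Simulate the harvested cohort: genotypes, sex/depth, and feather samples.

    Each individual's genotypes follow the pedigree of its true filial class
    (pure pools, F1 = one allele per pool, Fg = backcross chain). Sex is drawn
    1:1; ZW females get half-depth Z and present W loci, ZZ males full-depth Z
    and no W reads. Feather d2H_f is the feather-calibrated isoscape value at
    a class-dependent truncated-normal natal latitude plus N(0, iso_sd) noise.

    Returns (cohort SnpMatrix, truth labels, DepthProfile, samples DataFrame
    with columns sample_id, d2hf, day, sex, klass, natal_lat).
    """
    if len(wild_freqs) != len(gfm_freqs):
        raise ValueError("frequency vectors differ in length")
    if isoscape is None:
        isoscape = gen_isoscape(config)
    rng = np.random.default_rng(config.seed + 1)
    genos: list[np.ndarray] = []
    labels: list[str] = []
    ids: list[str] = []
    for klass, count in config.cohort_mix.items():
        if not FILIAL_LABEL_RE.match(klass):
            raise ValueError(f"unknown filial class {klass!r}")
        for i in range(count):
            genos.append(
                simulate_pedigree_individual(klass, wild_freqs, gfm_freqs, rng)
            )
            labels.append(klass)
            ids.append(f"{klass}_{i}")
    geno = np.asarray(genos, dtype=np.int8)
    _inject_missing(geno, config.missing_rate, rng)
    cohort = SnpMatrix(geno, _autosomal_meta(len(wild_freqs)), ids)
    truth = pd.Series(labels, index=ids, name="filial_class")

    n = len(ids)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    auto_d = config.depth_mean * (1 + config.depth_cv * rng.standard_normal(n))
    auto_d = np.clip(auto_d, 1.0, None)
    z_noise = 1 + config.depth_cv * rng.standard_normal(n)
    w_noise = 1 + config.depth_cv * rng.standard_normal(n)
    is_f = sex == "female"
    z_d = np.where(is_f, 0.5, 1.0) * auto_d * np.clip(z_noise, 0.5, 1.5)
    w_d = np.where(is_f, 0.5 * auto_d * np.clip(w_noise, 0.5, 1.5), 0.0)
    depth = DepthProfile(
        pd.DataFrame(
            {
                "sample_id": ids,
                "autosome_depth": auto_d,
                "z_depth": z_d,
                "w_depth": w_d,
            }
        )
    )

    lat_lo, lat_hi = isoscape.lats.min(), isoscape.lats.max()
    day = rng.integers(0, config.harvest_day_max + 1, size=n)
    mid_day = config.harvest_day_max / 2
    natal_lat = np.empty(n)
    for i, klass in enumerate(labels):
        mu = (
            config.natal_lat_mean
            + config.natal_lat_shift.get(klass, 0.0)
            + config.migration_trend * (day[i] - mid_day)
        )
        lat = rng.normal(mu, config.natal_lat_sd)
        while not lat_lo <= lat <= lat_hi:  # truncation to the grid
            lat = rng.normal(mu, config.natal_lat_sd)
        natal_lat[i] = lat
    # feather value = calibrated isoscape at natal latitude + individual noise
    d2hp = config.iso_intercept + config.iso_slope * natal_lat
    d2hf = (
        FEATHER_CALIB_INTERCEPT
        + FEATHER_CALIB_SLOPE * d2hp
        + rng.normal(0.0, config.iso_sd, size=n)
    )
    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "d2hf": d2hf,
            "day": day,
            "sex": sex,
            "klass": labels,
            "natal_lat": natal_lat,
        }
    )
    return cohort, truth, depth, samples


def gen_banding_data(
    config: SimConfig,
    bands_placed: Mapping[str, int] | None = None,
    direct_recoveries: Mapping[str, int] | None = None,
) -> BandingData:
    """Banding-effort and direct-recovery counts for the two source populations.

    Defaults give the mid-continent a 2x effort-adjusted recovery rate over
    the eastern population (recoveries 120/80 on 60k/80k bands placed).
    """
    bands = dict(bands_placed or {"mid-continent": 60_000, "eastern": 80_000})
    recov = dict(direct_recoveries or {"mid-continent": 120, "eastern": 80})
    return BandingData(
        pd.DataFrame(
            {
                "population": list(bands),
                "bands_placed": [bands[k] for k in bands],
                "direct_recoveries": [recov[k] for k in bands],
            }
        )
    )
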