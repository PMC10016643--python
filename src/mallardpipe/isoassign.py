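"""Feather-isotope geographic assignment.

A precipitation-deuterium isoscape (d2H_p) is rescaled to the feather scale
(d2H_f = -27.4 + 1.28 * d2H_p, a published mallard calibration), each bird's
feather value compared against every raster cell with a normal likelihood
(sd = 12.8 permil, the expected individual variation), and Bayes' theorem
applied to get a posterior origin surface per bird. Origins are summarized as
2:1-odds regions (smallest cell set holding 2/3 of the posterior), summed
count maps over cohorts, a local/immigrant call against the expected local
feather value, and band-recovery-weighted priors over source-population
polygons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_SD = 12.8  # permil; expected individual variation in d2H_f
DEFAULT_LOCAL_INTERVAL = (-84.5, -82.5)  # expected local d2H_f, permil
RESCALE_INTERCEPT = -27.4
RESCALE_SLOPE = 1.28


@dataclass
class Isoscape:
    """Regular lat/lon grid of d2H values with range mask and population labels.

    Row 0 is the northernmost row; coordinates are cell centers. ``mask`` is
    True inside the breeding range; ``pop_labels`` holds "eastern",
    "mid-continent" or "none" per cell.
    """

    values: np.ndarray
    mask: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    pop_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape != (len(self.lats), len(self.lons)):
            raise ValueError("grid shape inconsistent with coordinate vectors")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite value inside mask")
        if self.pop_labels is None:
            self.pop_labels = np.full(self.values.shape, "none", dtype=object)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def intersect_mask(self, other_mask: np.ndarray) -> "Isoscape":
        """Clip the breeding range by another boolean mask (e.g. a meridian cut)."""
        return Isoscape(
            self.values.copy(), self.mask & other_mask,
            self.lats.copy(), self.lons.copy(), np.array(self.pop_labels),
        )

    def mask_west_of(self, meridian: float) -> "Isoscape":
        keep = np.broadcast_to(self.lons[None, :] >= meridian, self.shape)
        return self.intersect_mask(keep)


@dataclass
class AssignmentSurface:
    """Per-cell posterior (sums to 1 over unmasked cells) and odds region."""

    posterior: np.ndarray
    mask: np.ndarray
    region: np.ndarray | None = None  # 0/1 after odds_region
    counts: np.ndarray | None = None  # integer grid after sum_surfaces

    def __post_init__(self) -> None:
        if self.posterior is not None:
            total = self.posterior[self.mask].sum()
            if abs(total - 1.0) > 1e-9:
                raise ValueError("posterior must sum to 1 over unmasked cells")
            if np.any(self.posterior[~self.mask] != 0):
                raise ValueError("posterior must be zero outside the mask")
        if self.region is not None and np.any(self.region.astype(bool) & ~self.mask):
            raise ValueError("odds region extends outside the mask")


@dataclass
class BandingData:
    """Bands placed and direct recoveries per source population."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"population", "bands_placed", "direct_recoveries"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"BandingData missing columns: {sorted(missing)}")
        t = self.table
        if (t["bands_placed"] <= 0).any():
            raise ValueError("bands_placed must be > 0")
        if (t["direct_recoveries"] < 0).any():
            raise ValueError("direct_recoveries must be >= 0")
        if (t["direct_recoveries"] > t["bands_placed"]).any():
            raise ValueError("recoveries exceed bands placed")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def rescale_isoscape(
    precip: Isoscape,
    intercept: float = RESCALE_INTERCEPT,
    slope: float = RESCALE_SLOPE,
) -> Isoscape:
    """Map a d2H_p surface to the feather scale: d2H_f = intercept + slope * d2H_p."""
    return Isoscape(
        intercept + slope * precip.values, precip.mask.copy(),
        precip.lats.copy(), precip.lons.copy(), np.array(precip.pop_labels),
    )


def posterior_surface(
    y: float,
    iso: Isoscape,
    sd: float = DEFAULT_SD,
    prior: np.ndarray | None = None,
) -> AssignmentSurface:
    """Bayes posterior that each unmasked cell is the bird's natal cell.

    posterior(c) proportional to prior(c) * Normal(y; mu_c, sd); uniform prior
    when none given; normalized to sum to 1 over unmasked cells.
    """
    if not np.isfinite(y):
        raise ValueError("feather value must be finite")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    like = np.zeros(iso.shape)
    like[iso.mask] = norm.pdf(y, loc=iso.values[iso.mask], scale=sd)
    if prior is not None:
        prior = np.asarray(prior, dtype=float)
        if prior.shape != iso.shape:
            raise ValueError("prior shape mismatch")
        if np.any(prior < 0) or prior[iso.mask].sum() == 0:
            raise ValueError("prior must be non-negative and not all zero on mask")
        like = like * prior
    total = like[iso.mask].sum()
    if total == 0:
        raise ValueError("posterior degenerate: zero likelihood everywhere on mask")
    post = np.zeros(iso.shape)
    post[iso.mask] = like[iso.mask] / total
    return AssignmentSurface(post, iso.mask.copy())


def odds_region(s: AssignmentSurface, odds: float = 2.0) -> AssignmentSurface:
    """Binarize a posterior at the given odds (2:1 keeps the upper 2/3).

    Cells are sorted by posterior descending (stable in flat cell order for
    ties); the smallest prefix whose cumulative probability reaches
    odds/(odds+1) is coded 1, all other cells 0.
    """
    target = odds / (odds + 1.0)
    flat = s.posterior.ravel()
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    n_keep = int(np.searchsorted(csum, target - 1e-12) + 1)
    n_keep = min(n_keep, int(s.mask.sum()))
    region = np.zeros(flat.shape, dtype=np.int64)
    region[order[:n_keep]] = 1
    region = region.reshape(s.posterior.shape)
    # minimality: dropping the smallest selected cell falls below the target
    if n_keep > 1:
        assert csum[n_keep - 2] < target
    return AssignmentSurface(s.posterior.copy(), s.mask.copy(), region=region)


def sum_surfaces(regions: Sequence[AssignmentSurface]) -> AssignmentSurface:
    """Per-cell count of individuals whose odds region covers the cell."""
    if not regions:
        raise ValueError("no surfaces to sum")
    shape = regions[0].mask.shape
    counts = np.zeros(shape, dtype=np.int64)
    for r in regions:
        if r.region is None:
            raise ValueError("surface has no odds region; call odds_region first")
        if r.mask.shape != shape:
            raise ValueError("grid mismatch")
        counts += r.region
    out = AssignmentSurface(None, regions[0].mask.copy(), counts=counts)
    return out


def classify_local(
    y: float,
    expected_local: tuple[float, float] = DEFAULT_LOCAL_INTERVAL,
    sd: float = DEFAULT_SD,
) -> str:
    """"local" if y is within one sd of the expected local feather interval.

    Distance is measured to the closest point of the interval (zero inside);
    the sd boundary is inclusive.
    """
    lo, hi = expected_local
    if lo > hi:
        raise ValueError("expected_local interval must be ordered (lo, hi)")
    dist = max(lo - y, y - hi, 0.0)
    return "local" if dist <= sd else "immigrant"


def banding_weights(
    b: BandingData, iso: Isoscape
) -> tuple[dict[str, float], np.ndarray]:
    """Effort-adjusted recovery weights per population, spread over its polygon.

    rate_k = direct recoveries / bands placed; weight_k = rate_k / sum(rates).
    The prior raster puts weight_k uniformly across population k's cells
    (weight_k / n_cells_k each) and zero elsewhere.
    """
    t = b.table
    rates = t["direct_recoveries"] / t["bands_placed"]
    total = rates.sum()
    if total == 0:
        raise ValueError("all recovery rates are zero; prior undefined")
    weights = {
        str(pop): float(r / total) for pop, r in zip(t["population"], rates)
    }
    prior = np.zeros(iso.shape)
    labels = np.asarray(iso.pop_labels)
    for pop, w in weights.items():
        cells = (labels == pop) & iso.mask
        n_cells = int(cells.sum())
        if n_cells == 0:
            continue
        prior[cells] = w / n_cells
    return weights, prior


# ---------------------------------------------------------------------------
# ASCII-grid raster I/O (6-line header; bit-identical round trip)
# ---------------------------------------------------------------------------


def write_ascii_grid(values: np.ndarray, lats: np.ndarray, lons: np.ndarray,
                     path: str, nodata: float = -9999.0,
                     mask: np.ndarray | None = None) -> None:
    rows, cols = values.shape
    cellsize = float(abs(lons[1] - lons[0])) if cols > 1 else 1.0
    out = np.array(values, dtype=float)
    if mask is not None:
        out = np.where(mask, out, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write(f"xllcorner {float(lons[0] - cellsize / 2)!r}\n")
        fh.write(f"yllcorner {float(lats[-1] - cellsize / 2)!r}\n")
        fh.write(f"cellsize {float(cellsize)!r}\n")
        fh.write(f"NODATA_value {float(nodata)!r}\n")
        for r in range(rows):
            fh.write(" ".join(repr(float(v)) for v in out[r]) + "\n")


def read_ascii_grid(path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Read an ASCII grid; returns (values, mask, lats, lons)."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (rows, cols):
        raise ValueError(f"grid body {values.shape} does not match header")
    cs = header["cellsize"]
    lons = header["xllcorner"] + cs / 2 + cs * np.arange(cols)
    lat0 = header["yllcorner"] + cs / 2 + cs * (rows - 1)
    lats = lat0 - cs * np.arange(rows)
    mask = values != header["nodata_value"]
    return values, mask, lats, lons


def nearest_cell(iso: Isoscape, lat: float, lon: float) -> tuple[int, int]:
    """Grid indices of the cell whose center is nearest to (lat, lon)."""
    return int(np.argmin(np.abs(iso.lats - lat))), int(np.argmin(np.abs(iso.lons - lon)))
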