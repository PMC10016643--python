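"""Genotype matrix container, I/O, SNP filtering, LD pruning and depth-based sexing.

The central object is :class:`SnpMatrix`: an individuals x loci matrix of
alternate-allele counts (0/1/2, ``-1`` for missing) for bi-allelic SNPs, with
per-locus metadata recording the chromosome class (autosome / Z / W) so that
population-structure analyses can be restricted to autosomal loci and sex can
be called from sequencing depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

CHROM_CLASSES = ("autosome", "Z", "W")


@dataclass
class SnpMatrix:
    """Bi-allelic genotypes as alt-allele counts.

    Parameters
    ----------
    genotypes : (n_samples, n_loci) int array
        Entries in {0, 1, 2} or ``MISSING`` (-1).
    locus_meta : DataFrame
        Columns ``id`` (str), ``chrom_class`` in {"autosome", "Z", "W"},
        ``pos`` (int).
    sample_ids : list of str
    """

    genotypes: np.ndarray
    locus_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x loci)")
        n, L = self.genotypes.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.locus_meta) != L:
            raise ValueError(f"{len(self.locus_meta)} locus rows for {L} columns")
        bad = set(self.locus_meta["chrom_class"]) - set(CHROM_CLASSES)
        if bad:
            raise ValueError(f"unknown chromosome class(es): {sorted(bad)}")
        vals = np.unique(self.genotypes)
        if not np.all(np.isin(vals, [MISSING, 0, 1, 2])):
            raise ValueError("genotypes must be in {0,1,2} or -1 (missing)")
        self.locus_meta = self.locus_meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def take_loci(self, idx: np.ndarray | Sequence[int]) -> "SnpMatrix":
        idx = np.asarray(idx)
        return SnpMatrix(
            self.genotypes[:, idx],
            self.locus_meta.iloc[idx].reset_index(drop=True),
            list(self.sample_ids),
        )

    def take_samples(self, idx: np.ndarray | Sequence[int]) -> "SnpMatrix":
        idx = np.asarray(idx)
        return SnpMatrix(
            self.genotypes[idx, :],
            self.locus_meta.copy(),
            [self.sample_ids[i] for i in idx],
        )

    def autosomal(self) -> "SnpMatrix":
        keep = np.flatnonzero((self.locus_meta["chrom_class"] == "autosome").to_numpy())
        return self.take_loci(keep)

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per locus over non-missing genotypes (NaN if all missing)."""
        g = self.genotypes.astype(float)
        g[self.genotypes == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(g, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def as_float(self) -> np.ndarray:
        """Genotypes as float with NaN for missing."""
        g = self.genotypes.astype(float)
        g[self.genotypes == MISSING] = np.nan
        return g


def concat_samples(matrices: Iterable[SnpMatrix]) -> SnpMatrix:
    """Stack matrices sample-wise; loci must agree in id and order."""
    mats = list(matrices)
    ref_ids = mats[0].locus_meta["id"].to_numpy()
    for m in mats[1:]:
        if not np.array_equal(m.locus_meta["id"].to_numpy(), ref_ids):
            raise ValueError("locus sets differ; cannot concatenate samples")
    return SnpMatrix(
        np.vstack([m.genotypes for m in mats]),
        mats[0].locus_meta.copy(),
        [s for m in mats for s in m.sample_ids],
    )


@dataclass
class DepthProfile:
    """Per-sample mean sequencing depth by chromosome class (reads/locus)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"sample_id", "autosome_depth", "z_depth", "w_depth"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DepthProfile missing columns: {sorted(missing)}")
        for col in ("autosome_depth", "z_depth", "w_depth"):
            if (self.table[col] < 0).any():
                raise ValueError(f"negative depth in {col}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=mallardpipe
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

# chromosome names carrying sex-linked loci in our VCF dialect
_CLASS_TO_CHROM = {"autosome": "chrA", "Z": "chrZ", "W": "chrW"}
_CHROM_TO_CLASS = {v: k for k, v in _CLASS_TO_CHROM.items()}


def write_genotypes(m: SnpMatrix, path: str, format: str = "vcf") -> None:
    """Write a SnpMatrix as VCF (v4.2, GT only) or TSV (samples x loci).

    The TSV dialect writes a companion ``<path>.loci.tsv`` with locus metadata
    so chromosome classes survive the round trip.
    """
    if format == "vcf":
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(m.sample_ids)
                + "\n"
            )
            for j in range(m.n_loci):
                meta = m.locus_meta.iloc[j]
                chrom = _CLASS_TO_CHROM[meta["chrom_class"]]
                gts = "\t".join(_GT_CODE[int(g)] for g in m.genotypes[:, j])
                fh.write(
                    f"{chrom}\t{int(meta['pos'])}\t{meta['id']}\tA\tT\t.\t.\t.\tGT\t{gts}\n"
                )
    elif format == "tsv":
        body = np.where(
            m.genotypes == MISSING, ".", m.genotypes.astype(str)
        )
        df = pd.DataFrame(body, index=m.sample_ids, columns=m.locus_meta["id"])
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
        m.locus_meta.to_csv(f"{path}.loci.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_genotypes(path: str, format: str = "vcf") -> SnpMatrix:
    """Read genotypes from VCF or TSV; multi-allelic VCF records are skipped."""
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path: str) -> SnpMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    sample_ids = list(vcf.samples)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    classes: list[str] = []
    pos: list[int] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING  # gts012: 3 == unknown
        cols.append(gt)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        classes.append(_CHROM_TO_CLASS.get(var.CHROM, "autosome"))
        pos.append(var.POS)
    vcf.close()
    if n_skipped:
        logger.info("skipped %d multi-allelic record(s) in %s", n_skipped, path)
    if not cols:
        raise ValueError(f"no bi-allelic loci in {path}")
    meta = pd.DataFrame({"id": ids, "chrom_class": classes, "pos": pos})
    return SnpMatrix(np.column_stack(cols), meta, sample_ids)


def _read_tsv(path: str) -> SnpMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValueError(f"no loci in {path}")
    geno = df.replace(".", str(MISSING)).astype(np.int8).to_numpy()
    try:
        meta = pd.read_csv(f"{path}.loci.tsv", sep="\t")
    except FileNotFoundError:
        meta = pd.DataFrame(
            {
                "id": df.columns,
                "chrom_class": "autosome",
                "pos": np.arange(1, df.shape[1] + 1),
            }
        )
    return SnpMatrix(geno, meta, list(df.index))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_snps(
    m: SnpMatrix, maf_min: float = 0.0023, max_missing: float = 0.05
) -> SnpMatrix:
    """Remove low-frequency and high-missingness loci.

    A locus is retained iff its minor-allele frequency (over non-missing
    genotypes) is >= ``maf_min`` and its missing fraction is strictly below
    ``max_missing``. With the default ``maf_min`` = 0.0023, singleton alleles
    in a cohort of ~296 diploids (1/592 ~ 0.0017) are removed. Locus order is
    preserved; the result may be empty.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    p = m.allele_frequencies()
    maf = np.minimum(p, 1 - p)
    miss = m.missing_fraction()
    with np.errstate(invalid="ignore"):
        keep = (maf >= maf_min) & (miss < max_missing)
    keep &= ~np.isnan(p)  # all-missing loci never survive
    dropped = int((~keep).sum())
    if dropped:
        logger.debug("filter_snps dropped %d of %d loci", dropped, m.n_loci)
    return m.take_loci(np.flatnonzero(keep))


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of genotype counts over jointly non-missing samples.

    Returns NaN when either locus is monomorphic among the shared samples
    (the correlation is undefined there).
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    if xs.std() == 0 or ys.std() == 0:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(
    m: SnpMatrix,
    window: int = 2,
    step: int = 1,
    r2_max: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> SnpMatrix:
    """Sliding-window LD pruning (PLINK ``--indep-pairwise``-style, SNP-count window).

    Within each window of ``window`` loci (advanced by ``step``), whenever a
    surviving pair has squared genotype correlation r^2 > ``r2_max``, one
    member of the pair is removed at random (seeded). Pairs with undefined r^2
    (monomorphic locus) are treated as unlinked.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    alive = np.ones(m.n_loci, dtype=bool)
    G = m.genotypes
    start = 0
    while start < m.n_loci:
        idx = [j for j in range(start, min(start + window, m.n_loci)) if alive[j]]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                ja, jb = idx[a], idx[b]
                if not (alive[ja] and alive[jb]):
                    continue
                r2 = pairwise_r2(G[:, ja], G[:, jb])
                if np.isnan(r2):
                    logger.debug("r2 undefined for loci %d,%d; kept both", ja, jb)
                    continue
                if r2 > r2_max:
                    drop = ja if rng.random() < 0.5 else jb
                    alive[drop] = False
        start += step
    return m.take_loci(np.flatnonzero(alive))


# ---------------------------------------------------------------------------
# Sex assignment from depth
# ---------------------------------------------------------------------------


def assign_sex(
    d: DepthProfile,
    z_female_max: float = 0.65,
    z_male_min: float = 0.85,
    w_presence_min: float = 0.05,
) -> pd.Series:
    """Call sex from Z/autosome and W/autosome depth ratios.

    The heterogametic sex (female, ZW) carries one Z and one W, so both
    sex-chromosome depth ratios sit near 0.5x the autosomal depth; males (ZZ)
    show a Z ratio near 1.0x and essentially no W-linked reads. Samples
    between the thresholds are reported as "ambiguous", never coerced.
    """
    t = d.table
    if (t["autosome_depth"] <= 0).any():
        bad = t.loc[t["autosome_depth"] <= 0, "sample_id"].tolist()
        raise ValueError(f"autosomal depth must be > 0 (samples {bad})")
    z_ratio = t["z_depth"] / t["autosome_depth"]
    w_ratio = t["w_depth"] / t["autosome_depth"]
    sex = pd.Series("ambiguous", index=t["sample_id"].to_numpy(), name="sex")
    sex[((z_ratio <= z_female_max) & (w_ratio >= w_presence_min)).to_numpy()] = "female"
    sex[((z_ratio >= z_male_min) & (w_ratio < w_presence_min)).to_numpy()] = "male"
    return sex
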