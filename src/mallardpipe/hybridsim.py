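"""Hybrid and backcross simulation, generation bands, filial-class assignment.

Filial-class cutoffs are calibrated by simulation: F1 hybrids are built by
sampling one allele per locus from each parental gene pool, and backcross
generations F2..F10 by crossing the previous generation against the recurrent
pool, so generation g carries expected 2^-g ancestry from the non-recurrent
pool (loci are treated as unlinked throughout). Simulated hybrids are appended
to the reference panel, the K=2 admixture model fitted repeatedly, replicates
aligned, and per-generation bands (mean/min/max wild-cluster q) extracted.
Empirical samples are then classified against those bands.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ancestry
from .genodata import SnpMatrix, concat_samples

logger = logging.getLogger(__name__)

FILIAL_CLASSES = ("WILD", "GFM", "F1", "F2_WMA", "F3_WMA", "FX_WMA", "FX_GFM")

# accepted truth labels for simulation: pure pools, F1, or Fg backcrosses of
# any generation toward either pool (FX_* draws a random generation >= 4)
FILIAL_LABEL_RE = re.compile(r"^(WILD|GFM|F1|F(\d+)_(WMA|GFM)|FX_(WMA|GFM))$")


@dataclass
class GenerationBand:
    """Wild-cluster assignment-probability band of one simulated generation."""

    generation: str  # "F1" .. "F10"
    direction: str | None  # recurrent pool: "wild" / "game-farm"; None for F1
    mean: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (0 <= self.min <= self.mean <= self.max <= 1):
            raise ValueError("band must satisfy 0 <= min <= mean <= max <= 1")

    def contains(self, q: float) -> bool:
        return self.min <= q <= self.max


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------


def _pool_gametes(freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return (rng.random(len(freqs)) < freqs).astype(np.int8)


def simulate_f1(
    wild_freqs: np.ndarray,
    gfm_freqs: np.ndarray,
    n: int = 10,
    seed: int | np.random.Generator = 0,
    locus_meta: pd.DataFrame | None = None,
) -> SnpMatrix:
    """F1 hybrids: one allele from each parental pool at every locus."""
    if len(wild_freqs) != len(gfm_freqs):
        raise ValueError("frequency vectors differ in length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(wild_freqs)
    geno = np.empty((n, L), dtype=np.int8)
    for i in range(n):
        geno[i] = _pool_gametes(wild_freqs, rng) + _pool_gametes(gfm_freqs, rng)
    if locus_meta is None:
        locus_meta = pd.DataFrame(
            {"id": [f"snp{j}" for j in range(L)], "chrom_class": "autosome",
             "pos": np.arange(1, L + 1) * 100}
        )
    elif len(locus_meta) != L:
        raise ValueError("locus_meta length does not match frequency vectors")
    return SnpMatrix(geno, locus_meta.copy(), [f"F1_{i}" for i in range(n)])


def _transmit(genotype: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a diploid genotype, independent per locus (unlinked)."""
    het = genotype == 1
    gam = (genotype // 2).astype(np.int8)  # 0 -> 0, 2 -> 1
    gam[het] = (rng.random(het.sum()) < 0.5).astype(np.int8)
    return gam


def simulate_backcrosses(
    f1: SnpMatrix,
    parental_freqs: np.ndarray,
    direction: str,
    generations: range | list[int] = range(2, 11),
    n_per_gen: int = 5,
    seed: int | np.random.Generator = 0,
) -> dict[str, SnpMatrix]:
    """Backcross lineages toward the recurrent pool for generations F2..F10.

    ``n_per_gen`` F1 individuals each found a lineage; at every step the
    current individual contributes one transmitted allele per locus and the
    recurrent pool the other, halving the non-recurrent ancestry per
    generation.
    """
    if f1.n_samples == 0:
        raise ValueError("empty previous generation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gens = list(generations)
    n_found = min(n_per_gen, f1.n_samples)
    current = [f1.genotypes[i].copy() for i in range(n_found)]
    out: dict[str, SnpMatrix] = {}
    tag = "WMA" if direction == "wild" else "GFM"
    for g in gens:
        nxt = [
            _transmit(geno, rng) + _pool_gametes(parental_freqs, rng)
            for geno in current
        ]
        geno = np.asarray(nxt, dtype=np.int8)
        out[f"F{g}"] = SnpMatrix(
            geno, f1.locus_meta.copy(),
            [f"F{g}{tag}_{i}" for i in range(len(nxt))],
        )
        current = nxt
    return out


def simulate_pedigree_individual(
    klass: str,
    wild_freqs: np.ndarray,
    gfm_freqs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotypes of one individual of a given true filial class.

    ``FX_WMA`` / ``FX_GFM`` ("hybrid swarm") individuals are crosses of
    unknown generation (hybrid x hybrid, switched backcross directions):
    mixed ancestry that need not sit at any 2^-g expectation. They are drawn
    with a continuous wild-ancestry fraction a ~ U(0.55, 0.97) (WMA) or
    U(0.03, 0.45) (GFM) and genotypes Binomial(2, a p_wild + (1-a) p_gfm),
    the admixture model's own generative form.
    """
    m = FILIAL_LABEL_RE.match(klass)
    if not m:
        raise ValueError(f"unknown filial class {klass!r}")
    if klass == "WILD":
        return rng.binomial(2, wild_freqs).astype(np.int8)
    if klass == "GFM":
        return rng.binomial(2, gfm_freqs).astype(np.int8)
    if klass.startswith("FX"):
        a = rng.uniform(0.55, 0.97) if klass.endswith("WMA") else rng.uniform(0.03, 0.45)
        mix = a * wild_freqs + (1 - a) * gfm_freqs
        return rng.binomial(2, mix).astype(np.int8)
    geno = _pool_gametes(wild_freqs, rng) + _pool_gametes(gfm_freqs, rng)  # F1
    if klass == "F1":
        return geno
    gen = int(m.group(2))
    direction = "wild" if m.group(3) == "WMA" else "game-farm"
    recurrent = wild_freqs if direction == "wild" else gfm_freqs
    for _ in range(gen - 1):
        geno = _transmit(geno, rng) + _pool_gametes(recurrent, rng)
    return geno


def expected_nonrecurrent_ancestry(generation: int) -> float:
    """Expected ancestry from the non-recurrent pool at backcross generation g: 2^-g."""
    return 2.0 ** (-generation)


# ---------------------------------------------------------------------------
# Generation bands
# ---------------------------------------------------------------------------


def build_generation_bands(
    reference: SnpMatrix,
    wild_freqs: np.ndarray,
    gfm_freqs: np.ndarray,
    wild_ref_ids: list[str],
    n_sims: int = 10,
    reps_per_sim: int = 25,
    seed: int = 0,
    n_f1: int = 10,
    n_per_gen: int = 5,
    generations: range | list[int] = range(2, 11),
    tol: float = 1e-4,
    max_iter: int = 500,
) -> tuple[list[GenerationBand], float]:
    """Simulate hybrid generations, refit K=2 admixture, extract q bands.

    For each of ``n_sims`` independent simulations, simulated F1s and both
    backcross directions are appended to the reference panel and the K=2
    model fitted ``reps_per_sim`` times; replicates are aligned within each
    simulation and the wild cluster anchored by the reference wild samples.
    Per-generation statistics pool the simulated individuals of all
    simulations. Also returns the minimum wild-q observed among reference
    wild samples (the pure-wild range floor used in classification).
    """
    rng = np.random.default_rng(seed)
    wild_idx = [reference.sample_ids.index(s) for s in wild_ref_ids]
    per_group: dict[tuple[str, str | None], list[np.ndarray]] = {}
    wild_ref_qs: list[np.ndarray] = []
    for s in range(n_sims):
        f1 = simulate_f1(wild_freqs, gfm_freqs, n=n_f1, seed=rng,
                         locus_meta=reference.locus_meta)
        bc_w = simulate_backcrosses(
            f1, wild_freqs, "wild", generations, n_per_gen, seed=rng
        )
        bc_g = simulate_backcrosses(
            f1, gfm_freqs, "game-farm", generations, n_per_gen, seed=rng
        )
        blocks = [reference, f1] + list(bc_w.values()) + list(bc_g.values())
        combined = concat_samples(blocks)
        fits = [
            ancestry.fit_admixture(
                combined, K=2, seed=int(rng.integers(2**31)),
                tol=tol, max_iter=max_iter,
            )
            for _ in range(reps_per_sim)
        ]
        consensus = ancestry.align_replicates(fits)
        wild_col = int(np.argmax(consensus.Q_mean[wild_idx].mean(axis=0)))
        q_wild = consensus.Q_mean[:, wild_col]
        wild_ref_qs.append(q_wild[wild_idx])
        offset = reference.n_samples
        per_group.setdefault(("F1", None), []).append(
            q_wild[offset : offset + f1.n_samples]
        )
        offset += f1.n_samples
        for direction, bc in (("wild", bc_w), ("game-farm", bc_g)):
            for gen_label, mat in bc.items():
                per_group.setdefault((gen_label, direction), []).append(
                    q_wild[offset : offset + mat.n_samples]
                )
                offset += mat.n_samples
    bands = []
    for (gen_label, direction), chunks in per_group.items():
        q = np.concatenate(chunks)
        bands.append(
            GenerationBand(gen_label, direction, float(q.mean()),
                           float(q.min()), float(q.max()))
        )
    wild_ref_min = float(np.concatenate(wild_ref_qs).min())
    return bands, wild_ref_min


def bands_to_frame(bands: list[GenerationBand]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"generation": b.generation, "direction": b.direction or "",
             "mean": b.mean, "min": b.min, "max": b.max}
            for b in bands
        ]
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_samples(
    wild_q: np.ndarray,
    sample_ids: list[str],
    bands: list[GenerationBand],
    wild_ref_min: float,
    pure_cut: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Assign each sample a filial class from its wild-cluster q.

    Rules, in order: pure wild if game-farm q <= ``pure_cut`` OR wild q falls
    within the range recovered among reference wild samples; pure game-farm if
    game-farm q >= 1 - ``pure_cut``; F1/F2/F3 if wild q lies inside that
    simulated generation's [min, max] band (earlier generations take priority
    when bands overlap — conservative toward detecting hybrids); remaining
    mixed-ancestry samples are hybrid swarm, split at wild q = 0.5 into FX_WMA
    and FX_GFM. Samples inside a game-farm-direction F2/F3 band are labelled
    FX_GFM (the class scheme carries no F2_GFM/F3_GFM).
    """
    wild_q = np.asarray(wild_q, dtype=float)
    if np.any((wild_q < 0) | (wild_q > 1)):
        raise ValueError("assignment probabilities must lie in [0, 1]")
    by_key = {(b.generation, b.direction): b for b in bands}
    for gen in ("F1", "F2", "F3"):
        dirs = [None] if gen == "F1" else ["wild", "game-farm"]
        for d in dirs:
            if (gen, d) not in by_key:
                raise ValueError(f"missing generation band ({gen}, {d})")
    priority = [
        ("F1", None, "F1"),
        ("F2", "wild", "F2_WMA"),
        ("F3", "wild", "F3_WMA"),
        ("F2", "game-farm", "FX_GFM"),
        ("F3", "game-farm", "FX_GFM"),
    ]
    labels = []
    for q in wild_q:
        gfm_q = 1.0 - q
        if gfm_q <= pure_cut or q >= wild_ref_min:
            labels.append("WILD")
            continue
        if gfm_q >= 1.0 - pure_cut:
            labels.append("GFM")
            continue
        label = None
        for gen, d, name in priority:
            if by_key[(gen, d)].contains(q):
                label = name
                break
        if label is None:
            label = "FX_WMA" if q > 0.5 else "FX_GFM"
        labels.append(label)
    report = pd.DataFrame(
        {"sample_id": sample_ids, "wild_q": wild_q, "klass": labels}
    )
    return report, summarize_counts(report["klass"].value_counts().to_dict())


def summarize_counts(counts: dict[str, int]) -> dict:
    """Class counts plus percentages of the total (the classification summary)."""
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no samples to summarize")
    return {
        "n": n,
        "counts": {k: int(v) for k, v in counts.items()},
        "percent": {k: 100.0 * v / n for k, v in counts.items()},
    }
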