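import numpy as np
import pandas as pd
import pytest

from mallardpipe import hybridsim, synthio
from mallardpipe.genodata import SnpMatrix


def make_matrix(genotypes, chrom_class="autosome", sample_ids=None):
    """SnpMatrix from a plain nested list / array, autosomal by default."""
    geno = np.asarray(genotypes, dtype=np.int8)
    n, L = geno.shape
    if isinstance(chrom_class, str):
        chrom_class = [chrom_class] * L
    meta = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(L)],
            "chrom_class": chrom_class,
            "pos": np.arange(1, L + 1) * 10,
        }
    )
    ids = sample_ids or [f"s{i}" for i in range(n)]
    return SnpMatrix(geno, meta, ids)


@pytest.fixture
def small_config():
    return synthio.SimConfig(
        n_loci=400,
        n_ref_wild=15,
        n_ref_gfm=15,
        cohort_mix={"WILD": 10, "F1": 5, "F2_WMA": 5, "F3_WMA": 5, "FX_WMA": 10},
        seed=7,
    )


@pytest.fixture(scope="session")
def world2000():
    """Reference panel and pools at the scale of the band-calibration checks:
    divergence 0.3, 2000 loci, 30 reference birds per pool."""
    cfg = synthio.SimConfig(seed=11)
    wild_f, gfm_f, ref, labels = synthio.gen_parental_pools(cfg)
    return cfg, wild_f, gfm_f, ref, labels


@pytest.fixture(scope="session")
def bands2000(world2000):
    """Generation bands at 2000 loci from 3 simulations x 5 admixture replicates
    (the scaled-down calibration the fast checks share). Expensive: built once."""
    cfg, wild_f, gfm_f, ref, labels = world2000
    bands, wild_ref_min = hybridsim.build_generation_bands(
        ref,
        wild_f,
        gfm_f,
        wild_ref_ids=list(labels.index[labels == "WILD"]),
        n_sims=3,
        reps_per_sim=5,
        seed=42,
    )
    return bands, wild_ref_min


@pytest.fixture(scope="session")
def bands2000_wide(world2000):
    """Bands from 10 simulations x 3 replicates: ten times the simulated
    individuals per generation, so band limits approach their population
    coverage. Used by the classification-recovery checks."""
    cfg, wild_f, gfm_f, ref, labels = world2000
    bands, wild_ref_min = hybridsim.build_generation_bands(
        ref,
        wild_f,
        gfm_f,
        wild_ref_ids=list(labels.index[labels == "WILD"]),
        n_sims=10,
        reps_per_sim=3,
        seed=42,
    )
    return bands, wild_ref_min
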