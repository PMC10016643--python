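"""Generate the synthetic study inputs.

Builds everything the downstream stages consume: reference wild and game-farm
genotype panels, a harvest cohort of known filial classes with depth profiles
and feather d2H values, a precipitation isoscape over the breeding range, and
band-recovery records for the two source populations. All outputs land under
results/sim/ as plain-text formats.
"""

from pathlib import Path

import pandas as pd

from mallardpipe import genodata, isoassign, synthio

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
# bulky genotype matrices go to scratch/ (regenerated on demand)
DATA = Path(__file__).resolve().parents[1] / "scratch" / "sim"
MASTER_SEED = 20


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    DATA.mkdir(parents=True, exist_ok=True)
    cfg = synthio.SimConfig(seed=MASTER_SEED)
    wild_f, gfm_f, reference, labels = synthio.gen_parental_pools(cfg)
    isoscape = synthio.gen_isoscape(cfg)
    cohort, truth, depth, samples = synthio.gen_cohort(cfg, wild_f, gfm_f, isoscape)
    banding = synthio.gen_banding_data(cfg)

    genodata.write_genotypes(reference, str(DATA / "reference.tsv"), format="tsv")
    genodata.write_genotypes(cohort, str(DATA / "cohort.tsv"), format="tsv")
    genodata.write_genotypes(reference, str(DATA / "reference.vcf"), format="vcf")
    labels.rename_axis("sample_id").reset_index().to_csv(
        OUT / "reference_labels.csv", index=False
    )
    pd.DataFrame({"wild": wild_f, "gfm": gfm_f}).to_csv(
        OUT / "pool_frequencies.csv", index=False
    )
    depth.table.to_csv(OUT / "depth.csv", index=False)
    samples.to_csv(OUT / "samples.csv", index=False)
    truth.rename_axis("sample_id").reset_index().to_csv(
        OUT / "truth.csv", index=False
    )
    banding.table.to_csv(OUT / "banding.csv", index=False)
    isoassign.write_ascii_grid(
        isoscape.values, isoscape.lats, isoscape.lons,
        str(OUT / "isoscape_d2hp.asc"), mask=isoscape.mask,
    )

    print(f"reference panel: {reference.n_samples} birds x {reference.n_loci} loci")
    print(f"cohort: {cohort.n_samples} birds, classes "
          f"{ {k: int(v) for k, v in truth.value_counts().items()} }")
    print(f"isoscape: {isoscape.shape[0]}x{isoscape.shape[1]} cells, "
          f"d2H_p {isoscape.values.min():.1f}..{isoscape.values.max():.1f} permil")
    print(f"tables in {OUT}; genotype matrices in {DATA}")


if __name__ == "__main__":
    main()
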