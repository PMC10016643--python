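"""Filter SNPs, prune linkage, and call sex from sequencing depth.

Applies the study's genotype hygiene to the combined reference + cohort
matrix: drop loci below the singleton minor-allele-frequency floor (0.0023)
or with >= 5% missing data, then prune one of every pair of linked SNPs
(r^2 > 0.5 in a 2-SNP sliding window). Sex is called from Z/autosome and
W/autosome depth ratios.
"""

from pathlib import Path

import pandas as pd

from mallardpipe import genodata

RESULTS = Path(__file__).resolve().parents[1] / "results"
SIM = RESULTS / "sim"
DATA = RESULTS.parent / "scratch" / "sim"
SEED = 21


def main() -> None:
    reference = genodata.read_genotypes(str(DATA / "reference.tsv"), format="tsv")
    cohort = genodata.read_genotypes(str(DATA / "cohort.tsv"), format="tsv")
    combined = genodata.concat_samples([reference, cohort])

    filtered = genodata.filter_snps(combined, maf_min=0.0023, max_missing=0.05)
    pruned = genodata.ld_prune(filtered, window=2, step=1, r2_max=0.5, seed=SEED)
    pruned = pruned.autosomal()
    genodata.write_genotypes(pruned, str(DATA / "genotypes_filtered.tsv"),
                             format="tsv")

    depth = genodata.DepthProfile(pd.read_csv(SIM / "depth.csv"))
    sex = genodata.assign_sex(depth)
    sex.rename_axis("sample_id").reset_index().to_csv(
        RESULTS / "sex_calls.csv", index=False
    )

    print(f"loci: {combined.n_loci} raw -> {filtered.n_loci} after maf/"
          f"missingness -> {pruned.n_loci} after LD pruning")
    print(f"sex calls: {sex.value_counts().to_dict()}")


if __name__ == "__main__":
    main()
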