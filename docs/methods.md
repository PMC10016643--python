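# Methods

`mallardpipe` implements a joint genomic–isotopic inference pipeline for
quantifying game-farm mallard introgression into wild mallard populations and
linking ancestry to geographic natal origin. This note documents the models,
their assumptions, the defaults that matter, and what the synthetic data
generator does and does not emulate.

## The admixture model (`ancestry`)

Genotypes are bi-allelic SNP alt-allele counts g ∈ {0, 1, 2}. Under the
K-cluster admixture model, individual i has ancestry proportions
q_i (Σ_k q_ik = 1) and cluster k has allele frequencies p_k, with

    g_il ~ Binomial(2, Σ_k q_ik p_kl)

The log-likelihood Σ_il [g_il log f_il + (2 − g_il) log(1 − f_il)],
f_il = Σ_k q_ik p_kl, is maximized over Q and P by EM with SQUAREM
acceleration. The accelerated (extrapolated) step is accepted only when it
improves the likelihood; otherwise the plain double-EM step is kept, so the
recorded trace is non-decreasing — the same contract as the block-relaxation
algorithm this stands in for, where quasi-Newton acceleration changes speed,
not the optimum. Missing genotypes contribute nothing to the likelihood.
Convergence: Δ log-likelihood < 1e-4 (default), matching standard practice
for this model class.

Numerical choices: probabilities are clipped to [1e-9, 1 − 1e-9]; Q is
initialized from a symmetric Dirichlet and P from observed frequencies plus
jitter, both seeded. At K = 1 the closed form (Q ≡ 1, P = observed
frequencies) is returned directly.

**Label switching.** Replicate fits are aligned by the column permutation
maximizing Σ_i ⟨Q_rep[i], Q_ref[i]⟩ against a running mean reference. For
K ≤ 4 the permutation search is exhaustive (≤ 24 candidates), so the greedy
search is exact in the range this analysis uses; aligned replicates are
averaged element-wise into the consensus Q.

**K selection.** Non-missing genotype entries are partitioned into folds;
each fold is masked, the model refitted, and masked entries scored by squared
error against 2 Σ_k q_ik p_kl. The optimum K minimizes mean CV error. On
two-pool synthetic data this selects K = 2, the value all downstream stages
fix.

## Genotype hygiene (`genodata`)

* maf filter: retain loci with minor-allele frequency ≥ 0.0023 (removes
  singletons in a ~296-bird diploid cohort) computed over non-missing calls;
  missingness filter: retain loci with < 5% missing. Filtering is idempotent.
* LD pruning: PLINK-style SNP-count sliding window (default 2/1/0.5). r² is
  the squared Pearson correlation of genotype counts over jointly non-missing
  individuals; one member of each linked pair is removed by seeded coin flip.
  Monomorphic pairs have undefined r² and are treated as unlinked.
* Sex from depth: females (ZW) are expected at ~0.5× autosomal depth on both
  sex chromosomes; males (ZZ) at ~1.0× on Z with no W reads. Thresholds
  (Z/A ≤ 0.65 + W present → female; Z/A ≥ 0.85 + W absent → male) are this
  package's choice — the model gives only the 0.5×/1.0× expectations — and
  anything between is reported as "ambiguous", never coerced.

## Filial-class calibration (`hybridsim`)

F1 hybrids draw one allele per locus from each parental pool with probability
equal to that pool's allele frequency; backcross generation g draws one
transmitted allele from a generation-(g−1) parent and one from the recurrent
pool, so expected non-recurrent ancestry is 2⁻ᵍ. Loci are unlinked throughout
(allele-sampling scheme; no recombination map).

Simulated hybrids (10 F1; 5 lineages × generations F2–F10, both directions)
are appended to the reference panel and the K = 2 model refitted repeatedly
(documented design 10 simulations × 25 replicates; tests and the bundled
analysis use 3 × 5). Replicates are aligned within each simulated dataset;
across simulations the wild cluster is anchored by the reference wild birds'
mean q (element-wise averaging across simulations is undefined because each
contains different simulated individuals). Per-generation bands are the
mean/min/max of consensus wild-q pooled over all simulations.

Classification rules, in priority order: pure wild if game-farm q ≤ 5% *or*
wild q within the range recovered among reference wild birds (the union —
the two conditions are presented as one definition); pure game-farm if
game-farm q ≥ 95%; F1/F2/F3 if wild q falls in that generation's band, with
the earlier generation winning when bands overlap (conservative toward
detecting hybrids); everything else is hybrid swarm, split at wild q = 0.5
into FX-WMA / FX-GFM. The class scheme has no F2-GFM/F3-GFM labels; samples
inside a game-farm-direction F2/F3 band are reported as FX-GFM.

**Inherent miss rate at band edges.** A fresh individual's fitted q is a
draw from the same continuous distribution as the simulated individuals that
define a band, so it escapes the simulated [min, max] with probability
2/(m+1) (m = simulated individuals in that band). Perfect recall of a filial
class is therefore not a property the band method can guarantee; misses are
edge cases that fall to the adjacent FX category. The tests assert ≥ 80%
recall for F1–F3 plus the edge-locality of every miss.

## Isotope assignment (`isoassign`)

The precipitation isoscape (δ²H_p, ‰ VSMOW) is rescaled to the feather scale
with the published mallard calibration δ²H_f = −27.4 + 1.28 · δ²H_p. For a
bird with feather value y, cell c gets posterior ∝ prior(c) · φ((y − μ_c)/σ)
with σ = 12.8‰ (expected individual variation; exposed separately for
assignment and for local classification, defaulting to the same value),
normalized over unmasked cells. The 2:1-odds region is the smallest
descending-posterior prefix reaching 2/3 cumulative probability (ties broken
by stable cell order); per-cohort maps are integer sums of the binarized
regions. Locals are birds within 12.8‰ of the expected local feather
interval (−84.5 to −82.5‰), measured as distance to the nearest point of the
interval (a range is printed, so interval distance rather than a midpoint;
boundary inclusive).

Band-recovery weighting: effort-adjusted rate_k = direct recoveries / bands
placed per source population; weights are normalized rates; the prior raster
spreads weight_k uniformly over population k's polygon cells (the spreading
rule is this package's documented choice; applying the prior before or after
per-bird normalization is mathematically equivalent). Range masking (e.g.
the 100th-meridian clip) is generic boolean mask intersection; real
continental polygons are out of scope and synthetic masks stand in.

Grid convention: cell centers, row 0 northernmost; ASCII-grid I/O (6-line
header) round-trips bit-identically; square cells assumed by the format.

## Origin statistics (`originstats`)

OLS of δ²H_f on ancestry class (treatment coding, pure wild = reference,
coefficient 0), harvest day (4 October = day 0, season span 76 days) and
sex; terms are tested with type-II F-tests, and sex is dropped and the model
refitted when non-significant at α = 0.05. Classes with fewer than 10 birds
(configurable) are excluded and reported descriptively (mean/min/max).
Pairwise class differences use Tukey HSD on least-squares (model-adjusted)
class means — covariates held at their sample means — with Tukey–Kramer
standard errors and studentized-range p-values (k groups, residual df).
The seasonal change is the day coefficient × 76.

## Synthetic world (`synthio`)

* Parental pools: Balding–Nichols-style — ancestral frequency
  p₀ ~ U(0.05, 0.95) per locus, each pool ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F)
  with F = divergence (default 0.3), giving a tunable F_ST analog with simple
  moments for oracle checks.
* Reference wild birds carry residual game-farm ancestry ~ U(0, 0.05): wild
  populations are not perfectly pure, which is exactly what makes a ≤5%
  alternative-assignment cutoff the natural pure-wild definition; with pure
  references the wild q range would collapse to ~1 and generations beyond F3
  would (unrealistically) remain separable.
* Cohort genotypes follow the exact pedigree of each bird's true class
  (pure, F1, Fg backcross chains). The hybrid swarm (FX) — crosses of
  unknown generation — is drawn with a continuous wild-ancestry fraction
  a ~ U(0.55, 0.97) (toward wild) or U(0.03, 0.45) (toward game-farm) and
  genotypes Binomial(2, a·p_wild + (1−a)·p_gfm), the admixture model's own
  generative form; FX birds whose a lands inside an F1–F3 band are
  *correctly* classified into that band by construction of the method, so
  FX "recall" is not a meaningful quantity.
* Missing genotypes injected uniformly at 2% (rate is a config knob; no
  missingness structure is claimed).
* Isoscape: δ²H_p = 81 − 3.0 · latitude over a 21 × 41 one-degree grid
  (40–60° N, 100–60° W), chosen so the expected local feather value at the
  harvest latitude (~41.5° N) falls in the −84.5 to −82.5‰ interval and
  boreal latitudes produce feathers below −140‰. Feather values are the
  calibrated isoscape value at a truncated-normal natal latitude
  (mean 47° N, sd 4°, class-specific shifts: wild +3°, F1 −3°) plus
  N(0, 12.8‰) noise — i.e., generated on the feather scale, so the
  assignment model is well-specified for the generator. Natal latitude also
  rises with harvest day (0.033°/day, ~2.5° across the 76-day season),
  emulating facultative migrants from farther north arriving later.
* Depth: autosomal depth ~118× with 10% CV; ZW birds get ~0.5× Z and W
  depth, ZZ birds ~1.0× Z and zero W.
* Banding records default to recoveries 120/80 on 60k/80k bands placed
  (mid-continent/eastern), i.e. a 2:1 effort-adjusted rate ratio.

**What a green test does not establish.** The generator draws unlinked loci,
injects unstructured missingness, uses a perfectly linear single-gradient
isoscape with known noise, and ties feather values to latitude through the
exact calibration the assignment step assumes. Real ddRAD data have linked
loci, structured missingness, reference panels of uneven quality, and
isoscapes with longitudinal structure and spatially varying rescaling error;
green tests establish the mechanisms, not field performance.

## Known limitations

* Supervised admixture (fixing reference Q), linkage-aware models and K > 5
  are out of scope; so are phasing, imputation and read-level filtering.
* GeoTIFF raster I/O is not provided (no georeferenced-TIFF writer among the
  supported dependencies); the ASCII-grid dialect is the raster interface.
* The published per-bird isotope reproductions require the original study's
  supplementary per-bird table (S1), which must be supplied as
  `data/s1_table.csv`; it is not redistributable here and cannot be
  reconstructed from summary statistics.
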