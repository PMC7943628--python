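# Methods

This note documents the statistical model, the default parameters, the
numerical conventions and the known limitations of `snpanel`. Nothing
here is an empirical claim about real germplasm; every number quoted is
either a closed-form property or is computed by the package itself.

## Genotype data model

Genotypes are biallelic SNP calls stored as int8 **dosage** (count of the
alternate allele: 0, 1, 2) with `-1` for missing. An unordered diploid
genotype at a biallelic site carries exactly the same information as its
dosage, so tokens such as `A/C` are derived views: alleles are printed in
alphabetical order, missing calls as `-`. VCF input (via pysam) skips
multiallelic and indel records and counts them; phase is ignored
(`1|1` ≡ `1/1`).

## Synthetic collection generator

The generator produces admixed diploid panels under a standard
hierarchical model:

- **Ancestral allele frequencies** (Balding–Nichols): a base frequency
  `p ~ Uniform(0.05, 0.95)` per locus, then per population
  `f ~ Beta(p(1-F)/F, (1-p)(1-F)/F)` with `F` the fixation index
  (`fst`, required in (0, 1)).
- **Admixture proportions**: per accession
  `q ~ Dirichlet(alpha)` over `K = n_populations` components
  (`K = 1` forces `q = 1`).
- **Genotypes**: `g ~ Binomial(2, q·f)` independently per locus.
- **Missingness**: missing-completely-at-random masking at
  `missing_rate`.

All randomness flows through one `numpy.random.default_rng(seed)`; equal
seeds give bit-identical panels, VCFs and downstream artifacts.

What the generator *emulates*: population structure, admixture, allele
frequency divergence between populations, random missingness, duplicate
accessions (`inject_duplicates`, with an optional per-locus error rate
whose perturbations always change the call). What it does *not* emulate:
linkage disequilibrium along chromosomes (loci are independent),
inbreeding or selfing (genotypes are Hardy–Weinberg-like given `q·f`),
genotyping error models beyond the duplicate perturbation, allele-drop or
null alleles, and sequencing depth. Marker placement on the toy
reference is uniform with fixed spacing margins, not a recombination
map.

The **toy reference** is a random-sequence genome with two-exon genes
(600 bp span, 100 bp intron, 390 bp CDS so the frame closes, alternating
strands, ≥ 2.5 kb between genes), serialisable to FASTA + GFF3 and read
back losslessly.

## Per-site statistics

- MAF: folded alternate-allele frequency over non-missing calls.
- PIC (Botstein): `1 − p² − q² − 2p²q²`; maximum 0.375 at `p = 0.5`.
- Heterozygosity: observed fraction of dosage-1 calls; expected `2pq`
  (maximum 0.5).
- HWE: 1-df chi-square goodness-of-fit against `p², 2pq, q²` expected
  counts (`scipy.stats.chi2.sf`); monomorphic loci return `p = 1`.
  Calibration is verified in the test suite: type-I error at `α = 0.01`
  over 10,000 null simulations lies in [0.005, 0.02].
- Ts/Tv: transitions are A↔G and C↔T; the ratio is reported to two
  decimals.

## Selection cascade (defaults)

| Stage | Rule | Default |
|---|---|---|
| prefilter | missing rate `≤ max_missing_rate`, MAF `≥ min_maf_prefilter` | 0.20 / 0.05 |
| PIC | PIC `≥ min_pic` | 0.35 |
| HWE | HWE p `≥ min_hwe_p` | 0.01 |
| LD prune | windowed `indep-pairwise`, dosage r² `≤ ld_r2_max` | 50 SNPs / step 10 / 0.2 |
| flank uniqueness | no other catalogued variant within `± flank_bp` | 100 bp |
| core selection | zero missing, het_obs `≤ max_het_obs`, MAF `≥ min_maf_panel` | 0.10 / 0.34 |

Conventions chosen for determinism and auditability:

- Thresholds are kept-at-equality: a locus exactly at a threshold
  survives (e.g. missing rate 0.20 is kept, HWE p = 0.01 is kept);
  removal requires strictly violating the rule. PIC strictly below 0.35
  is removed — note that MAF 0.34 corresponds to PIC ≈ 0.3481, which the
  PIC stage removes; the panel-MAF floor of 0.34 therefore binds only
  through the core-selection stage.
- LD pruning resolves the largest-r² offending pair first, removes the
  lower-MAF member (ties: the higher index), and sweeps windows to a
  fixpoint, so the survivors carry a brute-force-verifiable certificate:
  no surviving within-window pair exceeds the r² cap.
- The flank-uniqueness screen runs against the **full** variant
  catalogue, not merely the current survivors.
- Core selection ranks eligible markers by PIC descending, MAF
  descending, then (chrom, pos), and draws round-robin across
  chromosomes; the ranked list is split into the core panel (first 47 by
  default) and candidate panel (next 24).

### Core-constraint infeasibility and the pipeline fallback

The mainly-homozygous constraint (`het_obs ≤ 0.10`) reflects
fingerprinting practice for predominantly selfing crops. The synthetic
generator, however, produces *outbred* genotypes: at a well-powered
locus with MAF near 0.5 the expected heterozygosity is near 0.5, so no
simulated locus can satisfy the constraint and `select_core_panel`
legitimately returns an empty, `infeasible`-flagged selection. The
pipeline then logs a warning and falls back to ranking the
post-flank-stage survivors by PIC/MAF so the fingerprinting stages still
run; the strict behaviour remains available through the library API.
A related small-sample fact: a polymorphic locus with zero heterozygotes
has HWE chi-square equal to the sample size `n`, so such loci pass the
`p ≥ 0.01` filter only for `n ≤ 6` — engineered homozygous examples in
the test suite use six accessions for exactly this reason.

## KASP design

Assays carry the standard tails FAM `GAAGGTGACCAAGTTCATGCT` and VIC
`GAAGGTCGGAGTCAACGGATT`. Primer **bodies** (tails excluded) must have
GC < 60 %, Tm in [55, 62] °C, length 18–30 nt; the amplicon may span at
most 120 bp. The Tm model is deliberately simple and reproducible: the
Wallace rule `2(A+T) + 4(G+C)` up to 13 nt and `64.9 + 41(GC − 16.4)/N`
above; nearest-neighbour thermodynamics is an extension point. The scan
is deterministic (forward orientation first, allele-primer length
ascending, common primer by ascending product size) and infeasible
markers return structured rejections listing every violated constraint.
The conversion rate is reported to one decimal.

## Population genetics

- **p-distance**: per shared locus, identical homozygotes score 0,
  opposite homozygotes 1, and any comparison involving a heterozygote —
  including heterozygote vs heterozygote — scores 0.5; the distance is
  the mean over pairwise-complete loci. This literal scoring rule means
  two *identical outbred* individuals do not reach distance 0 unless
  their shared heterozygous loci are excluded; duplicate detection is
  therefore meaningful on homozygous (inbred-line-like) panels, which is
  also the regime the core-selection constraints target.
- **Neighbor joining** (Saitou–Nei): Q-criterion with lexicographic
  tie-breaking; negative branch lengths are clamped to zero with the
  deficit moved to the sister branch, preserving joined-pair path
  lengths. Additive matrices are recovered exactly (verified against
  scikit-bio).
- **PCA**: missing dosages mean-imputed per locus, columns centered,
  SVD; explained percentages are eigenvalue shares over all components.
- **Admixture EM**: binomial log-likelihood
  `Σ g·ln π + (2−g)·ln(1−π)` with `π = QF`, closed-form M-steps,
  probabilities clipped to `[1e-6, 1 − 1e-6]`, monotone log-likelihood,
  analytic solution at `K = 1`, optional restarts. **Cross-validation**
  masks a fraction of the observed entries per fold and scores
  `mean((g − 2π̂)²)/2`; the best `K` minimises the mean CV error.

## Fingerprinting and duplicates

Fingerprints list genotype tokens over the panel in (chrom, pos) order.
Barcode payloads are plain structured text (`Name`, `Type`,
`Classification`, `Markers`, `Code`) with a lossless parser — a
text-only stand-in for a 2D-barcode encoder. Duplicate detection is
two-stage: stage 1 groups accessions by connected components of
distance-0 pairs on the core panel with at least `min_overlap` compared
loci (pipeline default: 85 % of the panel); stage 2 recomputes distances
within each group on the disjoint candidate panel and keeps only pairs
that remain at distance 0, so stage-2 groups always refine stage-1
groups.

## Problem sizes

Defaults (60-accession, 240-locus synthetic collection; 47 + 24 panel
split; 216-accession discrimination check) are the package's own choices
for desk-scale demonstration: the full pipeline runs in ~2 s and the
whole test suite in ~30 s on one CPU. All sizes are configuration
parameters.

## Limitations

- The generator's independence across loci makes the LD-pruning stage
  nearly vacuous on simulated data; LD behaviour is exercised by
  engineered fixtures instead.
- The p-distance heterozygote rule (above) caps the resolution of
  duplicate detection on outbred panels.
- The Tm model is not nearest-neighbour thermodynamics; designed primers
  should be re-validated by a thermodynamic tool before wet-lab use.
- The HWE test is asymptotic (no exact mid-p option) and underpowered at
  very small n; see the small-sample note above.
- The admixture EM is a local optimiser; CV-based selection of K is
  reliable for strong structure but noisy near `Fst ≈ 0.1` or small
  panels.
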