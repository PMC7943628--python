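# snpanel

Core SNP marker panels for germplasm fingerprinting: from a variant
catalogue (real VCF or a built-in synthetic generator) through a
multi-stage marker-selection cascade and KASP assay design to population
genetics summaries, DNA fingerprints and duplicate-accession detection.

## What it does

Genebanks and breeding programmes need a small, robust set of SNP markers
that can tell every accession in a collection apart. `snpanel` implements
the full desk-scale workflow:

1. **Per-site statistics** — minor allele frequency (MAF), polymorphism
   information content (PIC, Botstein formula), observed/expected
   heterozygosity, a 1-df chi-square Hardy–Weinberg test, missing rate and
   transition/transversion classification.
2. **Selection cascade** — missingness/MAF prefilter, PIC filter, HWE
   filter, windowed LD pruning (genotype-dosage r², `indep-pairwise
   50 10 0.2` semantics), flank-uniqueness screening against the full
   catalogue, and a final round-robin pick of mainly-homozygous,
   high-MAF markers balanced across chromosomes. Every stage is logged in
   an auditable cascade report. The ranked selection is split into a
   **core panel** (default 47 markers) and a **candidate panel**
   (default 24) used for second-stage verification.
3. **KASP assay design** — two allele-specific primers carrying the
   standard FAM/VIC tails plus a common primer, under GC, melting
   temperature, length and product-size constraints; infeasible markers
   yield structured rejections, never exceptions.
4. **Population genetics** — pairwise p-distance (per-locus 0 / 0.5 / 1
   scoring), neighbor-joining trees with Newick output, PCA of dosage
   matrices, and an EM-fitted admixture model with cross-validation over
   K.
5. **Fingerprinting** — ordered genotype codes over the panel, text
   barcode payloads with lossless parsing, two-stage duplicate detection
   (distance-0 grouping on the core panel, refinement on the disjoint
   candidate panel) and a discrimination summary.
6. **Synthetic data** — an admixed genotype generator (Balding–Nichols
   ancestral frequencies, Dirichlet admixture proportions, binomial
   genotypes, MCAR missingness) plus a toy reference genome with a gene
   model, so every stage can be exercised end-to-end without external
   data. Everything is deterministic given a seed.

## Worked example

```python
import numpy as np

from snpanel.site_stats import pic
from snpanel.popgen import pair_distance
from snpanel.synthetic_data import PopulationModel, simulate_panel
from snpanel.fingerprinting import discrimination_summary, encode_fingerprint

# informativeness ceiling of a biallelic SNP
print("PIC at p=0.5:", pic(0.5))
print("PIC at p=0.34:", round(pic(0.34), 4))

# the three p-distance cases
for a, b, label in [(0, 0, "AA vs AA"), (0, 1, "AA vs AC"), (0, 2, "AA vs CC")]:
    d, _ = pair_distance(np.array([a]), np.array([b]))
    print(f"p-distance {label}: {d}")

# a synthetic admixed collection fingerprinted on 47 markers
model = PopulationModel(
    n_populations=4, fst=0.3, dirichlet_alpha=(0.3,) * 4,
    n_accessions=216, n_loci=47, missing_rate=0.0, seed=1,
)
gm, truth = simulate_panel(model)
panel = [m.id for m in gm.markers]
n_distinct, accuracy, per_locus = discrimination_summary(gm, panel)
print(f"distinct fingerprints: {n_distinct}/216, unique: {accuracy}%")

fp = encode_fingerprint(gm, panel[:5], gm.accessions[0])
print("first 5 loci of", fp.accession, "->", fp.code_string)
```

Output:

```text
PIC at p=0.5: 0.375
PIC at p=0.34: 0.3481
p-distance AA vs AA: 0.0
p-distance AA vs AC: 0.5
p-distance AA vs CC: 1.0
distinct fingerprints: 216/216, unique: 100.0%
first 5 loci of acc0001 -> C/C T/T G/G T/T C/C
```

## Command line

The `snpanel` entry point (or `python -m snpanel.cli`) exposes the whole
pipeline and each stage separately:

```bash
snpanel full --output-dir demo --seed 7
```

```text
... snpanel INFO inputs: 61 accessions x 240 loci
... snpanel INFO stats: 240 loci summarised
... snpanel INFO annotate: 240 variants classified
... snpanel INFO select: core 0, candidate 0 markers
... snpanel INFO popgen: best K = 3 (cv over [1, 2, 3, 4])
... snpanel WARNING select: no marker met the strict core constraints; falling back to top-PIC cascade survivors
... snpanel INFO fingerprint: 60 distinct codes, 96.7% unique, 1.3 accessions/locus
```

The default synthetic collection is outbred (admixed, Hardy–Weinberg-like
heterozygosity), so the strict mainly-homozygous core constraint is
infeasible and the pipeline transparently falls back to the top-PIC
cascade survivors — see `docs/methods.md` for the rationale. The run
directory contains every stage artifact (`site_stats.tsv`,
`cascade_report.tsv/json`, `core_panel.txt`, `kasp_assays.tsv` when a
core panel exists, `distance_matrix.tsv`, `nj_tree.nwk`,
`pca_scores.tsv`, `cv_errors.tsv`, `admixture_Q.tsv`,
`fingerprints.tsv`, `duplicates.json`) plus `manifest.json` with the
config hash and a SHA-256 per output; reruns with the same config and
seed are bit-identical.

Other subcommands: `simulate`, `stats`, `annotate`, `select`, `design`,
`popgen`, `fingerprint` (see `snpanel <cmd> --help`).

## Reproduction

```bash
pip install --no-build-isolation -e ".[test]"
python -m pytest -o addopts= -p no:cacheprovider -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite (~30 s on one CPU) covers closed-form values, boundary
behaviour at every filter threshold, property-based invariants
(hypothesis, derandomized), external oracles (scikit-bio for
neighbor-joining, dendropy for Newick parsing) and end-to-end pipeline
determinism. The acceptance script recomputes the headline quantities at
run time and writes them as JSON:

```json
{
  "t4": {"value": 0.375, "n": 1},
  "t6": {"value": 0.5,   "n": 1},
  "t7": {"value": 1.0,   "n": 1},
  "t8": {"value": 100.0, "n": 216}
}
```

(`t4` maximum biallelic PIC; `t6`/`t7` the p-distance equation cases;
`t8` fingerprint discrimination accuracy of a seeded 216-accession,
47-marker synthetic panel regenerated until all genotype vectors are
distinct.)

## Documentation

`docs/methods.md` describes the statistical model behind the generator,
every default parameter, the numerical conventions (Tm model, p-distance
scoring, tie-breaking rules) and the known limitations.
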