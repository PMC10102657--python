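# germdiv

Diversity analysis for clonally propagated crop germplasm — built
around the workflow used to characterise landrace collections of taro
and related aroids, but applicable to any collection with on-farm
census data, replicated field trials, and codominant SSR genotypes.

It answers, in one importable toolkit, the four questions a germplasm
study asks:

1. **How diverse is the standing population of landraces?**
   Richness, Gini–Simpson `1 − Σp²`, Shannon `H = −Σ p ln p`, and
   Pielou evenness `H/ln S` per site (`census_diversity`).
2. **Which traits can selection improve?** From a randomized-block
   trial: variance components `σ²_g = (MS_g − MS_e)/r`, GCV/PCV,
   broad-sense heritability `h² = σ²_g/σ²_p`, genetic advance
   `GA = k·h²·σ_p` (k = 2.06 at 5% selection), genotypic/phenotypic
   correlations, Dewey–Lu path coefficients solving `R·p = r`, Ward
   trait clustering, and PCA (`quantgen`).
3. **How is molecular variation structured?** Per-locus NA, NE, Ho,
   Nei gene diversity `He = 1 − Σp²`, Botstein PIC; Nei (1972) distance
   `D = −ln I` with UPGMA/NJ trees and Newick export; PCoA; three-level
   AMOVA with Φ-statistics and permutation tests; pairwise
   Weir–Cockerham F_ST (`popgen_markers`).
4. **How many gene pools, and who is admixed?** EM maximization of the
   admixture likelihood (Q matrix + cluster allele frequencies) and the
   Evanno ΔK criterion `ΔK = mean|L''(K)|/sd(L(K))` for choosing K
   (`structure_inference`).

A synthetic-data module (`synthetic_data`) generates censuses, RBD
trials, Balding–Nichols SSR panels with a selfing/clonality knob, and
replicate log-likelihood tables, so the entire pipeline is testable
without field or gel data. See `docs/methods.md` for models,
conventions and limitations.

## Worked example

`examples/` holds one short script per capability. From
`examples/census_indices.py` — a shifting-cultivation field census where
one landrace holds 47% of plants, two more 36% and 12%, and three minor
ones share the rest:

```
site            : jhum-field
richness S      : 6
Simpson (1-sum p^2): 0.63
Shannon H       : 1.18
Pielou evenness : 0.66
```

Two random plants differ in landrace 63% of the time; evenness well
below 1 quantifies the dominance of the leading landrace. From
`examples/quantitative_genetics.py` (50 genotypes × 3 blocks simulated
with σ²_g = 10000, σ²_e = 500, genetic correlation 0.6):

```
corm weight: sigma2_g = 8270 (true 10000), sigma2_e = 584 (true 500)
GCV = 37.6%  PCV = 38.9%  h2 = 93.4%
GA (5% selection) = 181.1 g  GAM = 74.9% of the mean
genotypic r(corm, yield) = 0.77 (true 0.6), phenotypic r = 0.68
```

High h² together with high GAM marks corm weight as a trait that
responds strongly to simple mass selection. The other scripts cover
marker summaries and trees, AMOVA/F_ST, and ΔK plus admixture
classification.

A thin CLI mirrors the library for shell use:

```bash
germdiv simulate markers --out geno.csv --seed 3
germdiv markers --in geno.csv --out locus_summary.csv
germdiv amova   --in geno.csv --out amova.csv --permutations 199 --seed 1
germdiv admix   --in geno.csv --k 2 --out q_matrix.csv --seed 1
```

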