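# Methods

This document states the statistical methods implemented in `pearid`, the
modeling assumptions behind the synthetic generator, the default parameters
and their rationale, and known limitations.

## 1. Marker statistics (`pearid.markers`)

Computed per locus over **diploid** genotypes only (allele dosage at a
codominant locus is ambiguous in a triploid). With allele-frequency vector
`p` and diploid sample size `n` at the locus:

| statistic | formula |
|---|---|
| Na | number of observed alleles |
| Ne | 1 / Σp² |
| Ho | fraction of diploids with two distinct alleles |
| He | (2n / (2n−1)) · (1 − Σp²) (unbiased gene diversity) |
| I  | −Σ p ln p (Shannon) |
| PIC | 1 − Σp² (Nei gene diversity, plug-in) |

A single-allele call in a diploid is counted as a homozygote (two copies).
Accessions showing three alleles at **any** locus are excluded from per-locus
statistics by default (`ploidy_filter="strict"`); `"calls"` excludes only
accessions reaching the triploid call threshold.

**Discrimination power.** DP = 1 − Σ pᵢ² over multilocus genotype
frequencies, computed across *all* accessions (diploid and triploid): the
probability that two accessions drawn with replacement differ in profile.
Default mode excludes accessions with any missing locus; `"lenient"` mode
counts a pair as distinguishable if they differ at some mutually scored locus.

Summary rows report arithmetic means and sample standard deviations
(ddof = 1) over loci.

## 2. Identity resolution (`pearid.identity`)

Genotypes are binarized into a band matrix: one presence/absence column per
observed (locus, allele) pair; all columns of a missing locus are marked
missing for that accession. Pairwise similarity is the **simple matching
coefficient** SM = (n₁₁ + n₀₀) / (columns scored in both); shared absences
count as matches, and pairs with no mutually scored column are undefined
(NaN).

Unique genotypes are the connected components of the graph joining pairs with
GS ≥ 1.0 ("identical on mutually scored loci"). Lower thresholds are allowed
but warn: the result is then a similarity cluster, not an identity class.
Within a group:

* **Synonym case** — ≥ 2 accessions carrying ≥ 2 distinct *normalized* names
  (case-folded, province-code and bare-numeral tokens stripped).
* **Homonym case** — a normalized name whose bearers span > 1 group; the
  minimum between-group GS is reported.
* Accessions with anonymous sample labels (default pattern `^pero\s*\d+$`)
  are excluded from name logic; they are assigned the majority name of their
  group when one exists, otherwise reported as unassigned novel profiles.

## 3. Ploidy (`pearid.ploidy`)

**SSR rule.** A diploid can show at most two alleles per locus, so triallelic
loci are evidence toward triploidy. Because one triallelic locus can also
arise from somatic mutation, chimerism or duplication, the default call
requires `min_loci = 2` triallelic loci; exactly one yields
`putative_triploid`, treated as diploid in summaries.

**DAPI cytometry.** The G1 fluorescence peak position is proportional to
nuclear DNA content. Sample/diploid-reference peak ratios within 1 ± 0.1 are
diploid, 1.5 ± 0.1 triploid; ratios near 2 are flagged tetraploid candidates;
ratios outside [0.75, 2.25] warn and are unassigned. Peaks are located as
prominent maxima of an edge-padded moving-average-smoothed histogram
(window 5, prominence ≥ 5% of the smoothed maximum).

**PI genome sizing.** With co-chopped internal standards of known 2C,
2C_sample = 2C_standard · (sample peak / standard peak); the combined
estimate is the mean over standards (*Raphanus sativus* 1.11 pg,
*Solanum lycopersicum* 1.96 pg). Standards whose implied channels-per-pg
slopes disagree by > 10% trigger a mis-assignment warning. When more peaks
are detected than standards, the assignment minimizing slope disagreement is
chosen and the largest leftover peak is the sample; runs whose sample peak
merges with a standard are flagged and skipped rather than mis-sized.

**Concordance.** SSR and cytometry calls are compared over shared
accessions; putative triploids map to diploid (configurable), unassigned
cytometry calls are dropped. Discordances are reported, never auto-resolved.

## 4. Population structure (`pearid.popstructure`)

**Distance AMOVA** (two levels, Excoffier-style from squared distances d²):

```
SS_total  = (1/N) Σ_{i<j} d²ij
SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²ij
σ²_w = SS_within / (N−G)
σ²_a = (SS_among/(G−1) − σ²_w) / n0,   n0 = (N − Σ n_g²/N) / (G−1)
Φ_ST = σ²_a / (σ²_a + σ²_w)
```

p-value by free permutation of accessions among groups (sizes preserved):
p = (#{Φ_perm ≥ Φ_obs} + 1) / (n_perm + 1). Negative variance components are
reported as computed (no truncation) with a warning, following common AMOVA
software. Default distance is the band-mismatch count (squared Euclidean on
the binary band matrix); 1 − GS is available. Undefined pairs are fatal with
an instruction to impute or drop.

**PCoA.** Gower double-centering B = −½ J d² J, symmetric
eigendecomposition; axes with negative eigenvalues are reported but dropped
from coordinates; axis percentages use the sum of **positive** eigenvalues.

**Evanno ΔK.** Per replicate r: L′_r(K) = L_r(K) − L_r(K−1),
|L″_r(K)| = |L′_r(K+1) − L′_r(K)|; ΔK(K) = mean_r|L″_r(K)| / sd_r(L(K))
(sd with ddof = 1). ΔK is undefined at edge Ks and where sd = 0 (warned).
All local maxima are reported alongside the global optimum.

## 5. Synthetic generator (`pearid.simulate`)

Defaults mirror the conditions of a regional pear germplasm survey; they are
the *study conditions*, not tuned values.

| parameter | default | rationale |
|---|---|---|
| n_accessions | 311 | survey panel size |
| provinces | FR 104, LT 66, RI 69, RM 57, VT 15 | survey sampling design |
| n_loci | 9 | SSR panel size |
| alleles per locus | 9–23 | observed allele-count range |
| freq_concentration | 0.7 | Dirichlet concentration giving uneven, realistic frequencies |
| fst | 0.017 | weak provincial structure (≈ 2% among-province variance) |
| triploid_fraction | 0.25 | survey-like triploid share |
| clone_groups | 26 groups, Σ(size−1) = 61, 14 alias | yields 250 unique genotypes, 14 synonym cases |
| missing_rate | 0.01 | per-cell missingness matching locus sample sizes ≈ 300–311 |
| diploid_2c_pg | 1.17 (×1.5 for triploids) | pear genome size; c_value_cv = 0.015 individual variation |

Model: global allele frequencies ~ Dirichlet; provincial frequencies from
the **Balding–Nichols** construction, Dirichlet(p_global · (1−F)/F), whose
marginal variance is exactly F·p(1−p). Diploids draw two alleles from their
province; triploids model an unreduced diploid egg (two maternal draws) plus
haploid pollen. Clone-group members are exact copies of a founder genotype
(alias groups get distinct variety names; same-name groups share one);
genotyping error (default 0) perturbs alleles by ±2 bp *after* cloning;
missingness is applied last, so clones differ only by missing cells.
Cytometry histograms are Gaussian G1 peaks (cv 3% DAPI, 1% PI) over 1024
channels with 2% uniform debris.

## 6. Numerical and I/O conventions

* Allele sizes are integers (round-half-up on ingest, optional bin-width
  snapping); allele sets are stored sorted ascending, so token order never
  matters.
* All random streams derive from `numpy` `SeedSequence.spawn`, one child per
  pipeline stage; fixing the seed fixes every output byte. Output files use
  `\n` line endings, JSON with sorted keys, and the manifest excludes the
  output directory path, so runs are location-independent.
* Strict parsing reports `path:row: column` coordinates; lenient parsing
  coerces malformed cells to missing and logs them. Accessions missing more
  than half their loci are dropped with a report.

## 7. Limitations

* Per-locus statistics assume the diploid subset is a random sample; in
  panels with many triploids the exclusion may bias frequencies.
* PIC is equated with Nei gene diversity (plug-in 1 − Σp²), not Botstein's
  stricter formula.
* The generator plants clones as *exact* copies; real synonym pairs can
  differ by somatic mutations, which would require threshold < 1 and
  cluster-based identity.
* AMOVA on panels containing clones deflates among-group variance
  (duplicates inflate within-group identity); a unique-genotypes-only mode
  is exposed (`amova_unique_only`).
* ΔK inherits the known weaknesses of the Evanno heuristic (cannot evaluate
  K = 1, sensitive to replicate variance); it is computed from supplied or
  synthesized log-likelihoods, not from an admixture model run.
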