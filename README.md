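# pearid

SSR-based germplasm characterization toolkit for clonally propagated fruit
crops (developed around pear, *Pyrus communis*). Given a table of
microsatellite (SSR) fragment-size genotypes — or a synthetic panel generated
with known ground truth — it computes marker informativeness statistics,
resolves accessions into unique genotypes (detecting synonyms and homonyms),
predicts ploidy from triallelic profiles with simulated flow-cytometric
confirmation, and quantifies population structure with distance-based AMOVA,
principal coordinate analysis and Evanno's ΔK.

## What it does

* **Marker statistics** (`pearid.markers`): per-locus Na, Ne, Ho, unbiased
  He, Shannon's I and PIC (Nei gene diversity) over diploid genotypes, plus
  the panel's discrimination power, DP = 1 − Σp² over multilocus genotype
  frequencies.
* **Identity resolution** (`pearid.identity`): binary band encoding,
  simple-matching similarity over mutually scored columns, collapse into
  unique genotypes (GS = 1 connected components), synonym cases (one genotype,
  several names), homonym cases (one name, several genotypes), anonymous
  sample assignment.
* **Ploidy** (`pearid.ploidy`): SSR calls from triallelic-locus counts
  (≥ 2 loci → triploid, exactly 1 → putative triploid); DAPI G1-peak-ratio
  calls; genome size (2C, pg) from propidium-iodide runs against co-chopped
  internal standards.
* **Population structure** (`pearid.popstructure`): two-level distance AMOVA
  with free-permutation testing, Gower-centered PCoA, and Evanno ΔK from
  replicate clustering-run log-likelihoods.
* **Synthetic data** (`pearid.simulate`): a generator whose defaults mirror a
  regional germplasm survey — 311 accessions over five provinces, 9 loci,
  Balding–Nichols provincial differentiation (Fst = 0.017), planted clone
  groups (250 unique genotypes, 14 cross-name synonym cases), 25% triploids
  from unreduced gametes, 1% missing data — with a full ground-truth sidecar.
* **Pipeline and CLI** (`pearid.pipeline`, `pearid` command): one-shot
  orchestration writing every artifact plus a manifest; outputs are a pure
  function of (inputs, config, seed).

## Worked example

```
$ pearid simulate --seed 7 --n 311 --out geno.csv
wrote 311 accessions x 9 loci to geno.csv

$ pearid stats geno.csv
locus   n    Na  Ne     Ho    He    I     PIC
SSR01   226  21  9.94   0.86  0.90  2.57  0.90
...
Mean    226  15  8.72   0.87  0.88  2.33  0.88
DP = 0.9935 over 290 complete profiles

$ pearid identity geno.csv
unique genotypes: 250 of 311
synonym cases: 14
  'Boretta FR' = 'Borona RI'
  ...

$ pearid ploidy geno.csv
triploid (>= 2 triallelic loci): 83/311 (26.7%)
>= 1 triallelic locus: 83/311 (26.7%)

$ pearid amova geno.csv --seed 7
among provinces: 2.5%  within: 97.5%
Phi_ST = 0.0253  p = 0.0010 (999 permutations, seed 7)
```

The full pipeline (`pearid run-all --seed 7 --outdir out/`) additionally
writes the similarity matrix, per-accession registry report, cytometry
concordance, genome sizes, PCoA tables, the ΔK table and a run manifest.
Running it twice with the same seed produces byte-identical outputs.

## Input formats

Genotype tables are delimited text with columns `accession_id`, `name`,
`province`, then one column per locus holding `/`-separated integer fragment
sizes (`134/138`, `134`, `134/138/142` for a triallelic call; empty = missing).
Clustering runs for ΔK are `K,replicate,lnP` tables; cytometry histograms are
`channel,count` tables. A GenAlEx-style export is provided. See
`docs/methods.md` for the statistical methods, model assumptions and default
parameter rationale.
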