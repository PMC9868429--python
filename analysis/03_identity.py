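#!/usr/bin/env python
"""Genotype identity resolution: unique genotypes, synonyms and homonyms.

Reads scratch/genotype_table.csv, writes the full similarity matrix to
scratch/ (large) and the identity report to results/.
"""

import json
from pathlib import Path

import numpy as np

from pearid.identity import binarize, collapse_genotypes, find_homonyms, similarity_matrix
from pearid.io import read_genotype_table

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    table = read_genotype_table(ROOT / "scratch" / "genotype_table.csv")
    sim = similarity_matrix(binarize(table))
    report = collapse_genotypes(sim, table)
    homonyms = find_homonyms(report, table, sim)

    scratch = ROOT / "scratch"
    np.savetxt(scratch / "similarity_matrix.csv", sim.values, delimiter=",",
               fmt="%.6f", header=",".join(sim.accession_ids), comments="")

    off = ~np.eye(sim.n, dtype=bool)
    gs = sim.values[off]
    gs = gs[~np.isnan(gs)]

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    out = results / "03_identity_report.json"
    out.write_text(json.dumps(
        {
            "n_accessions": table.n,
            "n_unique_genotypes": report.n_unique_genotypes,
            "n_synonym_cases": len(report.synonym_cases),
            "synonym_cases": [
                {"accession_ids": c.accession_ids, "names": c.names,
                 "provinces": c.provinces}
                for c in report.synonym_cases
            ],
            "homonym_cases": [
                {"name": h.normalized_name, "n_genotypes": len(h.group_indices),
                 "min_gs": h.min_gs}
                for h in homonyms
            ],
            "gs_range": [float(gs.min()), float(gs.max())],
        },
        indent=2, sort_keys=True) + "\n")
    print(f"{report.n_unique_genotypes} unique genotypes of {table.n}; "
          f"{len(report.synonym_cases)} synonym cases, {len(homonyms)} homonym cases")
    print(f"GS range {gs.min():.3f}-{gs.max():.3f} -> {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
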