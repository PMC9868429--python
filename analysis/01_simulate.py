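#!/usr/bin/env python
"""Generate the default synthetic germplasm panel and its ground-truth sidecar.

Writes the genotype table and ground truth to scratch/ (inputs to the later
numbered scripts) and a small provenance summary to results/.
"""

import argparse
import json
from pathlib import Path

from pearid.io import write_genotype_table
from pearid.simulate import default_panel, write_ground_truth

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    scratch = ROOT / "scratch"
    results = ROOT / "results"
    scratch.mkdir(exist_ok=True)
    results.mkdir(exist_ok=True)

    table, truth, config = default_panel(args.seed)
    write_genotype_table(table, scratch / "genotype_table.csv")
    write_ground_truth(truth, scratch / "ground_truth.csv")

    summary = {
        "seed": args.seed,
        "n_accessions": table.n,
        "n_loci": len(table.loci),
        "loci": list(table.loci),
        "true_unique_genotypes": truth.n_unique_genotypes,
        "true_synonym_cases": truth.n_synonym_cases,
        "true_n_triploid": sum(1 for p in truth.ploidy.values() if p == 3),
        "province_counts": {
            c: sum(1 for p in truth.provinces.values() if p == c)
            for c in sorted(set(truth.provinces.values()))
        },
        "fst": config.fst,
        "missing_rate": config.missing_rate,
    }
    out = results / "01_simulate_summary.json"
    out.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    print(f"panel: {table.n} accessions x {len(table.loci)} loci -> scratch/")
    print(f"summary -> {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
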