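#!/usr/bin/env python
"""Population structure: AMOVA by province, PCoA and Evanno ΔK.

Reads scratch/genotype_table.csv, writes PCoA coordinates to scratch/ and a
compact structure summary to results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from pearid.identity import binarize, similarity_matrix
from pearid.io import read_genotype_table
from pearid.popstructure import amova, distance_matrix, evanno_delta_k, pcoa
from pearid.simulate import simulate_structure_runs

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--permutations", type=int, default=999)
    args = parser.parse_args()

    table = read_genotype_table(ROOT / "scratch" / "genotype_table.csv")
    bands = binarize(table)

    d2 = distance_matrix(bands, "band_mismatch")
    res = amova(d2, [a.province for a in table.accessions],
                n_permutations=args.permutations, seed=args.seed)

    sim = similarity_matrix(bands)
    d_gs = 1.0 - sim.values
    np.fill_diagonal(d_gs, 0.0)
    ord_res = pcoa(d_gs)
    coords = ord_res.coordinates[:, : min(5, ord_res.coordinates.shape[1])]
    header = "accession_id," + ",".join(f"axis{i+1}" for i in range(coords.shape[1]))
    with (ROOT / "scratch" / "pcoa_coordinates.csv").open("w") as fh:
        fh.write(header + "\n")
        for acc_id, row in zip(sim.accession_ids, coords):
            fh.write(acc_id + "," + ",".join(f"{v:.6f}" for v in row) + "\n")

    runs = simulate_structure_runs(rng=np.random.default_rng(args.seed))
    ev = evanno_delta_k(runs)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    out = results / "05_popstructure_summary.json"
    out.write_text(json.dumps(
        {
            "amova": {
                "pct_among_provinces": res.pct_among,
                "pct_within_provinces": res.pct_within,
                "phi_st": res.phi_st,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            },
            "pcoa": {
                "axis_pct": [float(p) for p in ord_res.pct_variance[:5]],
                "n_negative_eigenvalues": ord_res.n_negative,
            },
            "evanno": {
                "optimal_k": ev.optimal_k,
                "local_maxima": ev.local_maxima,
                "delta_k": {str(k): (None if np.isnan(ev.delta_k[j]) else float(ev.delta_k[j]))
                            for j, k in enumerate(ev.ks)},
            },
        },
        indent=2, sort_keys=True) + "\n")
    print(f"AMOVA: {res.pct_among:.1f}% among / {res.pct_within:.1f}% within provinces "
          f"(Phi_ST={res.phi_st:.4f}, p={res.p_value:.4f})")
    print(f"PCoA axis 1-2: {ord_res.pct_variance[0]:.1f}% / {ord_res.pct_variance[1]:.1f}%")
    print(f"Evanno optimal K = {ev.optimal_k} -> {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
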