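#!/usr/bin/env python
"""Per-locus SSR informativeness statistics and panel discrimination power.

Reads scratch/genotype_table.csv (from 01_simulate.py) and writes the
per-locus statistics table plus panel means to results/.
"""

import csv
import json
from pathlib import Path

from pearid.io import read_genotype_table
from pearid.markers import panel_summary

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    table = read_genotype_table(ROOT / "scratch" / "genotype_table.csv")
    panel = panel_summary(table)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    out_csv = results / "02_marker_stats.csv"
    with out_csv.open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["locus", "sample_size", "Na", "Ne", "Ho", "He", "I", "PIC"])
        for s in panel.locus_stats:
            w.writerow([s.locus_id, s.n, s.na, f"{s.ne:.3f}", f"{s.ho:.3f}",
                        f"{s.he:.3f}", f"{s.i:.3f}", f"{s.pic:.3f}"])
        m = panel.means
        w.writerow(["Mean", f"{m['n']:.1f}", f"{m['na']:.1f}", f"{m['ne']:.3f}",
                    f"{m['ho']:.3f}", f"{m['he']:.3f}", f"{m['i']:.3f}",
                    f"{m['pic']:.3f}"])

    out_json = results / "02_panel_summary.json"
    out_json.write_text(json.dumps(
        {"means": panel.means, "sds": panel.sds, "dp": panel.dp,
         "n_diploid": panel.n_diploid, "n_profiles": panel.n_profiles},
        indent=2, sort_keys=True) + "\n")
    print(f"mean PIC = {m['pic']:.3f}, DP = {panel.dp:.4f} "
          f"over {panel.n_profiles} complete profiles")
    print(f"-> {out_csv.relative_to(ROOT)}, {out_json.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
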