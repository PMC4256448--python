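#!/usr/bin/env python
"""Cross-tabulations of the packaged 41-row differential-abundance summary
table: per-comparison totals, pairwise intersections, and the
comparison x co-abundance-cluster breakdown.

All counts are computed from the fixture at run time (checksum-guarded);
they are reported exactly as printed, including the spots where the
source narrative disagrees with its own table.  Outputs under
results/06_table/.
"""

import argparse
import json
from pathlib import Path

from plasmamir.table1 import column_totals, crosstab, load_fixture_table1


def run(outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    table = load_fixture_table1()
    totals = column_totals(table)
    (outdir / "totals.json").write_text(json.dumps(totals, indent=1))

    print(f"{totals['n_rows']} differentially abundant miRNAs")
    print("per-comparison totals:", totals["totals"])
    print("condition/line overlap:",
          totals["intersections"]["RF_vs_FD&Rplus_vs_Rminus"],
          "->", sorted(table.index[table['RF_vs_FD']
                                   & table['Rplus_vs_Rminus']]))
    print("cluster sizes among the 41:", totals["cluster_sizes"])
    for flag in ("RF_vs_FD", "Rplus_vs_Rminus"):
        ct = crosstab(table, flag, "cluster")
        ct.to_csv(outdir / f"crosstab_{flag}_by_cluster.tsv", sep="\t")
        print(f"{flag} x cluster:\n{ct.to_string()}")
    print(f"outputs in {outdir}")


if __name__ == "__main__":
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--outdir", type=Path, default=Path("results/06_table"))
    a = p.parse_args()
    run(a.outdir)
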