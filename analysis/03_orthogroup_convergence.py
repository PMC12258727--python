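#!/usr/bin/env python
"""Quantify cross-species convergence at the orthogroup level.

Aggregates per-protein log2 fold changes to orthogroup means, computes the
pairwise Spearman correlation matrix between species, counts co-occurrence
classes of differentially abundant orthogroups (which exact species subsets
share them) in both directions, and selects each species' top-50 winter-up
proteins.  Outputs under results/03_convergence/.
"""

from pathlib import Path

import pandas as pd

from rhizoprot import convergence as conv
from rhizoprot import io_formats as io

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "03_convergence"


def main() -> None:
    og = io.read_orthogroups(ROOT / "01_simulated" / "orthogroups.tsv")
    results = {p.name.split(".")[0]: pd.read_csv(p, sep="\t")
               for p in sorted((ROOT / "02_daps").glob("*.results.tsv"))}
    OUT.mkdir(parents=True, exist_ok=True)

    fc = conv.aggregate_orthogroup_lfc(results, og)
    fc.to_csv(OUT / "orthogroup_fc.tsv", sep="\t", index=False)
    rho = conv.spearman_matrix(fc)
    rho.round(4).to_csv(OUT / "spearman.tsv", sep="\t")
    print("Spearman correlations between orthogroup-level fold changes:")
    print(rho.round(2).to_string())

    frames = []
    for direction in ("up", "down"):
        co = conv.cooccurrence(fc, direction)
        frames.append(co.to_frame())
        print(f"\n{direction}: {co.total} DAP orthogroups; "
              f"{co.frac_shared_ge1:.0%} shared with >=1 other species, "
              f"{co.frac_shared_ge2:.0%} with >=2 others")
    pd.concat(frames, ignore_index=True).to_csv(OUT / "cooccurrence.tsv",
                                                sep="\t", index=False)

    rows = [{"species": sp, "rank": r + 1, "protein_id": p}
            for sp, res in results.items()
            for r, p in enumerate(conv.top_n_up(res, n=50))]
    pd.DataFrame(rows).to_csv(OUT / "top50_up.tsv", sep="\t", index=False)
    print(f"\ntables -> {OUT}")


if __name__ == "__main__":
    main()
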