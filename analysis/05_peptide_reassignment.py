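#!/usr/bin/env python
"""Exercise the cross-proteome tiered reassignment on a planted scenario.

Generates a peptide hit table in which every source protein has a known
true target and decoy competitors engineered to be resolved at each tier
of the tie-break ladder, runs the reassignment, re-keys a matching
intensity matrix, and verifies recovery and intensity conservation.
Outputs under results/05_remap/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rhizoprot import io_formats as io
from rhizoprot import remap as rm
from rhizoprot.io_formats import AbundanceMatrix
from rhizoprot.synthetic_data import gen_peptide_scenario

OUT = Path(__file__).resolve().parent.parent / "results" / "05_remap"


def main(seed: int = 20_260_105) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    hits, sources, targets, truth = gen_peptide_scenario(
        300, decoy_similarity=0.6, seed=seed)
    io.write_hit_table(hits, OUT / "hits.tsv")
    io.write_fasta(targets, OUT / "target_proteome.fasta")

    results = rm.reassign(hits)
    pd.DataFrame([r.__dict__ for r in results]).to_csv(
        OUT / "reassignments.tsv", sep="\t", index=False)
    rec = np.mean([r.chosen_target == truth.true_target[r.source_protein]
                   for r in results])
    tiers = pd.Series([r.decided_at_tier for r in results]).value_counts().sort_index()
    print(f"recovered true target for {rec:.1%} of {len(results)} source proteins")
    print("deciding tier counts:", tiers.to_dict())
    print("(tier-4 full ties are resolved lexicographically; the planted "
          "scenario makes about half of them unrecoverable by design)")

    rng = np.random.default_rng(seed)
    matrix = AbundanceMatrix(data=pd.DataFrame(
        rng.uniform(1, 100, size=(len(sources), 4)),
        index=[s.protein_id for s in sources],
        columns=[f"s{i}" for i in range(4)]))
    remapped, lost = rm.regenerate_summaries(matrix, results)
    io.write_abundance_tsv(remapped, OUT / "remapped.tsv")
    io.write_abundance_tsv(lost, OUT / "unassigned.tsv")
    total_in = np.nansum(matrix.data.to_numpy())
    total_out = np.nansum(remapped.data.to_numpy()) + np.nansum(lost.data.to_numpy())
    print(f"intensity conserved: {np.isclose(total_in, total_out)} "
          f"({total_in:.1f} -> {total_out:.1f}); tables -> {OUT}")


if __name__ == "__main__":
    main()
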