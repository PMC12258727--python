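#!/usr/bin/env python
"""Generate the synthetic five-species two-season study.

Writes per-species abundance matrices, sample metadata, the orthogroup
table and the planted ground truth under results/01_simulated/.  Defaults:
400 orthogroups per species, 10% of orthogroups seasonally regulated
(|log2FC| = 3, winter-up and winter-down in equal parts), 20% of regulated
orthogroups shared across all five species, log2 noise SD 0.3, 4 replicates
per season.
"""

import json
import sys
from pathlib import Path

from rhizoprot import io_formats as io
from rhizoprot.synthetic_data import SimulationConfig, gen_abundance_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "01_simulated"


def main(seed: int = 20_260_101) -> None:
    cfg = SimulationConfig(seed=seed)
    matrices, meta, og, truth = gen_abundance_dataset(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_metadata_tsv(meta, OUT / "metadata.tsv")
    species_of = {p: sp for sp, m in matrices.items() for p in m.protein_ids}
    io.write_orthogroups(og, OUT / "orthogroups.tsv", species_of=species_of.get)
    for sp, m in matrices.items():
        io.write_abundance_tsv(m, OUT / f"{sp}.abundance.tsv")
    (OUT / "ground_truth.json").write_text(json.dumps(truth.to_dict(), indent=1))

    n_reg = {sp: sum(1 for e in eff.values() if e != 0)
             for sp, eff in truth.true_effect.items()}
    print(f"simulated {len(matrices)} species x {cfg.n_orthogroups} orthogroups "
          f"({2 * cfg.n_replicates_per_season} samples each) -> {OUT}")
    print(f"planted regulated proteins per species: {n_reg}")
    print(f"{len(truth.shared_orthogroups)} orthogroups regulated in all species")


if __name__ == "__main__":
    main(*(int(a) for a in sys.argv[1:]))
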