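"""End-to-end orchestration: simulate -> normalize -> test -> aggregate ->
converge -> categorize -> profile, with one master seed, per-stage derived
seeds, and a machine-readable run summary.

Every number in the summary JSON is computed by a stage whose table output
is also written to the run directory, so results are traceable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import abundance, categories, convergence, lea_profile, synthetic_data
from .io_formats import write_abundance_tsv, write_metadata_tsv, write_orthogroups

log = logging.getLogger("rhizoprot")

__all__ = ["RunConfig", "run_pipeline", "derive_seed"]

_MOTIF_RULES = {"default": lea_profile.DEFAULT_RULE,
                "lenient_pos1": lea_profile.LENIENT_POS1_RULE}


def derive_seed(master: int, stage_index: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (master * 1_000_003 + stage_index * 7919 + 17) % (2**31)


@dataclass
class RunConfig:
    """Fully serializable run configuration (YAML round-trip)."""

    simulation: synthetic_data.SimulationConfig = field(
        default_factory=synthetic_data.SimulationConfig)
    adjust_for: tuple[str, ...] = ()
    min_per_season: int = 2
    lfc_min: float = 1.0
    alpha: float = 0.05
    top_n: int = 50
    category_map_path: str | None = None
    motif_rule: str = "default"
    hydropathy_scale: str = "kyte_doolittle"
    hydropathy_window: int = 11
    run_lea_stage: bool = True
    lea_chain_length: int = 6
    lea_insertion_len: int = 0
    seed: int = 0
    outdir: str = "run_output"

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = synthetic_data.SimulationConfig(**self.simulation)
        self.adjust_for = tuple(self.adjust_for)
        if self.motif_rule not in _MOTIF_RULES:
            raise ValueError(f"motif_rule must be one of {sorted(_MOTIF_RULES)}")
        # one master seed; stage seeds derive from it
        self.simulation.seed = derive_seed(self.seed, 0)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["adjust_for"] = list(self.adjust_for)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write stage outputs and ``summary.json`` under
    ``config.outdir``; return the summary dict.

    A stage failure aborts the run with the failing stage named and leaves a
    ``FAILED`` marker next to any partial outputs.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    summary: dict = {"seed": config.seed, "parameters": {
        "adjust_for": list(config.adjust_for), "lfc_min": config.lfc_min,
        "alpha": config.alpha, "min_per_season": config.min_per_season,
        "motif_rule": config.motif_rule,
        "hydropathy_scale": config.hydropathy_scale,
        "hydropathy_window": config.hydropathy_window,
    }}
    stage = "simulate"
    try:
        log.info("stage %s: generating synthetic dataset (seed %d)",
                 stage, config.simulation.seed)
        matrices, meta, og_table, truth = synthetic_data.gen_abundance_dataset(
            config.simulation)
        write_metadata_tsv(meta, out / "metadata.tsv")
        species_of = {p: sp for sp, m in matrices.items() for p in m.protein_ids}
        write_orthogroups(og_table, out / "orthogroups.tsv",
                          species_of=lambda p: species_of.get(p, og_table.species_names[0]))
        (out / "ground_truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
        for sp, m in matrices.items():
            write_abundance_tsv(m, out / f"{sp}.abundance.tsv")

        stage = "abundance"
        results = {}
        summary["species"] = {}
        for sp, m in matrices.items():
            sp_meta = meta[meta["species"] == sp]
            norm = abundance.normalize_total(m)
            kept = abundance.filter_both_seasons(norm, sp_meta,
                                                 min_per_season=config.min_per_season)
            res = abundance.seasonal_test(kept, sp_meta, adjust_for=config.adjust_for)
            res = abundance.call_daps(res, lfc_min=config.lfc_min, alpha=config.alpha)
            res.to_csv(out / f"{sp}.results.tsv", sep="\t", index=False)
            results[sp] = res
            summary["species"][sp] = {
                "n_quantified": int(m.shape[0]),
                "n_tested": int((res["call"] != "untested").sum()),
                "n_up": int((res["call"] == "up").sum()),
                "n_down": int((res["call"] == "down").sum()),
            }
            log.info("stage %s: %s up=%d down=%d", stage, sp,
                     summary["species"][sp]["n_up"], summary["species"][sp]["n_down"])

        stage = "convergence"
        fc = convergence.aggregate_orthogroup_lfc(results, og_table)
        fc.to_csv(out / "orthogroup_fc.tsv", sep="\t", index=False)
        rho = convergence.spearman_matrix(fc)
        rho.to_csv(out / "spearman.tsv", sep="\t")
        summary["spearman"] = {a: {b: float(rho.loc[a, b]) for b in rho.columns}
                               for a in rho.index}
        summary["cooccurrence"] = {}
        co_frames = []
        for direction in ("up", "down"):
            co = convergence.cooccurrence(fc, direction)
            co_frames.append(co.to_frame())
            summary["cooccurrence"][direction] = {
                "total": co.total,
                "frac_shared_ge1": co.frac_shared_ge1,
                "frac_shared_ge2": co.frac_shared_ge2,
            }
        if co_frames:
            import pandas as pd
            pd.concat(co_frames, ignore_index=True).to_csv(
                out / "cooccurrence.tsv", sep="\t", index=False)
        top = {sp: convergence.top_n_up(res, n=config.top_n)
               for sp, res in results.items()}
        with open(out / "top_up.tsv", "w") as fh:
            fh.write("species\trank\tprotein_id\n")
            for sp, prots in top.items():
                for r, p in enumerate(prots, 1):
                    fh.write(f"{sp}\t{r}\t{p}\n")

        stage = "categories"
        cmap = (categories.CategoryMap.from_file(config.category_map_path)
                if config.category_map_path else categories.CategoryMap.default())
        import pandas as pd
        up_ids = [p for prots in top.values() for p in prots]
        ann = synthetic_data.gen_annotations(up_ids, seed=derive_seed(config.seed, 1))
        assigned = categories.assign_categories(ann, cmap)
        group_of = pd.Series({p: species_of[p] for p in up_ids})
        if len(up_ids) and group_of.nunique() >= 2:
            tab = categories.count_table(assigned, group_of, cmap)
            tab.to_csv(out / "category_counts.tsv", sep="\t")
            # drop categories/groups never observed before testing homogeneity
            tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
            if tab.shape[0] >= 2 and tab.shape[1] >= 2:
                chi2, df, p = categories.chi_square_homogeneity(tab)
                summary["categories"] = {"chi2": chi2, "df": df, "p": p}
            else:
                summary["categories"] = None
        else:
            summary["categories"] = None

        if config.run_lea_stage:
            stage = "lea_profile"
            recs, motif_truth = synthetic_data.gen_motif_proteome(
                n_proteins=4, n_with_chain=2,
                chain_length=config.lea_chain_length,
                insertion_len=config.lea_insertion_len,
                seed=derive_seed(config.seed, 2))
            rule = _MOTIF_RULES[config.motif_rule]
            lea = {}
            with open(out / "motifs.tsv", "w") as fh:
                fh.write("protein_id\tstart\tgap_before\n")
                for rec in recs:
                    chain = lea_profile.detect_motifs(rec.sequence, rule,
                                                      protein_id=rec.protein_id)
                    for j, s in enumerate(chain.starts):
                        gap = chain.gaps[j - 1] if j else 0
                        fh.write(f"{rec.protein_id}\t{s}\t{gap}\n")
                    lea[rec.protein_id] = {
                        "n_motifs": chain.n_motifs,
                        "max_consecutive_run": chain.max_consecutive_run,
                        "gaps": chain.gaps,
                    }
            summary["lea"] = lea
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage!r} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
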