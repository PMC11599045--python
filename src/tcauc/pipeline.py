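"""End-to-end pipeline: simulate (or load) inputs, summarize, classify,
test concordance, and run the metabolome volcano, writing a deterministic
TSV output tree.

Configuration is a flat YAML mapping; every key has a default (see
``DEFAULT_CONFIG``) so an empty config runs the whole synthetic study.
Given one config and seed the output tree is byte-identical across runs.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from . import auc, classes, enrichment, io, metabolome, simulate

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    # synthetic experiment
    "class_counts": dict(simulate.DEFAULT_CLASS_COUNTS),
    "effect_log2": 2.0,
    "noise_sd_log2": 0.25,
    "time_grid_h": [0.0, 4.0, 8.0, 12.0, 24.0],
    "n_replicates": 2,
    # contrasts
    "pseudocount": 1.0,
    "treatment_chronic": "CHyp",
    "treatment_acute": "AHyp",
    "reference": "Norm",
    # classification / gene sets
    "up_thr": 1.0,
    "down_thr": 1.0,
    "set_threshold": 2.0,
    # enrichment
    "n_perm": 200,
    "weight_p": 1.0,
    # metabolome
    "n_metabolites": 60,
    "n_true_metabolites": 5,
    "metabolite_effect_log2": 3.0,
    "metabolite_noise_sd_log2": 0.25,
    "n_per_group": 3,
    "p_thr": 0.01,
    "fc_thr": 2.0,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file and overrides onto the defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    if overrides:
        cfg.update(overrides)
    return cfg


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run simulate -> AUC contrasts -> classes -> GSEA -> volcano.

    Writes the full input/output tree under ``out_dir`` and returns it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = {**DEFAULT_CONFIG, **config}
    seed = int(cfg["seed"])

    spec = simulate.SyntheticSpec(
        class_counts=dict(cfg["class_counts"]),
        effect_log2=float(cfg["effect_log2"]),
        noise_sd_log2=float(cfg["noise_sd_log2"]),
        time_grid_h=tuple(float(t) for t in cfg["time_grid_h"]),
        n_replicates=int(cfg["n_replicates"]),
        seed=seed,
    )
    exp, truth = simulate.simulate_timecourse(spec)
    io.write_expression(exp, out / "expression_matrix.tsv", out / "sample_sheet.tsv")
    io.write_results_table(truth, out / "truth_genes.tsv")

    # read back what was written: the pipeline consumes its own interchange
    exp = io.read_expression(out / "expression_matrix.tsv", out / "sample_sheet.tsv")

    chronic = auc.auc_contrast(
        exp, cfg["treatment_chronic"], cfg["reference"], cfg["pseudocount"]
    )
    acute = auc.auc_contrast(
        exp, cfg["treatment_acute"], cfg["reference"], cfg["pseudocount"]
    )
    chronic.to_tsv(out / "auc_chronic.tsv")
    acute.to_tsv(out / "auc_acute.tsv")

    assignment = classes.classify_genes(
        chronic, acute, up_thr=cfg["up_thr"], down_thr=cfg["down_thr"]
    )
    assignment.to_tsv(out / "classes.tsv")

    r = enrichment.pearson_r(
        chronic.log2_ratio.to_numpy(), acute.log2_ratio.reindex(chronic.genes).to_numpy()
    )

    sets = classes.build_direction_gene_sets(
        chronic, threshold=cfg["set_threshold"], name_prefix=chronic.name,
        allow_empty=True,
    )
    io.write_gmt(sets, out / "gene_sets.gmt")
    nonempty = io.GeneSetCollection([s for s in sets if s.members])
    results = enrichment.run_gsea(
        acute, nonempty, n_perm=int(cfg["n_perm"]), seed=seed,
        weight_p=float(cfg["weight_p"]),
    )
    io.write_results_table(enrichment.results_table(results), out / "gsea.tsv")

    met, met_truth = simulate.simulate_metabolome(
        n_metabolites=int(cfg["n_metabolites"]),
        n_true=int(cfg["n_true_metabolites"]),
        effect_log2=float(cfg["metabolite_effect_log2"]),
        n_per_group=int(cfg["n_per_group"]),
        noise_sd_log2=float(cfg["metabolite_noise_sd_log2"]),
        seed=seed,
        groups=(cfg["treatment_chronic"], cfg["reference"]),
    )
    met.values.to_csv(
        out / "metabolome.tsv", sep="\t", float_format=io.FLOAT_FORMAT,
        index_label="metabolite_id",
    )
    io.write_results_table(met_truth, out / "truth_metabolites.tsv")
    vol = metabolome.volcano(
        met, cfg["treatment_chronic"], cfg["reference"],
        p_thr=float(cfg["p_thr"]), fc_thr=float(cfg["fc_thr"]),
    )
    vol.to_csv(out / "volcano.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT)

    summary = {
        "seed": seed,
        "n_genes": int(len(exp.genes)),
        "pearson_r_chronic_vs_acute": round(float(r), 10),
        "class_counts": {k: int(v) for k, v in assignment.counts().items()},
        "n_significant_metabolites": int(vol["significant"].sum()),
    }
    with open(out / "summary.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    return out
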