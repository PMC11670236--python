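"""End-to-end orchestration: simulate -> QC/normalize -> gate -> score ->
classify -> repertoire -> statistics -> report.

Every stage writes its table through :mod:`clonal_surveil.io_formats`; the
run summary (JSON) collects every test report, the parameter values and the
seed, so each number in the report traces to a stage output file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from . import malignancy as mal
from . import module_scoring as ms
from . import repertoire as rep
from . import stats_core as st
from . import synthetic_data as syn

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "analyze_dataset"]


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-backed)."""

    seed: int = 0
    outdir: str = "results"
    simulate: dict = field(default_factory=dict)     # SimulationConfig overrides
    inputs: dict = field(default_factory=dict)       # or: paths to mtx/airr/annotation
    qc: dict = field(default_factory=lambda: {
        "min_counts": 500, "min_genes": 50, "max_pct_mito": 20.0})
    # n_ctrl sized to the default simulated gene universe (~60 genes per bin)
    scoring: dict = field(default_factory=lambda: {"n_bins": 24, "n_ctrl": 50})
    malignancy: dict = field(default_factory=dict)   # ClassificationParams fields
    gate: dict = field(default_factory=dict)         # GateRule fields
    repertoire: dict = field(default_factory=lambda: {
        "identity_threshold": 0.80, "mutation_freq_threshold": 2.0,
        "min_clone_size": 10})
    de: dict = field(default_factory=lambda: {"alpha_levels": [0.001, 0.05]})

    def __post_init__(self) -> None:
        if self.simulate and self.inputs:
            raise ValueError("configure either a simulation block or input paths, not both")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _load_inputs(config: RunConfig):
    """Either simulate a dataset or read matrices/repertoires from disk."""
    if config.inputs:
        matrix = iof.read_mtx_dir(config.inputs["mtx_dir"])
        annotation = iof.read_annotation(config.inputs["annotation"])
        records, rejected = iof.read_airr(config.inputs["airr"])
        if rejected:
            logger.warning("AIRR input: %d rows rejected", len(rejected))
        gene_sets = {
            "malignant": iof.read_gene_set(config.inputs["malignant_genes"], "malignant"),
            "nonmalignant": iof.read_gene_set(
                config.inputs["nonmalignant_genes"], "nonmalignant"),
        }
        germlines = iof.read_germline_fasta(config.inputs["germline_v"]) \
            if "germline_v" in config.inputs else syn.load_packaged_germlines()[0]
        return matrix, annotation, records, gene_sets, germlines, None
    sim_cfg = syn.SimulationConfig(**{"seed": config.seed, **config.simulate})
    ds = syn.generate_dataset(sim_cfg)
    return ds.matrix, ds.annotation, ds.rearrangements, ds.gene_sets, ds.germlines, ds.truth


def analyze_dataset(
    matrix, annotation, records, gene_sets, germlines, config: RunConfig
) -> dict:
    """Run every analysis stage in memory; returns the result bundle."""
    bundle: dict = {}
    # --- expression arm -------------------------------------------------
    filtered, qc_report = ms.qc_filter(matrix, **config.qc)
    lognorm = ms.log_normalize(filtered)
    bundle["qc"] = qc_report

    gate = mal.GateRule(**config.gate)
    gated_mask = mal.gate_plasma_cells(lognorm, gate)
    gated = lognorm.subset_cells(gated_mask)
    bundle["n_gated"] = gated.n_cells

    params = mal.ClassificationParams(**config.malignancy)
    scores = pd.DataFrame({"cell_id": gated.cells})
    scores["malignant_score"] = ms.module_score(
        gated, gene_sets["malignant"], seed=config.seed, **config.scoring)
    scores["nonmalignant_score"] = ms.module_score(
        gated, gene_sets["nonmalignant"], seed=config.seed + 1, **config.scoring)
    scores = mal.classify_cells(scores, params)
    ann_idx = annotation.set_index("cell_id")
    scores["sample_id"] = ann_idx.loc[scores["cell_id"], "sample_id"].to_numpy()
    scores["group"] = ann_idx.loc[scores["cell_id"], "group"].to_numpy()
    bundle["scores"] = scores
    bundle["histogram"] = mal.compound_distribution(scores, params)
    bundle["group_comparison"] = mal.compare_groups(scores)

    cell_groups = ann_idx.loc[lognorm.cells, "group"].to_numpy()
    de_table, de_counts = mal.differential_expression(
        lognorm, cell_groups, tuple(config.de["alpha_levels"]))
    bundle["de_table"] = de_table
    bundle["de_counts"] = de_counts

    # --- repertoire arm -------------------------------------------------
    rep_cfg = config.repertoire
    samples = sorted({r.sample_id for r in records if r.sample_id})
    group_of = dict(annotation[["sample_id", "group"]].drop_duplicates().itertuples(index=False))
    clonesets: dict[str, rep.CloneSet] = {}
    per_sample_records: dict[str, list] = {}
    for s in samples:
        recs = [r for r in records if r.sample_id == s]
        per_sample_records[s] = recs
        clonesets[s] = rep.assign_clonotypes(
            recs, identity_threshold=rep_cfg["identity_threshold"])
    bundle["clonesets"] = clonesets

    mut_freq = {
        s: rep.mutated_clonotype_frequency(
            clonesets[s], freq_threshold=rep_cfg["mutation_freq_threshold"],
            min_clone_size=rep_cfg["min_clone_size"])
        for s in samples
    }
    bundle["mutated_clonotype_frequency"] = pd.Series(mut_freq)

    iso_freq, iso_unknown = rep.isotype_frequencies(records)
    bundle["isotype_frequencies"] = iso_freq
    bundle["isotype_unknown"] = iso_unknown
    fam_freq, vj = rep.vfamily_and_vj_matrix(records)
    bundle["vfamily_frequencies"] = fam_freq
    bundle["vj_matrix"] = vj
    bundle["cdr3"] = {
        g: rep.cdr3_length_distribution(
            [r for r in records if group_of.get(r.sample_id) == g])
        for g in ("treated", "untreated")
        if any(group_of.get(r.sample_id) == g for r in records)
    }

    vh = rep.vh1_72_analysis(records, germlines)
    bundle["vh1_72"] = vh
    # pooled W33L 2x2 (treated vs untreated)
    wl = vh["w33l_counts"].copy()
    wl["group"] = [group_of.get(s, "unknown") for s in wl.index]
    tab = wl.groupby("group")[["L", "W", "other"]].sum()
    if {"treated", "untreated"} <= set(tab.index):
        table = np.array([
            [tab.loc["treated", "L"], tab.loc["treated", "W"] + tab.loc["treated", "other"]],
            [tab.loc["untreated", "L"], tab.loc["untreated", "W"] + tab.loc["untreated", "other"]],
        ])
        bundle["w33l_fisher"] = st.fisher_exact(table)
        bundle["w33l_table"] = table

    # clone sizes: pool each sample's clones within its group
    size_rows = []
    for s in samples:
        g = group_of.get(s)
        for c in clonesets[s].clones:
            if c.size >= 2:
                size_rows.append({"group": g, "sample_id": s, "clone_id": c.clone_id,
                                  "size": c.size,
                                  "log10_size": float(np.log10(c.size))})
    if size_rows:
        sizes_df = pd.DataFrame(size_rows)
        bundle["clone_sizes"] = sizes_df
        by_group = {g: sub["log10_size"].to_numpy()
                    for g, sub in sizes_df.groupby("group")}
        if len(by_group) == 2 and all(len(v) >= 1 for v in by_group.values()):
            gs = sorted(by_group)
            bundle["clone_size_test"] = st.mann_whitney(by_group[gs[0]], by_group[gs[1]])

    logos = {}
    for g in ("treated", "untreated"):
        wins = [w for s in samples if group_of.get(s) == g for w in vh["windows"][s]]
        if wins:
            logos[g] = rep.kl_logo(wins)
    bundle["logos"] = logos
    return bundle


def _write_bundle(bundle: dict, annotation, records, matrix, outdir: Path, config) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    iof.write_mtx_dir(matrix, outdir / "mtx")
    iof.write_annotation(annotation, outdir / "annotation.csv")
    iof.write_airr(records, outdir / "rearrangements.tsv")
    iof.write_scores(bundle["scores"], outdir / "scores.csv")
    bundle["histogram"].to_csv(outdir / "compound_histogram.csv", index=False)
    bundle["de_table"].to_csv(outdir / "differential_expression.csv", index=False)
    clone_tables = []
    for s, cs in bundle["clonesets"].items():
        t = cs.to_frame()
        t.insert(0, "sample_id", s)
        clone_tables.append(t)
    pd.concat(clone_tables).to_csv(outdir / "clones.csv", index=False)
    bundle["isotype_frequencies"].to_csv(outdir / "isotype_frequencies.csv")
    bundle["vfamily_frequencies"].rename("frequency").to_csv(outdir / "vfamily_frequencies.csv")
    rep.vj_long_format(bundle["vj_matrix"]).to_csv(outdir / "vj_pairs.csv", index=False)
    for g, d in bundle["cdr3"].items():
        d["frequencies"].rename("frequency").to_csv(outdir / f"cdr3_lengths_{g}.csv")
    bundle["vh1_72"]["usage"].to_csv(outdir / "vh1_72_usage.csv")
    bundle["vh1_72"]["w33l_counts"].to_csv(outdir / "w33l_counts.csv")
    if "clone_sizes" in bundle:
        bundle["clone_sizes"].to_csv(outdir / "clone_sizes.csv", index=False)
    for g, logo in bundle["logos"].items():
        logo.weights.to_csv(outdir / f"kl_logo_{g}.csv")

    summary = {
        "seed": config.seed,
        "parameters": {
            "qc": config.qc, "scoring": config.scoring,
            "malignancy": config.malignancy, "gate": config.gate,
            "repertoire": config.repertoire, "de": config.de,
        },
        "scored_on": "log-normalized values",
        "qc": bundle["qc"].to_dict(),
        "n_gated": bundle["n_gated"],
        "compound_score_mann_whitney":
            bundle["group_comparison"]["mann_whitney"].to_dict(),
        "de_counts": {str(k): v for k, v in bundle["de_counts"].items()},
        "mutated_clonotype_frequency": {
            k: (None if v is None else float(v))
            for k, v in bundle["mutated_clonotype_frequency"].items()
        },
        "vh1_72_usage": {k: float(v) for k, v in bundle["vh1_72"]["usage"].items()},
    }
    if "w33l_fisher" in bundle:
        summary["w33l_fisher"] = bundle["w33l_fisher"].to_dict()
    if "clone_size_test" in bundle and bundle["clone_size_test"] is not None:
        summary["clone_size_mann_whitney"] = bundle["clone_size_test"].to_dict()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; writes the report bundle and returns the summary."""
    outdir = Path(config.outdir)
    try:
        matrix, annotation, records, gene_sets, germlines, truth = _load_inputs(config)
        bundle = analyze_dataset(matrix, annotation, records, gene_sets, germlines, config)
        summary = _write_bundle(bundle, annotation, records, matrix, outdir, config)
        if truth is not None:
            truth.to_json(outdir / "truth.json")
            for name, gs in gene_sets.items():
                iof.write_gene_set(gs, outdir / f"{name}_genes.txt")
    except Exception:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "FAILED").touch()
        raise
    return summary
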