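"""End-to-end orchestration of the synthetic demonstration.

``run_all`` simulates a two-group cfDNA cohort, computes occupancy
(RPKM and NDR depth), runs the occupancy/expression overlap tests,
calls differential TSSs with clustering order, cross-validates the
promoter classifier, and writes a JSON manifest with a checksum for
every output file. Every stochastic step receives a seed derived from
the single root seed, so two runs with the same configuration produce
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .association import assign_categories, permutation_overlap_test
from .classifier import repeated_cv
from .differential import AnalysisThresholds, average_linkage_order, call_differential
from .occupancy import compute_metagene_profile, compute_ndr_depth, occupancy_matrix
from .simulate import CohortDesign, SimulatorConfig, simulate_cohort, simulate_landscape

logger = logging.getLogger("nucleofoot")


@dataclasses.dataclass
class RunConfig:
    """Parameters of the demonstration pipeline (desk-scale defaults)."""

    out_dir: str = "nucleofoot-run"
    seed: int = 0
    # simulator scale
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 400
    min_tss_spacing: int = 4000
    fragments_per_sample: int = 40_000
    depletion_strength: float = 0.8
    background_fraction: float = 0.1
    # cohort design
    n_group_a: int = 12
    n_group_b: int = 8
    n_differential_tss: int = 60
    effect_factor: float = 2.0
    # analysis
    flank: int = 1000
    p_max: float = 0.01
    fc_min: float = 1.5
    fdr_max: float | None = None
    pseudocount: float = 0.01
    n_permutations: int = 1000
    cv_folds: int = 5
    cv_repeats: int = 10

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def echo_dict(self) -> dict:
        """Effective parameters echoed into the manifest. The output
        location is omitted so manifests are byte-identical wherever
        the same run is placed (output paths are relative)."""
        d = self.to_dict()
        d.pop("out_dir")
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute simulate -> profile -> overlap-test -> differential ->
    classify on synthetic data; returns the manifest dict (also written
    to ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "fragments").mkdir(exist_ok=True)
    written: list[Path] = []

    def emit(path: Path):
        written.append(path)
        return path

    sim_cfg = SimulatorConfig(
        n_chroms=config.n_chroms,
        chrom_length=config.chrom_length,
        n_genes=config.n_genes,
        min_tss_spacing=config.min_tss_spacing,
        fragments_per_sample=config.fragments_per_sample,
        depletion_strength=config.depletion_strength,
        background_fraction=config.background_fraction,
        seed=config.seed,
    )
    design = CohortDesign(
        n_group_a=config.n_group_a,
        n_group_b=config.n_group_b,
        n_differential_tss=config.n_differential_tss,
        effect_factor=config.effect_factor,
    )
    logger.info("simulate: %d genes, %d+%d samples, seed %d",
                config.n_genes, config.n_group_a, config.n_group_b, config.seed)
    landscape = simulate_landscape(sim_cfg)
    samples_a, samples_b, truth = simulate_cohort(landscape, sim_cfg, design)
    all_samples = samples_a + samples_b

    io.write_tss_table(landscape.tss, emit(out / "tss.tsv"))
    io.write_expression(landscape.expression, emit(out / "expression.tsv"))
    io.write_json_result(emit(out / "truth.json"), truth.to_json_dict())
    for fs in all_samples:
        io.write_fragments(fs, emit(out / "fragments" / f"{fs.sample_id}.bed"))

    logger.info("profile: occupancy over %d TSSs x %d samples",
                len(landscape.tss), len(all_samples))
    occ = occupancy_matrix(all_samples, landscape.tss, flank=config.flank)
    io.write_matrix(emit(out / "occupancy_rpkm.tsv"), occ.df, index_label="tss_id")
    ndr = pd.concat(
        [compute_ndr_depth(fs, landscape.tss) for fs in all_samples], axis=1
    )
    io.write_matrix(emit(out / "ndr_depth.tsv"), ndr, index_label="tss_id")

    heg = landscape.expression.index[landscape.expression > 10]
    ueg = landscape.expression.index[landscape.expression == 0]
    for name, subset in (("heg", heg), ("ueg", ueg)):
        prof = compute_metagene_profile(samples_a[0], landscape.tss, subset,
                                        flank=config.flank)
        prof.to_frame().to_csv(emit(out / f"metagene_{name}.tsv"),
                               sep="\t", index=False)

    logger.info("overlap-test: %d permutations", config.n_permutations)
    mean_ndr = ndr[[fs.sample_id for fs in samples_a]].mean(axis=1)
    cats = assign_categories(mean_ndr, landscape.expression)
    overlap_results = {}
    for occ_name, occ_set in (("htss", cats.htss), ("ltss", cats.ltss)):
        for expr_name, expr_set in (("heg", cats.heg), ("ueg", cats.ueg)):
            res = permutation_overlap_test(
                occ_set, expr_set, cats.universe,
                n_permutations=config.n_permutations,
                seed=int(np.random.SeedSequence((config.seed, 10)).generate_state(1)[0]),
            )
            overlap_results[f"{occ_name}_x_{expr_name}"] = res.to_dict()
    io.write_json_result(emit(out / "overlap_tests.json"), overlap_results)

    logger.info("differential: p<%g, FC>=%g", config.p_max, config.fc_min)
    labels = {fs.sample_id: "a" for fs in samples_a}
    labels.update({fs.sample_id: "b" for fs in samples_b})
    thresholds = AnalysisThresholds(
        p_max=config.p_max, fc_min=config.fc_min,
        fdr_max=config.fdr_max, pseudocount=config.pseudocount,
    )
    table = call_differential(occ, labels, thresholds)
    table.to_csv(emit(out / "differential.tsv"), sep="\t", index_label="tss_id")
    sig = table.index[table["call"] != "ns"]
    cluster_rows = sig if len(sig) >= 2 else occ.df.index
    row_order, _ = average_linkage_order(occ.df.loc[cluster_rows], axis="rows")
    col_order, _ = average_linkage_order(occ.df.loc[cluster_rows], axis="columns")
    with open(emit(out / "cluster_order.tsv"), "wt") as fh:
        fh.write("axis\tid\n")
        for rid in row_order:
            fh.write(f"row\t{rid}\n")
        for cid in col_order:
            fh.write(f"column\t{cid}\n")

    logger.info("classify: %d-fold CV x %d repeats", config.cv_folds, config.cv_repeats)
    report = repeated_cv(
        occ, labels, n_folds=config.cv_folds, n_repeats=config.cv_repeats,
        seed=int(np.random.SeedSequence((config.seed, 11)).generate_state(1)[0] % (2**31)),
        filter_thresholds=thresholds, filter_scope="global",
    )
    io.write_json_result(emit(out / "cv_report.json"), report.to_json_dict())
    auc_df = pd.DataFrame(
        report.aucs,
        index=[f"repeat{r}" for r in range(report.n_repeats)],
        columns=[f"fold{f}" for f in range(report.n_folds)],
    )
    auc_df.to_csv(emit(out / "cv_aucs.tsv"), sep="\t", index_label="repeat")

    manifest = {
        "schema_version": io.SCHEMA_VERSION,
        "config": config.echo_dict(),
        "n_significant_tss": int(len(sig)),
        "median_auc": report.median_auc,
        "outputs": [
            {
                "path": str(p.relative_to(out)),
                "sha256": _sha256(p),
                "bytes": p.stat().st_size,
            }
            for p in sorted(written)
        ],
    }
    io.write_json_result(out / "manifest.json", manifest)
    logger.info("run-all complete: %d outputs, %d significant TSSs, median AUC %.3f",
                len(written), len(sig), report.median_auc)
    return manifest
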