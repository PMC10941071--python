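"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` executes simulate (optional) -> covariance -> functional
graphs -> gradients -> spins -> network statistics, writing every product
as headered TSV/JSON plus a manifest of content hashes.  A single global
seed fans out to per-stage seeds through a fixed offset scheme so stages
can be rerun in isolation; identical config + seed yields byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariance, fc_graph, gradients, network_analysis, spin_perm
from . import synthetic_data

#: fixed per-stage seed offsets (seed fan-out: stage_seed = seed + offset)
STAGE_SEED_OFFSETS = {"simulate": 0, "spins": 101}


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline; defaults follow the analysis settings
    (10% row density, k=10 components, 1,000 spins, FDR at 0.05)."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    # synthetic cohort (set simulate=False to read an existing cohort dir)
    simulate: bool = True
    in_dir: str | None = None
    n_subjects: int = 176
    n_parcels: int = 400
    n_timepoints: int = 240
    # analysis settings
    density: float = 0.10
    k: int = 10
    n_gradients_analyzed: int = 4
    n_perm: int = 1000
    fdr_alpha: float = 0.05
    confound_terms: tuple = ("age_linear", "age_quadratic", "sex")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["confound_terms"] = list(d["confound_terms"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "confound_terms" in d:
            d["confound_terms"] = tuple(d["confound_terms"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(in_dir) -> dict:
    """Cross-check a cohort directory; returns a machine-readable report
    with a (possibly empty) failure list rather than raising."""
    src = Path(in_dir)
    failures = []
    report = {"in_dir": str(src), "failures": failures}
    try:
        atlas = synthetic_data.ParcelAtlas.from_tsv(src / "atlas.tsv")
    except Exception as e:  # noqa: BLE001 - report, don't raise
        failures.append({"check": "atlas", "detail": str(e)})
        return report
    P = atlas.n_parcels
    cov_path = src / "covariates.tsv"
    if not cov_path.exists():
        failures.append({"check": "covariates", "detail": "covariates.tsv missing"})
        return report
    cov = pd.read_csv(cov_path, sep="\t", index_col="subject")
    for name in ("d1dr", "thickness"):
        f = src / f"{name}.tsv"
        if not f.exists():
            failures.append({"check": name, "detail": f"{f.name} missing"})
            continue
        df = pd.read_csv(f, sep="\t")
        if len(df) != P:
            failures.append({"check": name,
                             "detail": f"{len(df)} parcels vs atlas {P}"})
        subjects = [c for c in df.columns if c != "parcel_id"]
        missing = [s for s in subjects if s not in cov.index]
        if missing:
            failures.append({"check": name,
                             "detail": f"subjects missing covariates: {missing[:5]}"})
        vals = df[subjects].to_numpy(dtype=float)
        bad = np.argwhere(~np.isfinite(vals))
        for parcel, si in bad[:20]:
            failures.append({"check": name,
                             "detail": f"non-finite value at subject "
                                       f"{subjects[si]}, parcel {parcel}"})
    for f in sorted(src.glob("ts_*.tsv")):
        ts = pd.read_csv(f, sep="\t", header=None)
        if len(ts) != P:
            failures.append({"check": f.name,
                             "detail": f"{len(ts)} parcels vs atlas {P}"})
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the result bundle (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: cohort ----------------------------------------------------
    if config.simulate:
        atlas = synthetic_data.make_atlas(
            config.n_parcels, seed=config.seed + STAGE_SEED_OFFSETS["simulate"])
        spec = synthetic_data.CohortSpec(
            n_subjects=config.n_subjects, n_timepoints=config.n_timepoints,
            seed=config.seed + STAGE_SEED_OFFSETS["simulate"])
        cohort = synthetic_data.simulate_cohort(spec, atlas)
        synthetic_data.write_cohort(cohort, out / "cohort")
    else:
        if config.in_dir is None:
            raise ValueError("simulate=False requires in_dir")
        report = validate_inputs(config.in_dir)
        if report["failures"]:
            raise ValueError(f"stage 'validate' failed: {report['failures'][:3]}")
        cohort = synthetic_data.read_cohort(config.in_dir)
        atlas = cohort.atlas

    # --- stage: covariance ------------------------------------------------
    mask = covariance.detect_outliers(cohort.d1dr)
    d1_clean = covariance.impute_outliers(cohort.d1dr, mask)
    d1_adj = covariance.irca_matrix(d1_clean, residualize_first=True,
                                    terms=config.confound_terms)
    d1_adj_raw = covariance.irca_matrix(d1_clean, residualize_first=False)
    comparison = covariance.compare_matrices(d1_adj_raw, d1_adj)
    th_adj = covariance.irca_matrix(cohort.thickness, residualize_first=True,
                                    terms=config.confound_terms)
    d1_adj.to_tsv(out / "d1dr_adjacency.tsv")
    th_adj.to_tsv(out / "thickness_adjacency.tsv")

    # --- stage: functional graphs ----------------------------------------
    subject_graphs = {sid: fc_graph.subject_fc(ts)
                      for sid, ts in cohort.timeseries.items()}
    group = fc_graph.group_fc(subject_graphs.values())
    group.to_tsv(out / "group_fc.tsv")

    # --- stage: gradients -------------------------------------------------
    fc_grad = gradients.adjacency_gradients(group, config.density, config.k)
    d1_grad = gradients.adjacency_gradients(d1_adj, config.density, config.k)
    d1_aligned = gradients.procrustes_align(d1_grad, fc_grad, target_id="fc_group")
    fc_grad.to_tsv(out / "fc_gradients.tsv")
    d1_aligned.to_tsv(out / "d1dr_gradients_aligned.tsv")
    _, k50 = gradients.variance_profile(fc_grad, cumulative_threshold=0.5)

    # --- stage: spins -----------------------------------------------------
    spin_seed = config.seed + STAGE_SEED_OFFSETS["spins"]
    spins = spin_perm.build_spins(atlas, n_perm=config.n_perm, seed=spin_seed,
                                  method="nearest")
    matrix_spins = spin_perm.build_spins(atlas, n_perm=config.n_perm,
                                         seed=spin_seed, method="assignment")
    spins.to_tsv(out / "spins.tsv")

    grad_corr = []
    for i in range(min(config.n_gradients_analyzed, config.k)):
        rho, p, _ = spin_perm.spin_map_test(
            d1_aligned.gradient(i), fc_grad.gradient(i), spins)
        grad_corr.append({"gradient": f"G{i+1}", "rho": rho, "p_spin": p})
    grad_corr = pd.DataFrame(grad_corr)

    # --- stage: network analysis -----------------------------------------
    labels = atlas.network
    masks = network_analysis.edge_masks(labels)
    wb = network_analysis.within_between_summary(d1_adj, masks)
    stat = network_analysis.within_minus_between(labels)
    wb_obs, wb_p, _ = spin_perm.spin_matrix_test(d1_clean, matrix_spins, stat)
    density_vec, f_stat, f_p = network_analysis.nodal_density(d1_adj, labels)

    dist = network_analysis.euclidean_distances(atlas)
    d_edges = dist[masks.iu]
    x_edges = d1_adj.upper_edges()
    y_edges = group.upper_edges()
    partial_within = network_analysis.partial_spearman_edges(
        x_edges[masks.within], y_edges[masks.within],
        [d_edges[masks.within], d_edges[masks.within] ** 2])
    partial_between = network_analysis.partial_spearman_edges(
        x_edges[masks.between], y_edges[masks.between],
        [d_edges[masks.between], d_edges[masks.between] ** 2])

    med = network_analysis.mediation_sobel(
        x_edges[masks.within], th_adj.upper_edges()[masks.within],
        y_edges[masks.within],
        covariates=[d_edges[masks.within], d_edges[masks.within] ** 2])

    # subject-level hierarchy: individual gradients aligned to the group
    ref_idx = int(np.argmax([abs(gradients.spatial_corr(
        fc_grad.gradient(i), synthetic_data.hierarchy_template(atlas)))
        for i in range(min(4, config.k))]))
    scores = network_analysis.hierarchy_score(
        d1_clean.values, fc_grad.gradient(ref_idx))
    com = pd.DataFrame(
        {net: np.empty(len(scores)) for net in network_analysis.NETWORKS})
    for s, (sid, graph) in enumerate(subject_graphs.items()):
        sg = gradients.subject_gradients(graph, fc_grad, config.density, config.k)
        com.iloc[s] = network_analysis.network_center_of_mass(
            sg.gradient(ref_idx), labels)
    positions = network_analysis.network_position_regression(
        com, scores, cohort.covariates, fdr_alpha=config.fdr_alpha)

    # --- results + manifest ----------------------------------------------
    results = {
        "matrix_comparison": {
            "spearman_rho": comparison.spearman_rho,
            "dissimilarity_variance_fraction":
                comparison.dissimilarity_variance_fraction,
        },
        "variance_explained_fc": fc_grad.variance_explained.tolist(),
        "n_gradients_over_half_variance": k50,
        "gradient_correspondence": grad_corr.to_dict(orient="records"),
        "within_between": {**wb, "spin_p": wb_p},
        "nodal_density_F": f_stat,
        "nodal_density_p": f_p,
        "partial_rho_within": partial_within,
        "partial_rho_between": partial_between,
        "mediation": dataclasses.asdict(med),
        "network_positions": positions.to_dict(orient="records"),
        "hierarchy_reference_gradient": f"G{ref_idx+1}",
    }
    (out / "results.json").write_text(
        json.dumps(results, indent=2, sort_keys=True, default=float) + "\n")
    positions.to_csv(out / "network_positions.tsv", sep="\t", index=False,
                     float_format="%.10g")
    grad_corr.to_csv(out / "gradient_correspondence.tsv", sep="\t", index=False,
                     float_format="%.10g")

    config.to_yaml(out / "config.yaml")
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "stage_seeds": {k: config.seed + v for k, v in STAGE_SEED_OFFSETS.items()},
        "config": yaml.safe_load((out / "config.yaml").read_text()),
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["manifest"] = manifest
    return results
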