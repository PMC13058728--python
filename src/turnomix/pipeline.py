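"""Stage functions tying the library into reproducible runs.

Each stage consumes typed tables, writes its results as TSV under the
configured output directory, and records what it read and wrote in a run
manifest (config snapshot, input/output SHA-256 digests, seed), so a rerun
with identical inputs reproduces identical digests for deterministic
stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .io import ExperimentDesign, RunConfig, log_stage
from .simulate import SimulationSpec, simulate_all
from .turnover import differential_half_life, filter_measurements, half_life_matrix
from .lipidomics import (average_technical_replicates, differential_lipids,
                         normalize_internal_standard, _log2_with_offset)
from .gsea import gsea_significance, rank_features
from .integration import (correlate_layers, cross_reference, export_edges,
                          filter_interactors, mad_select, prioritize_clients)

__all__ = ["RunManifest", "stage_simulate", "stage_halflife", "stage_lipids",
           "stage_gsea", "stage_integrate", "run_all"]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    stage: str
    seed: int
    config: dict
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def add_inputs(self, paths: dict) -> None:
        for name, p in paths.items():
            self.inputs[name] = _sha256(p)

    def add_outputs(self, paths: dict) -> None:
        for name, p in paths.items():
            self.outputs[name] = _sha256(p)

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def _manifest(stage: str, cfg: RunConfig) -> RunManifest:
    return RunManifest(stage=stage, seed=cfg.seed, config=asdict(cfg))


def _design_from_cfg(cfg: RunConfig) -> ExperimentDesign:
    return ExperimentDesign(pulse_time_days=cfg.pulse_days)


def stage_simulate(spec: SimulationSpec, out_dir, cfg: RunConfig | None = None
                   ) -> dict[str, Path]:
    """Generate every pipeline input plus ground-truth tables."""
    cfg = cfg or RunConfig(seed=spec.seed)
    out_dir = Path(out_dir)
    data = simulate_all(spec)
    paths = {
        "peptides": tio.write_table(data["peptides"], out_dir / "peptides.tsv"),
        "lipids": tio.write_table(data["lipids"], out_dir / "lipids.csv"),
        "transcripts": tio.write_feature_matrix(
            data["transcripts"], out_dir / "transcripts.tsv"),
        "interactome": tio.write_table(
            data["interactome"], out_dir / "interactome.tsv"),
        "protein_truth": tio.write_table(
            data["protein_truth"], out_dir / "truth_proteins.tsv"),
        "lipid_truth": tio.write_table(
            data["lipid_truth"], out_dir / "truth_lipids.tsv"),
        "transcript_truth": tio.write_table(
            data["transcript_truth"], out_dir / "truth_transcripts.tsv"),
        "client_partners": tio.write_table(
            data["client_partners"], out_dir / "truth_client_partners.tsv"),
    }
    m = _manifest("simulate", cfg)
    m.add_outputs(paths)
    m.write(out_dir / "manifest_simulate.json")
    return paths


def stage_halflife(peptides: pd.DataFrame, cfg: RunConfig,
                   design: ExperimentDesign, out_dir,
                   contaminant_ids: frozenset[str] = frozenset()
                   ) -> dict[str, object]:
    """Filters -> per-sample protein half-lives -> differential turnover."""
    out_dir = Path(out_dir)
    filtered = filter_measurements(
        peptides, intensity_floor=cfg.intensity_floor,
        ratio_bounds=(cfg.ratio_min, cfg.ratio_max),
        contaminant_ids=contaminant_ids)
    if len(filtered) == 0:
        empty = pd.DataFrame(columns=["protein_id", "sample_id",
                                      "half_life_days", "n_peptides"])
        paths = {"half_lives": tio.write_table(empty, out_dir / "half_lives.tsv")}
        m = _manifest("halflife", cfg)
        m.add_outputs(paths)
        m.write(out_dir / "manifest_halflife.json")
        return {"matrix": pd.DataFrame(), "support": pd.DataFrame(),
                "differential": {}, "paths": paths}

    matrix, support = half_life_matrix(filtered, design,
                                       min_peptides=cfg.min_peptides)
    long = matrix.stack().rename("half_life_days").reset_index()
    long.columns = ["protein_id", "sample_id", "half_life_days"]
    long["n_peptides"] = [support.at[p, s] for p, s
                          in zip(long["protein_id"], long["sample_id"])]
    diffs = differential_half_life(matrix, design, alpha=cfg.alpha,
                                   log_scale=cfg.log_scale)
    paths = {"half_lives": tio.write_table(long, out_dir / "half_lives.tsv")}
    for cond, table in diffs.items():
        paths[f"differential_{cond}"] = tio.write_table(
            table, out_dir / f"differential_turnover_{cond}.tsv")
    m = _manifest("halflife", cfg)
    m.add_outputs(paths)
    m.write(out_dir / "manifest_halflife.json")
    return {"matrix": matrix, "support": support, "differential": diffs,
            "paths": paths}


def stage_lipids(lipids: pd.DataFrame, cfg: RunConfig,
                 design: ExperimentDesign, out_dir) -> dict[str, object]:
    """IS normalization -> duplicate averaging -> moderated differential."""
    out_dir = Path(out_dir)
    normalized = normalize_internal_standard(lipids)
    matrix = average_technical_replicates(normalized)
    diffs = {}
    for cond in design.conditions:
        diffs[cond] = differential_lipids(
            matrix, design, condition=cond, alpha=cfg.alpha,
            fc_threshold=cfg.fc_threshold, moderate=cfg.moderate_variance)
    flat = matrix.reset_index()
    paths = {"normalized_matrix": tio.write_table(
        flat, out_dir / "lipid_matrix.tsv")}
    for cond, table in diffs.items():
        paths[f"differential_{cond}"] = tio.write_table(
            table, out_dir / f"differential_lipids_{cond}.tsv")
    m = _manifest("lipids", cfg)
    m.add_outputs(paths)
    m.write(out_dir / "manifest_lipids.json")
    return {"matrix": matrix, "differential": diffs, "paths": paths}


def _collapsed_rank_input(diff: pd.DataFrame, design: ExperimentDesign
                          ) -> pd.DataFrame:
    """feature_id / p_value / log2fc (mean over mutants) for ranking."""
    mutants = [g for g in design.genotypes if g != design.reference_genotype]
    fc_cols = [f"log2fc_{g}" for g in mutants if f"log2fc_{g}" in diff.columns]
    out = pd.DataFrame({
        "feature_id": diff["feature_id"],
        "p_value": diff["p_value"],
        "log2fc": diff[fc_cols].mean(axis=1) if fc_cols else 0.0,
    })
    return out.loc[out["p_value"].notna()].reset_index(drop=True)


def stage_gsea(diff: pd.DataFrame, gene_sets, cfg: RunConfig,
               design: ExperimentDesign, out_dir, label: str = "gsea"
               ) -> dict[str, object]:
    """Rank a differential table and test gene sets by permutation."""
    out_dir = Path(out_dir)
    ranked = rank_features(_collapsed_rank_input(diff, design))
    results = gsea_significance(ranked, gene_sets, n_perm=cfg.n_perm,
                                weight=cfg.gsea_weight, seed=cfg.seed)
    paths = {label: tio.write_table(results, out_dir / f"{label}.tsv")}
    m = _manifest("gsea", cfg)
    m.add_outputs(paths)
    m.write(out_dir / f"manifest_{label}.json")
    return {"ranked": ranked, "results": results, "paths": paths}


def _log2_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    vals = _log2_with_offset(matrix.to_numpy(float))
    return pd.DataFrame(vals, index=matrix.index, columns=matrix.columns)


def stage_integrate(interactome: pd.DataFrame, diffs: dict[str, pd.DataFrame],
                    half_life_matrix: pd.DataFrame,
                    lipid_matrix: pd.DataFrame,
                    transcript_matrix: pd.DataFrame,
                    cfg: RunConfig, design: ExperimentDesign, out_dir
                    ) -> dict[str, object]:
    """Interactor filter -> cross-reference -> MAD -> correlation -> clients."""
    out_dir = Path(out_dir)
    ids = filter_interactors(interactome, min_ratio=cfg.min_enrichment)
    conds = list(design.conditions)
    summary = cross_reference(ids, diffs[conds[0]], diffs[conds[1]], design,
                              alpha=cfg.alpha, mode=cfg.direction_mode)

    prot = _log2_matrix(half_life_matrix.loc[
        [p for p in half_life_matrix.index if p in ids]])
    if isinstance(lipid_matrix.index, pd.MultiIndex):
        lipid_matrix = lipid_matrix.droplevel("lipid_class")
    lip = mad_select(_log2_matrix(lipid_matrix), quantile=cfg.mad_quantile)
    tra = mad_select(_log2_matrix(transcript_matrix), quantile=cfg.mad_quantile)

    edges = pd.concat([
        correlate_layers(prot, lip, layer_a_name="protein",
                         layer_b_name="lipid"),
        correlate_layers(prot, tra, layer_a_name="protein",
                         layer_b_name="transcript"),
    ], ignore_index=True)

    entries = interactome.loc[interactome["protein_id"].isin(ids)]
    candidates, cand_edges = prioritize_clients(
        entries, diffs[cfg.candidate_condition], edges,
        r_threshold=cfg.r_threshold, alpha=cfg.alpha)

    summary_df = pd.DataFrame([summary.as_dict()])
    paths = {
        "crossref_summary": tio.write_table(
            summary_df, out_dir / "crossref_summary.tsv"),
        "crossref_assignments": tio.write_table(
            summary.assignments, out_dir / "crossref_assignments.tsv"),
        "client_candidates": tio.write_table(
            candidates, out_dir / "client_candidates.tsv"),
    }
    kept = export_edges(candidates, cand_edges, out_dir / "client_edges.tsv")
    paths["client_edges"] = out_dir / "client_edges.tsv"
    m = _manifest("integrate", cfg)
    m.add_outputs(paths)
    m.write(out_dir / "manifest_integrate.json")
    return {"interactor_ids": ids, "summary": summary,
            "candidates": candidates, "edges": edges,
            "candidate_edges": kept, "paths": paths}


def run_all(cfg: RunConfig, spec: SimulationSpec, out_dir,
            gene_sets=None) -> dict[str, object]:
    """Chain every stage on a synthetic data set (deterministic per seed)."""
    out_dir = Path(out_dir)
    design = spec.design
    data = simulate_all(spec)
    stage_simulate(spec, out_dir / "inputs", cfg)
    hl = stage_halflife(data["peptides"], cfg, design, out_dir)
    lp = stage_lipids(data["lipids"], cfg, design, out_dir)
    gs = None
    if gene_sets:
        gs = stage_gsea(hl["differential"][cfg.candidate_condition],
                        gene_sets, cfg, design, out_dir,
                        label="gsea_turnover")
    it = stage_integrate(data["interactome"], hl["differential"],
                         hl["matrix"], lp["matrix"], data["transcripts"],
                         cfg, design, out_dir)
    log_stage("run_all", 0, 0, seed=cfg.seed)
    return {"data": data, "halflife": hl, "lipids": lp, "gsea": gs,
            "integration": it}
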