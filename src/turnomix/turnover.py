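"""Protein turnover from a single heavy-pulse timepoint.

After a pulse of heavy-isotope amino acids of duration t_s, the
heavy-to-light abundance ratio of a peptide, psi = H/L, encodes the
degradation rate of its parent protein: under first-order turnover at
steady state the light channel decays as e^(-k t_s), the heavy channel
accumulates as 1 - e^(-k t_s), so psi = e^(k t_s) - 1 and

    t_half = t_s * ln 2 / ln(1 + psi).

Peptide half-lives are aggregated per protein and sample as the harmonic
mean over unique peptides (peptides observed under more than one protein
accession are discarded). Differential turnover across genotypes is a
per-protein one-way ANOVA on log2 half-lives with Benjamini-Hochberg
correction across the tested proteome.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExperimentDesign, log_stage
from .stats import bh_adjust, oneway_anova_matrix

__all__ = [
    "peptide_half_life",
    "protein_half_life",
    "filter_measurements",
    "compute_psi",
    "half_life_matrix",
    "differential_half_life",
    "differential_matrix",
]


def peptide_half_life(psi, pulse_time_days):
    """Half-life (days) from a single-timepoint heavy-to-light ratio.

    Evaluates t_half = t_s * ln2 / ln(1 + psi); strictly decreasing in psi.
    Accepts scalars or arrays; psi and t_s must be positive.
    """
    psi = np.asarray(psi, dtype=float)
    ts = np.asarray(pulse_time_days, dtype=float)
    if np.any(psi <= 0):
        raise ValueError("psi must be > 0")
    if np.any(ts <= 0):
        raise ValueError("pulse_time_days must be > 0")
    out = ts * np.log(2.0) / np.log1p(psi)
    return float(out) if out.ndim == 0 else out


def protein_half_life(peptide_half_lives: Sequence[float]) -> tuple[float, int]:
    """Harmonic-mean half-life over a protein's unique peptides.

    Returns (half_life, n_peptides); raises on an empty list — the caller
    is expected to drop proteins with no surviving peptides.
    """
    t = np.asarray(peptide_half_lives, dtype=float)
    if t.size == 0:
        raise ValueError("no peptide half-lives to aggregate")
    if np.any(t <= 0):
        raise ValueError("half-lives must be > 0")
    return float(t.size / np.sum(1.0 / t)), int(t.size)


def compute_psi(table: pd.DataFrame) -> pd.Series:
    """Heavy-to-light ratio per record; NaN where either channel is 0/missing."""
    light = table["light_intensity"].to_numpy(float)
    heavy = table["heavy_intensity"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = np.where((light > 0) & (heavy > 0), heavy / light, np.nan)
    return pd.Series(psi, index=table.index, name="psi")


def filter_measurements(table: pd.DataFrame,
                        intensity_floor: float = 1000.0,
                        ratio_bounds: tuple[float, float] = (0.02, 100.0),
                        contaminant_ids: frozenset[str] | set[str] = frozenset(),
                        ) -> pd.DataFrame:
    """Apply the raw-report filters in order, logging per-rule removals.

    Removes (1) contaminant rows, (2) rows where either channel intensity is
    below the floor or missing, (3) rows whose heavy-to-light ratio falls
    strictly above/below the bounds — retention at the exact bounds is
    inclusive. An empty result is a warning, not an error.
    """
    lo, hi = ratio_bounds
    if not (0 < lo < hi):
        raise ValueError("require 0 < lo < hi for ratio bounds")
    n_in = len(table)

    contam = table["is_contaminant"].to_numpy(bool) | \
        table["protein_id"].isin(contaminant_ids).to_numpy()
    t = table.loc[~contam]
    n_contam = int(contam.sum())

    light = t["light_intensity"].to_numpy(float)
    heavy = t["heavy_intensity"].to_numpy(float)
    low = ~((light >= intensity_floor) & (heavy >= intensity_floor))
    t = t.loc[~low]
    n_low = int(low.sum())

    psi = compute_psi(t).to_numpy()
    out_of_range = ~((psi >= lo) & (psi <= hi))
    t = t.loc[~out_of_range]
    n_range = int(out_of_range.sum())

    log_stage("filter_measurements", n_in, len(t),
              {"contaminant": n_contam, "below_intensity_floor": n_low,
               "ratio_out_of_bounds": n_range})
    if len(t) == 0:
        import logging
        logging.getLogger("turnomix").warning(
            "filter_measurements: no records survive the filters")
    return t.reset_index(drop=True)


def half_life_from_intensity_arrays(light: np.ndarray, heavy: np.ndarray,
                                    pulse_time_days: float,
                                    intensity_floor: float = 1000.0,
                                    ratio_bounds: tuple[float, float] = (0.02, 100.0),
                                    ) -> np.ndarray:
    """Array kernel of the full estimator: filters, per-peptide half-life,
    harmonic mean over the peptide axis.

    ``light``/``heavy`` have shape (n_proteins, n_peptides, n_samples);
    returns the (n_proteins, n_samples) harmonic-mean half-life matrix with
    NaN where no peptide survives the intensity-floor and ratio filters.
    Identical arithmetic to the DataFrame pipeline, for simulation studies
    at proteome scale.
    """
    lo, hi = ratio_bounds
    valid = (light >= intensity_floor) & (heavy >= intensity_floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = np.where(valid, heavy / light, np.nan)
    valid &= (psi >= lo) & (psi <= hi)
    with np.errstate(invalid="ignore"):
        t = pulse_time_days * np.log(2.0) / np.log1p(psi)
    inv = np.where(valid, 1.0 / t, 0.0)
    n = valid.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        hm = np.where(n > 0, n / inv.sum(axis=1), np.nan)
    return hm


def _unique_peptides(table: pd.DataFrame) -> pd.DataFrame:
    """Drop peptides observed under more than one protein accession."""
    owners = table.groupby("peptide_seq")["protein_id"].nunique()
    shared = set(owners.index[owners > 1])
    if shared:
        table = table.loc[~table["peptide_seq"].isin(shared)]
    return table


def half_life_matrix(table: pd.DataFrame, design: ExperimentDesign,
                     min_peptides: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protein, per-sample harmonic-mean half-lives from filtered peptides.

    Returns ``(matrix, support)``: ``matrix`` is protein x sample half-lives
    in days (NaN where unquantified), ``support`` the matching unique-peptide
    counts. Proteins whose peptide support falls below ``min_peptides`` in a
    sample are set missing there.
    """
    t = _unique_peptides(table)
    psi = compute_psi(t)
    keep = psi.notna()
    t = t.loc[keep]
    hl = peptide_half_life(psi[keep].to_numpy(), design.pulse_time_days)
    work = pd.DataFrame({
        "protein_id": t["protein_id"].to_numpy(),
        "sample_id": t["sample_id"].to_numpy(),
        "inv_t": 1.0 / hl,
    })
    grp = work.groupby(["protein_id", "sample_id"])["inv_t"].agg(["mean", "count"])
    hm = (1.0 / grp["mean"]).unstack("sample_id")
    n_pep = grp["count"].unstack("sample_id")
    cols = [s for s in design.sample_ids() if s in hm.columns]
    extra = [s for s in hm.columns if s not in cols]
    hm = hm[cols + extra]
    n_pep = n_pep.reindex(columns=hm.columns)
    low = n_pep.fillna(0) < min_peptides
    hm = hm.mask(low)
    log_stage("half_life_matrix", len(table), int(hm.notna().sum().sum()))
    return hm, n_pep.fillna(0).astype(int)


def differential_matrix(matrix: pd.DataFrame, design: ExperimentDesign,
                        condition: str, alpha: float = 0.05,
                        log_scale: bool = True) -> pd.DataFrame:
    """One-way ANOVA across genotypes within one condition.

    ``matrix`` is protein x sample (half-lives in days). The test runs on
    log2 values by default; direction per mutant is the sign of
    (mutant group mean - reference group mean), reported only where
    p_adj < alpha. Proteins with fewer than two non-missing replicates in
    any genotype are excluded from the BH family and flagged untested.
    """
    samples = [s for s in design.sample_ids(condition) if s in matrix.columns]
    sub = matrix[samples]
    geno_of = {s: s.rsplit("_", 2)[0] for s in samples}
    groups = []
    for g in design.genotypes:
        idx = [i for i, s in enumerate(samples) if geno_of[s] == g]
        groups.append(np.asarray(idx, dtype=int))

    vals = sub.to_numpy(float)
    if log_scale:
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(vals > 0, np.log2(vals), np.nan)
    res = oneway_anova_matrix(vals, groups, min_per_group=2)
    p_adj = bh_adjust(res.p)

    out = pd.DataFrame(index=matrix.index)
    out.index.name = "feature_id"
    out["condition"] = condition
    out["p_value"] = res.p
    out["p_adj"] = p_adj
    out["tested"] = res.tested
    out["degenerate"] = res.degenerate
    ref = design.reference_genotype
    for j, g in enumerate(design.genotypes):
        out[f"mean_{g}"] = res.group_means[:, j]
        out[f"n_{g}"] = res.n_per_group[:, j]
    sig = p_adj < alpha
    for j, g in enumerate(design.genotypes):
        if g == ref:
            continue
        delta = res.group_means[:, j] - res.group_means[:, 0]
        direction = np.where(delta > 0, "prolonged",
                             np.where(delta < 0, "shortened", "none"))
        direction = np.where(sig & ~np.isnan(delta), direction, "none")
        out[f"direction_{g}"] = direction
        out[f"log2fc_{g}"] = delta if log_scale else np.log2(
            res.group_means[:, j] / res.group_means[:, 0])
    log_stage(f"differential_half_life[{condition}]", len(matrix),
              int(res.tested.sum()),
              {"untested": int((~res.tested).sum())})
    return out.reset_index()


def differential_half_life(matrix: pd.DataFrame, design: ExperimentDesign,
                           alpha: float = 0.05, log_scale: bool = True
                           ) -> dict[str, pd.DataFrame]:
    """Differential turnover per condition; keys are condition labels."""
    return {c: differential_matrix(matrix, design, c, alpha=alpha,
                                   log_scale=log_scale)
            for c in design.conditions}


def direction_calls(diff: pd.DataFrame, design: ExperimentDesign,
                    alpha: float = 0.05, mode: str = "either"
                    ) -> pd.Series:
    """Collapse per-mutant directions into one call per protein.

    mode='either': any mutant significant & prolonged -> 'prolonged' (and
    likewise 'shortened'; a conflict yields 'discordant'). mode='both':
    all mutants must agree.
    """
    mutants = [g for g in design.genotypes if g != design.reference_genotype]
    cols = [f"direction_{g}" for g in mutants]
    dirs = diff[cols].to_numpy(dtype=object)
    sig = diff["p_adj"].to_numpy(float) < alpha
    calls = []
    for i in range(len(diff)):
        if not sig[i]:
            calls.append("none")
            continue
        d = set(dirs[i]) - {"none"}
        if mode == "both":
            full = set(dirs[i])
            if full == {"prolonged"}:
                calls.append("prolonged")
            elif full == {"shortened"}:
                calls.append("shortened")
            else:
                calls.append("none")
        else:
            if d == {"prolonged"}:
                calls.append("prolonged")
            elif d == {"shortened"}:
                calls.append("shortened")
            elif d:
                calls.append("discordant")
            else:
                calls.append("none")
    return pd.Series(calls, index=diff.index, name="direction")
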