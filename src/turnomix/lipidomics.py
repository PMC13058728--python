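"""Internal-standard normalization and differential testing of lipidomes.

Each identified lipid species is normalized to its class-matched internal
standard measured in the same analytical run, technical duplicate runs are
averaged per biological sample, and per-species group differences are
tested with a one-way ANOVA on log2 normalized intensities with optional
empirical-Bayes variance moderation (per-species variances shrunk toward a
pooled inverse-gamma prior fitted by method of moments across species) and
Benjamini-Hochberg correction across all species. A species is called
significantly altered when p_adj < alpha and |log2 fold change| exceeds
log2 of the fold-change threshold in at least one mutant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExperimentDesign, ValidationError, log_stage
from .stats import bh_adjust, moment_squeeze_variances, oneway_anova_matrix

__all__ = [
    "normalize_internal_standard",
    "average_technical_replicates",
    "differential_lipids",
    "class_summary",
]

_TINY_P = np.nextafter(0.0, 1.0)


def normalize_internal_standard(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each species intensity by its internal standard in the same run.

    Returns the non-standard rows with a ``normalized`` column. A standard
    that is missing or zero in a run where one of its species was measured
    is an error listing the offending (run, standard) pairs.
    """
    is_rows = table.loc[table["is_internal_standard"]]
    is_level = is_rows.set_index(["run_id", "species"])["intensity"]
    dup = is_level.index.duplicated()
    if dup.any():
        is_level = is_level[~dup]

    out = table.loc[~table["is_internal_standard"]].copy()
    key = pd.MultiIndex.from_arrays(
        [out["run_id"], out["internal_standard_id"]])
    matched = is_level.reindex(key)
    bad = matched.isna() | (matched.to_numpy() <= 0)
    if bad.any():
        offenders = sorted({(r, s) for (r, s), b in zip(key, bad) if b})
        raise ValidationError(
            "internal standard missing or zero in runs: "
            + "; ".join(f"run={r} standard={s}" for r, s in offenders[:20]))
    out["normalized"] = out["intensity"].to_numpy() / matched.to_numpy()
    log_stage("normalize_internal_standard", len(table), len(out))
    return out.reset_index(drop=True)


def average_technical_replicates(normalized: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of normalized intensities across a sample's runs.

    Returns a species x sample matrix (one column per biological sample)
    with the species -> class map attached as a ``lipid_class`` index level.
    """
    grp = normalized.groupby(["species", "lipid_class", "sample_id"])
    agg = grp["normalized"].mean()
    runs = grp["run_id"].nunique()
    matrix = agg.unstack("sample_id")
    matrix.index.names = ["species", "lipid_class"]
    log_stage("average_technical_replicates", len(normalized),
              matrix.size, {"max_runs_per_sample": int(runs.max())})
    return matrix


def _log2_with_offset(values: np.ndarray) -> np.ndarray:
    """log2(x + eps) with eps = half the smallest nonzero value per species."""
    out = np.empty_like(values, dtype=float)
    for i in range(values.shape[0]):
        row = values[i]
        pos = row[np.isfinite(row) & (row > 0)]
        eps = pos.min() / 2.0 if pos.size else 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            out[i] = np.log2(row + eps)
        out[i][~np.isfinite(out[i])] = np.nan
    return out


def differential_lipids(matrix: pd.DataFrame, design: ExperimentDesign,
                        condition: str | None = None, alpha: float = 0.05,
                        fc_threshold: float = 2.0, moderate: bool = True,
                        prior_df: float | None = None) -> pd.DataFrame:
    """Per-species moderated one-way ANOVA across genotypes.

    ``matrix`` is the species x sample output of
    :func:`average_technical_replicates` (a plain species-indexed frame also
    works). When ``condition`` is given, only that condition's samples are
    tested. With ``moderate=False`` the test is the plain fixed-effects
    ANOVA; with moderation the residual variances are shrunk toward the
    pooled prior and the denominator degrees of freedom gain the prior df.
    Species with all-zero values are excluded and flagged.
    """
    samples = [s for s in design.sample_ids(condition) if s in matrix.columns]
    if not samples:
        raise ValidationError("no design samples found in the lipid matrix")
    sub = matrix[samples]
    species = (sub.index.get_level_values("species")
               if isinstance(sub.index, pd.MultiIndex) else sub.index)
    classes = (sub.index.get_level_values("lipid_class")
               if isinstance(sub.index, pd.MultiIndex) else pd.Index([""] * len(sub)))

    vals = sub.to_numpy(float)
    all_zero = np.all(~(vals > 0) | ~np.isfinite(vals), axis=1)
    logv = _log2_with_offset(vals)

    geno_of = [s.rsplit("_", 2)[0] for s in samples]
    groups = [np.asarray([i for i, g in enumerate(geno_of) if g == gt], int)
              for gt in design.genotypes]
    res = oneway_anova_matrix(logv, groups, min_per_group=2)

    p = res.p.copy()
    f = res.f.copy()
    if moderate:
        df_resid = res.df_within
        ok = res.tested & np.isfinite(res.s2_within) & ~res.degenerate & ~all_zero
        if ok.sum() >= 2:
            df = float(np.median(df_resid[ok]))
            squeezed, d0, _s0 = moment_squeeze_variances(
                res.s2_within[ok], df, prior_df=prior_df)
            f_mod = res.ms_between[ok] / squeezed
            df2 = df_resid[ok] + (d0 if np.isfinite(d0) else 1e9)
            p_mod = sps.f.sf(f_mod, res.df_between[ok], df2)
            zero_b = res.ms_between[ok] <= 0
            p_mod[zero_b] = 1.0
            p[ok] = p_mod
            f[ok] = f_mod

    tested = res.tested & ~all_zero
    p[~tested] = np.nan
    p_adj = bh_adjust(p)

    out = pd.DataFrame({
        "feature_id": np.asarray(species),
        "lipid_class": np.asarray(classes),
        "p_value": p,
        "p_adj": p_adj,
        "tested": tested,
        "excluded_all_zero": all_zero,
        "degenerate": res.degenerate,
    })
    ref_j = 0
    sig_fc = np.zeros(len(out), dtype=bool)
    for j, g in enumerate(design.genotypes):
        out[f"mean_{g}"] = res.group_means[:, j]
        out[f"n_{g}"] = res.n_per_group[:, j]
        if j == ref_j:
            continue
        delta = res.group_means[:, j] - res.group_means[:, ref_j]
        out[f"log2fc_{g}"] = delta
        passing = np.abs(delta) > np.log2(fc_threshold)
        sig_fc |= np.nan_to_num(passing)
        direction = np.where(delta > 0, "up", np.where(delta < 0, "down", "none"))
        direction = np.where((p_adj < alpha) & ~np.isnan(delta), direction, "none")
        out[f"direction_{g}"] = direction
    out["significant"] = (p_adj < alpha) & sig_fc
    log_stage(f"differential_lipids[{condition or 'all'}]", len(matrix),
              int(tested.sum()), {"all_zero": int(all_zero.sum())})
    return out


def class_summary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-class arithmetic mean of member species, per sample.

    Requires the class level on the matrix index; classes without any
    species never appear.
    """
    if not isinstance(matrix.index, pd.MultiIndex):
        raise ValidationError("class_summary needs a (species, lipid_class) index")
    return matrix.groupby(level="lipid_class").mean()
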