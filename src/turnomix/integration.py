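"""Client-protein nomination by multi-omic cross-referencing.

High-confidence bait interactors (pulldown enrichment ratio strictly above
the cutoff) are cross-referenced against differential turnover in both
culture conditions, robust-variability (MAD) filtering selects informative
lipid and transcript features, cross-layer Pearson correlations are
computed over matched samples, and candidates are proteins that are
interactors, have significantly altered turnover in the relevant
condition, and correlate with at least one lipid or transcript feature at
|r| >= the threshold. The threshold is applied to |r| with the sign
preserved in reports, so negatively correlated partners are reported as
such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExperimentDesign, ValidationError, log_stage, write_table
from .turnover import direction_calls

__all__ = [
    "filter_interactors",
    "CrossReferenceSummary",
    "cross_reference",
    "mad_select",
    "correlate_layers",
    "prioritize_clients",
    "export_edges",
]

EDGE_COLUMNS = ["layer_a", "id_a", "layer_b", "id_b", "r", "n_samples"]


def filter_interactors(entries: pd.DataFrame, min_ratio: float = 10.0
                       ) -> set[str]:
    """Ids with pulldown enrichment strictly greater than ``min_ratio``."""
    if min_ratio <= 0:
        raise ValidationError("min_ratio must be > 0")
    keep = entries["enrichment_ratio"].to_numpy(float) > min_ratio
    ids = set(entries.loc[keep, "protein_id"])
    log_stage("filter_interactors", len(entries), len(ids))
    return ids


@dataclass
class CrossReferenceSummary:
    """Interactor x differential-turnover intersection counts.

    ``n_prolonged`` partitions as ``n_both + n_cm_only + n_gs_only`` over
    the two conditions (labels follow the design); an interactor absent
    from both tested sets is 'unquantified'. A protein prolonged in one
    condition counts as prolonged even if accelerated in the other
    (prolonged takes precedence, keeping the partition disjoint).
    """

    n_interactors: int
    n_prolonged: int
    n_accelerated: int
    n_both: int
    n_first_only: int
    n_second_only: int
    n_unquantified: int
    conditions: tuple[str, str]
    assignments: pd.DataFrame = field(repr=False)

    def as_dict(self) -> dict:
        c1, c2 = self.conditions
        return {
            "n_interactors": self.n_interactors,
            "n_prolonged": self.n_prolonged,
            "n_accelerated": self.n_accelerated,
            "n_both_conditions": self.n_both,
            f"n_{c1}_only": self.n_first_only,
            f"n_{c2}_only": self.n_second_only,
            "n_unquantified": self.n_unquantified,
        }


def cross_reference(interactors: set[str], diff_first: pd.DataFrame,
                    diff_second: pd.DataFrame, design: ExperimentDesign,
                    alpha: float = 0.05, mode: str = "either"
                    ) -> CrossReferenceSummary:
    """Classify each interactor's turnover change per condition.

    ``diff_first``/``diff_second`` are the two conditions' differential
    tables (same proteome). A protein is 'prolonged' in a condition when
    p_adj < alpha and the mutant direction call is prolonged (``mode``
    picks either- or both-mutant agreement); 'accelerated' likewise for
    shortened half-lives. Proteins absent from a condition's tested set
    count as not-altered there; absent from both, as unquantified.
    """
    conds = (str(diff_first["condition"].iloc[0]) if len(diff_first) else "c1",
             str(diff_second["condition"].iloc[0]) if len(diff_second) else "c2")

    def calls(diff: pd.DataFrame) -> pd.Series:
        d = direction_calls(diff, design, alpha=alpha, mode=mode)
        return pd.Series(d.to_numpy(), index=diff["feature_id"].to_numpy())

    c1 = calls(diff_first)
    c2 = calls(diff_second)
    tested1 = pd.Series(diff_first["tested"].to_numpy(),
                        index=diff_first["feature_id"].to_numpy())
    tested2 = pd.Series(diff_second["tested"].to_numpy(),
                        index=diff_second["feature_id"].to_numpy())

    rows = []
    for pid in sorted(interactors):
        in1 = bool(tested1.get(pid, False))
        in2 = bool(tested2.get(pid, False))
        s1 = c1.get(pid, "none") if in1 else "none"
        s2 = c2.get(pid, "none") if in2 else "none"
        if not in1 and not in2:
            status = "unquantified"
        elif "prolonged" in (s1, s2):
            if s1 == "prolonged" and s2 == "prolonged":
                status = "prolonged_both"
            elif s1 == "prolonged":
                status = f"prolonged_{conds[0]}_only"
            else:
                status = f"prolonged_{conds[1]}_only"
        elif "shortened" in (s1, s2):
            status = "accelerated"
        else:
            status = "unchanged"
        rows.append((pid, s1, s2, status))
    assign = pd.DataFrame(rows, columns=[
        "protein_id", f"call_{conds[0]}", f"call_{conds[1]}", "status"])

    n_both = int((assign["status"] == "prolonged_both").sum())
    n_first = int((assign["status"] == f"prolonged_{conds[0]}_only").sum())
    n_second = int((assign["status"] == f"prolonged_{conds[1]}_only").sum())
    summary = CrossReferenceSummary(
        n_interactors=len(interactors),
        n_prolonged=n_both + n_first + n_second,
        n_accelerated=int((assign["status"] == "accelerated").sum()),
        n_both=n_both, n_first_only=n_first, n_second_only=n_second,
        n_unquantified=int((assign["status"] == "unquantified").sum()),
        conditions=conds, assignments=assign)
    log_stage("cross_reference", len(interactors), len(assign))
    return summary


def mad_select(matrix: pd.DataFrame, quantile: float = 0.75) -> pd.DataFrame:
    """Keep features whose MAD reaches the given quantile of all MADs.

    MAD is the unscaled median absolute deviation from the feature median;
    the threshold is the linear-interpolation percentile of the MAD
    distribution. Constant features (MAD 0) are never kept; an all-constant
    matrix yields an empty selection with a warning.
    """
    if not (0 <= quantile < 1):
        raise ValidationError("quantile must lie in [0, 1)")
    vals = matrix.to_numpy(float)
    med = np.nanmedian(vals, axis=1, keepdims=True)
    mad = np.nanmedian(np.abs(vals - med), axis=1)
    if np.all(mad == 0):
        logging.getLogger("turnomix").warning(
            "mad_select: all features constant; empty selection")
        return matrix.iloc[[]]
    thr = float(np.quantile(mad, quantile))
    keep = (mad >= thr) & (mad > 0)
    log_stage("mad_select", len(matrix), int(keep.sum()))
    return matrix.loc[keep]


def _rankdata_rows(vals: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata
    return np.apply_along_axis(rankdata, 1, vals)


def correlate_layers(layer_a: pd.DataFrame, layer_b: pd.DataFrame,
                     method: str = "pearson",
                     layer_a_name: str = "a", layer_b_name: str = "b",
                     min_n: int = 3) -> pd.DataFrame:
    """Cross-layer correlation of every (row of a) x (row of b) pair.

    Both matrices are feature x sample; correlations run over the shared
    sample columns (order taken from ``layer_a``). Pairs with missing
    values use complete observations only; pairs with fewer than ``min_n``
    complete observations are omitted and counted.
    """
    shared = [c for c in layer_a.columns if c in set(layer_b.columns)]
    if len(shared) < min_n:
        raise ValidationError(
            f"need >= {min_n} shared samples, found {len(shared)}")
    a = layer_a[shared].to_numpy(float)
    b = layer_b[shared].to_numpy(float)
    if method == "spearman":
        a_nan, b_nan = np.isnan(a), np.isnan(b)
        a = np.where(a_nan, np.nan, _rankdata_rows(np.nan_to_num(a)))
        b = np.where(b_nan, np.nan, _rankdata_rows(np.nan_to_num(b)))
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    n_s = len(shared)
    omitted = 0
    rows = []
    clean = not (np.isnan(a).any() or np.isnan(b).any())
    if clean:
        az = a - a.mean(axis=1, keepdims=True)
        bz = b - b.mean(axis=1, keepdims=True)
        sa = np.sqrt((az * az).sum(axis=1))
        sb = np.sqrt((bz * bz).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (az @ bz.T) / np.outer(sa, sb)
        for i, fa in enumerate(layer_a.index):
            for j, fb in enumerate(layer_b.index):
                rows.append((layer_a_name, fa, layer_b_name, fb,
                             float(r[i, j]), n_s))
    else:
        for i, fa in enumerate(layer_a.index):
            for j, fb in enumerate(layer_b.index):
                mask = ~np.isnan(a[i]) & ~np.isnan(b[j])
                n = int(mask.sum())
                if n < min_n:
                    omitted += 1
                    continue
                x, y = a[i, mask], b[j, mask]
                xz, yz = x - x.mean(), y - y.mean()
                denom = np.sqrt((xz * xz).sum() * (yz * yz).sum())
                r_ij = float(xz @ yz / denom) if denom > 0 else np.nan
                rows.append((layer_a_name, fa, layer_b_name, fb, r_ij, n))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    log_stage(f"correlate_layers[{layer_a_name}x{layer_b_name}]",
              len(layer_a) * len(layer_b), len(edges),
              {"too_few_complete_obs": omitted})
    return edges


def prioritize_clients(interactors: pd.DataFrame, turnover_diff: pd.DataFrame,
                       edges: pd.DataFrame, r_threshold: float = 0.6,
                       alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nominate client candidates from the assembled evidence.

    ``interactors``: already-filtered pulldown entries (protein_id,
    enrichment_ratio). ``turnover_diff``: the differential table of the
    relevant condition. ``edges``: cross-layer correlations whose ``id_a``
    is a protein. A candidate must show p_adj < alpha and at least one edge
    with |r| >= r_threshold; candidates are sorted by enrichment ratio,
    descending. Returns (candidates, their passing edges with sign intact).
    """
    diff = turnover_diff.set_index("feature_id")
    strong = edges.loc[np.abs(edges["r"].to_numpy(float)) >= r_threshold]
    edges_of = dict(iter(strong.groupby("id_a"))) if len(strong) else {}

    rows = []
    kept_edges = []
    for _, rec in interactors.sort_values(
            ["enrichment_ratio", "protein_id"],
            ascending=[False, True]).iterrows():
        pid = rec["protein_id"]
        if pid not in diff.index:
            continue
        p_adj = float(diff.at[pid, "p_adj"]) if pd.notna(diff.at[pid, "p_adj"]) else np.nan
        if not (p_adj < alpha):
            continue
        e = edges_of.get(pid)
        if e is None or len(e) == 0:
            continue
        dir_cols = [c for c in turnover_diff.columns if c.startswith("direction_")]
        directions = ";".join(f"{c[10:]}={diff.at[pid, c]}" for c in dir_cols)
        best = e.loc[e["r"].abs().idxmax()]
        rows.append({
            "protein_id": pid,
            "enrichment_ratio": float(rec["enrichment_ratio"]),
            "p_adj": p_adj,
            "directions": directions,
            "n_edges": len(e),
            "best_r": float(best["r"]),
            "best_partner": f"{best['layer_b']}:{best['id_b']}",
        })
        kept_edges.append(e)
    candidates = pd.DataFrame(rows, columns=[
        "protein_id", "enrichment_ratio", "p_adj", "directions",
        "n_edges", "best_r", "best_partner"])
    cand_edges = (pd.concat(kept_edges, ignore_index=True)
                  if kept_edges else pd.DataFrame(columns=EDGE_COLUMNS))
    cand_edges = cand_edges.sort_values(
        ["id_a", "layer_b", "id_b"], kind="mergesort").reset_index(drop=True)
    log_stage("prioritize_clients", len(interactors), len(candidates))
    return candidates, cand_edges


def export_edges(candidates: pd.DataFrame, edges: pd.DataFrame, path
                 ) -> pd.DataFrame:
    """Write the circos-style edge table for the candidate proteins.

    Deterministic row order (id_a, layer_b, id_b); headers are written even
    when no candidate has edges.
    """
    keep = edges.loc[edges["id_a"].isin(set(candidates["protein_id"]))]
    keep = keep.sort_values(["id_a", "layer_b", "id_b"],
                            kind="mergesort").reset_index(drop=True)
    write_table(keep, path, columns=EDGE_COLUMNS)
    return keep
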