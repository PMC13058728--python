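"""Preranked gene-set enrichment with a gene-label permutation null.

Features are ranked by a signed significance statistic (default
sign(effect) * -log10 p). The enrichment score of a set is the extremum of
the weighted Kolmogorov-Smirnov running sum over the ranked list: each hit
adds |stat|^weight normalized by the summed hit weights, each miss
subtracts 1/(N - N_hits). Significance comes from re-scoring random
member sets of the same size; p-values are sign-matched and pseudocounted,
p = (b + 1) / (n_same_sign + 1), and the normalized enrichment score is
ES divided by the mean |null ES| of matching sign, so positive and
negative scores are comparable. BH correction is applied across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneSet, log_stage
from .stats import bh_adjust

__all__ = ["rank_features", "enrichment_score", "gsea_significance"]

_SIGN_OF = {"prolonged": 1.0, "up": 1.0, "shortened": -1.0, "down": -1.0,
    "accelerated": -1.0, "none": 0.0, "discordant": 0.0}


def rank_features(results: pd.DataFrame, metric: str = "signed_logp"
                  ) -> pd.DataFrame:
    """Build a descending ranked list from a differential-result table.

    ``results`` needs ``feature_id`` and ``p_value`` plus either a
    ``log2fc`` column (sign of the effect) or a ``direction`` label column.
    Untested rows (NaN p) are excluded. ``metric='signed_logp'`` scores
    each feature sign x -log10(p); ``metric='stat'`` passes through a
    ``stat`` column unchanged. Ties are broken by lexicographic feature id.
    """
    df = results.loc[results["p_value"].notna()].copy() \
        if "p_value" in results else results.copy()
    if metric == "stat":
        stat = df["stat"].to_numpy(float)
    elif metric == "signed_logp":
        if "log2fc" in df.columns:
            sign = np.sign(df["log2fc"].to_numpy(float))
        elif "direction" in df.columns:
            sign = df["direction"].map(_SIGN_OF).fillna(0.0).to_numpy(float)
        else:
            raise ValueError("need a 'log2fc' or 'direction' column")
        p = np.clip(df["p_value"].to_numpy(float), np.nextafter(0, 1), 1.0)
        stat = sign * (-np.log10(p))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    df = pd.DataFrame({"feature_id": df["feature_id"].to_numpy(), "stat": stat})
    if len(df) and np.allclose(stat, stat[0]):
        import logging
        logging.getLogger("turnomix").warning(
            "rank_features: all statistics identical; ranking is arbitrary")
    df = df.sort_values(["stat", "feature_id"],
                        ascending=[False, True], kind="mergesort")
    dup = df["feature_id"].duplicated()
    if dup.any():
        raise ValueError("duplicate feature ids in ranked list")
    return df.reset_index(drop=True)


def _es_from_positions(pos: np.ndarray, absw: np.ndarray, n: int
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ES for rows of sorted hit positions.

    ``pos``: (m, k) hit positions (ascending within each row);
    ``absw``: length-n weights |stat|^w. Returns (es, extremum_hit_index,
    extremum_is_positive) per row. The running sum attains its extrema only
    immediately before/after hits, so only 2k candidate values are scored.
    """
    m, k = pos.shape
    w = absw[pos]
    sumw = w.sum(axis=1, keepdims=True)
    uniform = sumw <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cumw = np.cumsum(w, axis=1) / sumw
    if uniform.any():
        flat = np.tile(np.arange(1, k + 1, dtype=float) / k, (m, 1))
        cumw = np.where(uniform, flat, cumw)
    miss = 1.0 / (n - k)
    j = np.arange(k, dtype=float)
    after = cumw - (pos - j) * miss          # value just after each hit
    before = after - np.where(uniform, 1.0 / k, w / np.where(sumw > 0, sumw, 1.0))
    # extrema occur only just before or just after hits; interleave the
    # candidates in list order so a tie resolves to the earliest position,
    # matching a left-to-right scan of the running sum
    cand = np.empty((m, 2 * k))
    cand[:, 0::2] = before
    cand[:, 1::2] = after
    idx = np.argmax(np.abs(cand), axis=1)
    es = cand[np.arange(m), idx]
    hit_idx = idx // 2
    return es, hit_idx, es >= 0


def enrichment_score(ranked: pd.DataFrame, gene_set: GeneSet,
                     weight: float = 1.0) -> tuple[float, list[str]]:
    """ES of one set against a ranked list, with its leading edge.

    The leading edge contains the member features at or before the running
    sum extremum for a positive ES, and at or after it for a negative ES.
    A set covering none or all of the list has no defined score.
    """
    ids = ranked["feature_id"].to_numpy()
    stats = ranked["stat"].to_numpy(float)
    n = len(ids)
    hit_mask = np.isin(ids, list(gene_set.members))
    k = int(hit_mask.sum())
    if k == 0 or k == n:
        raise ValueError(
            f"gene set {gene_set.name!r} covers {k} of {n} ranked features")
    pos = np.flatnonzero(hit_mask)[None, :]
    absw = np.abs(stats) ** weight
    es, hit_idx, positive = _es_from_positions(pos, absw, n)
    j = int(hit_idx[0])
    hits = pos[0]
    leading = hits[: j + 1] if positive[0] else hits[j:]
    return float(es[0]), [str(ids[i]) for i in leading]


def _null_es(n: int, k: int, absw: np.ndarray, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """Null ES distribution from random same-size member sets."""
    keys = rng.random((n_perm, n))
    pos = np.argpartition(keys, k - 1, axis=1)[:, :k]
    pos.sort(axis=1)
    es, _, _ = _es_from_positions(pos, absw, n)
    return es


def gsea_significance(ranked: pd.DataFrame, sets: Sequence[GeneSet],
                      n_perm: int = 1000, weight: float = 1.0,
                      seed: int = 0) -> pd.DataFrame:
    """Permutation GSEA over a collection of gene sets.

    Sets larger than the ranked list (or with no overlap) are skipped and
    flagged. Results carry ES, sign-matched permutation p, NES, BH-adjusted
    p, leading edge and the effective set size.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ids = ranked["feature_id"].to_numpy()
    stats = ranked["stat"].to_numpy(float)
    n = len(ids)
    absw = np.abs(stats) ** weight
    rng = np.random.default_rng(seed)

    rows = []
    for gs in sets:
        k = int(np.isin(ids, list(gs.members)).sum())
        if k == 0 or k >= n:
            rows.append({"set_name": gs.name, "size": k, "es": np.nan,
                         "nes": np.nan, "p_value": np.nan, "n_perm": 0,
                         "leading_edge": "", "skipped": True})
            continue
        es, leading = enrichment_score(ranked, gs, weight=weight)
        null = _null_es(n, k, absw, n_perm, rng)
        same = null >= 0 if es >= 0 else null < 0
        n_same = int(same.sum())
        b = int((np.abs(null[same]) >= abs(es)).sum())
        p = (b + 1.0) / (n_same + 1.0)
        mean_null = float(np.abs(null[same]).mean()) if n_same else np.nan
        nes = es / mean_null if n_same and mean_null > 0 else np.nan
        rows.append({"set_name": gs.name, "size": k, "es": es, "nes": nes,
                     "p_value": p, "n_perm": n_perm,
                     "leading_edge": ",".join(leading), "skipped": False})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    log_stage("gsea_significance", len(sets),
              int((~out["skipped"]).sum()),
              {"skipped": int(out["skipped"].sum())}, seed=seed)
    return out
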