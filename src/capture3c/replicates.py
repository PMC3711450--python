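"""Combining interaction calls across biological replicates.

Reproducibility of viewpoint-capture signals is low for weak and trans
contacts, which are dominated by random ligation, so count-model testing
across replicates is not appropriate.  Instead, each replicate is analyzed
on its own and the per-replicate calls are combined: candidate regions are
the union (significant in any replicate) or intersection (significant in
all) of the per-replicate significant sets, counts and signals are averaged
across all replicates, and per-replicate p-values are merged with Fisher's
combined probability test.  q-values are recomputed on the combined batch.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .calling import qvalues

logger = logging.getLogger(__name__)

_TINY_P = np.finfo(float).tiny


def fisher_combine(p_list) -> float:
    """Fisher's combined probability: X = -2 sum(ln p_i) ~ chi2(2k) under H0."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to the smallest positive float")
        p = np.maximum(p, _TINY_P)
    x = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x, df=2 * p.size))


def _fisher_combine_rows(pmat: np.ndarray) -> np.ndarray:
    pmat = np.maximum(pmat, _TINY_P)
    x = -2.0 * np.sum(np.log(pmat), axis=1)
    return stats.chi2.sf(x, df=2 * pmat.shape[1])


def combine_replicates(
    call_sets: list[pd.DataFrame],
    method: str = "union",
    fdr_level: float = 0.05,
    random_state: int = 0,
) -> pd.DataFrame:
    """Combine k per-replicate call tables into one replicate-supported table.

    All call tables must derive from the same fragment map or window grid
    (identical region ids).  Candidate regions are selected by ``method``;
    raw counts, RPM and normalized RPM are averaged over all k replicates
    (including replicates in which the region was not individually
    significant), p-values are Fisher-combined, and q-values are recomputed
    on the combined batch, separately for cis and trans candidates.  The
    ``support`` column counts replicates in which the region was
    individually significant.
    """
    if method not in ("union", "intersection"):
        raise ValueError(f"method must be 'union' or 'intersection', got {method!r}")
    if not call_sets:
        raise ValueError("need at least one call set")
    k = len(call_sets)
    ref_ids = np.sort(call_sets[0]["region_id"].to_numpy())
    for i, cs in enumerate(call_sets[1:], start=2):
        ids = np.sort(cs["region_id"].to_numpy())
        if len(ids) != len(ref_ids) or np.any(ids != ref_ids):
            diff = np.setdiff1d(ids, ref_ids)
            if len(diff) == 0:
                diff = np.setdiff1d(ref_ids, ids)
            raise ValueError(
                f"replicate {i} uses a different region grid; first "
                f"mismatching region id: {diff[0]}"
            )
    indexed = [cs.set_index("region_id").sort_index() for cs in call_sets]
    sig_sets = [set(cs.index[cs["significant"]]) for cs in indexed]
    candidates = set.union(*sig_sets) if method == "union" else set.intersection(*sig_sets)
    candidates = np.array(sorted(candidates), dtype=ref_ids.dtype)
    if len(candidates) == 0:
        logger.info("no candidate regions after %s of %d replicates", method, k)
        base = indexed[0].loc[[], :].reset_index()
        base["support"] = pd.Series(dtype=int)
        return base

    first = indexed[0].loc[candidates]
    out = first[["chrom", "start", "end"]].copy()
    out["distance"] = first["distance"]
    out["is_cis"] = first["is_cis"]
    for col in ("raw_count", "rpm", "norm_rpm", "signal"):
        if col in first.columns:
            out[col] = np.mean(
                [cs.loc[candidates, col].to_numpy() for cs in indexed], axis=0
            )
    pmat = np.column_stack([cs.loc[candidates, "p"].to_numpy() for cs in indexed])
    if np.any(pmat == 0):
        warnings.warn("p-value of 0 clamped to the smallest positive float")
    out["p"] = _fisher_combine_rows(pmat)
    for i in range(k):
        out[f"p_rep{i + 1}"] = pmat[:, i]
    out["support"] = np.sum(
        [[rid in s for rid in candidates] for s in sig_sets], axis=0
    )
    out["q"] = np.nan
    out["significant"] = False
    for is_cis in (True, False):
        mask = out["is_cis"] == is_cis
        if mask.any():
            q, sig = qvalues(
                out.loc[mask, "p"].to_numpy(), fdr_level=fdr_level,
                random_state=random_state,
            )
            out.loc[mask, "q"] = q
            out.loc[mask, "significant"] = sig
    out = out.reset_index().sort_values(
        ["q", "p"], kind="stable"
    ).reset_index(drop=True)
    logger.info(
        "%s of %d replicates: %d candidates, %d significant at FDR %.3g",
        method, k, len(out), int(out["significant"].sum()), fdr_level,
    )
    return out
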