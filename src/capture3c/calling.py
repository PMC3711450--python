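"""Statistical calling of cis and trans interactions with a viewpoint.

Contact frequency decays with genomic distance from the viewpoint simply
because nearby sequences are tethered to it during cross-linking.  On the
viewpoint (cis) chromosome this proximity trend is estimated by a cubic
smoothing spline of normalized signal against distance and used as the
expected signal; each region is then scored as z = (obs - exp) / SD where
SD is the standard deviation of the residuals.  On trans chromosomes there
is no proximity trend, so regions are scored against the global mean and
standard deviation of the data set (regions within +/-100 kb of the
viewpoint excluded).  Upper-tail normal p-values are converted to q-values
with a bootstrap estimate of pi0, and regions with q at or below the FDR
level are reported as interactions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import Viewpoint
from .smoothing import SmoothingSpline

logger = logging.getLogger(__name__)

SPAR_RANGE = (0.06, 0.4)


@dataclass
class CallingConfig:
    """Parameters of the interaction-calling step."""

    fdr_level: float = 0.05
    trans_exclusion_bp: int = 100_000
    spar: float = 0.1
    signed_distance: bool = False
    signal_col: str = "norm_rpm"
    random_state: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")


@dataclass
class CisBackground:
    """Spline-smoothed expected signal on the cis chromosome."""

    spline: SmoothingSpline
    expected: pd.Series          # clamped at 0, indexed by region_id
    residual_sd: float
    spar: float
    distance: pd.Series          # signed bp, indexed by region_id
    fit_region_ids: np.ndarray   # regions the spline was fitted on
    excluded_region_ids: np.ndarray  # viewpoint fragment +/- 1


def _signal_column(signals: pd.DataFrame, preferred: str = "norm_rpm") -> str:
    for col in (preferred, "norm_rpm", "rpm"):
        if col in signals.columns:
            return col
    raise ValueError("signals carry neither norm_rpm nor rpm; normalize first")


def region_distances(regions: pd.DataFrame, vp: Viewpoint) -> pd.Series:
    """Signed distance from region midpoint to viewpoint midpoint (bp)."""
    mid = (regions["start"] + regions["end"]) / 2.0
    return mid - vp.midpoint


def _viewpoint_neighborhood(cis: pd.DataFrame, vp: Viewpoint) -> np.ndarray:
    """Region ids of the viewpoint region and its immediate neighbours."""
    sub = cis.sort_values("start").reset_index(drop=True)
    overlap = np.minimum(sub["end"].to_numpy(), vp.end) - np.maximum(
        sub["start"].to_numpy(), vp.start
    )
    if overlap.max() <= 0:
        return np.array([], dtype=np.int64)
    i = int(np.argmax(overlap))
    take = [j for j in (i - 1, i, i + 1) if 0 <= j < len(sub)]
    return sub["region_id"].to_numpy()[take]


def fit_cis_background(
    signals: pd.DataFrame,
    vp: Viewpoint,
    spar: float = 0.1,
    signed_distance: bool = False,
    signal_col: str | None = None,
    allow_spar_outside: bool = False,
    min_regions: int = 30,
) -> CisBackground:
    """Fit the distance-decay background on the viewpoint chromosome.

    The spline is fitted on regions with positive signal, against absolute
    distance by default (up- and downstream pooled; the decay is roughly
    symmetric and pooling doubles the points per distance stratum).  The
    viewpoint region and its two immediate neighbours are excluded: they
    carry self-ligation signal.  Zero-signal regions do not enter the fit
    (they would drag the spline down in the far-cis tail) but receive an
    interpolated expectation for scoring.  Expected values are clamped at 0.
    """
    if not (SPAR_RANGE[0] <= spar <= SPAR_RANGE[1]) and not allow_spar_outside:
        raise ValueError(
            f"spar={spar} outside the supported range {SPAR_RANGE}; "
            "pass allow_spar_outside=True to override"
        )
    col = _signal_column(signals, signal_col or "norm_rpm")
    cis = signals[signals["chrom"] == vp.chrom].copy()
    if cis.empty:
        raise ValueError(f"no regions on viewpoint chromosome {vp.chrom!r}")
    cis["distance"] = region_distances(cis, vp)
    excluded = _viewpoint_neighborhood(cis, vp)
    fit_mask = ~cis["region_id"].isin(excluded) & (cis[col] > 0)
    n_fit = int(fit_mask.sum())
    if n_fit < min_regions:
        raise ValueError(
            f"only {n_fit} cis regions with positive signal (need >= {min_regions})"
        )
    x_all = cis["distance"] if signed_distance else cis["distance"].abs()
    spline = SmoothingSpline(spar=spar).fit(
        x_all[fit_mask].to_numpy(), cis.loc[fit_mask, col].to_numpy()
    )
    expected = np.maximum(spline.predict(x_all.to_numpy()), 0.0)
    expected = pd.Series(expected, index=cis["region_id"].to_numpy())
    resid = cis.loc[fit_mask, col].to_numpy() - expected.loc[
        cis.loc[fit_mask, "region_id"]
    ].to_numpy()
    residual_sd = float(np.std(resid, ddof=1))
    scale = max(float(cis.loc[fit_mask, col].abs().max()), 1.0)
    if residual_sd <= 1e-8 * scale:
        raise ValueError(
            "degenerate cis background: residual standard deviation is ~0"
        )
    return CisBackground(
        spline=spline,
        expected=expected,
        residual_sd=residual_sd,
        spar=spar,
        distance=pd.Series(cis["distance"].to_numpy(), index=cis["region_id"].to_numpy()),
        fit_region_ids=cis.loc[fit_mask, "region_id"].to_numpy(),
        excluded_region_ids=excluded,
    )


def zscores_cis(
    signals: pd.DataFrame, bg: CisBackground, signal_col: str | None = None
) -> pd.Series:
    """z = (obs - exp) / residual SD for regions covered by the background."""
    if bg.residual_sd <= 0:
        raise ValueError("degenerate background: residual SD is zero")
    col = _signal_column(signals, signal_col or "norm_rpm")
    sub = signals[signals["region_id"].isin(bg.expected.index)]
    obs = sub[col].to_numpy()
    exp = bg.expected.loc[sub["region_id"]].to_numpy()
    return pd.Series((obs - exp) / bg.residual_sd, index=sub["region_id"].to_numpy())


def zscores_trans(
    signals: pd.DataFrame,
    vp: Viewpoint,
    exclusion_bp: int = 100_000,
    signal_col: str | None = None,
    min_regions: int = 30,
) -> pd.Series:
    """Score trans regions against the global signal mean and SD.

    Mean and SD (n-1 denominator) are computed over all regions genome-wide
    except those within ``exclusion_bp`` of the viewpoint midpoint; z is
    returned for every region on a non-viewpoint chromosome.
    """
    col = _signal_column(signals, signal_col or "norm_rpm")
    on_vp_chrom = signals["chrom"] == vp.chrom
    near = pd.Series(False, index=signals.index)
    if on_vp_chrom.any():
        d = region_distances(signals[on_vp_chrom], vp).abs()
        near.loc[d.index] = d <= exclusion_bp
    pool = signals.loc[~near, col].to_numpy()
    if len(pool) < min_regions:
        raise ValueError(
            f"only {len(pool)} regions outside the exclusion zone "
            f"(need >= {min_regions})"
        )
    mean, sd = float(np.mean(pool)), float(np.std(pool, ddof=1))
    if sd <= 0 or sd <= 1e-12 * max(abs(mean), 1.0):
        raise ValueError("degenerate trans background: global SD is zero")
    trans = signals[~on_vp_chrom]
    z = (trans[col].to_numpy() - mean) / sd
    return pd.Series(z, index=trans["region_id"].to_numpy())


def pvalues_from_z(z, sidedness: str = "upper") -> np.ndarray:
    """Upper-tail standard-normal p-values: p = 1 - Phi(z).

    Only enrichment over the background constitutes an interaction, so the
    upper tail is the default (and only) sidedness.
    """
    if sidedness != "upper":
        raise ValueError("only upper-tail p-values are supported")
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    return stats.norm.sf(z)


def estimate_pi0_bootstrap(
    p: np.ndarray,
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
) -> float:
    """Bootstrap estimate of pi0, the proportion of true null hypotheses.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the grid
    lambda = 0.05, 0.10, ..., 0.95; the bootstrap picks the lambda whose
    estimated mean squared error around the minimal pi0(lambda) is smallest,
    and the estimate is clamped into (0, 1].
    """
    rng = rng or np.random.default_rng(0)
    p = np.asarray(p, dtype=float)
    m = len(p)
    lambdas = np.arange(0.05, 0.951, 0.05)
    pi0_l = np.array([np.mean(p > lam) / (1 - lam) for lam in lambdas])
    min_pi0 = pi0_l.min()
    p_sorted = np.sort(p)
    mse = np.zeros(len(lambdas))
    for _ in range(n_boot):
        pb = np.sort(rng.choice(p_sorted, size=m, replace=True))
        tail = m - np.searchsorted(pb, lambdas, side="right")
        pi0_b = tail / (m * (1 - lambdas))
        mse += (pi0_b - min_pi0) ** 2
    pi0 = float(pi0_l[int(np.argmin(mse))])
    if pi0 <= 0:
        warnings.warn(
            "estimated pi0 <= 0 (p-values are not uniform under the null); "
            "falling back to the conservative pi0 = 1"
        )
        return 1.0
    return min(pi0, 1.0)


def qvalues(
    p,
    fdr_level: float = 0.05,
    pi0_method: str = "bootstrap",
    pi0: float | None = None,
    n_boot: int = 100,
    random_state: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """q-values by the step-up construction q_(i) = min_{j>=i} pi0 m p_(j) / j.

    With ``pi0`` fixed at 1 this is exactly Benjamini-Hochberg.  Returns
    (q, significant) with significant <=> q <= fdr_level.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    if pi0 is None:
        if pi0_method != "bootstrap":
            raise ValueError(f"unknown pi0 method {pi0_method!r}")
        if m < 10:
            warnings.warn(
                f"only {m} p-values: too few for bootstrap pi0, using pi0=1"
            )
            pi0 = 1.0
        else:
            pi0 = estimate_pi0_bootstrap(
                p, n_boot=n_boot, rng=np.random.default_rng(random_state)
            )
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= fdr_level


def call_interactions(
    signals: pd.DataFrame,
    vp: Viewpoint,
    config: CallingConfig | None = None,
) -> pd.DataFrame:
    """Score every region against its background and assemble the call table.

    Cis regions are scored against the spline distance-decay background,
    trans regions against the global mean/SD.  q-values are computed in
    separate batches for cis and trans (the two batches have different null
    models, and the dense cis batch would otherwise dictate pi0 for trans).
    The viewpoint region and its two neighbours are excluded from the output.
    Calls are sorted by q, then by decreasing |z|.
    """
    config = config or CallingConfig()
    col = _signal_column(signals, config.signal_col)
    keep_cols = [
        c for c in ("chrom", "start", "end", "region_id", "raw_count", "rpm",
                    "norm_rpm")
        if c in signals.columns
    ]
    batches = []

    bg = fit_cis_background(
        signals, vp, spar=config.spar, signed_distance=config.signed_distance,
        signal_col=col,
    )
    z_cis = zscores_cis(signals, bg, signal_col=col)
    scored = ~np.isin(z_cis.index.to_numpy(), bg.excluded_region_ids)
    z_cis = z_cis[scored]
    cis = signals[signals["region_id"].isin(z_cis.index)][keep_cols].copy()
    cis["distance"] = bg.distance.loc[cis["region_id"]].to_numpy()
    cis["signal"] = cis[col] if col in cis.columns else signals.loc[cis.index, col]
    cis["z"] = z_cis.loc[cis["region_id"]].to_numpy()
    cis["p"] = pvalues_from_z(cis["z"].to_numpy())
    q, sig = qvalues(
        cis["p"].to_numpy(), fdr_level=config.fdr_level,
        random_state=config.random_state,
    )
    cis["q"], cis["significant"] = q, sig
    cis["is_cis"] = True
    batches.append(cis)

    if (signals["chrom"] != vp.chrom).any():
        z_trans = zscores_trans(
            signals, vp, exclusion_bp=config.trans_exclusion_bp, signal_col=col
        )
        trans = signals[signals["region_id"].isin(z_trans.index)][keep_cols].copy()
        trans["distance"] = np.nan
        trans["signal"] = trans[col] if col in trans.columns else np.nan
        trans["z"] = z_trans.loc[trans["region_id"]].to_numpy()
        trans["p"] = pvalues_from_z(trans["z"].to_numpy())
        q, sig = qvalues(
            trans["p"].to_numpy(), fdr_level=config.fdr_level,
            random_state=config.random_state,
        )
        trans["q"], trans["significant"] = q, sig
        trans["is_cis"] = False
        batches.append(trans)

    calls = pd.concat(batches, ignore_index=True)
    calls = calls.sort_values(
        ["q", "z"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    logger.info(
        "called %d significant regions of %d at FDR %.3g",
        int(calls["significant"].sum()), len(calls), config.fdr_level,
    )
    return calls
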