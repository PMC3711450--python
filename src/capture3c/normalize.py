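"""Read-count normalization: simple RPM and power-law reverse-cumulative RPM.

Per-region read counts in viewpoint capture libraries, like CAGE tag counts,
approximately follow a power law: the reverse-cumulative distribution
R(t) = #{regions with count >= t} is close to a straight line in log-log
space with slope ~ -1.35.  Libraries differ mainly in sequencing depth
(offset), not in slope, so mapping each library's fitted line onto a common
reference line (slope alpha_ref = -1.35, depth n0 = 1 million reads) puts
samples on a shared scale.  The mapped counts are "power-law normalized RPM".

The reference line needs an intercept convention.  We fix l_ref =
log10(n0 / zeta(-alpha_ref)): a library of m regions whose counts follow the
discrete reference law P(T >= t) = t**alpha_ref has R(t) = m * t**alpha_ref
and total reads m * zeta(-alpha_ref), so a reference library holding n0
reads has R(1) = n0 / zeta(-alpha_ref).  Only relative signals are consumed
downstream, so any consistent constant works; this one makes the identity
mapping hold for a library already distributed as the reference law.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import zeta

from .fragments import FragmentMap, Viewpoint, locate_viewpoint_fragment

logger = logging.getLogger(__name__)

ALPHA_REF = -1.35
N0_REF = 1_000_000
MIN_COUNT_DEFAULT = 50


def reference_offset(alpha_ref: float = ALPHA_REF, n0: float = N0_REF) -> float:
    """log10 intercept of the reference reverse-cumulative line."""
    return float(np.log10(n0 / zeta(-alpha_ref)))


@dataclass
class PowerLawFit:
    """OLS fit of log10 R(t) = offset + slope * log10 t, plus the reference."""

    slope: float
    offset: float
    alpha_ref: float = ALPHA_REF
    n0: float = N0_REF
    min_count: int = MIN_COUNT_DEFAULT
    n_regions_fit: int = 0

    @property
    def l_ref(self) -> float:
        return reference_offset(self.alpha_ref, self.n0)

    def transform(self, counts: np.ndarray) -> np.ndarray:
        """Map raw counts onto the reference distribution (monotone in t)."""
        counts = np.asarray(counts, dtype=float)
        out = np.zeros_like(counts)
        pos = counts > 0
        log_t = np.log10(counts[pos])
        out[pos] = 10.0 ** (
            (self.offset + self.slope * log_t - self.l_ref) / self.alpha_ref
        )
        return out


def simple_rpm(signals: pd.DataFrame, count_col: str = "raw_count") -> pd.DataFrame:
    """Reads-per-million: count / total mapped reads * 1e6 (column ``rpm``)."""
    total = signals[count_col].sum()
    if total <= 0:
        raise ValueError("cannot compute RPM: all region counts are zero")
    out = signals.copy()
    out["rpm"] = out[count_col] / total * 1e6
    return out


def fit_reverse_cumulative(
    counts,
    min_count: int = MIN_COUNT_DEFAULT,
    alpha_ref: float = ALPHA_REF,
    n0: float = N0_REF,
) -> PowerLawFit:
    """Fit the reverse-cumulative count distribution in log-log space.

    Counts below ``min_count`` are removed; R(t) is evaluated at every
    distinct surviving count t and log10 R is regressed on log10 t by
    unweighted ordinary least squares (one point per distinct count).
    """
    counts = np.asarray(counts, dtype=float)
    surv = np.sort(counts[counts >= min_count])
    t = np.unique(surv)
    if len(t) < 3:
        raise ValueError(
            f"only {len(t)} distinct count value(s) survive the >= {min_count} "
            "filter; need >= 3 — consider lowering min_count"
        )
    r = len(surv) - np.searchsorted(surv, t, side="left")
    slope, offset = np.polyfit(np.log10(t), np.log10(r), 1)
    logger.info(
        "power-law fit: slope=%.4f offset=%.4f over %d regions (%d distinct counts)",
        slope, offset, len(surv), len(t),
    )
    return PowerLawFit(
        slope=float(slope), offset=float(offset), alpha_ref=alpha_ref,
        n0=n0, min_count=min_count, n_regions_fit=int(len(surv)),
    )


def _viewpoint_region_index(signals: pd.DataFrame, vp: Viewpoint) -> np.ndarray:
    """Positional indices of the viewpoint region and its two neighbours."""
    cis = signals.index[signals["chrom"] == vp.chrom]
    if len(cis) == 0:
        return np.array([], dtype=int)
    sub = signals.loc[cis].sort_values("start")
    overlap = np.minimum(sub["end"].to_numpy(), vp.end) - np.maximum(
        sub["start"].to_numpy(), vp.start
    )
    if overlap.max() <= 0:
        return np.array([], dtype=int)
    i = int(np.argmax(overlap))
    take = [j for j in (i - 1, i, i + 1) if 0 <= j < len(sub)]
    return sub.index.to_numpy()[take]


def fit_powerlaw(
    signals: pd.DataFrame,
    viewpoint: Viewpoint | None = None,
    min_count: int = MIN_COUNT_DEFAULT,
    alpha_ref: float = ALPHA_REF,
    n0: float = N0_REF,
    count_col: str = "raw_count",
) -> PowerLawFit:
    """Fit the power law on region counts, excluding the viewpoint.

    The viewpoint fragment and its two adjacent fragments are removed before
    fitting: they carry self-ligation and incomplete-digestion signal that
    does not reflect the genome-wide count distribution.
    """
    drop = (
        _viewpoint_region_index(signals, viewpoint)
        if viewpoint is not None
        else np.array([], dtype=int)
    )
    counts = signals.drop(index=drop)[count_col].to_numpy()
    return fit_reverse_cumulative(counts, min_count, alpha_ref, n0)


def powerlaw_normalize(
    signals: pd.DataFrame, fit: PowerLawFit, count_col: str = "raw_count"
) -> pd.DataFrame:
    """Fill ``norm_rpm`` by mapping counts onto the reference power law."""
    out = signals.copy()
    out["norm_rpm"] = fit.transform(out[count_col].to_numpy())
    return out


def sample_reference_counts(
    n: int,
    rng: np.random.Generator,
    alpha: float = ALPHA_REF,
    min_count: int = 1,
) -> np.ndarray:
    """Draw per-region counts from the discrete reference power law.

    Inverse-transform sampling of the law P(T >= t) = (t/min_count)**alpha on
    t >= min_count.  With ``min_count`` set to the fitting threshold this
    emulates the post-filter count population of a deeply sequenced library,
    where the part of the distribution entering the fit is well populated.
    """
    u = rng.random(n)
    return np.floor(min_count * u ** (1.0 / alpha)).astype(np.int64)
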