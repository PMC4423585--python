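"""Randomized reliability analysis of slice-subsampled ICV estimation.

For each sampling period ``m`` the procedure repeatedly (default 5000
times) draws a random start offset per subject, computes the subsampled ICV
of every subject, and records the intraclass correlation between the
estimates and the reference every-slice measurements together with the
maximum percentage error (MPE) over subjects.  The empirical ICC
distribution per period is summarized by its 5th/25th/50th/75th/95th
percentiles and its spread (p95 - p5), from which two protocol guidelines
are read off:

* ``confidence_icc``: the largest period whose ICC stays above a threshold
  (default 0.99) with a given confidence (default 95%, i.e. the 5th
  percentile of the draws is at or above the threshold);
* ``tight_spread``: the largest period whose ICC spread is at most a bound
  (default 0.005).

Both use a contiguous-from-smallest rule: a period qualifies only if every
smaller tested period qualifies too, because the ICC becomes erratic as the
period grows and an isolated large-period pass is not a safe
recommendation.

The ICC is the single-measure absolute-agreement two-way random-effects
coefficient ICC(2,1): with n subjects and k = 2 raters (reference vs
subsampled),

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

where MSR, MSC and MSE are the rows (subjects), columns (raters) and
residual mean squares of the two-way ANOVA decomposition.  Absolute
agreement is used (not consistency) so that a systematic subsampling bias
lowers the coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .phantom import MaskVolume
from .subsample import slice_counts, period_mm

__all__ = [
    "ICCDraw",
    "GuidelineResult",
    "icc_two_way_random",
    "max_percentage_error",
    "run_randomized_reliability",
    "summarize_curve",
    "guideline_max_period",
]


@dataclass(frozen=True)
class ICCDraw:
    """Row schema of the draws table: one (period, repetition) outcome."""

    m: int
    rep_index: int
    icc: float
    mpe_percent: float


@dataclass(frozen=True)
class GuidelineResult:
    """Maximum safe sampling period under one criterion.

    ``max_period_slices``/``max_period_mm`` are None when no tested period
    satisfies the criterion ("none satisfied" is a result, not an error).
    """

    criterion: str
    max_period_slices: int | None
    max_period_mm: float | None
    icc_threshold: float
    confidence: float
    spread_max: float
    satisfied: bool

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "max_period_slices": self.max_period_slices,
            "max_period_mm": self.max_period_mm,
            "icc_threshold": self.icc_threshold,
            "confidence": self.confidence,
            "spread_max": self.spread_max,
            "satisfied": self.satisfied,
        }


# ---------------------------------------------------------------------------
# ICC and MPE
# ---------------------------------------------------------------------------

def _icc2_matrix(ref: np.ndarray, est: np.ndarray, absolute: bool) -> np.ndarray:
    """Vectorized ICC(2,1) of ``ref`` (n,) against each row of ``est`` (R, n)."""
    n = ref.size
    k = 2
    grand = (ref[None, :].mean(axis=1, keepdims=True) + est.mean(axis=1, keepdims=True)) / 2
    row_mean = (ref[None, :] + est) / 2
    col_mean_ref = np.full((est.shape[0], 1), ref.mean())
    col_mean_est = est.mean(axis=1, keepdims=True)
    ssr = k * ((row_mean - grand) ** 2).sum(axis=1)
    ssc = n * ((col_mean_ref - grand) ** 2 + (col_mean_est - grand) ** 2).sum(axis=1)
    sst = ((ref[None, :] - grand) ** 2).sum(axis=1) + ((est - grand) ** 2).sum(axis=1)
    sse = np.maximum(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if absolute:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (msr - mse) / denom
    return icc


def icc_two_way_random(
    x: Sequence[float],
    y: Sequence[float],
    kind: str = "absolute",
) -> float:
    """Single-measure two-way random-effects ICC of two paired measurements.

    ``kind="absolute"`` (default) is ICC(2,1), absolute agreement;
    ``kind="consistency"`` is ICC(3,1)'s consistency form under the same
    two-way decomposition.  Equals 1 when ``y == x`` elementwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and of equal length")
    if x.size < 2:
        raise ValueError("at least 2 paired observations required")
    if kind not in ("absolute", "consistency"):
        raise ValueError("kind must be 'absolute' or 'consistency'")
    allv = np.concatenate([x, y])
    if np.all(allv == allv[0]):
        raise ValueError("all values identical: ICC is 0/0 (degenerate input)")
    icc = float(_icc2_matrix(x, y[None, :], absolute=(kind == "absolute"))[0])
    return min(icc, 1.0)


def max_percentage_error(
    estimates: Sequence[float],
    references: Sequence[float],
) -> float:
    """MPE: max over subjects of |estimate - reference| / reference x 100."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape or est.size == 0:
        raise ValueError("estimates and references must be equal-length and non-empty")
    if (ref <= 0).any():
        raise ValueError("all references must be > 0")
    return float(np.max(np.abs(est - ref) / ref) * 100.0)


# ---------------------------------------------------------------------------
# Randomized resampling procedure
# ---------------------------------------------------------------------------

def run_randomized_reliability(
    cohort_masks: Sequence[MaskVolume],
    reference_icvs: Sequence[float],
    periods: Sequence[int],
    n_reps: int = 5000,
    seed: int = 0,
    shared_start: bool = False,
    icc_kind: str = "absolute",
) -> pd.DataFrame:
    """Empirical ICC/MPE distributions over random start offsets.

    For each period ``m`` and repetition, a start offset is drawn uniformly
    from {0, ..., m-1} independently per subject (or once per repetition
    with ``shared_start=True``), each subject's subsampled ICV is computed,
    and the ICC against ``reference_icvs`` plus the MPE (max percentage
    error over subjects) is recorded.  Deterministic for a fixed seed.

    Returns a DataFrame with columns ``m, rep_index, icc, mpe_percent``
    (see :class:`ICCDraw` for the row schema).
    """
    n_sub = len(cohort_masks)
    if n_sub < 2:
        raise ValueError("cohort must contain at least 2 subjects")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ref = np.asarray(reference_icvs, dtype=float)
    if ref.size != n_sub:
        raise ValueError("reference_icvs must match the cohort size")
    if (ref <= 0).any():
        raise ValueError("reference ICVs must be > 0")

    # per subject: trimmed slice counts and the voxel volume (mm^3)
    profiles: list[np.ndarray] = []
    voxvols = np.empty(n_sub)
    for j, mask in enumerate(cohort_masks):
        counts = slice_counts(mask)
        nz = np.flatnonzero(counts)
        if nz.size == 0:
            raise ValueError(f"subject {j}: empty mask")
        profiles.append(counts[nz[0] : nz[-1] + 1])
        voxvols[j] = mask.voxel_volume_mm3

    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    frames = []
    absolute = icc_kind == "absolute"
    if icc_kind not in ("absolute", "consistency"):
        raise ValueError("icc_kind must be 'absolute' or 'consistency'")
    for m in periods:
        m = int(m)
        if m < 1:
            raise ValueError("sampling periods must be >= 1")
        # every start offset's estimate, tabulated once per subject; the
        # operation order (integer count x voxel volume / 1e6) matches the
        # reference volumetry bit for bit, so m = 1 is exact
        tables = np.empty((n_sub, m))
        for j, prof in enumerate(profiles):
            for s in range(m):
                tables[j, s] = (m * int(prof[s::m].sum(dtype=np.int64))) * voxvols[j] / 1e6
        if shared_start:
            offsets = np.broadcast_to(
                rng.integers(0, m, size=(n_reps, 1)), (n_reps, n_sub)
            )
        else:
            offsets = rng.integers(0, m, size=(n_reps, n_sub))
        est = tables[np.arange(n_sub)[None, :], offsets]
        icc = np.minimum(_icc2_matrix(ref, est, absolute), 1.0)
        mpe = np.max(np.abs(est - ref[None, :]) / ref[None, :], axis=1) * 100.0
        frames.append(
            pd.DataFrame(
                {
                    "m": m,
                    "rep_index": np.arange(n_reps),
                    "icc": icc,
                    "mpe_percent": mpe,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Summaries and guidelines
# ---------------------------------------------------------------------------

_ICC_PCTS = (5, 25, 50, 75, 95)


def summarize_curve(draws: pd.DataFrame) -> pd.DataFrame:
    """Per-period percentile summary of the empirical ICC/MPE distributions.

    Percentiles use linear interpolation between order statistics (the
    inclusive rule); the spread is p95 - p5 of the ICC draws; the MPE's
    [p5, p95] interval is its 90% empirical confidence interval.
    Returns a DataFrame indexed by ``m``.
    """
    if len(draws) == 0:
        raise ValueError("no draws to summarize")
    rows = []
    for m, grp in draws.groupby("m", sort=True):
        icc_p = np.percentile(grp["icc"], _ICC_PCTS)
        mpe = grp["mpe_percent"].to_numpy()
        rows.append(
            {
                "m": int(m),
                **{f"icc_p{p}": v for p, v in zip(_ICC_PCTS, icc_p)},
                "spread": icc_p[-1] - icc_p[0],
                "mpe_min": float(mpe.min()),
                "mpe_max": float(mpe.max()),
                "mpe_p5": float(np.percentile(mpe, 5)),
                "mpe_p95": float(np.percentile(mpe, 95)),
                "n_reps": int(len(grp)),
            }
        )
    return pd.DataFrame(rows).set_index("m")


_CONF_TO_PCT = {0.95: 5, 0.75: 25, 0.50: 50, 0.25: 75, 0.05: 95}


def guideline_max_period(
    curve: pd.DataFrame,
    criterion: str,
    icc_threshold: float = 0.99,
    confidence: float = 0.95,
    spread_max: float = 0.005,
    slice_spacing: float = 1.0,
) -> GuidelineResult:
    """Largest safe sampling period under a reliability criterion.

    ``confidence_icc``: period m qualifies iff the (1-confidence) lower
    percentile of its ICC draws is at or above ``icc_threshold`` (at the
    default 95% confidence: at least 95% of draws above the threshold).
    ``tight_spread``: m qualifies iff spread <= ``spread_max``.  The
    returned period is the largest m such that every tested m' <= m
    qualifies; if the smallest tested period already fails, the result is
    explicitly "none satisfied".
    """
    if criterion not in ("confidence_icc", "tight_spread"):
        raise ValueError("criterion must be 'confidence_icc' or 'tight_spread'")
    if not 0 < icc_threshold <= 1 or not 0 < confidence < 1 or spread_max < 0:
        raise ValueError("thresholds out of valid range")
    if len(curve) == 0:
        raise ValueError("empty reliability curve")
    if criterion == "confidence_icc":
        pct = _CONF_TO_PCT.get(round(confidence, 2))
        if pct is None:
            raise ValueError(
                "confidence must map to a tabulated percentile "
                f"(one of {sorted(_CONF_TO_PCT)})"
            )
        ok = curve[f"icc_p{pct}"] >= icc_threshold
    else:
        ok = curve["spread"] <= spread_max

    best: int | None = None
    for m in sorted(curve.index):
        if bool(ok.loc[m]):
            best = int(m)
        else:
            break
    return GuidelineResult(
        criterion=criterion,
        max_period_slices=best,
        max_period_mm=None if best is None else period_mm(best, slice_spacing),
        icc_threshold=icc_threshold,
        confidence=confidence,
        spread_max=spread_max,
        satisfied=best is not None,
    )


def plot_curve(curve: pd.DataFrame, path, slice_spacing: float = 1.0, title: str = ""):
    """Percentile/MPE plot of a reliability curve (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = curve.index.to_numpy() * slice_spacing
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for p in _ICC_PCTS:
        ax1.plot(x, curve[f"icc_p{p}"], label=f"p{p}")
    ax1.axhline(0.99, color="k", ls="--", lw=0.8)
    ax1.set_xlabel("sampling period (mm)")
    ax1.set_ylabel("ICC")
    ax1.legend(fontsize=7)
    ax2.fill_between(x, curve["mpe_p5"], curve["mpe_p95"], alpha=0.3)
    ax2.plot(x, curve["mpe_max"], lw=0.8)
    ax2.set_xlabel("sampling period (mm)")
    ax2.set_ylabel("MPE (%)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
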