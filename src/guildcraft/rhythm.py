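"""Empirical JTK_CYCLE rhythm detection at a fixed period.

A series sampled on a Zeitgeber-time grid (typically every 6 h over 48 h,
with replicates per timepoint) is compared by Kendall's tau-b against a
family of phased cosine reference waveforms at the set period (24 h by
default).  The observed statistic is the maximum tau over the phase grid;
the p-value is empirical, from permutations of the values across all
time-replicate slots, so it is exact under exchangeability and invariant to
monotone transforms of the series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reference waveforms
# ---------------------------------------------------------------------------

def reference_waveforms(
    period: float, timepoints, phase_step: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cosine references cos(2*pi*(t - phase)/period) on a phase grid.

    Returns ``(phases, waveforms)`` with one row per retained phase.  Phases
    whose reference has an identical rank pattern at the sampled timepoints
    (e.g. separated by a full period) are deduplicated.  The default phase
    step is the sampling interval.
    """
    t = np.asarray(timepoints, dtype=float)
    if period <= 0:
        raise ValueError("period must be positive")
    distinct = np.unique(np.mod(t, period))
    if distinct.size < 3:
        raise ValueError("need at least three distinct timepoints per period")
    if phase_step is None:
        phase_step = float(np.min(np.diff(np.sort(distinct))))
    if phase_step <= 0:
        raise ValueError("phase_step must be positive")
    phases = np.arange(0.0, period, phase_step)
    keep_phases, keep_waves, seen = [], [], set()
    for phi in phases:
        # rounding makes symmetric timepoints tie exactly (cos(pi/2) is not
        # floating-point zero), which tau-b's tie correction relies on
        wave = np.round(np.cos(2 * np.pi * (t - phi) / period), 12)
        key = tuple(stats.rankdata(wave))
        if key in seen:
            continue
        seen.add(key)
        keep_phases.append(phi)
        keep_waves.append(wave)
    return np.array(keep_phases), np.array(keep_waves)


# ---------------------------------------------------------------------------
# tau statistic
# ---------------------------------------------------------------------------

def jtk_statistic(series, reference) -> float:
    """Kendall's tau-b between a series and a reference waveform.

    Replicates within a timepoint share the reference value, so the
    tie-corrected tau-b variant is required.  A constant series is
    degenerate and scores 0.
    """
    x = np.asarray(series, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series and reference must have equal length")
    if np.unique(x).size < 2:
        log.info("jtk_statistic: constant series, tau set to 0")
        return 0.0
    tau, _ = stats.kendalltau(x, y)
    return float(tau)


def _sign_matrix(v: np.ndarray) -> np.ndarray:
    return np.sign(v[:, None] - v[None, :])


def _tau_denominator(sx: np.ndarray, sy: np.ndarray) -> float:
    """tau-b denominator from sign matrices (tie-corrected)."""
    n = sx.shape[0]
    n0 = n * (n - 1) / 2
    n1 = ((sx == 0).sum() - n) / 2  # tied pairs in x
    n2 = ((sy == 0).sum() - n) / 2
    return float(np.sqrt((n0 - n1) * (n0 - n2)))


# ---------------------------------------------------------------------------
# empirical JTK
# ---------------------------------------------------------------------------

@dataclass
class RhythmResult:
    """Best-phase fit of a series to the reference family at a set period."""

    series_id: str
    period: float
    best_phase: float
    tau: float
    empirical_p: float
    n_perm: int


def ejtk(
    series,
    timepoints,
    period: float = 24.0,
    phase_step: float | None = None,
    n_perm: int = 999,
    seed=None,
    series_id: str = "series",
) -> RhythmResult:
    """Empirical JTK_CYCLE at a set period.

    Observed statistic: max over phased cosine references of Kendall tau-b
    between the series and the reference.  Empirical p = (1 + #{permutations
    with max-tau >= observed}) / (1 + n_perm), permuting the values across
    all time-replicate slots.  Degenerate (constant) series get p = 1.
    """
    x = np.asarray(series, dtype=float)
    if n_perm < 199:
        raise ValueError("n_perm must be >= 199 for a usable empirical p")
    phases, waves = reference_waveforms(period, timepoints, phase_step)
    if np.unique(x).size < 2:
        return RhythmResult(series_id, period, float("nan"), 0.0, 1.0, n_perm)

    n = x.size
    sx = _sign_matrix(x)
    sy = [_sign_matrix(w) for w in waves]
    denom = np.array([_tau_denominator(sx, s) for s in sy])
    # numerator = sum_{i<j} sign(x_i-x_j) sign(y_i-y_j) = (Sx * Sy).sum()/2
    obs_taus = np.array([(sx * s).sum() / 2.0 for s in sy]) / denom
    best = int(np.argmax(obs_taus))
    obs = float(obs_taus[best])

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    # permuted sign matrices are row/column permutations of sx; tie structure
    # (hence the tau-b denominator) is permutation-invariant
    sx_perm = sx[perms[:, :, None], perms[:, None, :]]
    num = np.einsum("pij,rij->pr", sx_perm, np.array(sy)) / 2.0
    max_tau = (num / denom[None, :]).max(axis=1)
    p = (1.0 + float((max_tau >= obs - 1e-12).sum())) / (1.0 + n_perm)
    return RhythmResult(series_id, period, float(phases[best]), obs, p, n_perm)


def rhythm_scan(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    period: float = 24.0,
    phase_step: float | None = None,
    n_perm: int = 999,
    seed=None,
    group_cols: tuple[str, ...] = ("diet", "regime"),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply ejtk to every series (column) within every sample group.

    ``meta`` supplies ``zt_hours`` per sample and the grouping columns
    (diet x regime by default).  Returns the per-series results plus the
    count of significant series (empirical p < ``alpha``) per group.
    """
    absent = table.index.difference(meta.index)
    if len(absent):
        raise ValueError(f"samples without metadata: {absent.tolist()}")
    meta = meta.loc[table.index]
    group_labels = meta[list(group_cols)].astype(str).agg("_".join, axis=1)
    rng = np.random.default_rng(seed)
    rows = []
    counts: dict[str, int] = {}
    for group in sorted(group_labels.unique()):
        idx = group_labels.index[group_labels == group]
        zt = meta.loc[idx, "zt_hours"].to_numpy(dtype=float)
        n_sig = 0
        for col in table.columns:
            res = ejtk(
                table.loc[idx, col].to_numpy(dtype=float),
                zt,
                period=period,
                phase_step=phase_step,
                n_perm=n_perm,
                seed=rng.integers(2**31),
                series_id=str(col),
            )
            rows.append(
                {
                    "group": group,
                    "series": res.series_id,
                    "tau": res.tau,
                    "best_phase": res.best_phase,
                    "empirical_p": res.empirical_p,
                    "period": res.period,
                }
            )
            n_sig += int(res.empirical_p < alpha)
        counts[group] = n_sig
    return pd.DataFrame(rows), counts
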