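"""Statistical evaluation of topographic-correction effectiveness.

A good correction should (i) preserve band-wise mean reflectance, (ii)
reduce the standard deviation (radiometric homogeneity), and (iii) weaken
the linear dependence of reflectance on the solar incidence cosine. This
module quantifies all three per band and per method: paired t-tests on
pixel values before/after, two-sided variance-ratio F-tests, the R^2 of
reflectance regressed on cos i, and relative changes
100 * (after - before) / before, plus cross-band averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .raster import ReflectanceStack

__all__ = [
    "BandStats", "band_stats", "paired_t_test", "variance_f_test",
    "illumination_dependence", "relative_change", "correction_report",
    "render_report",
]


@dataclass(frozen=True)
class BandStats:
    """Mean/std (sample, n-1 denominator) of one band over valid pixels."""

    band: str
    mean: float
    std: float
    n: int


def band_stats(band: np.ndarray, mask: np.ndarray, name: str = "band") -> BandStats:
    """Arithmetic mean and sample standard deviation over valid pixels."""
    vals = np.asarray(band)[np.asarray(mask, dtype=bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError(f"{name}: need >= 2 valid pixels, got {vals.size}")
    return BandStats(name, float(vals.mean()), float(vals.std(ddof=1)),
                     int(vals.size))


def paired_t_test(before: np.ndarray, after: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on per-pixel differences.

    Zero-variance differences are degenerate for the t formula: when every
    difference is exactly 0 the test is reported as (0.0, 1.0); a nonzero
    constant difference yields (inf-signed t, 0.0) conceptually but is
    reported as (nan, 0.0) to flag the degenerate case.
    """
    before = np.asarray(before, dtype=float).ravel()
    after = np.asarray(after, dtype=float).ravel()
    if before.shape != after.shape:
        raise ValueError("before/after must be paired (equal length)")
    if before.size < 2:
        raise ValueError("need at least 2 pairs")
    d = after - before
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        return float("nan"), 0.0
    t, p = stats.ttest_rel(after, before)
    return float(t), float(p)


def variance_f_test(before: np.ndarray, after: np.ndarray) -> tuple[float, float]:
    """Two-sided variance-ratio F-test, F = s2_before / s2_after.

    The p-value is two-sided from the F(n1-1, n2-1) distribution:
    p = 2 * min(P[F <= f], P[F >= f]).
    """
    b = np.asarray(before, dtype=float).ravel()
    a = np.asarray(after, dtype=float).ravel()
    if b.size < 2 or a.size < 2:
        raise ValueError("need at least 2 values in each sample")
    s2b, s2a = b.var(ddof=1), a.var(ddof=1)
    if s2a == 0:
        raise ValueError("zero variance in denominator sample")
    f = s2b / s2a
    dist = stats.f(b.size - 1, a.size - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))


def illumination_dependence(band: np.ndarray, cos_i: np.ndarray,
                            mask: np.ndarray) -> float:
    """R^2 of the OLS regression of reflectance on cos i over valid pixels."""
    ok = (np.asarray(mask, dtype=bool) & np.isfinite(band) & np.isfinite(cos_i))
    x, y = np.asarray(cos_i)[ok], np.asarray(band)[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 valid pixels, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in cos i")
    if np.ptp(y) == 0:
        return 0.0
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2)


def relative_change(before: float, after: float) -> float:
    """Relative change in percent, 100 * (after - before) / before."""
    if before <= 0:
        raise ValueError(f"relative change requires before > 0, got {before}")
    return 100.0 * (after - before) / before


def correction_report(original: ReflectanceStack,
                      corrected: dict[str, ReflectanceStack],
                      cos_i: np.ndarray,
                      mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per band x method effectiveness report (Tables-style long format).

    Columns: method, band, n, mean_before/after, std_before/after, t_stat,
    t_p, f_stat, f_p, r2_before/after, and the three relative changes in
    percent. Statistics are computed on pixels valid in the original, the
    corrected stack and the optional analysis mask simultaneously, so the
    t-test pairing is well defined.
    """
    rows = []
    for method, stack in corrected.items():
        if stack.shape != original.shape:
            raise ValueError(f"{method}: corrected stack not co-registered")
        for b, name in enumerate(original.band_names):
            ok = original.mask & stack.mask & np.isfinite(cos_i)
            if mask is not None:
                ok = ok & mask
            before = original.bands[b]
            after = stack.bands[b]
            sb = band_stats(before, ok, name)
            sa = band_stats(after, ok, name)
            t, tp = paired_t_test(before[ok], after[ok])
            f, fp = variance_f_test(before[ok], after[ok])
            r2b = illumination_dependence(before, cos_i, ok)
            r2a = illumination_dependence(after, cos_i, ok)
            rows.append({
                "method": method, "band": name, "n": sb.n,
                "mean_before": sb.mean, "mean_after": sa.mean,
                "std_before": sb.std, "std_after": sa.std,
                "t_stat": t, "t_p": tp, "f_stat": f, "f_p": fp,
                "r2_before": r2b, "r2_after": r2a,
                "mean_change_pct": relative_change(sb.mean, sa.mean),
                "std_change_pct": relative_change(sb.std, sa.std),
                "r2_change_pct": (relative_change(r2b, r2a)
                                  if r2b > 0 else np.nan),
            })
    df = pd.DataFrame(rows)
    return df


def cross_band_averages(report: pd.DataFrame) -> pd.DataFrame:
    """Per-method averages of the per-band relative changes (percent)."""
    return (report.groupby("method")[
        ["mean_change_pct", "std_change_pct", "r2_change_pct"]
    ].mean().reset_index())


def render_report(report: pd.DataFrame) -> str:
    """Human-readable summary: reflectance stats to 5 decimals, percentages
    to one decimal, plus cross-band averages."""
    lines = []
    for method, grp in report.groupby("method"):
        lines.append(f"Method: {method}")
        for _, r in grp.iterrows():
            star_t = "*" if r.t_p < 0.05 else " "
            star_f = "*" if r.f_p < 0.05 else " "
            lines.append(
                f"  {r.band:8s} mean {r.mean_before:.5f} -> {r.mean_after:.5f}{star_t}"
                f" ({r.mean_change_pct:+.1f}%)  std {r.std_before:.5f} ->"
                f" {r.std_after:.5f}{star_f} ({r.std_change_pct:+.1f}%)"
                f"  R2 {r.r2_before:.5f} -> {r.r2_after:.5f}"
                f" ({r.r2_change_pct:+.1f}%)"
            )
        avg = grp[["mean_change_pct", "std_change_pct", "r2_change_pct"]].mean()
        lines.append(
            f"  average  mean {avg.mean_change_pct:+.1f}%  std"
            f" {avg.std_change_pct:+.1f}%  R2 {avg.r2_change_pct:+.1f}%"
        )
    return "\n".join(lines)
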