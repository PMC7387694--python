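"""Group statistics: pointwise t-maps with significance masks, summary-form
t-tests, Mann-Whitney U tests, and p-to-z conversion.

Between-condition comparisons default to equal-variance independent
two-sample t-tests (df = n1 + n2 - 2); with equal group sizes this
coincides with the Welch form.  A paired variant is provided for
within-subject designs.  Significance masks are pointwise p < alpha with
no multiple-comparison correction by default (a Benjamini-Hochberg option
exists); contiguous significant regions ("distributions of significance")
are enumerated by 4-connectivity on the (frequency, time) grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "TMapResult",
    "ttest_ind",
    "ttest_ind_summary",
    "ttest_paired",
    "pointwise_tmap",
    "mask_average",
    "mann_whitney_u",
    "p_to_z",
]

_STRUCTURE_4CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class GroupSample:
    """Per-subject values for one condition."""

    values: np.ndarray
    condition: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise ValueError("a group sample needs at least 2 subjects")

    @property
    def n(self) -> int:
        return self.values.size


def _as_values(x) -> np.ndarray:
    return x.values if isinstance(x, GroupSample) else np.asarray(x, dtype=float)


def ttest_ind(x, y):
    """Equal-variance two-sample t-test.

    Returns ``(t, df, p_two_sided)`` with df = n1 + n2 - 2.
    """
    a, b = _as_values(x), _as_values(y)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), int(a.size + b.size - 2), float(res.pvalue)


def ttest_ind_summary(m1, s1, n1, m2, s2, n2):
    """Equal-variance two-sample t-test from group means/SDs/sizes.

    Reproduces the raw-data test exactly when the summaries are computed
    from the raw values (sample SDs, n-1 denominator).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be non-negative")
    if s1 == 0 and s2 == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(res.statistic), int(n1 + n2 - 2), float(res.pvalue)


def ttest_paired(x, y):
    """Paired t-test (within-subject variant), df = n - 1."""
    a, b = _as_values(x), _as_values(y)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.var(a - b, ddof=1) == 0:
        raise ValueError("zero variance of differences")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), int(a.size - 1), float(res.pvalue)


@dataclass
class TMapResult:
    """Pointwise t-map with its significance mask and clusters."""

    t: np.ndarray  # (n_freqs, n_times)
    p: np.ndarray
    mask: np.ndarray  # bool, p < alpha (and valid)
    alpha: float
    clusters: list = field(default_factory=list)


def pointwise_tmap(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    alpha: float = 0.01,
    valid: np.ndarray | None = None,
    correction: str | None = None,
    freqs: np.ndarray | None = None,
    times_ms: np.ndarray | None = None,
) -> TMapResult:
    """Independent t-test at every (f, t) point across subjects.

    ``maps_a``/``maps_b``: arrays (n_subjects, n_freqs, n_times), e.g.
    stacked per-subject z-normalized ITC maps for the two conditions.
    ``correction='fdr_bh'`` applies Benjamini-Hochberg to the valid points
    before masking (off by default).  Clusters of the resulting mask are
    enumerated with 4-connectivity, separately for positive and negative t.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("map stacks must have identical shapes")
    if a.ndim != 3 or a.shape[0] < 2:
        raise ValueError("need (n_subjects >= 2, n_freqs, n_times) stacks")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(a, b, axis=0, equal_var=True)
    t = np.asarray(res.statistic)
    p = np.asarray(res.pvalue)

    ok = np.isfinite(p)
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)
    if correction == "fdr_bh":
        p = p.copy()
        p[ok] = sps.false_discovery_control(p[ok], method="bh")
    elif correction not in (None, "none"):
        raise ValueError(f"unknown correction {correction!r}")
    mask = ok & (p < alpha)

    clusters = []
    for sign in (1, -1):
        m = mask & (np.sign(t) == sign)
        labels, n_lab = ndimage.label(m, structure=_STRUCTURE_4CONN)
        for lab in range(1, n_lab + 1):
            fi, ti = np.nonzero(labels == lab)
            info = {
                "sign": sign,
                "n_points": fi.size,
                "f_index_range": (int(fi.min()), int(fi.max())),
                "t_index_range": (int(ti.min()), int(ti.max())),
                "peak_abs_t": float(np.abs(t[fi, ti]).max()),
            }
            if freqs is not None:
                info["f_hz_range"] = (float(freqs[fi.min()]), float(freqs[fi.max()]))
            if times_ms is not None:
                info["t_ms_range"] = (
                    float(times_ms[ti.min()]),
                    float(times_ms[ti.max()]),
                )
            clusters.append(info)
    clusters.sort(key=lambda c: -c["n_points"])
    return TMapResult(t=t, p=p, mask=mask, alpha=alpha, clusters=clusters)


def mask_average(maps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-subject mean of map values over the masked points.

    ``maps``: (n_subjects, n_freqs, n_times); ``mask``: boolean (f, t)
    subset, e.g. one cluster of a :class:`TMapResult` or its band
    restriction.  Returns one scalar per subject.
    """
    maps = np.asarray(maps, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return maps[:, mask].mean(axis=1)


def mann_whitney_u(x, y):
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U is the smaller of the two rank-sum
    statistics.  The p-value is exact (enumeration) when n1 + n2 <= 20 and
    the pooled sample is tie-free, else a normal approximation with tie and
    continuity corrections.
    """
    a, b = _as_values(x), _as_values(y)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (n1 + n2 <= 20 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    u1 = float(res.statistic)
    return min(u1, n1 * n2 - u1), float(res.pvalue)


def p_to_z(p: float, direction_sign: float = 1.0, alpha: float | None = None):
    """Signed z-value of a two-sided p: z = sign * Phi^-1(1 - p/2).

    With ``alpha`` given, p-values at or above it are masked and ``nan`` is
    returned (p < 5% masking before display).
    """
    if p <= 0 or p > 1:
        raise ValueError("p must lie in (0, 1]")
    if alpha is not None and p >= alpha:
        return float("nan")
    return float(np.sign(direction_sign) * sps.norm.isf(p / 2.0))
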