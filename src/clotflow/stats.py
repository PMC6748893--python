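"""Group comparison pipeline for pooled clotting-event samples.

Samples pool all donors and repetitions of one experimental condition
(clotting events are independent by design, so pooling is justified).
Comparisons follow a normality-routed scheme: both samples are tested with
Jarque-Bera; if both look normal the unpaired two-sided t test is used,
otherwise the two-sided Wilcoxon-Mann-Whitney rank-sum test (exact null
for small samples without ties, normal approximation with tie correction
otherwise).  Families of comparisons are Bonferroni-adjusted, with
significance declared at adjusted P <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class SampleSet:
    """Pooled measurements for one condition/time/location."""

    label: str
    values: np.ndarray
    provenance: tuple = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1 or not np.isfinite(v).all():
            raise ValueError("values must be a non-empty finite 1-D array")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size


def normality_test(sample: SampleSet | np.ndarray) -> tuple[float, float]:
    """Jarque-Bera normality test.

    JB = n/6 (S² + K²/4) with sample skewness S and excess kurtosis K,
    referred to a χ² distribution with 2 degrees of freedom.  The χ²
    reference is asymptotic; for the small samples typical of microfluidic
    pools it is anticonservative, which only makes the routing below fall
    back to the rank-sum test more often.
    """
    v = sample.values if isinstance(sample, SampleSet) else \
        np.asarray(sample, dtype=float)
    if v.size < 4:
        raise ValueError("need n >= 4 for the Jarque-Bera test")
    if np.var(v) == 0:
        raise ValueError("degenerate sample: zero variance")
    res = sps.jarque_bera(v)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ComparisonResult:
    p: float
    test_used: str          # "t" or "ranksum"
    statistic: float
    normality_p: tuple = field(default=(np.nan, np.nan))


def compare_samples(a: SampleSet | np.ndarray, b: SampleSet | np.ndarray,
                    alpha: float = 0.05,
                    force_test: str | None = None) -> ComparisonResult:
    """Two-sided comparison with normality routing.

    The t branch runs only if BOTH samples pass Jarque-Bera at ``alpha``
    (the conservative joint rule); otherwise the rank-sum branch runs.
    ``force_test`` ("t" or "ranksum") bypasses the routing.
    """
    va = a.values if isinstance(a, SampleSet) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, SampleSet) else np.asarray(b, dtype=float)
    if va.size < 2 or vb.size < 2:
        raise ValueError("need n >= 2 in both samples")

    pn = (np.nan, np.nan)
    if force_test is None:
        try:
            pn = (normality_test(va)[1], normality_test(vb)[1])
            use_t = pn[0] > alpha and pn[1] > alpha
        except ValueError:
            use_t = False
        test = "t" if use_t else "ranksum"
    else:
        test = force_test

    if test == "t":
        if np.var(va) == 0 and np.var(vb) == 0 and np.mean(va) == np.mean(vb):
            return ComparisonResult(p=1.0, test_used="t", statistic=0.0,
                                    normality_p=pn)
        t, p = sps.ttest_ind(va, vb)
        return ComparisonResult(p=float(p), test_used="t",
                                statistic=float(t), normality_p=pn)
    ties = len(np.unique(np.concatenate([va, vb]))) < va.size + vb.size
    method = "exact" if (min(va.size, vb.size) <= 8 and not ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(va, vb, alternative="two-sided", method=method)
    return ComparisonResult(p=float(res.pvalue), test_used="ranksum",
                            statistic=float(res.statistic), normality_p=pn)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m·p).

    ``m`` defaults to the number of p-values and must not be smaller.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= the number of p-values")
    return np.minimum(1.0, m * p)


def compare_conditions(samples: dict[str, SampleSet],
                       reference: str,
                       alpha: float = 0.05) -> dict[str, dict]:
    """Compare a reference condition against every other, with Bonferroni.

    Returns per-condition reports (test used, raw and adjusted p,
    decision at adjusted P <= alpha).
    """
    others = [k for k in samples if k != reference]
    results = {k: compare_samples(samples[reference], samples[k])
               for k in others}
    adj = bonferroni([results[k].p for k in others], len(others))
    return {k: {"test_used": results[k].test_used,
                "p_raw": results[k].p,
                "p_adjusted": float(adj[i]),
                "significant": bool(adj[i] <= alpha)}
            for i, k in enumerate(others)}
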