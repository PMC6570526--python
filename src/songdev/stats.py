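"""Group-level inferential wrappers used by the pipeline.

The unit of analysis is the bird: within-bird replicates are averaged
before any test.  All tests are two-sided at alpha = 0.05.  Paired t
compares matched per-bird values between treatments; one-sample t checks
whether deterioration/recovery exceeds zero; one-way ANOVA with Tukey
HSD (all pairs) or Dunnett-style many-to-one comparisons handles
multi-group designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupResult",
    "paired_t",
    "one_sample_t",
    "anova_tukey_dunnett",
]


@dataclass(frozen=True)
class GroupResult:
    """One test's outcome."""

    test: str
    statistic: float
    df: float
    p_value: float
    comparison: tuple[str, ...]
    n: int
    degenerate: bool = False

    def __post_init__(self):
        if not self.degenerate and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.test, "statistic": self.statistic, "df": self.df,
            "p_value": self.p_value, "comparison": list(self.comparison),
            "n": self.n, "degenerate": self.degenerate,
        }


def paired_t(
    values_a, values_b, labels: tuple[str, str] = ("a", "b")
) -> GroupResult:
    """Two-sided paired-samples t-test on per-bird value pairs."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t needs two equal-length samples, n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return GroupResult("paired_t", float("nan"), float(a.size - 1),
                           float("nan"), labels, int(a.size), degenerate=True)
    res = sps.ttest_rel(a, b)
    return GroupResult("paired_t", float(res.statistic), float(a.size - 1),
                       float(res.pvalue), labels, int(a.size))


def one_sample_t(values, mu: float = 0.0, label: str = "sample") -> GroupResult:
    """Two-sided one-sample t-test against ``mu`` (default 0)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("one-sample t needs n >= 2")
    if np.allclose(x.std(ddof=1), 0.0):
        return GroupResult("one_sample_t", float("nan"), float(x.size - 1),
                           float("nan"), (label, f"mu={mu}"), int(x.size),
                           degenerate=True)
    res = sps.ttest_1samp(x, mu)
    return GroupResult("one_sample_t", float(res.statistic),
                       float(x.size - 1), float(res.pvalue),
                       (label, f"mu={mu}"), int(x.size))


def anova_tukey_dunnett(
    groups: dict[str, np.ndarray], control: str | None = None,
    random_state: int = 0,
) -> list[GroupResult]:
    """Omnibus one-way ANOVA plus post-hoc comparisons.

    With ``control=None`` every pair is compared (Tukey HSD); naming a
    control group switches to Dunnett-style many-to-one comparisons
    against it.  Results start with the omnibus F.  Dunnett p-values come
    from randomized integration of the multivariate t; ``random_state``
    pins them for reproducible reports.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    for g, arr in zip(labels, arrays):
        if arr.size < 2:
            raise ValueError(f"group {g!r} has n < 2")
    n_total = int(sum(a.size for a in arrays))
    k = len(arrays)
    f = sps.f_oneway(*arrays)
    out = [GroupResult("anova_F", float(f.statistic), float(k - 1),
                       float(f.pvalue), tuple(labels), n_total)]
    if control is None:
        res = sps.tukey_hsd(*arrays)
        for i in range(k):
            for j in range(i + 1, k):
                out.append(GroupResult(
                    "tukey_hsd", float(res.statistic[i, j]),
                    float(n_total - k), float(res.pvalue[i, j]),
                    (labels[i], labels[j]),
                    int(arrays[i].size + arrays[j].size)))
    else:
        if control not in groups:
            raise ValueError(f"control group {control!r} not present")
        others = [g for g in labels if g != control]
        res = sps.dunnett(*[np.asarray(groups[g], float) for g in others],
                          control=np.asarray(groups[control], float),
                          random_state=np.random.default_rng(random_state))
        for g, stat, p in zip(others, np.atleast_1d(res.statistic),
                              np.atleast_1d(res.pvalue)):
            out.append(GroupResult(
                "dunnett", float(stat), float(n_total - k), float(p),
                (g, control), int(groups[g].size + groups[control].size)))
    return out
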