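"""Cochran-Mantel-Haenszel chi-square test for stratified 2×2 tables.

Each stratum k is a 2×2 table

    =============  ========  ============
    .              removed   not removed
    =============  ========  ============
    real isoform     a_k        b_k
    decoy isoform    c_k        d_k
    =============  ========  ============

Under the null hypothesis of no association within any stratum,
conditioning on the margins gives a hypergeometric law for ``a_k`` with

    E[a_k]   = (a+b)(a+c) / n
    Var[a_k] = (a+b)(c+d)(a+c)(b+d) / (n^2 (n-1))

and the test statistic is

    X^2 = ( |sum_k a_k - sum_k E[a_k]| - c )^2 / sum_k Var[a_k]

with continuity correction ``c = 0.5`` (the classical Mantel-Haenszel
form, and the default of R's ``mantelhaen.test``) or ``c = 0``.  The
p-value is the upper tail of chi-square with 1 degree of freedom.

Strata with a zero row or column margin carry no information under the
conditional null and are skipped (their count is reported).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2


@dataclass
class Stratified2x2:
    """An ordered collection of 2×2 tables, one per stratum."""

    tables: np.ndarray  # shape (K, 2, 2): [[a, b], [c, d]] per stratum
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        tables = np.asarray(self.tables, dtype=float)
        if tables.ndim != 3 or tables.shape[1:] != (2, 2):
            raise ValueError("tables must have shape (K, 2, 2)")
        if tables.shape[0] < 1:
            raise ValueError("at least one stratum required")
        if (tables < 0).any():
            raise ValueError("cell counts must be non-negative")
        if (tables.sum(axis=(1, 2)) <= 0).any():
            raise ValueError("every stratum must have a positive total")
        self.tables = tables
        if not self.labels:
            self.labels = [str(i) for i in range(tables.shape[0])]
        elif len(self.labels) != tables.shape[0]:
            raise ValueError("labels length must match number of strata")

    def __len__(self) -> int:
        return self.tables.shape[0]

    @classmethod
    def from_counts(
        cls, counts: list[tuple[float, float, float, float]], labels: list[str] | None = None
    ) -> "Stratified2x2":
        arr = np.array(counts, dtype=float).reshape(-1, 2, 2)
        return cls(arr, labels or [])


@dataclass
class CMHResult:
    """Outcome of a CMH test, with the observed frequency pair.

    ``real_frequency`` and ``control_frequency`` are the pooled
    removed-fractions of the first and second row across informative
    strata; the test itself is stratified, the frequencies are descriptive.
    """

    statistic: float
    p_value: float
    real_frequency: float
    control_frequency: float
    n_strata: int
    n_skipped: int
    correction: bool

    @property
    def defined(self) -> bool:
        return math.isfinite(self.statistic)


def cmh_test(tables: Stratified2x2, correction: bool = True) -> CMHResult:
    """Cochran-Mantel-Haenszel chi-square test (df = 1).

    ``correction`` applies the 0.5 continuity correction (default on).
    Returns a result with ``statistic = nan`` (flagged undefined) when the
    summed conditional variance is zero, e.g. when every informative
    stratum is degenerate.
    """
    t = tables.tables
    a = t[:, 0, 0]
    row1 = t[:, 0, :].sum(axis=1)
    row2 = t[:, 1, :].sum(axis=1)
    col1 = t[:, :, 0].sum(axis=1)
    col2 = t[:, :, 1].sum(axis=1)
    n = t.sum(axis=(1, 2))

    informative = (row1 > 0) & (row2 > 0) & (col1 > 0) & (col2 > 0) & (n > 1)
    n_skipped = int((~informative).sum())

    # descriptive pooled frequencies over informative strata
    keep = t[informative]
    if keep.shape[0] > 0 and keep[:, 0, :].sum() > 0:
        real_freq = float(keep[:, 0, 0].sum() / keep[:, 0, :].sum())
    else:
        real_freq = float("nan")
    if keep.shape[0] > 0 and keep[:, 1, :].sum() > 0:
        control_freq = float(keep[:, 1, 0].sum() / keep[:, 1, :].sum())
    else:
        control_freq = float("nan")

    if keep.shape[0] == 0:
        return CMHResult(
            statistic=float("nan"),
            p_value=float("nan"),
            real_frequency=real_freq,
            control_frequency=control_freq,
            n_strata=0,
            n_skipped=n_skipped,
            correction=correction,
        )

    ak = a[informative]
    r1, r2 = row1[informative], row2[informative]
    c1, c2 = col1[informative], col2[informative]
    nn = n[informative]
    expected = r1 * c1 / nn
    variance = r1 * r2 * c1 * c2 / (nn * nn * (nn - 1.0))
    var_sum = float(variance.sum())
    if var_sum <= 0:
        statistic = float("nan")
        p_value = float("nan")
    else:
        deviation = abs(float((ak - expected).sum()))
        if correction:
            deviation -= 0.5
        statistic = deviation**2 / var_sum
        p_value = float(chi2.sf(statistic, df=1))
    return CMHResult(
        statistic=statistic,
        p_value=p_value,
        real_frequency=real_freq,
        control_frequency=control_freq,
        n_strata=int(informative.sum()),
        n_skipped=n_skipped,
        correction=correction,
    )
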