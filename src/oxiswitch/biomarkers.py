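"""Targeted lipid-peroxidation biomarker panel statistics.

Analytes are quantified as relative responses (analyte peak area over
internal-standard peak area).  Analytes below the limit of quantification
in every study sample are excluded; changes over time are assessed with
two-sided Wilcoxon rank-sum tests of each post-procedure timepoint
against baseline, and association with FTOE with Pearson correlation
(strong iff |r| > 0.5 and p < 0.05).  No multiple-testing correction is
applied.
"""

from __future__ import annotations

import itertools
import math
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from oxiswitch.errors import ValidationError

ANALYTES = ("IsoPs", "Di-homo-IsoPs", "Di-homo-IsoFs", "NeuroFs", "IsoFs", "NeuroPs")

PANEL_COLUMNS = ("sample_id", "analyte", "analyte_area", "is_area", "below_loq")

#: combined group size at or below which the rank-sum p is exact
EXACT_N_MAX = 12


def relative_response(analyte_area, is_area):
    """Analyte response relative to the internal standard (dimensionless).

    Nonpositive internal-standard areas yield NaN (flagged missing).
    """
    analyte_area = np.asarray(analyte_area, dtype=float)
    is_area = np.asarray(is_area, dtype=float)
    out = np.where(is_area > 0, analyte_area / np.where(is_area > 0, is_area, 1.0), np.nan)
    return out if out.ndim else float(out)


def _check_panel(panel: pd.DataFrame) -> None:
    for col in ("analyte", "below_loq"):
        if col not in panel.columns:
            raise ValidationError(f"biomarker panel is missing column {col!r}")


def loq_exclude(panel: pd.DataFrame) -> list[str]:
    """Analytes retained after LOQ screening.

    An analyte is excluded iff it is below the LOQ in *all* samples.
    Idempotent by construction.
    """
    _check_panel(panel)
    retained = []
    for analyte, grp in panel.groupby("analyte", sort=False):
        if not grp["below_loq"].astype(bool).all():
            retained.append(analyte)
    return retained


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by exhaustive enumeration of group assignments (with midranks
    for ties) when the combined sample size is <= :data:`EXACT_N_MAX`;
    otherwise the normal approximation with tie and continuity
    corrections.  The exact two-sided p is ``min(1, 2*min(P(W <= w),
    P(W >= w)))`` for the observed rank sum ``w`` of the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValidationError("rank-sum test requires non-empty groups")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    n = n1 + n2

    if n <= EXACT_N_MAX:
        count_le = 0
        count_ge = 0
        total = 0
        for comb in itertools.combinations(range(n), n1):
            ws = ranks[list(comb)].sum()
            if ws <= w + 1e-9:
                count_le += 1
            if ws >= w - 1e-9:
                count_ge += 1
            total += 1
        p = 2.0 * min(count_le / total, count_ge / total)
        return min(1.0, p)

    mean = n1 * (n + 1) / 2.0
    # tie correction for the variance of the rank sum
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    diff = w - mean
    cc = min(0.5, abs(diff))  # continuity correction toward the mean
    z = (abs(diff) - cc) / math.sqrt(var)
    return min(1.0, 2.0 * float(stats.norm.sf(z)))


def wilcoxon_over_time(
    panel: pd.DataFrame,
    baseline: str = "pre",
    comparisons: tuple[str, ...] | None = None,
    value_column: str = "relative_response",
) -> pd.DataFrame:
    """Rank-sum p for each analyte at each post-baseline timepoint.

    ``panel`` needs columns ``analyte, timepoint`` and the value column;
    rows below the LOQ contribute their reported value if present (a
    reported value below LOQ is still a measurement), otherwise they are
    dropped.  Analytes failing :func:`loq_exclude` are omitted.
    """
    _check_panel(panel)
    for col in ("timepoint", value_column):
        if col not in panel.columns:
            raise ValidationError(f"biomarker panel is missing column {col!r}")
    retained = set(loq_exclude(panel))
    if comparisons is None:
        comparisons = tuple(
            tp for tp in pd.unique(panel["timepoint"]) if tp != baseline
        )
    rows = []
    for analyte, grp in panel.groupby("analyte", sort=False):
        if analyte not in retained:
            continue
        base = grp.loc[grp["timepoint"] == baseline, value_column].dropna().to_numpy()
        for tp in comparisons:
            other = grp.loc[grp["timepoint"] == tp, value_column].dropna().to_numpy()
            if base.size < 2 or other.size < 2:
                raise ValidationError(
                    f"analyte {analyte!r}: need >= 2 observations per group "
                    f"({baseline}: {base.size}, {tp}: {other.size})"
                )
            rows.append((analyte, baseline, tp, rank_sum_test(other, base)))
    return pd.DataFrame(rows, columns=["analyte", "baseline", "timepoint", "p"])


class FtoeCorrelation(NamedTuple):
    analyte: str
    r: float
    p: float
    n: int
    strong: bool
    constant: bool


def biomarker_ftoe_correlation(
    panel: pd.DataFrame,
    ftoe: dict[tuple[str, str], float],
    value_column: str = "relative_response",
) -> list[FtoeCorrelation]:
    """Pearson correlation of each analyte's responses against FTOE.

    ``panel`` needs ``patient_id`` and ``timepoint`` columns to pair each
    sample with its FTOE value.  ``strong`` iff |r| > 0.5 (strict) and
    p < 0.05.
    """
    for col in ("analyte", "patient_id", "timepoint", value_column):
        if col not in panel.columns:
            raise ValidationError(f"biomarker panel is missing column {col!r}")
    out = []
    for analyte, grp in panel.groupby("analyte", sort=False):
        pairs = [
            (float(v), ftoe[(str(p), str(t))])
            for v, p, t in zip(grp[value_column], grp["patient_id"], grp["timepoint"])
            if (str(p), str(t)) in ftoe and np.isfinite(v)
        ]
        if len(pairs) < 3:
            raise ValidationError(f"analyte {analyte!r}: fewer than 3 paired values")
        v = np.array([a for a, _ in pairs])
        f = np.array([b for _, b in pairs])
        n = v.size
        if np.all(v == v[0]) or np.all(f == f[0]):
            out.append(FtoeCorrelation(analyte, math.nan, math.nan, n, False, True))
            continue
        vc = v - v.mean()
        fc = f - f.mean()
        r = float((vc @ fc) / math.sqrt((vc @ vc) * (fc @ fc)))
        r = max(-1.0, min(1.0, r))
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1 - r * r))
            p = min(1.0, 2.0 * float(stats.t.sf(abs(t), n - 2)))
        strong = abs(r) > 0.5 and p < 0.05
        out.append(FtoeCorrelation(analyte, r, p, n, strong, False))
    return out
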