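"""Cerebral oximetry derivations and clinical association statistics.

Cerebral oxygen extraction is estimated as the difference of arterial and
regional cerebral tissue saturation (CEO2 = SaO2 - ScO2) and fractional
tissue oxygen extraction as FTOE = CEO2/SaO2.  Both accept either the
fraction (0-1] or percent (0-100] scale, as long as the two inputs share
one; FTOE is dimensionless either way.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from oxiswitch.errors import ValidationError


def _is_percent_scale(x: np.ndarray) -> bool:
    return bool(np.nanmax(x) > 1.0)


def compute_ceo2(sao2, sco2):
    """Cerebral oxygen extraction: SaO2 - ScO2 (same scale for both)."""
    sao2 = np.asarray(sao2, dtype=float)
    sco2 = np.asarray(sco2, dtype=float)
    if sao2.size and sco2.size and _is_percent_scale(sao2) != _is_percent_scale(sco2):
        raise ValidationError(
            "sao2 and sco2 appear to be on different scales (fraction vs percent)"
        )
    out = sao2 - sco2
    return out if out.ndim else float(out)


def compute_ftoe(ceo2, sao2):
    """Fractional tissue oxygen extraction: CEO2/SaO2 (dimensionless)."""
    ceo2 = np.asarray(ceo2, dtype=float)
    sao2 = np.asarray(sao2, dtype=float)
    if np.any(sao2 == 0):
        raise ValidationError("sao2 must be nonzero to compute FTOE")
    out = ceo2 / sao2
    return out if out.ndim else float(out)


def derive_oximetry(clinical: pd.DataFrame) -> pd.DataFrame:
    """Append derived ``ceo2``/``ftoe`` columns and a negative-CEO2 flag.

    Negative CEO2 values (ScO2 above SaO2, physiologically noisy but
    possible) are kept, not clipped.
    """
    for col in ("patient_id", "timepoint", "sao2", "sco2"):
        if col not in clinical.columns:
            raise ValidationError(f"clinical sheet is missing column {col!r}")
    out = clinical.copy()
    ceo2 = compute_ceo2(out["sao2"].to_numpy(), out["sco2"].to_numpy())
    out["ceo2"] = ceo2
    out["ftoe"] = compute_ftoe(ceo2, out["sao2"].to_numpy())
    out["ceo2_negative"] = out["ceo2"] < 0
    return out


def read_clinical(path: str | Path) -> pd.DataFrame:
    sep = "\t"
    with open(path) as fh:
        if fh.readline().count(",") > 0:
            sep = ","
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str, "timepoint": str})
    return df


def ftoe_lookup(clinical: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Map ``(patient_id, timepoint)`` to FTOE, deriving it if needed."""
    df = clinical if "ftoe" in clinical.columns else derive_oximetry(clinical)
    return {
        (str(r.patient_id), str(r.timepoint)): float(r.ftoe)
        for r in df.itertuples(index=False)
    }


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    n: int
    exact: bool


_EXACT_N_MAX = 8


def spearman_assoc(x, y, exact_n_max: int = _EXACT_N_MAX) -> SpearmanResult:
    """Spearman rank correlation with a two-sided p-value.

    Ranks use average ranks for ties.  For n <= ``exact_n_max`` the
    p-value is computed by exhaustive permutation of one variable
    (probability of |rho| at least as extreme); larger n use the
    t-approximation with n-2 degrees of freedom.  NaN pairs are dropped
    pairwise.  A constant vector yields an undefined (NaN) rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValidationError(f"need at least 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(math.nan, math.nan, n, False)

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= exact_n_max:
        # enumerate all orderings of one rank vector against the other
        ry_perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        ryc = ry_perms - ry_perms.mean(axis=1, keepdims=True)
        num = ryc @ rxc
        den = np.sqrt((ryc**2).sum(axis=1) * (rxc**2).sum())
        rhos = num / den
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return SpearmanResult(rho, p, n, True)

    if abs(rho) >= 1.0:
        return SpearmanResult(rho, 0.0, n, False)
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return SpearmanResult(rho, min(p, 1.0), n, False)
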