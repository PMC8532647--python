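"""Post-correction feature exclusion rules: blank, QC-RSD and drug ions.

The cascade removes, in order:

1. features detected in blanks -- median study intensity below
   ``blank_ratio`` (default 5x) times the blank signal, strict ``<``;
2. features with QC RSD%% at or above ``rsd_threshold_percent``
   (default 20, inclusive per the ">= 20%" rule);
3. features whose m/z falls within ``drug_mz_tolerance`` (default 10 mDa)
   of an administered drug's molecular ion, its Na/K adducts, or their
   first 13C isotopologues.

The surviving set is independent of the order (the rules touch disjoint
evidence); only the per-feature removal-reason attribution follows the
cascade order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from oxiswitch.errors import ValidationError
from oxiswitch.ions import adduct_mz, check_mode
from oxiswitch.peaktable import BLANK, QC, STUDY, FeatureTable, PipelineConfig


@dataclass(frozen=True)
class DrugEntry:
    """An administered drug (or drug metabolite) by neutral monoisotopic mass."""

    name: str
    neutral_mass: float

    def __post_init__(self):
        if not self.neutral_mass > 0:
            raise ValidationError(f"drug {self.name!r}: neutral_mass must be positive")


@dataclass
class FilterReport:
    """Accounting of the filter cascade; counts always reconcile."""

    n_input: int
    n_removed_blank: int
    n_removed_rsd: int
    n_removed_drug: int
    n_surviving: int
    reasons: dict[str, str] = field(default_factory=dict)  # feature_id -> first reason

    def __post_init__(self):
        total = self.n_removed_blank + self.n_removed_rsd + self.n_removed_drug
        if self.n_input != self.n_surviving + total:
            raise ValidationError("filter report counts do not reconcile")


def read_drug_list(path: str | Path) -> list[DrugEntry]:
    df = pd.read_csv(path, sep="\t")
    for col in ("name", "neutral_mass"):
        if col not in df.columns:
            raise ValidationError(f"drug list {path} is missing column {col!r}")
    return [DrugEntry(str(r.name), float(r.neutral_mass)) for r in df.itertuples(index=False)]


def packaged_drug_list() -> list[DrugEntry]:
    """Drugs commonly administered in the neonatal setting (fixture list)."""
    with resources.as_file(resources.files("oxiswitch.data") / "drugs.tsv") as p:
        return read_drug_list(p)


def rsd_percent(values) -> float:
    """RSD%% = 100 * sample standard deviation (n-1) / mean.

    A nonpositive mean yields ``inf`` (flagged unusable precision).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("RSD needs at least 2 values")
    mean = values.mean()
    if mean <= 0:
        return float("inf")
    return float(100.0 * values.std(ddof=1) / mean)


def blank_filter(table: FeatureTable, ratio: float = 5.0) -> tuple[FeatureTable, list[str]]:
    """Remove features whose median study signal is below ``ratio`` times
    the blank signal (max over blank injections); zero-blank features are
    always kept."""
    blank_mask = table.role_mask(BLANK)
    if not blank_mask.any():
        raise ValidationError("blank filter requires at least one blank injection")
    study_mask = table.role_mask(STUDY)
    blank_signal = table.intensities[:, blank_mask].max(axis=1)
    study_median = np.median(table.intensities[:, study_mask], axis=1)
    removed = (blank_signal > 0) & (study_median < ratio * blank_signal)
    removed_ids = [f.feature_id for f, r in zip(table.features, removed) if r]
    return table.subset_features(~removed), removed_ids


def rsd_filter(table: FeatureTable, threshold: float = 20.0) -> tuple[FeatureTable, list[str]]:
    """Remove features with QC RSD%% >= ``threshold`` (inclusive)."""
    qc_mask = table.role_mask(QC)
    if qc_mask.sum() < 2:
        raise ValidationError("RSD filter requires at least 2 non-conditioning QC injections")
    qc = table.intensities[:, qc_mask]
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    rsd = np.full(mean.shape, np.inf)
    ok = mean > 0
    rsd[ok] = 100.0 * sd[ok] / mean[ok]
    removed = rsd >= threshold
    removed_ids = [f.feature_id for f, r in zip(table.features, removed) if r]
    return table.subset_features(~removed), removed_ids


def expand_drug_ions(drug: DrugEntry, mode: str) -> list[tuple[str, float]]:
    """Expected m/z values of a drug's ions in one ionization mode.

    Positive mode: [M+H]+, [M+Na]+, [M+K]+; negative mode: [M-H]-,
    [M+Na-2H]-, [M+K-2H]-; each with its first 13C isotopologue.
    """
    check_mode(mode)
    return [
        (f"{drug.name} {label}", mz)
        for label, mz in adduct_mz(drug.neutral_mass, mode, isotopologues=True)
    ]


def drug_filter(
    table: FeatureTable, drugs: list[DrugEntry], tol: float = 0.010
) -> tuple[FeatureTable, list[str]]:
    """Remove features whose m/z lies strictly within ``tol`` Th of any
    expanded drug ion of the feature's mode (retention time is ignored)."""
    if tol < 0:
        raise ValidationError("drug m/z tolerance must be nonnegative")
    if not drugs:
        warnings.warn("empty drug list: drug filter is a no-op", stacklevel=2)
        return table.subset_features(np.ones(len(table.features), dtype=bool)), []
    ion_mz = {
        mode: np.array(
            [mz for drug in drugs for _, mz in expand_drug_ions(drug, mode)]
        )
        for mode in ("positive", "negative")
    }
    removed = np.zeros(len(table.features), dtype=bool)
    for i, feat in enumerate(table.features):
        ions = ion_mz[feat.mode]
        if ions.size and np.min(np.abs(feat.mz - ions)) < tol:
            removed[i] = True
    removed_ids = [f.feature_id for f, r in zip(table.features, removed) if r]
    return table.subset_features(~removed), removed_ids


def apply_filter_cascade(
    table: FeatureTable,
    config: PipelineConfig | None = None,
    drugs: list[DrugEntry] | None = None,
) -> tuple[FeatureTable, FilterReport]:
    """Blank filter, then RSD filter, then drug filter."""
    config = config or PipelineConfig()
    if drugs is None:
        drugs = packaged_drug_list()
    n_input = len(table.features)
    table1, blank_ids = blank_filter(table, config.blank_ratio)
    table2, rsd_ids = rsd_filter(table1, config.rsd_threshold_percent)
    table3, drug_ids = drug_filter(table2, drugs, config.drug_mz_tolerance)
    reasons: dict[str, str] = {}
    for fid in blank_ids:
        reasons[fid] = "blank"
    for fid in rsd_ids:
        reasons[fid] = "rsd"
    for fid in drug_ids:
        reasons[fid] = "drug"
    report = FilterReport(
        n_input=n_input,
        n_removed_blank=len(blank_ids),
        n_removed_rsd=len(rsd_ids),
        n_removed_drug=len(drug_ids),
        n_surviving=len(table3.features),
        reasons=reasons,
    )
    return table3, report
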