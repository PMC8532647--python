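"""Domain types, readers/writers and validation for aligned peak tables.

A peak table is a nonnegative intensity matrix (features x injections)
carrying per-feature (m/z, RT, ionization mode) metadata and per-injection
batch metadata (order, role, patient, timepoint).  Zero intensity means
"not detected / filled" and is treated as an observed value throughout.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from oxiswitch.errors import ValidationError
from oxiswitch.ions import MODES

STUDY = "study"
QC = "qc"
BLANK = "blank"
CONDITIONING = "conditioning"
ROLES = (STUDY, QC, BLANK, CONDITIONING)

#: canonical sampling timepoints: 5 min pre-procedure, then 5 min to 96 h post
TIMEPOINTS = ("pre", "5min", "6h", "24h", "48h", "72h", "96h")

#: hours after the procedure for each timepoint (pre mapped to 0)
TIMEPOINT_HOURS = {
    "pre": 0.0,
    "5min": 5.0 / 60.0,
    "6h": 6.0,
    "24h": 24.0,
    "48h": 48.0,
    "72h": 72.0,
    "96h": 96.0,
}


@dataclass(frozen=True)
class Feature:
    """A single aligned LC-MS feature."""

    feature_id: str
    mz: float
    rt: float
    mode: str

    def __post_init__(self):
        if not self.feature_id:
            raise ValidationError("feature_id must be a non-empty string")
        if not (self.mz > 0) or not math.isfinite(self.mz):
            raise ValidationError(f"feature {self.feature_id!r}: mz must be positive, got {self.mz}")
        if self.rt < 0 or not math.isfinite(self.rt):
            raise ValidationError(f"feature {self.feature_id!r}: rt must be nonnegative, got {self.rt}")
        if self.mode not in MODES:
            raise ValidationError(
                f"feature {self.feature_id!r}: unknown ionization mode {self.mode!r}"
            )


@dataclass(frozen=True)
class Injection:
    """One injection of the analytical batch."""

    injection_id: str
    order: int
    role: str
    patient_id: str | None = None
    timepoint: str | None = None

    def __post_init__(self):
        if not self.injection_id:
            raise ValidationError("injection_id must be a non-empty string")
        if self.role not in ROLES:
            raise ValidationError(
                f"injection {self.injection_id!r}: unknown role {self.role!r}; expected one of {ROLES}"
            )
        if int(self.order) != self.order or self.order < 1:
            raise ValidationError(
                f"injection {self.injection_id!r}: order must be a 1-based integer, got {self.order}"
            )
        if self.role == STUDY:
            if not self.patient_id or not self.timepoint:
                raise ValidationError(
                    f"study injection {self.injection_id!r} must carry patient_id and timepoint"
                )
            if self.timepoint not in TIMEPOINTS:
                raise ValidationError(
                    f"injection {self.injection_id!r}: unknown timepoint {self.timepoint!r}"
                )


@dataclass
class FeatureTable:
    """Intensity matrix plus feature and injection metadata.

    ``intensities[i, j]`` is the intensity of feature ``i`` in injection
    ``j``; zeros are legal (filled/absent) values.
    """

    features: list[Feature]
    injections: list[Injection]
    intensities: np.ndarray

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValidationError("intensities must be a 2-D matrix")
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        nf, ni = self.intensities.shape
        if nf != len(self.features) or ni != len(self.injections):
            raise ValidationError(
                f"matrix shape {self.intensities.shape} does not match "
                f"{len(self.features)} features x {len(self.injections)} injections"
            )
        seen: set[str] = set()
        for feat in self.features:
            if feat.feature_id in seen:
                raise ValidationError(f"duplicate feature_id {feat.feature_id!r}")
            seen.add(feat.feature_id)
        seen_inj: set[str] = set()
        seen_order: set[int] = set()
        for inj in self.injections:
            if inj.injection_id in seen_inj:
                raise ValidationError(f"duplicate injection_id {inj.injection_id!r}")
            if inj.order in seen_order:
                raise ValidationError(
                    f"injection {inj.injection_id!r}: duplicate order {inj.order}"
                )
            seen_inj.add(inj.injection_id)
            seen_order.add(inj.order)
        if self.intensities.size and not np.all(np.isfinite(self.intensities)):
            i, j = np.argwhere(~np.isfinite(self.intensities))[0]
            raise ValidationError(
                f"non-finite intensity for feature {self.features[i].feature_id!r} "
                f"in injection {self.injections[j].injection_id!r}"
            )
        if self.intensities.size and self.intensities.min() < 0:
            i, j = np.argwhere(self.intensities < 0)[0]
            raise ValidationError(
                f"negative intensity for feature {self.features[i].feature_id!r} "
                f"in injection {self.injections[j].injection_id!r}"
            )

    # -- convenience accessors ----------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def injection_ids(self) -> list[str]:
        return [i.injection_id for i in self.injections]

    @property
    def orders(self) -> np.ndarray:
        return np.array([i.order for i in self.injections], dtype=int)

    def role_mask(self, role: str) -> np.ndarray:
        return np.array([i.role == role for i in self.injections], dtype=bool)

    def subset_features(self, keep: Sequence[bool] | Sequence[int]) -> "FeatureTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return FeatureTable(
            [self.features[i] for i in idx],
            list(self.injections),
            self.intensities[idx, :],
        )

    def subset_injections(self, keep: Sequence[bool] | Sequence[int]) -> "FeatureTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return FeatureTable(
            list(self.features),
            [self.injections[j] for j in idx],
            self.intensities[:, idx],
        )

    def study_samples(self) -> "FeatureTable":
        return self.subset_injections(self.role_mask(STUDY))

    def features_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": [f.feature_id for f in self.features],
                "mz": [f.mz for f in self.features],
                "rt": [f.rt for f in self.features],
                "mode": [f.mode for f in self.features],
            }
        )

    def injections_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "injection_id": [i.injection_id for i in self.injections],
                "order": [i.order for i in self.injections],
                "role": [i.role for i in self.injections],
                "patient_id": [i.patient_id for i in self.injections],
                "timepoint": [i.timepoint for i in self.injections],
            }
        )


@dataclass
class PipelineConfig:
    """Tunable thresholds of the full pipeline.

    Defaults mirror the reference analysis: blank exclusion below 5x the
    blank signal, QC RSD% >= 20 exclusion, 10 mDa drug-ion tolerance,
    10 ppm annotation accuracy, top-10% significant fraction and the
    p < 0.05 / |r| > 0.5 correlation rule.
    """

    blank_ratio: float = 5.0
    rsd_threshold_percent: float = 20.0
    drug_mz_tolerance: float = 0.010
    annotation_ppm: float = 10.0
    sig_top_fraction: float = 0.10
    corr_p_threshold: float = 0.05
    corr_r_threshold: float = 0.5
    svr_epsilon_grid: tuple[float, ...] = (2.5, 3.75, 5.0, 6.25, 7.5)
    svr_gamma_grid: tuple[float, ...] = (1.0, 1e1, 1e2, 1e3, 1e4, 1e5)
    permutations: int = 1000
    rng_seed: int = 0

    def __post_init__(self):
        for name in (
            "blank_ratio",
            "rsd_threshold_percent",
            "annotation_ppm",
            "corr_p_threshold",
            "corr_r_threshold",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.drug_mz_tolerance < 0:
            raise ValidationError("drug_mz_tolerance must be nonnegative")
        if not (0 < self.sig_top_fraction <= 1):
            raise ValidationError("sig_top_fraction must be in (0, 1]")
        if self.permutations < 1:
            raise ValidationError("permutations must be >= 1")
        self.svr_epsilon_grid = tuple(float(v) for v in self.svr_epsilon_grid)
        self.svr_gamma_grid = tuple(float(v) for v in self.svr_gamma_grid)
        if not self.svr_epsilon_grid or not self.svr_gamma_grid:
            raise ValidationError("SVR grids must be non-empty")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FEATURE_COLS = ["feature_id", "mz", "rt", "mode"]
_META_COLS = ["injection_id", "order", "role", "patient_id", "timepoint"]


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_feature_table(path: str | Path, metadata_path: str | Path) -> FeatureTable:
    """Read a peak table (CSV/TSV) and its injection metadata sheet.

    The peak table has one row per feature with columns
    ``feature_id, mz, rt, mode`` followed by one intensity column per
    injection.  The metadata sheet is keyed by ``injection_id`` with
    columns ``order, role, patient_id, timepoint``.  The delimiter is
    auto-detected from the header row.
    """
    peaks = pd.read_csv(
        path, sep=_sniff_sep(path), dtype={"feature_id": str}, float_precision="round_trip"
    )
    missing = [c for c in _FEATURE_COLS if c not in peaks.columns]
    if missing:
        raise ValidationError(f"peak table {path} is missing columns {missing}")
    meta = pd.read_csv(metadata_path, sep=_sniff_sep(metadata_path), dtype={"injection_id": str})
    missing = [c for c in _META_COLS[:3] if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata sheet {metadata_path} is missing columns {missing}")

    injections = []
    for row in meta.itertuples(index=False):
        patient = getattr(row, "patient_id", None)
        timepoint = getattr(row, "timepoint", None)
        patient = None if patient is None or (isinstance(patient, float) and math.isnan(patient)) else str(patient)
        timepoint = None if timepoint is None or (isinstance(timepoint, float) and math.isnan(timepoint)) else str(timepoint)
        injections.append(
            Injection(str(row.injection_id), int(row.order), str(row.role), patient, timepoint)
        )

    injection_ids = [i.injection_id for i in injections]
    missing_cols = [iid for iid in injection_ids if iid not in peaks.columns]
    if missing_cols:
        raise ValidationError(
            f"peak table {path} has no intensity column for injections {missing_cols[:5]}"
        )
    extra = [
        c for c in peaks.columns if c not in _FEATURE_COLS and c not in set(injection_ids)
    ]
    if extra:
        raise ValidationError(f"peak table {path} has unexpected columns {extra[:5]}")

    features = [
        Feature(str(r.feature_id), float(r.mz), float(r.rt), str(r.mode))
        for r in peaks.itertuples(index=False)
    ]
    intensities = peaks[injection_ids].to_numpy(dtype=float)
    return FeatureTable(features, injections, intensities)


def _format_float(x: float) -> str:
    # repr() of a Python float is the shortest string that round-trips
    return repr(float(x))


def write_feature_table(
    table: FeatureTable, path: str | Path, metadata_path: str | Path | None = None, sep: str = ","
) -> None:
    """Write a peak table (and optionally its metadata sheet) to disk.

    Values are serialized at full precision so that a read-back
    reproduces the table bit-faithfully.
    """
    ids = table.injection_ids
    with open(path, "w") as fh:
        fh.write(sep.join(_FEATURE_COLS + ids) + "\n")
        for i, feat in enumerate(table.features):
            row = [feat.feature_id, _format_float(feat.mz), _format_float(feat.rt), feat.mode]
            row += [_format_float(v) for v in table.intensities[i]]
            fh.write(sep.join(row) + "\n")
    if metadata_path is not None:
        write_injection_metadata(table.injections, metadata_path)


def write_injection_metadata(injections: Iterable[Injection], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_META_COLS) + "\n")
        for inj in injections:
            fh.write(
                "\t".join(
                    [
                        inj.injection_id,
                        str(inj.order),
                        inj.role,
                        inj.patient_id or "",
                        inj.timepoint or "",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# mode concatenation
# ---------------------------------------------------------------------------


def concatenate_modes(pos: FeatureTable, neg: FeatureTable) -> FeatureTable:
    """Feature-wise concatenation of the two ionization-mode tables.

    Study injections are aligned by ``(patient_id, timepoint)``; QC, blank
    and conditioning injections are aligned by order rank within their
    role.  The returned table keeps the positive-mode injection metadata.
    """

    def _study_key_index(table: FeatureTable) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for j, inj in enumerate(table.injections):
            if inj.role == STUDY:
                key = (inj.patient_id, inj.timepoint)
                if key in out:
                    raise ValidationError(f"duplicate study sample {key} in one mode")
                out[key] = j
        return out

    pos_study = _study_key_index(pos)
    neg_study = _study_key_index(neg)
    missing = sorted(set(pos_study) ^ set(neg_study))
    if missing:
        raise ValidationError(f"unmatched study samples between modes: {missing}")

    def _role_indices(table: FeatureTable, role: str) -> list[int]:
        idx = [j for j, inj in enumerate(table.injections) if inj.role == role]
        return sorted(idx, key=lambda j: table.injections[j].order)

    neg_col_for_pos_col: dict[int, int] = {}
    for key, j in pos_study.items():
        neg_col_for_pos_col[j] = neg_study[key]
    for role in (QC, BLANK, CONDITIONING):
        pos_idx = _role_indices(pos, role)
        neg_idx = _role_indices(neg, role)
        if len(pos_idx) != len(neg_idx):
            raise ValidationError(
                f"mode mismatch for role {role!r}: {len(pos_idx)} vs {len(neg_idx)} injections"
            )
        for pj, nj in zip(pos_idx, neg_idx):
            neg_col_for_pos_col[pj] = nj

    order = [neg_col_for_pos_col[j] for j in range(len(pos.injections))]
    neg_aligned = neg.intensities[:, order]
    features = list(pos.features) + list(neg.features)
    intensities = np.vstack([pos.intensities, neg_aligned]) if features else np.zeros((0, len(pos.injections)))
    return FeatureTable(features, list(pos.injections), intensities)
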