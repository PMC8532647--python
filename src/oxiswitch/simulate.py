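"""Synthetic cohort and LC-MS batch generator with known planted structure.

Emulates the study design end-to-end: 9 patients sampled at 7 timepoints
(5 min pre-procedure; 5 min, 6, 24, 48, 72 and 96 h post), analyzed in
randomized order in a single batch per ionization mode with 8 conditioning
QC injections, a QC every ``qc_period`` study samples plus batch start and
end, and blank injections mid-batch and at the end.

Planted feature classes (exactly one per feature):

* ``stable`` -- constant baseline, biological + measurement noise;
* ``drifting`` -- smooth injection-order drift (linear + low-frequency
  cosine mixture, normalized so ``drift_amplitude`` is the relative SD of
  the drift over the batch);
* ``blank_contaminant`` -- strong signal in blank injections;
* ``drug_ion`` -- m/z placed within the drug-ion exclusion tolerance of a
  packaged administered-drug adduct;
* ``ftoe_correlated`` -- log-intensity correlated with the sample's FTOE
  at a target Pearson r, each assigned a compound of the planted pathway.

Oximetry trajectories are anchored to the printed cohort medians
(SaO2 0.856 pre rising to 0.90 by 24 h; rcSO2 0.50 pre to 0.692 by 24 h,
then plateau), interpolated linearly on the hours axis between the pre and
24 h anchors, so the derived FTOE stays near its baseline through 6 h and
drops to its plateau by 24 h (recovery completes at 24 h).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from oxiswitch.enrichment import PathwayLibrary
from oxiswitch.errors import ValidationError
from oxiswitch.filters import DrugEntry, expand_drug_ions, packaged_drug_list
from oxiswitch.ions import NEGATIVE, POSITIVE, adduct_mz
from oxiswitch.oximetry import derive_oximetry
from oxiswitch.peaktable import (
    BLANK,
    CONDITIONING,
    QC,
    STUDY,
    TIMEPOINT_HOURS,
    TIMEPOINTS,
    Feature,
    FeatureTable,
    Injection,
    write_feature_table,
    write_injection_metadata,
)

CLASS_STABLE = "stable"
CLASS_DRIFTING = "drifting"
CLASS_BLANK = "blank_contaminant"
CLASS_DRUG = "drug_ion"
CLASS_CORRELATED = "ftoe_correlated"
FEATURE_CLASSES = (CLASS_STABLE, CLASS_DRIFTING, CLASS_BLANK, CLASS_DRUG, CLASS_CORRELATED)

PLANTED_PATHWAY_ID = "map_planted"


@dataclass
class SimulationParams:
    """Knobs of the synthetic study; defaults emulate the reference design."""

    n_patients: int = 9
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_features_per_mode: int = 500
    frac_drifting: float = 0.3
    frac_blank_contaminant: float = 0.05
    frac_drug: float = 0.03
    frac_ftoe_correlated: float = 0.1
    target_abs_r: float = 0.7
    noise_cv: float = 0.08
    drift_amplitude: float = 0.3
    qc_period: int = 6
    n_conditioning: int = 8
    n_blanks: int = 2
    rng_seed: int = 0
    # cohort noise
    patient_sd: float = 0.02
    obs_sd: float = 0.01
    # biological between-sample variation of non-correlated features
    bio_cv: float = 0.25
    # pathway-library shape
    n_decoy_pathways: int = 3
    decoy_pathway_size: int = 12
    # oximetry anchors (fraction scale): printed cohort medians
    sao2_pre: float = 0.856
    sao2_24h: float = 0.900
    sco2_pre: float = 0.500
    sco2_24h: float = 0.692

    def __post_init__(self):
        fr = (
            self.frac_drifting
            + self.frac_blank_contaminant
            + self.frac_drug
            + self.frac_ftoe_correlated
        )
        if fr > 1 + 1e-9:
            raise ValidationError("feature-class fractions must sum to <= 1")
        if self.n_patients < 2:
            raise ValidationError("n_patients must be >= 2")
        if self.qc_period < 2:
            raise ValidationError("qc_period must be >= 2")
        if self.n_blanks < 1:
            raise ValidationError("n_blanks must be >= 1")
        for tp in self.timepoints:
            if tp not in TIMEPOINT_HOURS:
                raise ValidationError(f"unknown timepoint {tp!r}")
    def effective_decoy_size(self) -> int:
        """Decoy pathway size, shrunk so every decoy compound can be
        hosted by a distinct stable feature."""
        n_stable = self.class_counts()[CLASS_STABLE]
        if self.n_decoy_pathways == 0:
            return 0
        return min(self.decoy_pathway_size, n_stable // self.n_decoy_pathways)

    def class_counts(self) -> dict[str, int]:
        n = self.n_features_per_mode
        counts = {
            CLASS_DRIFTING: round(self.frac_drifting * n),
            CLASS_BLANK: round(self.frac_blank_contaminant * n),
            CLASS_DRUG: round(self.frac_drug * n),
            CLASS_CORRELATED: round(self.frac_ftoe_correlated * n),
        }
        counts[CLASS_STABLE] = n - sum(counts.values())
        if counts[CLASS_STABLE] < 0:
            raise ValidationError("rounded class counts exceed the feature count")
        return counts


@dataclass
class SimulationTruth:
    """Ground-truth registry of the planted structure for one mode."""

    feature_class: dict[str, str]
    drift_params: dict[str, dict[str, float]]  # fid -> {weight, freq, phase, amplitude}
    correlated: dict[str, dict] = field(default_factory=dict)  # fid -> {sign, compound}
    planted_pathway_id: str = PLANTED_PATHWAY_ID

    def __post_init__(self):
        for fid, cls in self.feature_class.items():
            if cls not in FEATURE_CLASSES:
                raise ValidationError(f"feature {fid}: unknown class {cls!r}")

    def ids_of(self, cls: str) -> list[str]:
        return [fid for fid, c in self.feature_class.items() if c == cls]

    def to_dict(self) -> dict:
        return {
            "feature_class": self.feature_class,
            "drift_params": self.drift_params,
            "correlated": self.correlated,
            "planted_pathway_id": self.planted_pathway_id,
        }


# ---------------------------------------------------------------------------
# cohort oximetry
# ---------------------------------------------------------------------------


def _anchor(t_hours: float, pre: float, h24: float) -> float:
    # linear on the hours axis up to 24 h, plateau afterwards
    return pre + (h24 - pre) * min(t_hours, 24.0) / 24.0


def simulate_cohort(params: SimulationParams) -> pd.DataFrame:
    """Per patient-timepoint SaO2/rcSO2 trajectories (fraction scale).

    Medians follow the printed anchors with per-patient random offsets
    (sd ``patient_sd``) and per-observation noise (sd ``obs_sd``); all
    values are clipped to (0, 1].  With both noise terms at zero every
    patient reproduces the anchors exactly.
    """
    rng = np.random.default_rng([params.rng_seed, 101])
    rows = []
    for pi in range(params.n_patients):
        pid = f"P{pi + 1:02d}"
        off_sao2 = rng.normal(0.0, params.patient_sd) if params.patient_sd > 0 else 0.0
        off_sco2 = rng.normal(0.0, params.patient_sd) if params.patient_sd > 0 else 0.0
        for tp in params.timepoints:
            t = TIMEPOINT_HOURS[tp]
            sao2 = _anchor(t, params.sao2_pre, params.sao2_24h) + off_sao2
            sco2 = _anchor(t, params.sco2_pre, params.sco2_24h) + off_sco2
            if params.obs_sd > 0:
                sao2 += rng.normal(0.0, params.obs_sd)
                sco2 += rng.normal(0.0, params.obs_sd)
            rows.append((pid, tp, float(np.clip(sao2, 0.01, 1.0)), float(np.clip(sco2, 0.01, 1.0))))
    return pd.DataFrame(rows, columns=["patient_id", "timepoint", "sao2", "sco2"])


# ---------------------------------------------------------------------------
# planted compound libraries
# ---------------------------------------------------------------------------


def _drug_ion_mzs(drugs: list[DrugEntry]) -> np.ndarray:
    mzs = []
    for drug in drugs:
        for mode in (POSITIVE, NEGATIVE):
            mzs += [mz for _, mz in expand_drug_ions(drug, mode)]
    return np.array(mzs)


def plant_compounds(
    params: SimulationParams, drugs: list[DrugEntry] | None = None
) -> tuple[list[str], list[tuple[str, list[str]]], dict[str, float]]:
    """Deterministically generate planted and decoy compound sets.

    Returns ``(planted_codes, [(decoy_pathway_id, codes), ...], masses)``.
    Compound masses are drawn away from any packaged drug ion so planted
    features survive the drug filter.
    """
    rng = np.random.default_rng([params.rng_seed, 202])
    drugs = drugs if drugs is not None else packaged_drug_list()
    drug_mzs = _drug_ion_mzs(drugs)

    def draw_mass() -> float:
        for _ in range(1000):
            mass = float(rng.uniform(130.0, 650.0))
            ions = [mz for mode in (POSITIVE, NEGATIVE) for _, mz in adduct_mz(mass, mode)]
            if drug_mzs.size == 0 or min(
                abs(i - d) for i in ions for d in drug_mzs
            ) > 0.05:
                return mass
        raise RuntimeError("could not place a compound mass away from drug ions")

    n_corr = params.class_counts()[CLASS_CORRELATED]
    masses: dict[str, float] = {}
    planted = []
    for i in range(n_corr):
        code = f"PC{i + 1:04d}"
        masses[code] = draw_mass()
        planted.append(code)
    decoys = []
    ci = 0
    decoy_size = params.effective_decoy_size()
    for d in range(params.n_decoy_pathways):
        codes = []
        for _ in range(decoy_size):
            ci += 1
            code = f"DC{ci:04d}"
            masses[code] = draw_mass()
            codes.append(code)
        decoys.append((f"map_decoy{d + 1}", codes))
    return planted, decoys, masses


def build_library(params: SimulationParams, drugs: list[DrugEntry] | None = None) -> PathwayLibrary:
    """Pathway library with the planted pathway plus decoys."""
    planted, decoys, masses = plant_compounds(params, drugs)
    pathways = [(PLANTED_PATHWAY_ID, "Planted pathway", tuple(planted))]
    pathways += [(pid, pid.replace("map_", "Decoy "), tuple(codes)) for pid, codes in decoys]
    return PathwayLibrary(pathways, masses)


# ---------------------------------------------------------------------------
# batch simulation
# ---------------------------------------------------------------------------


def _injection_sequence(
    study_keys: list[tuple[str, str]], params: SimulationParams, rng: np.random.Generator, prefix: str
) -> list[Injection]:
    """Conditioning block, QC-bracketed randomized study samples, blanks."""
    shuffled = [study_keys[i] for i in rng.permutation(len(study_keys))]
    n_study = len(shuffled)
    mid_blank_after = {n_study * j // params.n_blanks for j in range(1, params.n_blanks)}

    roles: list[tuple[str, str | None, str | None]] = []
    for _ in range(params.n_conditioning):
        roles.append((CONDITIONING, None, None))
    roles.append((QC, None, None))
    since_qc = 0
    for s_i, (pid, tp) in enumerate(shuffled):
        roles.append((STUDY, pid, tp))
        since_qc += 1
        if since_qc == params.qc_period:
            roles.append((QC, None, None))
            since_qc = 0
        if (s_i + 1) in mid_blank_after:
            roles.append((BLANK, None, None))
    if roles[-1][0] != QC:
        roles.append((QC, None, None))
    roles.append((BLANK, None, None))

    counters = {QC: 0, BLANK: 0, CONDITIONING: 0}
    injections = []
    for order, (role, pid, tp) in enumerate(roles, start=1):
        if role == STUDY:
            iid = f"{prefix}_{pid}_{tp}"
        else:
            counters[role] += 1
            iid = f"{prefix}_{role}{counters[role]:02d}"
        injections.append(Injection(iid, order, role, pid, tp))
    return injections


def _drift_curve(
    orders: np.ndarray, amplitude: float, weight: float, freq: float, phase: float
) -> np.ndarray:
    """Smooth drift factor, unit mean and relative SD = ``amplitude``."""
    if amplitude == 0:
        return np.ones_like(orders, dtype=float)
    t = (orders - orders.min()) / max(orders.max() - orders.min(), 1.0)
    g = weight * (2.0 * t - 1.0) + (1.0 - weight) * np.cos(2.0 * math.pi * freq * t + phase)
    sd = g.std()
    if sd == 0:
        return np.ones_like(orders, dtype=float)
    return np.maximum(1.0 + amplitude * (g - g.mean()) / sd, 0.05)


def simulate_batch(
    cohort: pd.DataFrame,
    params: SimulationParams,
    mode: str = POSITIVE,
    drugs: list[DrugEntry] | None = None,
) -> tuple[FeatureTable, SimulationTruth]:
    """Simulate one ionization-mode batch for a cohort.

    Intensity model: ``baseline x drift(order) x class effect x
    log-normal measurement noise`` (CV ``noise_cv``).  FTOE-correlated
    features receive a multiplicative term calibrated so the population
    Pearson correlation of log-intensity with the sample's FTOE equals
    ``target_abs_r`` (random sign).  Deterministic given
    ``params.rng_seed`` and mode.
    """
    if mode not in (POSITIVE, NEGATIVE):
        raise ValidationError(f"unknown mode {mode!r}")
    drugs = drugs if drugs is not None else packaged_drug_list()
    rng = np.random.default_rng([params.rng_seed, 11 if mode == POSITIVE else 12])
    prefix = "pos" if mode == POSITIVE else "neg"

    oxi = derive_oximetry(cohort)
    ftoe_map = {
        (str(r.patient_id), str(r.timepoint)): float(r.ftoe) for r in oxi.itertuples(index=False)
    }
    study_keys = [(str(r.patient_id), str(r.timepoint)) for r in cohort.itertuples(index=False)]
    injections = _injection_sequence(study_keys, params, rng, prefix)
    orders = np.array([inj.order for inj in injections], dtype=float)
    study_cols = np.array([inj.role == STUDY for inj in injections])
    blank_cols = np.array([inj.role == BLANK for inj in injections])
    ftoe = np.array(
        [ftoe_map[(inj.patient_id, inj.timepoint)] for inj in injections if inj.role == STUDY]
    )

    n = params.n_features_per_mode
    counts = params.class_counts()
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    pos = 0
    for cls in (CLASS_DRIFTING, CLASS_BLANK, CLASS_DRUG, CLASS_CORRELATED, CLASS_STABLE):
        for i in perm[pos : pos + counts[cls]]:
            labels[i] = cls
        pos += counts[cls]

    planted_codes, decoys, comp_masses = plant_compounds(params, drugs)
    corr_idx = np.flatnonzero(labels == CLASS_CORRELATED)
    stable_idx = np.flatnonzero(labels == CLASS_STABLE)
    decoy_codes_flat = [c for _pid, codes in decoys for c in codes]
    if len(decoy_codes_flat) > stable_idx.size:
        raise ValidationError("not enough stable features to host the decoy compounds")
    decoy_host_idx = stable_idx[: len(decoy_codes_flat)]

    drug_ions = np.array(
        [mz for drug in drugs for _, mz in expand_drug_ions(drug, mode)]
    )
    adduct_labels = [label for label, _ in adduct_mz(200.0, mode)]

    def compound_feature_mz(code: str) -> float:
        ions = adduct_mz(comp_masses[code], mode)
        _label, ion = ions[rng.integers(len(ions))]
        return float(ion * (1.0 + rng.uniform(-6e-6, 6e-6)))

    mz = rng.uniform(100.0, 1000.0, size=n)
    feature_ids = [f"{prefix.upper()[0]}{i + 1:04d}" for i in range(n)]
    truth_corr: dict[str, dict] = {}
    for slot, i in enumerate(corr_idx):
        code = planted_codes[slot]
        mz[i] = compound_feature_mz(code)
        truth_corr[feature_ids[i]] = {"compound": code}
    for slot, i in enumerate(decoy_host_idx):
        mz[i] = compound_feature_mz(decoy_codes_flat[slot])
    for i in np.flatnonzero(labels == CLASS_DRUG):
        ion = drug_ions[rng.integers(drug_ions.size)]
        mz[i] = float(ion + rng.uniform(-0.8, 0.8) * 0.010)

    rt = rng.uniform(30.0, 480.0, size=n)
    features = [Feature(feature_ids[i], float(mz[i]), float(rt[i]), mode) for i in range(n)]

    baseline = 10.0 ** rng.uniform(3.0, 7.0, size=n)
    sigma_m = math.sqrt(math.log1p(params.noise_cv**2))
    sigma_b = math.sqrt(math.log1p(params.bio_cv**2))
    ftoe_sd = ftoe.std()
    r_target = params.target_abs_r
    alpha_mag = (
        sigma_m * r_target / (math.sqrt(1.0 - r_target**2) * ftoe_sd)
        if ftoe_sd > 0 and sigma_m > 0 and r_target < 1
        else 0.0
    )

    n_inj = len(injections)
    intensities = np.zeros((n, n_inj))
    drift_truth: dict[str, dict[str, float]] = {}
    ftoe_centered = ftoe - ftoe.mean()

    for i in range(n):
        cls = labels[i]
        row = np.full(n_inj, baseline[i])
        if cls == CLASS_CORRELATED:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            row[study_cols] = baseline[i] * np.exp(sign * alpha_mag * ftoe_centered)
            row[blank_cols] = 0.0
            truth_corr[feature_ids[i]]["sign"] = sign
        elif cls == CLASS_BLANK:
            row[study_cols] = baseline[i] * rng.uniform(0.5, 3.0, size=int(study_cols.sum()))
            row[blank_cols] = baseline[i] * rng.uniform(1.0, 2.0, size=int(blank_cols.sum()))
        else:
            if sigma_b > 0:
                row[study_cols] = baseline[i] * np.exp(
                    rng.normal(0.0, sigma_b, size=int(study_cols.sum())) - sigma_b**2 / 2.0
                )
            row[blank_cols] = 0.0
        if cls == CLASS_DRIFTING:
            weight = float(rng.uniform(0.0, 1.0))
            freq = float(rng.uniform(0.5, 1.5))
            phase = float(rng.uniform(0.0, 2.0 * math.pi))
            row *= _drift_curve(orders, params.drift_amplitude, weight, freq, phase)
            drift_truth[feature_ids[i]] = {
                "weight": weight,
                "freq": freq,
                "phase": phase,
                "amplitude": params.drift_amplitude,
            }
        if sigma_m > 0:
            row *= np.exp(rng.normal(0.0, sigma_m, size=n_inj) - sigma_m**2 / 2.0)
        intensities[i] = row

    table = FeatureTable(features, injections, intensities)
    truth = SimulationTruth(
        feature_class={feature_ids[i]: labels[i] for i in range(n)},
        drift_params=drift_truth,
        correlated=truth_corr,
    )
    return table, truth


# ---------------------------------------------------------------------------
# full study + on-disk fixture
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    params: SimulationParams
    cohort: pd.DataFrame
    tables: dict[str, FeatureTable]
    truths: dict[str, SimulationTruth]
    library: PathwayLibrary
    drugs: list[DrugEntry]


def simulate_study(params: SimulationParams | None = None) -> SyntheticStudy:
    """Cohort plus both ionization-mode batches, library and drug list."""
    params = params or SimulationParams()
    drugs = packaged_drug_list()
    cohort = simulate_cohort(params)
    tables = {}
    truths = {}
    for mode in (POSITIVE, NEGATIVE):
        table, truth = simulate_batch(cohort, params, mode, drugs)
        tables[mode] = table
        truths[mode] = truth
    library = build_library(params, drugs)
    return SyntheticStudy(params, cohort, tables, truths, library, drugs)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write all fixture files of a synthetic study to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for mode, short in ((POSITIVE, "pos"), (NEGATIVE, "neg")):
        peaks = outdir / f"{short}_peaks.csv"
        meta = outdir / f"{short}_meta.tsv"
        write_feature_table(study.tables[mode], peaks)
        write_injection_metadata(study.tables[mode].injections, meta)
        paths[f"{short}_peaks"] = peaks
        paths[f"{short}_meta"] = meta
    clinical = outdir / "clinical.tsv"
    study.cohort.to_csv(clinical, sep="\t", index=False)
    paths["clinical"] = clinical
    pathways = outdir / "pathways.tsv"
    with open(pathways, "w") as fh:
        fh.write("pathway_id\tname\tcompound_code\tneutral_mass\n")
        for pid, name, codes in study.library.pathways:
            for code in codes:
                fh.write(f"{pid}\t{name}\t{code}\t{study.library.masses[code]!r}\n")
    paths["pathways"] = pathways
    drugs = outdir / "drugs.tsv"
    with open(drugs, "w") as fh:
        fh.write("name\tneutral_mass\n")
        for d in study.drugs:
            fh.write(f"{d.name}\t{d.neutral_mass!r}\n")
    paths["drugs"] = drugs
    truth = outdir / "truth.json"
    with open(truth, "w") as fh:
        json.dump(
            {mode: study.truths[mode].to_dict() for mode in study.truths},
            fh,
            indent=1,
            sort_keys=True,
        )
    paths["truth"] = truth
    return paths
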