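import numpy as np
import pytest

from oxiswitch.errors import ValidationError
from oxiswitch.filters import (
    DrugEntry,
    apply_filter_cascade,
    blank_filter,
    drug_filter,
    expand_drug_ions,
    packaged_drug_list,
    rsd_filter,
    rsd_percent,
)
from oxiswitch.peaktable import PipelineConfig
from tests.conftest import build_table

# independent element-mass oracle (CODATA/AME values, more digits than the
# implementation's ion-shift constants)
_ELEMENTS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
}
_ELECTRON = 0.00054857990907
_NA = 22.9897692809
_K = 38.96370668


def _formula_mass(counts: dict[str, int]) -> float:
    return sum(_ELEMENTS[el] * n for el, n in counts.items())


CAFFEINE = _formula_mass({"C": 8, "H": 10, "N": 4, "O": 2})  # C8H10N4O2


class TestRsdPercent:
    def test_constant(self):
        assert rsd_percent([100, 100, 100]) == 0.0

    def test_hand_arithmetic(self):
        # sd([80,100,120]) = 20 (n-1), mean = 100 -> RSD = 20.0
        assert rsd_percent([80, 100, 120]) == pytest.approx(20.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_two_pass_variance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(1, 1000, size=rng.integers(2, 30))
        mean = sum(v) / len(v)
        var = sum((x - mean) ** 2 for x in v) / (len(v) - 1)
        expected = 100 * var**0.5 / mean
        assert rsd_percent(v) == pytest.approx(expected, rel=1e-10)

    def test_nonpositive_mean_infinite(self):
        assert rsd_percent([0.0, 0.0]) == np.inf

    def test_too_short(self):
        with pytest.raises(ValidationError):
            rsd_percent([1.0])


class TestBlankFilter:
    def _table(self, study_vals, blank_val):
        # 7 study + 2 qc + 1 blank
        mat = np.array([list(study_vals) + [50.0, 50.0, blank_val]])
        return build_table(mat, ["study"] * 7 + ["qc", "qc", "blank"])

    def test_below_ratio_removed(self):
        table = self._table([49.0] * 7, 10.0)
        kept, removed = blank_filter(table, ratio=5.0)
        assert removed == ["F000"]
        assert len(kept.features) == 0

    def test_boundary_strict(self):
        table = self._table([50.0] * 7, 10.0)
        kept, removed = blank_filter(table, ratio=5.0)
        assert removed == []
        assert len(kept.features) == 1

    def test_zero_blank_always_kept(self):
        table = self._table([0.1] * 7, 0.0)
        kept, removed = blank_filter(table, ratio=5.0)
        assert removed == []

    def test_max_over_blanks(self):
        mat = np.array([[49.0] * 7 + [50.0, 5.0, 10.0]])
        table = build_table(mat, ["study"] * 7 + ["qc", "blank", "blank"])
        _kept, removed = blank_filter(table, ratio=5.0)
        assert removed == ["F000"]  # max(5, 10) = 10; 49 < 50

    def test_no_blanks_error(self):
        table = build_table(np.ones((1, 3)), ["study", "qc", "qc"])
        with pytest.raises(ValidationError, match="blank"):
            blank_filter(table)


class TestRsdFilter:
    def _table(self, qc_vals):
        mat = np.array([[100.0] * 3 + list(qc_vals)])
        return build_table(mat, ["study"] * 3 + ["qc"] * len(qc_vals))

    def test_inclusive_boundary_removed(self):
        kept, removed = rsd_filter(self._table([80, 100, 120]), threshold=20.0)
        assert removed == ["F000"]

    def test_low_rsd_kept(self):
        kept, removed = rsd_filter(self._table([99, 100, 101]), threshold=20.0)
        assert removed == []

    def test_infinite_threshold_keeps_all(self):
        kept, removed = rsd_filter(self._table([1, 1000, 5]), threshold=np.inf)
        assert removed == []

    def test_one_qc_error(self):
        table = build_table(np.ones((1, 2)), ["study", "qc"])
        with pytest.raises(ValidationError, match="2 non-conditioning"):
            rsd_filter(table)


class TestExpandDrugIons:
    def test_caffeine_protonated(self):
        drug = DrugEntry("caffeine", CAFFEINE)
        ions = dict(expand_drug_ions(drug, "positive"))
        expected = CAFFEINE + _ELEMENTS["H"] - _ELECTRON
        assert ions["caffeine [M+H]+"] == pytest.approx(expected, abs=2e-5)
        assert ions["caffeine [M+H]+"] == pytest.approx(195.087652, abs=2e-5)

    def test_caffeine_sodiated(self):
        drug = DrugEntry("caffeine", CAFFEINE)
        ions = dict(expand_drug_ions(drug, "positive"))
        expected = CAFFEINE + _NA - _ELECTRON
        assert ions["caffeine [M+Na]+"] == pytest.approx(expected, abs=2e-5)
        assert ions["caffeine [M+Na]+"] == pytest.approx(217.069594, abs=2e-5)

    def test_negative_mode_adducts(self):
        drug = DrugEntry("caffeine", CAFFEINE)
        ions = dict(expand_drug_ions(drug, "negative"))
        assert ions["caffeine [M-H]-"] == pytest.approx(
            CAFFEINE - _ELEMENTS["H"] + _ELECTRON, abs=2e-5
        )
        assert ions["caffeine [M+K-2H]-"] == pytest.approx(
            CAFFEINE + _K - 2 * _ELEMENTS["H"] + _ELECTRON, abs=2e-5
        )

    def test_isotopologue_spacing(self):
        drug = DrugEntry("x", 300.0)
        for mode in ("positive", "negative"):
            ions = dict(expand_drug_ions(drug, mode))
            for label, mz in ions.items():
                if label.endswith(" 13C"):
                    assert mz == pytest.approx(ions[label[:-4]] + 1.003355, abs=1e-9)
        assert sum(1 for lbl in dict(expand_drug_ions(drug, "positive")) if lbl.endswith(" 13C")) == 3

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValidationError):
            DrugEntry("bad", 0.0)


class TestDrugFilter:
    def _table(self, mz):
        mat = np.ones((len(mz), 4))
        return build_table(mat, ["study", "study", "qc", "blank"], mz=mz)

    def test_within_tolerance_removed(self):
        drugs = [DrugEntry("caffeine", 194.080376)]
        # [M+H]+ = 195.087652; delta = 0.002652 < 0.010
        _kept, removed = drug_filter(self._table([195.0850]), drugs, tol=0.010)
        assert removed == ["F000"]

    def test_outside_tolerance_kept(self):
        drugs = [DrugEntry("caffeine", 194.080376)]
        # delta = 0.011348 > 0.010
        _kept, removed = drug_filter(self._table([195.0990]), drugs, tol=0.010)
        assert removed == []

    def test_zero_tolerance_noop(self):
        drugs = [DrugEntry("caffeine", 194.080376)]
        _kept, removed = drug_filter(self._table([195.087652]), drugs, tol=0.0)
        assert removed == []

    def test_mode_specific(self):
        drugs = [DrugEntry("caffeine", 194.080376)]
        table = self._table([195.0876])
        table.features = [
            type(f)(f.feature_id, f.mz, f.rt, "negative") for f in table.features
        ]
        _kept, removed = drug_filter(table, drugs, tol=0.010)
        assert removed == []  # positive-mode ion, negative-mode feature

    def test_empty_drug_list_warns(self):
        with pytest.warns(UserWarning, match="empty drug list"):
            _kept, removed = drug_filter(self._table([195.0876]), [], tol=0.010)
        assert removed == []


def brute_force_survivors(table, drugs, config):
    """Independent single-pass application of all three rules."""
    survivors = []
    study = table.role_mask("study")
    qc = table.role_mask("qc")
    blank = table.role_mask("blank")
    ion_mz = {
        mode: [mz for d in drugs for _, mz in expand_drug_ions(d, mode)]
        for mode in ("positive", "negative")
    }
    for i, feat in enumerate(table.features):
        b = table.intensities[i, blank].max()
        blank_removed = b > 0 and np.median(table.intensities[i, study]) < config.blank_ratio * b
        qv = table.intensities[i, qc]
        mean = qv.mean()
        rsd = np.inf if mean <= 0 else 100 * qv.std(ddof=1) / mean
        rsd_removed = rsd >= config.rsd_threshold_percent
        drug_removed = any(
            abs(feat.mz - ion) < config.drug_mz_tolerance for ion in ion_mz[feat.mode]
        )
        if not (blank_removed or rsd_removed or drug_removed):
            survivors.append(feat.feature_id)
    return set(survivors)


def _random_toy_table(seed, n_features=20):
    rng = np.random.default_rng(seed)
    roles = ["study"] * 8 + ["qc"] * 4 + ["blank"] * 2
    vals = 10.0 ** rng.uniform(0, 5, size=(n_features, len(roles)))
    # plant some boundary-ish cases
    vals[:, -2:] *= rng.choice([0.0, 0.1, 1.0], size=(n_features, 2))
    mz = rng.uniform(100, 400, n_features)
    drugs = packaged_drug_list()
    # push some features near drug ions
    for i in range(0, n_features, 5):
        ion = expand_drug_ions(drugs[i % len(drugs)], "positive")[0][1]
        mz[i] = ion + rng.uniform(-0.02, 0.02)
    return build_table(vals, roles, mz=mz), drugs


class TestCascade:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        table, drugs = _random_toy_table(seed)
        config = PipelineConfig()
        filtered, report = apply_filter_cascade(table, config, drugs)
        assert set(filtered.feature_ids) == brute_force_survivors(table, drugs, config)

    def test_all_contaminant_zero_survivors(self):
        mat = np.array([[1.0] * 8 + [1.0] * 4 + [10.0, 10.0]] * 3)
        table = build_table(mat, ["study"] * 8 + ["qc"] * 4 + ["blank"] * 2)
        filtered, report = apply_filter_cascade(table, PipelineConfig(), [])
        assert report.n_surviving == 0
        assert all(reason == "blank" for reason in report.reasons.values())

    def test_idempotent(self):
        table, drugs = _random_toy_table(1)
        config = PipelineConfig()
        once, _ = apply_filter_cascade(table, config, drugs)
        twice, rep2 = apply_filter_cascade(once, config, drugs)
        assert twice.feature_ids == once.feature_ids
        assert rep2.n_removed_blank == rep2.n_removed_rsd == rep2.n_removed_drug == 0

    def test_survivors_order_independent(self):
        table, drugs = _random_toy_table(2)
        config = PipelineConfig()
        cascade, _ = apply_filter_cascade(table, config, drugs)
        # apply in a different order: drug -> rsd -> blank
        t1, _ = drug_filter(table, drugs, config.drug_mz_tolerance)
        t2, _ = rsd_filter(t1, config.rsd_threshold_percent)
        t3, _ = blank_filter(t2, config.blank_ratio)
        assert set(t3.feature_ids) == set(cascade.feature_ids)

    def test_report_reconciles(self):
        table, drugs = _random_toy_table(3)
        _filtered, report = apply_filter_cascade(table, PipelineConfig(), drugs)
        assert report.n_input == (
            report.n_surviving
            + report.n_removed_blank
            + report.n_removed_rsd
            + report.n_removed_drug
        )
        assert len(report.reasons) == report.n_input - report.n_surviving

    def test_reason_labels_follow_cascade_order(self):
        # feature violating blank AND rsd rules is attributed to blank
        mat = np.array([[1.0] * 8 + [1.0, 1000.0, 1.0, 1.0] + [10.0, 10.0]])
        table = build_table(mat, ["study"] * 8 + ["qc"] * 4 + ["blank"] * 2)
        _filtered, report = apply_filter_cascade(table, PipelineConfig(), [])
        assert report.reasons["F000"] == "blank"
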