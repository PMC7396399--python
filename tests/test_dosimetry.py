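import numpy as np
import pandas as pd
import pytest
from importlib import resources
from scipy.integrate import quad

from petquant import (
    F18_HALF_LIFE_H,
    OrganRetention,
    RetentionFit,
    absorbed_doses,
    bladder_with_urine,
    effective_dose,
    fit_retention,
    load_s_matrix,
    load_weights,
    percent_id,
    residence_time,
    residence_time_from_series,
)

LAMBDA_PHYS = np.log(2.0) / F18_HALF_LIFE_H


def pkg_data(name):
    return resources.files("petquant").joinpath(f"data/{name}")


class TestPercentId:
    def test_direct_formula(self):
        assert percent_id(1000.0, 100.0, 1e6) == pytest.approx(10.0)

    def test_linearity_in_volume(self):
        assert percent_id(1000.0, 200.0, 1e6) == pytest.approx(
            2 * percent_id(1000.0, 100.0, 1e6)
        )

    def test_zero_injected_rejected(self):
        with pytest.raises(ValueError):
            percent_id(1000.0, 100.0, 0.0)


class TestBladderWithUrine:
    def _bladder(self):
        return OrganRetention("bladder", [0.5, 1.0, 2.0, 4.0], [1.0, 2.0, 1.0, 2.0])

    def test_no_voids_is_identity(self):
        out = bladder_with_urine(self._bladder(), [], [])
        assert np.allclose(out.pid, self._bladder().pid)

    def test_single_void_steps_later_points(self):
        out = bladder_with_urine(self._bladder(), [1.0], [5.0])
        assert np.allclose(out.pid, [1.0, 7.0, 6.0, 7.0])

    def test_negative_urine_rejected(self):
        with pytest.raises(ValueError):
            bladder_with_urine(self._bladder(), [1.0], [-1.0])


class TestFitRetention:
    T = np.array([0.15, 0.45, 0.75, 1.725, 2.175, 3.725, 4.175, 5.8])

    def test_constant_data_is_plateau(self):
        fit = fit_retention(OrganRetention("o", self.T, np.full(8, 10.0)))
        assert fit.n_exp == 1
        assert fit.a[0] == pytest.approx(10.0, rel=1e-6)
        assert fit.lam[0] == pytest.approx(0.0, abs=1e-8)

    def test_biexponential_recovery(self):
        y = 20 * np.exp(-0.5 * self.T) + 5 * np.exp(-0.05 * self.T)
        fit = fit_retention(OrganRetention("o", self.T, y), n_exp=2)
        order = np.argsort(fit.lam)
        assert fit.a[order] == pytest.approx([5.0, 20.0], rel=0.02)
        assert fit.lam[order] == pytest.approx([0.05, 0.5], rel=0.02)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            fit_retention(OrganRetention("o", [1.0, 2.0], [5.0, 4.0]), n_exp=3)


class TestResidenceTime:
    def test_pure_physical_decay_whole_body(self):
        fit = RetentionFit("wb", np.array([100.0]), np.array([0.0]), 1, 0, 0, True)
        assert residence_time(fit) == pytest.approx(F18_HALF_LIFE_H / np.log(2),
                                                    abs=1e-4)

    def test_linear_scaling(self):
        fit = RetentionFit("o", np.array([10.0]), np.array([0.0]), 1, 0, 0, True)
        assert residence_time(fit) == pytest.approx(0.26394, abs=2e-4)

    def test_closed_form_matches_quadrature(self):
        a = np.array([20.0, 5.0])
        lam = np.array([0.5, 0.05])
        fit = RetentionFit("o", a, lam, 2, 0, 0, True)
        tau = residence_time(fit)
        oracle = quad(
            lambda t: np.sum(a * np.exp(-lam * t)) * np.exp(-LAMBDA_PHYS * t) / 100,
            0, np.inf,
        )[0]
        assert tau == pytest.approx(oracle, rel=1e-6)

    def test_series_fallback_close_to_closed_form(self):
        t = np.array([0.15, 0.45, 0.75, 1.725, 2.175, 3.725, 4.175, 5.8])
        a, lam = np.array([10.0]), np.array([0.3])
        ret = OrganRetention("o", t, a[0] * np.exp(-lam[0] * t))
        fit = RetentionFit("o", a, lam, 1, 0, 0, True)
        assert residence_time_from_series(ret) == pytest.approx(
            residence_time(fit), rel=0.05
        )


class TestAbsorbedDoses:
    def test_identity_s_matrix(self):
        s = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        doses = absorbed_doses({"a": 0.5, "b": 0.25}, s)
        # 1 mGy/(MBq.h) * tau h -> 1000 uSv/MBq per unit tau
        assert doses["a"] == pytest.approx(500.0)
        assert doses["b"] == pytest.approx(250.0)

    def test_hand_matrix_product(self):
        s = pd.DataFrame([[2.0, 1.0], [0.0, 1.0]], index=["a", "b"],
                         columns=["a", "b"])
        doses = absorbed_doses({"a": 0.5, "b": 0.5}, s)
        assert doses["a"] == pytest.approx(1.5 * 1000)

    def test_zero_residence_times(self):
        s = load_s_matrix(pkg_data("s_matrix_toy.csv"))
        doses = absorbed_doses({c: 0.0 for c in s.columns}, s)
        assert all(v == 0.0 for v in doses.values())

    def test_unmatched_source_routed_to_remainder(self):
        s = load_s_matrix(pkg_data("s_matrix_toy.csv"))
        d1 = absorbed_doses({"liver": 0.4, "rest_of_body": 0.1}, s)
        d2 = absorbed_doses({"liver": 0.4, "salivary_glands": 0.1}, s)
        assert d1 == pytest.approx(d2)

    def test_unknown_source_without_remainder_rejected(self):
        s = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(KeyError):
            absorbed_doses({"c": 0.5}, s)


class TestEffectiveDose:
    ORGANS = [
        "testes", "red_marrow", "uli_wall", "lli_wall", "lungs", "stomach",
        "bladder", "breasts", "liver", "thymus", "thyroid", "skin",
        "osteogenic_cells", "adrenals", "brain", "small_intestine", "kidneys",
        "muscle", "pancreas", "spleen", "uterus",
    ]

    def test_uniform_dose_field(self):
        res = effective_dose({o: 12.5 for o in self.ORGANS})
        assert res["ed"] == pytest.approx(12.5)
        assert not res["splitting_applied"]

    def test_monotone_in_every_organ(self):
        base = {o: 10.0 for o in self.ORGANS}
        ed0 = effective_dose(base)["ed"]
        for organ in self.ORGANS:
            bumped = dict(base)
            bumped[organ] = 11.0
            assert effective_dose(bumped)["ed"] >= ed0

    def test_missing_organ_is_named(self):
        doses = {o: 10.0 for o in self.ORGANS if o != "thyroid"}
        with pytest.raises(KeyError, match="thyroid"):
            effective_dose(doses)

    def test_custom_weights_dot_product_oracle(self):
        organs = [f"o{i}" for i in range(13)]
        scheme = {
            "scheme": "uniform-13",
            "weights": {o: 1.0 / 13.0 for o in organs[:12]},
            "remainder_weight": 1.0 / 13.0,
            "remainder": [organs[12]],
            "splitting_rule": False,
        }
        doses = {o: float(i + 1) for i, o in enumerate(organs)}
        res = effective_dose(doses, scheme)
        oracle = np.dot(np.full(13, 1.0 / 13.0), np.arange(1, 14.0))
        assert res["ed"] == pytest.approx(oracle, abs=1e-12)

    def test_published_organ_doses_reproduce_study_ed(self):
        df = pd.read_csv(pkg_data("study_organ_doses.csv"), comment="#")
        res = effective_dose(dict(zip(df.organ, df["mean"])))
        assert res["splitting_applied"]  # pancreas exceeds every named organ
        assert res["ed"] == pytest.approx(24.7, rel=0.05)

    def test_ed_not_above_max_organ_dose(self):
        df = pd.read_csv(pkg_data("study_organ_doses.csv"), comment="#")
        doses = dict(zip(df.organ, df["mean"]))
        res = effective_dose(doses)
        assert res["ed"] <= max(doses.values())


def test_weights_file_loads_and_sums_to_one():
    scheme = load_weights()
    total = sum(scheme["weights"].values()) + scheme["remainder_weight"]
    assert total == pytest.approx(1.0)
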