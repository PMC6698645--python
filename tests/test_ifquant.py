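"""Immunofluorescence z-scores, classification and cohort summaries."""

import numpy as np
import pytest

from mitofibre import ifquant as iq


def make_fibre(porin, nduf, coxi, fid="f", subject="control", ftype="I"):
    return iq.FibreOD(fid, "P", subject, porin, nduf, coxi, ftype)


@pytest.fixture()
def exact_line_controls():
    # ndufb8 = 2*porin + 1, coxi = 0.5*porin + 0.2, no scatter
    porins = [0.5, 0.8, 1.0, 1.2, 1.5]
    return [
        make_fibre(p, 2 * p + 1, 0.5 * p + 0.2, fid=f"c{i}")
        for i, p in enumerate(porins)
    ]


class TestBackgroundCorrect:
    @pytest.mark.parametrize(
        "raw, npc, want", [(0.50, 0.10, 0.40), (0.50, 0.00, 0.50), (0.05, 0.10, 0.0)]
    )
    def test_subtraction_clipped_at_zero(self, raw, npc, want):
        assert iq.background_correct(raw, npc) == pytest.approx(want)

    def test_negative_raw_rejected(self):
        with pytest.raises(iq.IfQuantError):
            iq.background_correct(-0.1, 0.0)


class TestControlModel:
    def test_exact_line_recovered(self, exact_line_controls):
        m = iq.fit_control_model(exact_line_controls)
        assert m.slope_ndufb8 == pytest.approx(2.0)
        assert m.intercept_ndufb8 == pytest.approx(1.0)
        assert m.resid_sd_ndufb8 == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_recovered_within_3_se(self):
        # closed-form least squares on a seeded draw is the oracle
        rng = np.random.default_rng(11)
        n, slope, intercept, sd = 200, 0.9, 0.1, 0.05
        porin = rng.uniform(0.5, 1.5, n)
        nduf = intercept + slope * porin + rng.normal(0, sd, n)
        controls = [
            make_fibre(p, max(y, 0), 0.5 * p + 0.2, fid=f"c{i}")
            for i, (p, y) in enumerate(zip(porin, nduf))
        ]
        m = iq.fit_control_model(controls)
        se = sd / np.sqrt(np.sum((porin - porin.mean()) ** 2))
        assert abs(m.slope_ndufb8 - slope) < 3 * se

    def test_too_few_controls_rejected(self, exact_line_controls):
        with pytest.raises(iq.IfQuantError, match=">= 3"):
            iq.fit_control_model(exact_line_controls[:2])

    def test_zero_porin_variance_rejected(self):
        same = [make_fibre(1.0, 2.0, 1.0, fid=f"c{i}") for i in range(5)]
        with pytest.raises(iq.IfQuantError, match="variance"):
            iq.fit_control_model(same)


class TestZScores:
    def test_fibre_on_regression_line_scores_zero(self):
        rng = np.random.default_rng(3)
        porin = rng.uniform(0.5, 1.5, 50)
        controls = [
            make_fibre(p, 2 * p + 1 + rng.normal(0, 0.05),
                       0.5 * p + 0.2 + rng.normal(0, 0.05), fid=f"c{i}")
            for i, p in enumerate(porin)
        ]
        m = iq.fit_control_model(controls)
        f = make_fibre(1.0, m.intercept_ndufb8 + m.slope_ndufb8 * 1.0,
                       m.intercept_coxi + m.slope_coxi * 1.0)
        z = iq.zscores(f, m)
        assert z.z_ndufb8 == pytest.approx(0.0, abs=1e-9)
        assert z.z_coxi == pytest.approx(0.0, abs=1e-9)

    def test_porin_at_control_mean_scores_zero(self, exact_line_controls):
        m = iq.fit_control_model(exact_line_controls)
        f = make_fibre(m.porin_mean, 2 * m.porin_mean + 1, 0.5 * m.porin_mean + 0.2)
        assert iq.zscores(f, m).z_porin == pytest.approx(0.0)

    def test_planted_displacement_recovered(self):
        rng = np.random.default_rng(5)
        porin = rng.uniform(0.5, 1.5, 100)
        sd = 0.05
        controls = [
            make_fibre(p, 2 * p + 1 + rng.normal(0, sd),
                       0.5 * p + 0.2 + rng.normal(0, sd), fid=f"c{i}")
            for i, p in enumerate(porin)
        ]
        m = iq.fit_control_model(controls)
        f = make_fibre(
            1.0,
            m.intercept_ndufb8 + m.slope_ndufb8 - 2 * m.resid_sd_ndufb8,
            m.intercept_coxi + m.slope_coxi * 1.0,
        )
        assert iq.zscores(f, m).z_ndufb8 == pytest.approx(-2.0, abs=1e-9)

    def test_control_set_zscores_centred(self):
        rng = np.random.default_rng(9)
        porin = rng.uniform(0.5, 1.5, 200)
        controls = [
            make_fibre(p, 2 * p + 1 + rng.normal(0, 0.05),
                       0.5 * p + 0.2 + rng.normal(0, 0.05), fid=f"c{i}")
            for i, p in enumerate(porin)
        ]
        m = iq.fit_control_model(controls)
        zs = np.array([iq.zscores(c, m).z_ndufb8 for c in controls])
        zp = np.array([iq.zscores(c, m).z_porin for c in controls])
        assert abs(zs.mean()) < 3 / np.sqrt(len(controls))
        assert abs(zp.mean()) < 3 / np.sqrt(len(controls))


class TestClassification:
    def test_isolated_ci_deficiency(self):
        c = iq.classify_fibre(iq.FibreZ(z_porin=0, z_ndufb8=-5, z_coxi=0))
        assert c.mrc_class == "CI-CIV+"
        assert c.level_ndufb8 == "intermediate_minus"

    def test_rrf_strictly_above_porin_cut(self):
        hi = iq.classify_fibre(iq.FibreZ(z_porin=2.6, z_ndufb8=0, z_coxi=0))
        at = iq.classify_fibre(iq.FibreZ(z_porin=2.5, z_ndufb8=0, z_coxi=0))
        assert hi.mrc_class == "CI+CIV+" and hi.is_rrf
        assert not at.is_rrf

    def test_combined_deficiency_levels(self):
        c = iq.classify_fibre(iq.FibreZ(z_porin=0, z_ndufb8=-7, z_coxi=-7))
        assert c.mrc_class == "CI-CIV-"
        assert c.level_ndufb8 == c.level_coxi == "deficient"

    @pytest.mark.parametrize(
        "z, want",
        [(-3.5, "very_low"), (-2.5, "low"), (0, "normal"), (2.5, "high"), (3.5, "very_high")],
    )
    def test_mass_bands(self, z, want):
        c = iq.classify_fibre(iq.FibreZ(z_porin=z, z_ndufb8=0, z_coxi=0))
        assert c.mass_class == want

    def test_every_z_gets_exactly_one_class(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            z = iq.FibreZ(*rng.normal(0, 4, 3))
            c = iq.classify_fibre(z)
            assert c.mrc_class in iq.MRC_CLASSES
            assert c.mass_class in iq.MASS_CLASSES
            assert c.level_ndufb8 in iq.LEVELS


class TestSummaries:
    def _classified(self, rows):
        import pandas as pd
        return pd.DataFrame(rows)

    def test_rrf_mrc_breakdown_percentages(self):
        # 535 of 636 RRF fibres doubly deficient, 67 CIV only, 2 CI only
        rows = (
            [{"mrc_class": "CI-CIV-", "is_rrf": True, "fibre_type": "I"}] * 535
            + [{"mrc_class": "CI+CIV-", "is_rrf": True, "fibre_type": "I"}] * 67
            + [{"mrc_class": "CI-CIV+", "is_rrf": True, "fibre_type": "I"}] * 2
            + [{"mrc_class": "CI+CIV+", "is_rrf": True, "fibre_type": "I"}] * 32
        )
        s = iq.summarize_cohort(self._classified(rows))["rrf_by_mrc"]
        got = dict(zip(s.category, s.percent))
        assert got["CI-CIV-"] == 84.1
        assert got["CI+CIV-"] == 10.5
        assert got["CI-CIV+"] == 0.3

    def test_rrf_fibre_type_breakdown(self):
        rows = (
            [{"mrc_class": "CI-CIV-", "is_rrf": True, "fibre_type": "I"}] * 30
            + [{"mrc_class": "CI-CIV-", "is_rrf": True, "fibre_type": "IIa"}] * 7
            + [{"mrc_class": "CI-CIV-", "is_rrf": True, "fibre_type": "IIx/IIb"}] * 1
        )
        s = iq.summarize_cohort(self._classified(rows))["rrf_by_fibre_type"]
        got = dict(zip(s.category, s.percent))
        assert got["I"] == 78.9
        assert got["IIa"] == 18.4
        assert got["IIx/IIb"] == 2.6

    def test_single_fibre_cohort(self):
        s = iq.summarize_cohort(
            self._classified([{"mrc_class": "CI+CIV+", "is_rrf": False, "fibre_type": "I"}])
        )["mrc"]
        assert dict(zip(s.category, s.percent))["CI+CIV+"] == 100.0

    def test_percentages_sum_to_100(self):
        rows = (
            [{"mrc_class": "CI-CIV-", "is_rrf": True, "fibre_type": "I"}] * 7
            + [{"mrc_class": "CI+CIV+", "is_rrf": False, "fibre_type": "IIa"}] * 13
            + [{"mrc_class": "CI-CIV+", "is_rrf": False, "fibre_type": "I"}] * 3
        )
        for table in iq.summarize_cohort(self._classified(rows)).values():
            if len(table):
                assert abs(table["percent"].sum() - 100.0) <= 0.2

    def test_empty_cohort_rejected(self):
        import pandas as pd
        with pytest.raises(iq.IfQuantError):
            iq.summarize_cohort(pd.DataFrame())


def test_mrc_plot_data_projects_all_fibres():
    import pandas as pd
    df = pd.DataFrame(
        {
            "fibre_id": ["a", "b", "c"],
            "z_ndufb8": [0.0, -4.0, -7.0],
            "z_coxi": [0.0, 0.0, -7.0],
            "mass_class": ["normal", "high", "very_high"],
            "extra": [1, 2, 3],
        }
    )
    out = iq.mrc_plot_data(df)
    assert list(out.columns) == ["fibre_id", "z_ndufb8", "z_coxi", "mass_class"]
    assert len(out) == 3
    assert len(iq.mrc_plot_data(pd.DataFrame(columns=out.columns))) == 0
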