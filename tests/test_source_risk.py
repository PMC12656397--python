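"""Allocation conservation, exposure doses, hazard quotients, risk tables."""

import numpy as np
import pandas as pd
import pytest

from pmfrisk import (
    CHILDREN,
    ADULTS,
    SURVEY_MEAN_CONC,
    allocate_concentrations,
    average_daily_dose,
    element_hazard_quotients,
    fit_pmf,
    hazard_quotient,
    surveylike_dataset,
    risk_shares,
    risk_table,
)
from pmfrisk.pmf import PMFModel
from pmfrisk.source_risk import SourceAllocation


def model_from(g, f):
    g = np.asarray(g, dtype=float)
    f = np.asarray(f, dtype=float)
    return PMFModel(
        g=g, f=f, q_true=0.0, q_robust=0.0, q_theoretical=0.0,
        scaled_residuals=np.zeros((g.shape[0], f.shape[1])),
        converged=True, n_starts=1, seed=0,
    )


@pytest.fixture()
def fitted(registry):
    table, truth = surveylike_dataset(n=80, seed=4)
    from pmfrisk import build_uncertainty

    unc = build_uncertainty(table, registry)
    model = fit_pmf(unc.working_conc, unc, 4, n_starts=3, seed=0, max_iter=1500)
    return table, model


class TestAllocation:
    def test_single_source_gets_everything(self, registry, small_table):
        f = small_table.conc.mean(axis=0).to_numpy()[None, :]
        model = model_from(np.ones((3, 1)), f)
        alloc = allocate_concentrations(small_table, model)
        np.testing.assert_allclose(alloc.share, 1.0)
        np.testing.assert_allclose(
            alloc.conc_by_source[:, :, 0], small_table.conc.to_numpy()
        )

    def test_two_factor_normalization_arithmetic(self, registry):
        from pmfrisk.core_data import from_arrays

        # one sample, Cr measured 10, modelled split 4:6
        conc = np.array([[0.1, 10.0, 5.0, 5.0, 5.0, 10.0, 2.0, 0.01]])
        table = from_arrays(conc, registry)
        f = np.tile(conc / 2, (2, 1))
        f[0, 1], f[1, 1] = 4.0, 6.0
        model = model_from(np.ones((1, 2)), f)
        alloc = allocate_concentrations(table, model)
        np.testing.assert_allclose(alloc.conc_by_source[0, 1], [4.0, 6.0])

    def test_conservation_exact_on_synthetic_fit(self, fitted):
        table, model = fitted
        alloc = allocate_concentrations(table, model)
        np.testing.assert_allclose(
            alloc.conc_by_source.sum(axis=2),
            table.conc.to_numpy(),
            rtol=0, atol=1e-12 * table.conc.to_numpy().max(),
        )
        np.testing.assert_allclose(alloc.share.sum(axis=2), 1.0, atol=1e-12)

    def test_zero_reconstruction_falls_back_to_mass_shares(self, registry, caplog):
        from pmfrisk.core_data import from_arrays

        conc = np.array([[0.1, 10.0, 5.0, 5.0, 5.0, 10.0, 2.0, 0.01]])
        table = from_arrays(conc, registry)
        f = np.tile(conc / 2, (2, 1))
        model = model_from(np.array([[0.0, 0.0]]), f)  # reconstruction all zero
        import logging

        with caplog.at_level(logging.WARNING):
            alloc = allocate_concentrations(table, model)
        np.testing.assert_allclose(alloc.share.sum(axis=2), 1.0)
        assert any("zero reconstruction" in r.message for r in caplog.records)


class TestDose:
    def test_child_ingestion_hand_value(self):
        add = average_daily_dose(7.6, CHILDREN, "ing")
        assert add == pytest.approx(9.717e-5, rel=1e-3)

    def test_zero_concentration_zero_dose(self):
        for pw in ("ing", "inh", "dermal"):
            assert average_daily_dose(0.0, ADULTS, pw) == 0.0

    def test_linearity_in_concentration(self):
        for pw in ("ing", "inh", "dermal"):
            assert average_daily_dose(2 * 3.7, CHILDREN, pw) == pytest.approx(
                2 * average_daily_dose(3.7, CHILDREN, pw), rel=1e-12
            )

    def test_unknown_pathway(self):
        with pytest.raises(ValueError):
            average_daily_dose(1.0, CHILDREN, "oral")


class TestHazardQuotient:
    def test_child_as_matches_printed_value(self, registry):
        hq = hazard_quotient(7.6, CHILDREN, registry["As"])
        assert hq["total"] == pytest.approx(0.33, rel=0.05)

    def test_child_pb_matches_printed_value(self, registry):
        hq = hazard_quotient(26.8, CHILDREN, registry["Pb"])
        assert hq["total"] == pytest.approx(9.9e-2, rel=0.05)

    def test_total_is_sum_of_pathways(self, registry):
        hq = hazard_quotient(50.0, ADULTS, registry["Cr"])
        assert hq["total"] == pytest.approx(hq["ing"] + hq["inh"] + hq["dermal"])

    def test_zero_concentration_zero_hq(self, registry):
        assert hazard_quotient(0.0, CHILDREN, registry["Cd"])["total"] == 0.0


class TestRiskTable:
    def test_single_source_total_equals_source_row(self, registry, small_table):
        f = small_table.conc.mean(axis=0).to_numpy()[None, :]
        model = model_from(np.ones((3, 1)), f)
        alloc = allocate_concentrations(small_table, model)
        rt = risk_table(alloc, CHILDREN, registry)
        np.testing.assert_allclose(
            rt.hq.loc["Total"].to_numpy(), rt.hq.iloc[0].to_numpy(), rtol=1e-12
        )

    def test_total_row_is_sum_of_sources(self, fitted, registry):
        table, model = fitted
        alloc = allocate_concentrations(table, model)
        rt = risk_table(alloc, CHILDREN, registry)
        sources = rt.hq.drop("Total")
        np.testing.assert_allclose(
            rt.hq.loc["Total"].to_numpy(), sources.sum(axis=0).to_numpy(), rtol=1e-12
        )

    def test_hi_is_row_sum_of_element_hqs(self, fitted, registry):
        table, model = fitted
        alloc = allocate_concentrations(table, model)
        rt = risk_table(alloc, ADULTS, registry)
        np.testing.assert_allclose(
            rt.hq["HI"].to_numpy(),
            rt.hq.drop(columns="HI").sum(axis=1).to_numpy(),
            rtol=1e-12,
        )

    def test_per_source_risk_is_additive_in_concentration(self, fitted, registry):
        # linearity: HQ of the summed concentrations == sum of per-source HQs
        table, model = fitted
        alloc = allocate_concentrations(table, model)
        rt = risk_table(alloc, CHILDREN, registry)
        direct = element_hazard_quotients(
            dict(table.conc.mean(axis=0)), CHILDREN, registry
        )
        np.testing.assert_allclose(
            rt.hq.loc["Total"].drop("HI").to_numpy(),
            direct[list(table.elements)].to_numpy(),
            rtol=1e-12,
        )


class TestRiskShares:
    def test_equal_sources_share_equally(self, registry):
        conc = np.full((1, 8, 4), 2.0)
        alloc = SourceAllocation(
            share=np.full((1, 8, 4), 0.25), conc_by_source=conc,
            elements=list(SURVEY_MEAN_CONC), source_names=list("abcd"),
            sample_index=pd.RangeIndex(1),
        )
        rt = risk_table(alloc, CHILDREN, registry)
        np.testing.assert_allclose(risk_shares(rt), 25.0)

    def test_shares_sum_to_100(self, fitted, registry):
        table, model = fitted
        alloc = allocate_concentrations(table, model)
        rt = risk_table(alloc, ADULTS, registry)
        shares = risk_shares(rt)
        assert shares.sum() == pytest.approx(100.0, abs=1e-9)
        assert (shares >= 0).all()


class TestPrintedChildHQs:
    """Deterministic reproduction of the survey's child hazard quotients."""

    @pytest.mark.parametrize(
        "element, printed",
        [("As", 3.3e-1), ("Pb", 9.9e-2), ("Ni", 2.3e-2),
         ("Cu", 8.4e-3), ("Zn", 2.9e-3), ("Hg", 1.3e-3)],
    )
    def test_survey_mean_hqs(self, registry, element, printed):
        hqs = element_hazard_quotients(SURVEY_MEAN_CONC, CHILDREN, registry)
        assert hqs[element] == pytest.approx(printed, rel=0.05)
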