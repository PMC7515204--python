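"""Experiment drivers: sweeps, Monte Carlo, sensitivities, collapse search."""

import numpy as np
import pytest
from scipy import stats

from mitoh2o2 import experiments as ex
from mitoh2o2 import model_core as mc
from mitoh2o2 import simulate as sim


# ----------------------------------------------------------------- sweeps

def test_single_point_sweep_matches_find_steady_state(params, basal_states):
    res = ex.basal_prx3_sweep(grid=[62.0], params=params)
    assert res.table.h2o2_nM.iloc[0] == pytest.approx(
        basal_states[62.0].h2o2_nM, rel=1e-9)


def test_default_sweep_spans_reported_range(params):
    res = ex.basal_prx3_sweep(params=params, n_points=4)
    tab = res.table
    assert tab.prx3_total_uM.iloc[0] == 48.0
    assert tab.prx3_total_uM.iloc[-1] == 110.0
    assert 4.3 < tab.h2o2_nM.max() < 4.5
    assert 1.7 < tab.h2o2_nM.min() < 1.95
    assert tab.prx3_dimer.iloc[0] == pytest.approx(0.048, abs=0.001)


# ------------------------------------------------------------ Monte Carlo

def test_mc_sampling_contract():
    with pytest.raises(ValueError):
        ex.sample_uniform(0, 48.0, 110.0, 1)
    draws = ex.sample_uniform(400, 48.0, 110.0, 11)
    assert draws.min() >= 48.0 and draws.max() <= 110.0
    assert draws.mean() == pytest.approx(79.0, abs=4.0)
    # substreams: a longer run extends, never reshuffles, a shorter one
    assert np.array_equal(ex.sample_uniform(50, 48.0, 110.0, 11), draws[:50])
    # draws are KS-compatible with the uniform distribution
    u = (draws - 48.0) / 62.0
    assert stats.kstest(u, "uniform").pvalue > 1e-3


def test_mc_zero_width_range(params):
    df = ex.monte_carlo_basal(n=4, prx3_range=(62.0, 62.0), seed=5,
                              params=params, method="refine")
    assert df.h2o2_uM.nunique() == 1


def test_mc_seed_reproducibility(params):
    a = ex.monte_carlo_basal(n=20, seed=3, params=params, method="refine")
    b = ex.monte_carlo_basal(n=20, seed=3, params=params, method="refine")
    assert np.array_equal(a.h2o2_uM.to_numpy(), b.h2o2_uM.to_numpy())
    c = ex.monte_carlo_basal(n=20, seed=4, params=params, method="refine")
    assert not np.array_equal(a.h2o2_uM.to_numpy(), c.h2o2_uM.to_numpy())


def test_mc_refine_agrees_with_integration(params):
    a = ex.monte_carlo_basal(n=15, seed=9, params=params, method="integrate")
    b = ex.monte_carlo_basal(n=15, seed=9, params=params, method="refine")
    assert np.allclose(a.h2o2_uM, b.h2o2_uM, rtol=1e-6)


# ----------------------------------------------------------- perturbation

def test_perturbation_dimer_fraction_rises_then_collapses(perturbation_endpoints):
    dimers = {kd: sim.fractions(s).prx3_dimer
              for kd, s in perturbation_endpoints.items()}
    pre = [dimers[kd] for kd in (0.0, 8.0, 23.0, 47.0)]
    assert all(a < b for a, b in zip(pre, pre[1:]))
    assert dimers[54.0] < 0.02 < dimers[47.0]  # crash past the threshold


def test_perturbation_zero_rate_matches_basal(params, basal_states,
                                              perturbation_endpoints):
    basal = sim.fractions(basal_states[62.0].state)
    after_hour = sim.fractions(perturbation_endpoints[0.0])
    assert after_hour.prx3_dimer == pytest.approx(basal.prx3_dimer, rel=0.02)


def test_collapse_threshold_bracketing_errors(params, basal_states):
    with pytest.raises(ex.BracketError, match="never met"):
        ex.collapse_threshold(0.0, 10.0, params=params)


def test_collapse_threshold_between_printed_rows(params):
    kd = ex.collapse_threshold(45.0, 56.0, iterations=8, params=params)
    assert 47.0 < kd < 54.0


# ------------------------------------------------------------ sensitivity

@pytest.fixture(scope="module")
def tornado(params):
    return ex.sensitivity_analysis(outputs=("H2O2", "Prx3-SS"), params=params)


def test_h2o2_most_sensitive_to_source_then_prx3_oxidation(tornado):
    h = tornado[tornado.output == "H2O2"]
    assert list(h.parameter.iloc[:2]) == ["k1", "k6"]
    assert h.s_normalized.iloc[0] == pytest.approx(1.0, abs=0.1)
    assert h.s_normalized.iloc[1] == pytest.approx(-1.0, abs=0.15)


def test_prx3_ss_sensitive_to_source_and_trx2_recycling(tornado):
    s = tornado[tornado.output == "Prx3-SS"]
    top = set(s.parameter.iloc[:3])
    assert {"k1", "k10"} <= top


def test_normalization_consistency(tornado):
    """s̄ equals the raw sensitivity rescaled by k_i/C_j."""
    p = mc.default_parameters()
    h = tornado[(tornado.output == "H2O2") & (tornado.parameter == "k1")].iloc[0]
    c_h2o2 = h.s_raw * p.k1 / h.s_normalized
    assert c_h2o2 == pytest.approx(3.37e-3, rel=0.05)  # basal H2O2, uM


def test_truncation_and_tornado_ordering(tornado):
    for _, grp in tornado.groupby("output"):
        mags = grp.s_normalized.abs().to_numpy()
        assert np.all(mags >= 1e-5)
        assert np.all(np.diff(mags) <= 1e-15)  # descending


def test_sensitivity_shrinks_with_smaller_delta(params):
    """Forward differences converge: a smaller step lands closer to the
    central-difference reference."""
    ref = ex.sensitivity_analysis(outputs=("H2O2",), delta=0.02,
                                  central=True, params=params)
    get = lambda df, k: df[(df.output == "H2O2")
                           & (df.parameter == k)].s_normalized.iloc[0]
    for k in ("k6", "k1"):
        err10 = abs(get(ex.sensitivity_analysis(("H2O2",), 0.10, params=params), k)
                    - get(ref, k))
        err05 = abs(get(ex.sensitivity_analysis(("H2O2",), 0.05, params=params), k)
                    - get(ref, k))
        assert err05 < err10


# ----------------------------------------------------------------- efflux

def test_paired_efflux_cancels_in_zeroth_order_mode(params, basal_states):
    """A zeroth-order efflux equal to the DAAO source nets out to baseline."""
    base = basal_states[62.0].state
    paired = params.with_values(kdaao=20.0, kefflux=20.0,
                                efflux_mode="zeroth_order")
    ta = sim.integrate(base, paired, 100.0, output_times=[100.0]).final
    tb = sim.integrate(base, params, 100.0, output_times=[100.0]).final
    assert np.allclose(ta, tb, rtol=1e-6, atol=1e-12)


def test_efflux_percentile_bands_are_coherent(params):
    df = ex.efflux_monte_carlo(kefflux_range=(50.0, 100.0), n=8, seed=2,
                               times=[0.0, 900.0, 3600.0], params=params)
    for (_, _), grp in df.groupby(["time_s", "variable"]):
        ordered = grp.sort_values("percentile").value.to_numpy()
        assert np.all(np.diff(ordered) >= -1e-12)
    samples = df.attrs["samples"]
    assert samples["kdaao"].min() >= 50.0 and samples["kdaao"].max() <= 100.0
    assert samples["kefflux"].min() >= 50.0
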