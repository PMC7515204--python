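"""Network definition: parameters, initial states, rate laws, stoichiometry."""

import numpy as np
import pytest

from mitoh2o2 import model_core as mc


@pytest.mark.parametrize("name, expected", [
    ("k1", 4.0), ("k2", 60.0), ("k4", 10.0), ("k5", 57.0), ("k6", 20.0),
    ("k7", 0.014), ("k8", 3e-3), ("k9", 20.0), ("k10", 0.22),
    ("k20", 375.0), ("k22", 9.6e-5), ("k24", 14.7), ("k29", 1.23e-5),
    ("k28", 0.0), ("k30", 0.0),
])
def test_default_parameters_literature_values(name, expected):
    p = mc.default_parameters()
    assert getattr(p, name) == expected


def test_parameter_overrides_and_validation():
    p = mc.default_parameters(kdaao=47.0, k1=11.0)
    assert p.k28 == 47.0 and p.k1 == 11.0
    with pytest.raises(KeyError):
        p.with_values(k99=1.0)
    with pytest.raises(ValueError):
        mc.RateParameters(k=tuple([-1.0] + [0.0] * 29))
    with pytest.raises(ValueError):
        mc.default_parameters().with_values(efflux_mode="cubic")


def test_network_has_28_species_and_30_reactions():
    assert len(mc.SPECIES) == 28
    net = mc.ReactionSet()
    assert len(net.reactions) == 30
    assert net.S.shape == (28, 30)


def test_stoichiometry_conserves_protein_pools():
    """Every closed pool's indicator vector lies in the left null space of S."""
    net = mc.ReactionSet()
    for name, members in mc.CONSERVED_POOLS.items():
        v = np.zeros(mc.N_SPECIES)
        for s in members:
            v[mc.species_index(s)] = 1.0
        assert np.allclose(v @ net.S, 0.0), f"pool {name} not conserved"


def test_initial_state_printed_abundances():
    y = mc.default_initial_state(62.0)
    get = lambda s: y[mc.species_index(s)]
    assert get("GSH") == 5000.0
    assert get("NADPH") == 30.0
    assert get("Trx2-SH") == 7.7
    assert get("Srx") == 8.8e-3
    assert get("Prx3-SH") == 62.0
    assert get("Gpx4ox") == 0.0 and get("Gpx4-SSG") == 0.0


def test_initial_state_range_enforcement():
    with pytest.raises(ValueError, match=r"48.*110"):
        mc.default_initial_state(47.9)
    y = mc.default_initial_state(47.9, allow_out_of_range=True)
    assert y[mc.species_index("Prx3-SH")] == 47.9


def test_table_policy_preserves_totals():
    a = mc.conserved_pools(mc.default_initial_state(62.0, policy="zeros"))
    b = mc.conserved_pools(mc.default_initial_state(62.0, policy="table"))
    for pool in ("Prx3", "Prx5", "Gpx1"):
        assert a[pool] == pytest.approx(b[pool], rel=1e-12)


def test_michaelis_menten_half_saturation():
    """At [NADP+] = k5 the NADPH regeneration flux is half-maximal."""
    p = mc.default_parameters()
    y = mc.default_initial_state(62.0)
    y[mc.species_index("NADP+")] = 57.0
    v = mc.reaction_rates(y, p)
    assert v[4] == pytest.approx(375.0 / 2.0)


def test_only_zeroth_order_fluxes_at_zero_state():
    p = mc.default_parameters(kdaao=5.0)
    v = mc.reaction_rates(np.zeros(mc.N_SPECIES), p)
    nonzero = {mc.ReactionSet().reactions[j].rid for j in np.nonzero(v)[0]}
    assert nonzero == {"R1", "R21", "R28", "R29"}


def test_srx_repair_flux_balances_srx_import():
    """At the derived basal abundances, Srx-mediated repair of Prx3-SOOH
    runs at the Srx import rate."""
    p = mc.default_parameters()
    y = mc.default_initial_state(62.0)
    y[mc.species_index("Prx3-SOOH")] = 0.466
    v = mc.reaction_rates(y, p)
    repair = v[7]  # R8
    assert repair == pytest.approx(3e-3 * 0.466 * 8.8e-3)
    assert repair == pytest.approx(p.k29, rel=0.01)


def test_reaction_rates_reject_negative_state():
    y = mc.default_initial_state(62.0)
    y[0] = -1e-3
    with pytest.raises(ValueError, match="negative"):
        mc.reaction_rates(y, mc.default_parameters())


def test_rhs_pool_derivatives_vanish():
    rng = np.random.default_rng(42)
    p = mc.default_parameters(kdaao=10.0, kefflux=5.0)
    for _ in range(5):
        y = rng.uniform(0.0, 50.0, mc.N_SPECIES)
        dy = mc.rhs(y, p)
        for name, members in mc.CONSERVED_POOLS.items():
            total = sum(dy[mc.species_index(s)] for s in members)
            assert abs(total) < 1e-9, f"pool {name} derivative {total}"


def test_jacobian_matches_finite_differences():
    rng = np.random.default_rng(7)
    p = mc.default_parameters(kdaao=3.0, kefflux=2.0)
    y = rng.uniform(0.1, 20.0, mc.N_SPECIES)
    J = mc.jacobian(y, p)
    eps = 1e-6
    f0 = mc.rhs(y, p)
    for i in range(mc.N_SPECIES):
        yy = y.copy()
        yy[i] += eps
        col = (mc.rhs(yy, p) - f0) / eps
        assert np.allclose(J[:, i], col, rtol=1e-4, atol=1e-5)


def test_efflux_rate_law_modes():
    p0 = mc.default_parameters(kefflux=10.0, efflux_mode="zeroth_order")
    p1 = mc.default_parameters(kefflux=10.0, efflux_mode="first_order")
    y = mc.default_initial_state(62.0)
    y[0] = 0.5  # well above the cutoff
    assert mc.reaction_rates(y, p0)[29] == pytest.approx(10.0)
    assert mc.reaction_rates(y, p1)[29] == pytest.approx(5.0)
    y[0] = 5e-4  # below the zeroth-order cutoff: sink throttles linearly
    assert mc.reaction_rates(y, p0)[29] == pytest.approx(10.0 * 0.5)


def test_h2o2_flux_balance_oracle(basal_states):
    """Independent algebraic check: at the basal fixed point the OxPhos
    source balances the lumped bimolecular clearance, and Prx3 dominates."""
    p = mc.default_parameters()
    st = basal_states[62.0].state
    g = lambda s: st[mc.species_index(s)]
    clearance = (p.k6 * g("Prx3-SH") + p.k23 * g("Prx5-SH")
                 + p.k2 * g("Gpx1red") + p.k26 * g("Gpx4red")
                 + p.k12 * g("Pr-SH") + p.k16 * g("Pr-(SH)2")
                 + p.k7 * g("Prx3-SOH"))
    h2o2_pred = p.k1 / clearance
    assert g("H2O2") == pytest.approx(h2o2_pred, rel=1e-6)
    assert abs(mc.rhs(st, p)[0]) < 1e-9
    assert p.k6 * g("Prx3-SH") * g("H2O2") == pytest.approx(p.k1, rel=0.2)


def test_network_document_roundtrip():
    doc = mc.network_document()
    assert len(doc["species"]) == 28
    assert len(doc["reactions"]) == 30
    assert doc["parameters"]["k1"] == 4.0
    stoich_h2o2 = sum(r["stoichiometry"].get("H2O2", 0.0)
                      for r in doc["reactions"])
    assert stoich_h2o2 == 2 - 8  # two sources, eight sinks (incl. efflux)
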