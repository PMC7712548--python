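"""Free-energy landscape construction and feature analysis."""

import math

import numpy as np
import pytest

from crownpore import constants as K
from crownpore.core import Conditions, IonSpecies, PoreChargeSet, PoreGeometry, ChargeGroup
from crownpore.landscape import (FreeEnergyProfile, classify_feature_relevance,
                                 constriction_entropy, crossing_entropy,
                                 dehydration_fraction, discrete_gradients,
                                 model_free_energy, tilt_profile, well_entropy,
                                 LandscapeFeature)


def _bare_ion(**kw):
    return IonSpecies(name="test", valence=1, mobility=7.62e-8,
                      hydration_layers=kw.get("layers", []))


class TestDehydrationFraction:
    def test_zero_far_from_membrane(self, geometry):
        assert dehydration_fraction(1.5, 0.33, geometry) == 0.0
        assert dehydration_fraction(-1.5, 0.55, geometry) == 0.0

    def test_small_at_one_nanometre(self, geometry):
        # fully hydrated ion a nanometre out: no shell exclusion at all
        assert dehydration_fraction(1.0, 0.33, geometry) == 0.0

    def test_shell_through_pore_not_excluded(self, geometry):
        # a shell narrower than the opening passes freely
        assert dehydration_fraction(0.0, 0.10, geometry, pore_radius=0.137) == 0.0

    def test_monte_carlo_volume_oracle(self, geometry):
        # rejection-sampling oracle on the thin shell at the pore centre
        R, half, rp = 0.33, 0.17, 0.137
        rng = np.random.default_rng(12345)
        n = 400_000
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = v * R  # shell centred at z=0
        inside_slab = np.abs(pts[:, 2]) <= half
        outside_pore = pts[:, 0] ** 2 + pts[:, 1] ** 2 > rp**2
        mc = np.mean(inside_slab & outside_pore)
        geom = PoreGeometry(carbon_vdw_radius=half)
        assert dehydration_fraction(0.0, R, geom, pore_radius=rp) == pytest.approx(
            mc, rel=0.01)

    @pytest.mark.parametrize("z", np.linspace(-1.0, 1.0, 9).tolist())
    def test_fraction_bounded(self, geometry, z):
        f = dehydration_fraction(z, 0.33, geometry)
        assert 0.0 <= f <= 1.0


class TestModelFreeEnergy:
    def test_single_charge_coulomb_closed_form(self):
        # one -1e group at 0.5 nm in eps=80: e^2/(4 pi eps0 eps r) ~ -1.4 kBT
        charges = PoreChargeSet(groups=[ChargeGroup(charge=-1.0, count=1,
                                                    radial_position=0.5)])
        cond = Conditions(relative_permittivity=80.0)
        F = model_free_energy([0.0], _bare_ion(), charges, PoreGeometry(),
                              eps_pore=80.0, conditions=cond)
        ev_nm = 1.602176634e-19 / (4 * math.pi * 8.8541878128e-12) * 1e9  # 1.44 eV nm
        expected = -(ev_nm / (80 * 0.5)) * 1.602176634e-19 / (1.380649e-23 * 298)
        assert F[0] == pytest.approx(expected, rel=1e-6)
        assert F[0] == pytest.approx(-1.4, rel=0.02)

    def test_zero_charges_zero_hydration_is_zero(self, geometry):
        charges = PoreChargeSet(groups=[])
        F = model_free_energy(np.linspace(-1, 1, 11), _bare_ion(), charges, geometry)
        assert np.allclose(F, 0.0, atol=1e-12)

    def test_small_far_from_pore(self, potassium, crown_charges, geometry):
        F = model_free_energy([1.0, 1.5, -1.0], potassium, crown_charges, geometry)
        assert np.all(np.abs(F) < 1.0)

    def test_reduces_to_coulomb_when_hydration_energies_zero(self, geometry):
        from crownpore.landscape import _effective_permittivity
        layers = [type(h)(h.radius, 0.0, h.eta)
                  for h in IonSpecies.potassium().hydration_layers]
        ion = _bare_ion(layers=layers)
        charges = PoreChargeSet.crown_ether(-0.54)
        cond = Conditions()
        z = np.linspace(-1, 1, 21)
        full = model_free_energy(z, ion, charges, geometry, conditions=cond)
        # manual screened Coulomb sum with the same permittivity knots
        coul = K.coulomb_kbt_nm(cond.temperature)
        bare = np.zeros_like(z)
        for g in charges.groups:
            r = np.sqrt(z**2 + g.radial_position**2)
            eps = _effective_permittivity(r, 4.0, cond.relative_permittivity,
                                          layers[0].radius, layers[-1].radius)
            bare += coul * g.charge * g.count / (eps * r)
        assert np.allclose(full, bare, atol=1e-12)

    def test_zero_distance_rejected(self, geometry):
        charges = PoreChargeSet(groups=[ChargeGroup(charge=-1.0, count=1,
                                                    radial_position=0.0)])
        with pytest.raises(ValueError, match="coincides"):
            model_free_energy([0.0], _bare_ion(), charges, geometry)


class TestTiltProfile:
    def _flat(self):
        z = np.linspace(-1.5, 1.5, 121)
        return FreeEnergyProfile(z=z, F=np.zeros_like(z))

    def test_interior_slope_quarter_volt(self):
        # 0.25 V over +/-0.5 nm: ~10 kBT/nm of ideal field
        tilted = tilt_profile(self._flat(), 0.25, drop_halfwidth=0.5)
        sel = np.abs(tilted.z) < 0.45
        slope = np.polyfit(tilted.z[sel], tilted.F[sel], 1)[0]
        assert slope == pytest.approx(-0.25 / K.thermal_voltage(298), rel=1e-9)
        assert abs(slope) == pytest.approx(9.7, abs=0.2)

    def test_zero_voltage_identity(self):
        p = self._flat()
        assert np.array_equal(tilt_profile(p, 0.0).F, p.F)

    def test_total_drop_is_qv(self):
        tilted = tilt_profile(self._flat(), 0.37)
        drop = tilted.F[0] - tilted.F[-1]
        assert drop == pytest.approx(0.37 / K.thermal_voltage(298), rel=1e-12)

    def test_additivity(self):
        p = self._flat()
        once = tilt_profile(tilt_profile(p, 0.1), 0.15)
        combined = tilt_profile(p, 0.25)
        assert np.allclose(once.F, combined.F, atol=1e-12)


def _exhaustive_min_next_max(z, F):
    """Independent oracle: strict local extrema by direct comparison, each
    minimum paired with the first maximum at larger z."""
    minima = [i for i in range(1, len(F) - 1) if F[i] < F[i - 1] and F[i] < F[i + 1]]
    maxima = [i for i in range(1, len(F) - 1) if F[i] > F[i - 1] and F[i] > F[i + 1]]
    out = []
    for i in minima:
        nxt = [j for j in maxima if j > i]
        if nxt:
            out.append((z[i], F[i], z[nxt[0]], F[nxt[0]]))
    return out


class TestDiscreteGradients:
    def test_piecewise_linear_single_feature(self):
        z = np.array([-0.6, -0.4, -0.2, 0.0])
        F = np.array([5.0, 0.0, 5.0, 0.0])
        prof = FreeEnergyProfile(z=z, F=F)
        feats = discrete_gradients(prof, smooth_window=1, min_prominence=0.5)
        assert len(feats) == 1
        f = feats[0]
        assert f.gradient == pytest.approx(25.0)
        assert f.mean_position == pytest.approx(-0.3)

    def test_monotone_profile_empty(self):
        z = np.linspace(-1, 1, 50)
        prof = FreeEnergyProfile(z=z, F=3 * z)
        assert discrete_gradients(prof) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_scan_oracle(self, seed):
        # well-separated, large-amplitude features so that every strict
        # local extremum is prominent and the pairing is unambiguous
        rng = np.random.default_rng(seed)
        z = np.linspace(-1.2, 1.2, 97)
        F = np.zeros_like(z)
        signs = rng.permutation([1, -1, 1, -1])
        for pos, sgn in zip((-0.9, -0.3, 0.3, 0.9), signs):
            F += sgn * rng.uniform(2, 4) * np.exp(-(z - pos) ** 2 / (2 * 0.12**2))
        prof = FreeEnergyProfile(z=z, F=F)
        feats = discrete_gradients(prof, smooth_window=1, min_prominence=0.5)
        oracle = _exhaustive_min_next_max(z, F)
        got = {(round(f.min_position, 6), round(f.max_position, 6)) for f in feats}
        ref = {(round(a, 6), round(c, 6)) for (a, b, c, d) in oracle}
        assert got == ref
        for f in feats:
            assert f.gradient >= 0.0

    def test_invariant_under_constant_offset(self):
        z = np.linspace(-1, 1, 81)
        F = 3 * np.exp(-z**2 / 0.02) - 2 * np.exp(-(z - 0.5) ** 2 / 0.02)
        a = discrete_gradients(FreeEnergyProfile(z=z, F=F))
        b = discrete_gradients(FreeEnergyProfile(z=z, F=F + 7.0))
        assert len(a) == len(b)
        for fa, fb in zip(a, b):
            assert fa.gradient == pytest.approx(fb.gradient, abs=1e-12)
            assert fa.mean_position == fb.mean_position


class TestFeatureRelevance:
    def _feature(self, grad, mean=0.0, width=0.2):
        half = width / 2
        return LandscapeFeature(min_position=mean - half, min_value=0.0,
                                max_position=mean + half, max_value=grad * width)

    def test_steep_feature_survives_quarter_volt(self):
        # 40 kBT/nm against a ~10 kBT/nm ideal field: still present
        eq = [self._feature(40.0)]
        biased = [self._feature(30.0)]
        labels = classify_feature_relevance(eq, biased, v_ext=0.25)
        assert labels[0].label not in ("washed_out",)

    def test_absent_feature_washed_out(self):
        labels = classify_feature_relevance([self._feature(10.0)], [], v_ext=0.25)
        assert labels[0].label == "washed_out"

    def test_unchanged_feature_is_irrelevant(self):
        # gradient untouched although the field should have reduced it
        eq = [self._feature(8.0)]
        biased = [self._feature(7.8)]
        labels = classify_feature_relevance(eq, biased, v_ext=0.25)
        assert labels[0].label == "irrelevant"


class TestEntropies:
    def test_constriction_penalty_defaults(self):
        # ABF cylinder vs bulk spacing: ~1.7 kBT
        assert constriction_entropy(0.28, 1.2) == pytest.approx(1.7, rel=0.1)

    def test_constriction_zero_when_areas_match(self):
        r = math.sqrt(1.44 / math.pi)  # pi r^2 = l^2
        assert constriction_entropy(r, 1.2) == pytest.approx(0.0, abs=1e-12)

    def test_constriction_half_radius(self):
        assert constriction_entropy(0.14, 1.2) == pytest.approx(
            constriction_entropy(0.28, 1.2) + 2 * math.log(2), rel=1e-12)
        assert constriction_entropy(0.14, 1.2) == pytest.approx(3.2, rel=0.05)

    def test_crossing_penalty_defaults(self):
        # squeeze from the ABF cylinder to the 0.02 nm crossing region: ~5 kBT
        assert crossing_entropy(0.02, 0.28) == pytest.approx(5.0, rel=0.1)

    def test_crossing_zero_for_equal_radii(self):
        assert crossing_entropy(0.28, 0.28) == 0.0

    def test_well_localization_band(self):
        val = well_entropy(0.3, 1.2)
        assert 1.0 <= val <= 2.0

    @pytest.mark.parametrize("fn, a, b", [
        (crossing_entropy, 0.02, 0.28),
        (well_entropy, 0.3, 1.2),
    ])
    def test_antisymmetric_under_scale_swap(self, fn, a, b):
        assert fn(a, b) == pytest.approx(-fn(b, a), rel=1e-12)
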