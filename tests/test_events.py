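import numpy as np
import pytest
from scipy import stats

import bnctcam as bc
from bnctcam.errors import CsvParseError
from bnctcam.events import _exact_energy_split
from bnctcam.geometry import M_E_C2


def kn_density(theta, energy):
    """Independent Klein-Nishina angular density (unnormalized)."""
    a = energy / M_E_C2
    c = np.cos(theta)
    eps = 1.0 / (1.0 + a * (1.0 - c))
    return eps**2 * (eps + 1.0 / eps - 1.0 + c**2) * np.sin(theta)


class TestKleinNishinaSampler:
    def test_angles_within_open_interval(self, rng):
        th = bc.sample_klein_nishina_angle(478.0, rng, size=5000)
        assert np.all(th > 0) and np.all(th < np.pi)

    def test_forward_peaking(self, rng):
        th = bc.sample_klein_nishina_angle(478.0, rng, size=20000)
        assert np.mean(th < np.pi / 2) > np.mean(th > np.pi / 2)

    def test_histogram_matches_analytic_density(self, rng):
        n, bins = 100_000, 50
        th = bc.sample_klein_nishina_angle(478.0, rng, size=n)
        edges = np.linspace(0.0, np.pi, bins + 1)
        obs, _ = np.histogram(th, edges)
        fine = np.linspace(0.0, np.pi, 20001)
        pdf = kn_density(fine, 478.0)
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2
                                               * np.diff(fine))])
        cdf /= cdf[-1]
        exp = n * np.diff(np.interp(edges, fine, cdf))
        p = stats.chisquare(obs, exp * obs.sum() / exp.sum()).pvalue
        assert p > 0.001

    def test_rejects_nonpositive_energy(self, rng):
        with pytest.raises(ValueError):
            bc.sample_klein_nishina_angle(0.0, rng)


class TestVertexSampler:
    def test_no_background_stays_inside_source(self, rng):
        src, ph = bc.SourceModel(), bc.PhantomGeometry()
        v = bc.sample_source_vertex(src, ph, rng, size=3000)
        assert src.contains(v).all()

    def test_five_points_hit_the_five_vertices(self, rng):
        src, ph = bc.SourceModel(shape="five_points"), bc.PhantomGeometry.air()
        v = bc.sample_source_vertex(src, ph, rng, size=500)
        assert src.contains(v).all()

    @pytest.mark.parametrize("tn", [2.0, 5.0])
    def test_tumor_fraction_matches_emission_model(self, rng, tn):
        src, ph = bc.SourceModel(tn_ratio=tn), bc.PhantomGeometry()
        p = bc.tumor_probability(src, ph)
        n = 100_000
        v = bc.sample_source_vertex(src, ph, rng, size=n)
        frac = src.contains(v).mean()
        assert abs(frac - p) < 3.0 * np.sqrt(p * (1 - p) / n)
        # background vertices stay inside the phantom, outside the source
        bg = v[~src.contains(v)]
        assert ph.contains(bg).all()

    def test_source_outside_phantom_raises(self, rng):
        with pytest.raises(bc.errors.GeometryError):
            bc.sample_source_vertex(bc.SourceModel(center=(0.0, 60.0, 0.0)),
                                    bc.PhantomGeometry(), rng)


class TestPropagation:
    def test_away_from_detector_misses(self, rng):
        cfg = bc.SimulationConfig(phantom=bc.PhantomGeometry.air())
        ev = bc.propagate_and_detect((0.0, 0.0, 0.0), (0.0, 0.0, -1.0), cfg, rng)
        assert ev is None

    def test_hits_land_inside_the_layers(self, air_events, air_config):
        det = air_config.detector
        for layer, r in ((1, air_events.r1), (2, air_events.r2)):
            lo, hi = det.layer_bounds(layer)
            assert np.all(r >= lo - 1e-9) and np.all(r <= hi + 1e-9)

    def test_energy_sum_exact(self, air_events):
        assert np.all(air_events.e1 + air_events.e2 == 478.0)
        assert np.all(air_events.e1 > 0) and np.all(air_events.e2 > 0)

    def test_compton_angle_consistent_with_geometry(self, air_events):
        """The energy-derived angle reproduces the geometric scattering angle."""
        w = air_events.r1 - air_events.truth_vertex
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        s = air_events.r2 - air_events.r1
        s /= np.linalg.norm(s, axis=1, keepdims=True)
        cos_geo = np.sum(w * s, axis=1)
        cos_e = 1.0 - M_E_C2 * (1.0 / air_events.e2 - 1.0 / 478.0)
        assert np.max(np.abs(cos_geo - cos_e)) < 1e-9

    def test_exact_energy_split_helper(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(-1.0, 1.0, 10000)
        e1, e2 = _exact_energy_split(478.0, c)
        assert np.all(e1 + e2 == 478.0)


class TestGenerate:
    def test_seed_determinism(self):
        cfg = bc.SimulationConfig(phantom=bc.PhantomGeometry.air(),
                                  n_emitted=60_000, seed=5)
        assert bc.generate_events(cfg) == bc.generate_events(cfg)

    def test_true_event_target_count(self, air_config):
        ev = bc.generate_true_events(air_config, 123)
        assert len(ev) == 123

    def test_tissue_attenuation_only_removes_events(self):
        kw = dict(n_emitted=150_000, seed=9)
        n_air = len(bc.generate_events(
            bc.SimulationConfig(phantom=bc.PhantomGeometry.air(), **kw)))
        n_tis = len(bc.generate_events(
            bc.SimulationConfig(phantom=bc.PhantomGeometry.soft_tissue(), **kw)))
        assert 0 < n_tis <= n_air

    def test_empty_run_warns(self):
        cfg = bc.SimulationConfig(phantom=bc.PhantomGeometry.air(),
                                  n_emitted=5, seed=1)
        with pytest.warns(UserWarning):
            ev = bc.generate_events(cfg)
        assert len(ev) == 0


class TestEventCsv:
    def test_roundtrip_identity(self, air_events, tmp_path):
        p = tmp_path / "events.csv"
        bc.write_event_csv(p, air_events)
        back = bc.read_event_csv(p)
        assert back == bc.EventList(air_events.r1, air_events.r2,
                                    air_events.e1, air_events.e2,
                                    air_events.gamma_energy,
                                    truth_vertex=air_events.truth_vertex)

    def test_empty_list_roundtrip(self, tmp_path):
        p = tmp_path / "empty.csv"
        bc.write_event_csv(p, bc.EventList.empty(478.0))
        assert p.read_text().count("\n") == 1
        assert len(bc.read_event_csv(p, gamma_energy=478.0)) == 0

    def test_wrong_field_count_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("x1,y1,z1,e1,x2,y2,z2,e2\n"
                     "0,0,60,200,0,0,66,278\n"
                     "1,2,3,4,5,6,7\n")
        with pytest.raises(CsvParseError) as err:
            bc.read_event_csv(p)
        assert err.value.line_number == 3

    def test_non_numeric_field_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("x1,y1,z1,e1,x2,y2,z2,e2\n0,0,60,oops,0,0,66,278\n")
        with pytest.raises(CsvParseError) as err:
            bc.read_event_csv(p)
        assert err.value.line_number == 2
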