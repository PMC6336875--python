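"""Generator behaviour: determinism, configured ground truth, positional
bias, pool conservation, and the flow-event mixture."""

import numpy as np
import pytest
from scipy import stats

import dipscan as d
from dipscan.synthetic_data import position_weights


class TestReference:
    def test_length_and_frame(self):
        ref = d.make_reference(435, seed=1)
        assert len(ref.cds) == 1305
        assert ref.n_residues == 435
        assert ref.cds.startswith("ATG")
        internal = [ref.cds[i:i + 3] for i in range(0, len(ref.cds) - 3, 3)]
        assert not any(c in {"TAA", "TAG", "TGA"} for c in internal)

    def test_deterministic(self):
        assert d.make_reference(10, seed=7).cds == d.make_reference(10, seed=7).cds

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            d.make_reference(9, seed=1)


class TestTruth:
    def test_all_permissive_fractions(self, small_reference, domains):
        truth = d.simulate_truth(small_reference, domains,
                                 class_fractions={"permissive": 1.0}, seed=0)
        assert all(s.site_class == "permissive" for s in truth)
        # identical trafficking across domains
        assert all(len(set(s.p_se.values())) == 1 for s in truth)

    def test_differential_gap(self, small_reference, domains):
        truth = d.simulate_truth(small_reference, domains, seed=4)
        diff = [s for s in truth if s.site_class == "differential"]
        assert diff
        for s in diff:
            gap = abs(s.p_se["PDZ"] - s.p_se["Cib81"])
            assert gap == pytest.approx(0.6)

    def test_every_slot_classified_and_deterministic(self, reference_435,
                                                     domains):
        t1 = d.simulate_truth(reference_435, domains, seed=9)
        t2 = d.simulate_truth(reference_435, domains, seed=9)
        assert [s.site_class for s in t1] == [s.site_class for s in t2]
        slots = d.scoreable_positions(reference_435)
        assert [s.aa_pos for s in t1] == list(slots)

    def test_bad_fractions_rejected(self, small_reference, domains):
        with pytest.raises(ValueError):
            d.simulate_truth(small_reference, domains,
                             class_fractions={"permissive": 0.9})


class TestLibrary:
    def test_unbiased_positions_uniform(self, reference_435, domains):
        cfg = d.SimulationConfig(seed=5, n_variants=100_000,
                                 depth_per_pool=1, bias_amplitude=0.0,
                                 domains=domains)
        lib = d.simulate_library(reference_435, cfg)
        by_pos = lib.groupby("nt_pos")["count"].sum()
        n_pos = len(reference_435.cds) - 4
        observed = np.zeros(n_pos)
        observed[by_pos.index] = by_pos.to_numpy()
        chi2 = stats.chisquare(observed).pvalue
        assert chi2 > 0.01

    def test_five_prime_depression(self, reference_435, domains):
        cfg = d.SimulationConfig(seed=5, n_variants=100_000,
                                 depth_per_pool=1, bias_amplitude=0.8,
                                 bias_length_scale=150.0, domains=domains)
        lib = d.simulate_library(reference_435, cfg)
        first = lib[lib.nt_pos < 150]["count"].sum() / 150
        last = lib[lib.nt_pos >= lib.nt_pos.max() - 149]["count"].sum() / 150
        assert first < last

    def test_weight_form(self):
        w = position_weights(10, 0.8, 150.0)
        assert w[0] == pytest.approx(0.2)
        assert np.all(np.diff(w) > 0)

    def test_empty_library(self, small_reference, domains):
        cfg = d.SimulationConfig(seed=1, n_variants=0, depth_per_pool=1,
                                 domains=domains)
        assert len(d.simulate_library(small_reference, cfg)) == 0

    def test_productive_fraction_one_sixth(self, reference_435, domains):
        cfg = d.SimulationConfig(seed=6, n_variants=60_000, depth_per_pool=1,
                                 bias_amplitude=0.0, domains=domains)
        lib = d.simulate_library(reference_435, cfg)
        prod = lib[(lib.orientation == "forward") & (lib.nt_pos % 3 == 0)]
        frac = prod["count"].sum() / lib["count"].sum()
        assert abs(frac - 1 / 6) < 0.01


class TestSortCounts:
    def test_read_conservation(self, reference_435, domains, full_study):
        lib = d.simulate_library(reference_435, full_study["config"])
        se, nse = d.simulate_sort_counts(lib, full_study["truth"], "PDZ",
                                         full_study["config"], 1)
        assert se.t == se.counts.sum() == full_study["config"].depth_per_pool
        assert nse.t == nse.counts.sum()

    def test_all_surface_expressed_empties_nse(self, small_reference,
                                               domains, small_config):
        truth = d.simulate_truth(small_reference, domains,
                                 class_fractions={"permissive": 1.0},
                                 p_se_table={"permissive": 1.0}, seed=0)
        lib = d.simulate_library(small_reference, small_config)
        se, nse = d.simulate_sort_counts(lib, truth, "PDZ", small_config, 1)
        assert nse.t == 0
        assert se.t == small_config.depth_per_pool

    def test_even_split_gives_equal_fractions(self, reference_435, domains):
        truth = d.simulate_truth(reference_435, domains,
                                 class_fractions={"permissive": 1.0},
                                 p_se_table={"permissive": 0.5}, seed=0)
        cfg = d.SimulationConfig(seed=7, n_variants=500_000,
                                 depth_per_pool=1_000_000, domains=domains)
        lib = d.simulate_library(reference_435, cfg)
        se, nse = d.simulate_sort_counts(lib, truth, "PDZ", cfg, 1)
        delta = np.abs(se.counts / se.t - nse.counts / nse.t)
        assert delta.max() < 0.005

    def test_deterministic(self, small_reference, domains, small_config):
        truth = d.simulate_truth(small_reference, domains, seed=0)
        lib = d.simulate_library(small_reference, small_config)
        a = d.simulate_sort_counts(lib, truth, "PDZ", small_config, 2)
        b = d.simulate_sort_counts(lib, truth, "PDZ", small_config, 2)
        assert np.array_equal(a[0].counts, b[0].counts)
        assert np.array_equal(a[1].counts, b[1].counts)

    def test_unknown_domain_rejected(self, small_reference, domains,
                                     small_config):
        truth = d.simulate_truth(small_reference, domains, seed=0)
        lib = d.simulate_library(small_reference, small_config)
        with pytest.raises(KeyError):
            d.simulate_sort_counts(lib, truth, "nope", small_config, 1)

    def test_se_read_share_monotone_in_p_se(self, small_reference, domains):
        """Varying one class's trafficking probability against a fixed
        background raises those sites' share of the SE pool monotonically."""
        cfg = d.SimulationConfig(seed=8, n_variants=100_000,
                                 depth_per_pool=100_000, domains=domains)
        lib = d.simulate_library(small_reference, cfg)
        fractions = {"permissive": 0.5, "intermediate": 0.5}
        shares = []
        for p in np.arange(0.1, 0.95, 0.1):
            truth = d.simulate_truth(small_reference, domains,
                                     class_fractions=fractions,
                                     p_se_table={"permissive": float(p),
                                                 "intermediate": 0.5},
                                     seed=0)
            varied = [s.aa_pos for s in truth
                      if s.site_class == "permissive"]
            se, _ = d.simulate_sort_counts(lib, truth, "PDZ", cfg, 1)
            shares.append(se.counts[varied].sum() / se.t)
        assert np.all(np.diff(shares) > 0)


class TestReads:
    def test_deterministic_and_error_free_structure(self, small_reference,
                                                    cassette, small_config):
        lib = d.simulate_library(small_reference, small_config).head(10)
        p1 = d.simulate_reads(lib, small_reference, cassette, small_config)
        p2 = d.simulate_reads(lib, small_reference, cassette, small_config)
        assert p1 == p2
        cass = cassette.full_nt()
        for (id1, s1), (_, s2) in p1:
            # each error-free read carries reference and cassette sequence
            assert len(s1) == small_config.read_length
            assert (cass[:15] in s1) or (d.revcomp(cass)[:15] in s1) \
                or (cass[-15:] in s1) or (d.revcomp(cass)[-15:] in s1)

    def test_short_reads_rejected(self, small_reference, cassette, domains):
        cfg = d.SimulationConfig(seed=1, n_variants=10, depth_per_pool=1,
                                 read_length=20, domains=domains)
        lib = d.simulate_library(small_reference, cfg)
        with pytest.raises(ValueError):
            d.simulate_reads(lib, small_reference, cassette, cfg)


class TestFeatures:
    def test_shape_and_categories(self, full_study):
        feats = d.simulate_features(full_study["truth"], seed=0)
        assert feats.values.shape == (len(full_study["truth"]), 5 + 21 + 20)
        assert len(feats.names("static")) == 5
        assert len(feats.names("conservation")) == 21
        assert len(feats.names("dynamic")) == 20

    def test_zero_effect_is_uninformative(self, full_study):
        labels = d.truth_labels(full_study["truth"])
        hits = 0
        trials = 100
        for s in range(trials):
            feats = d.simulate_features(full_study["truth"], effect_size=0.0,
                                        seed=s)
            col = feats.values.iloc[:, 0].to_numpy()
            r = stats.pointbiserialr(labels, col).statistic
            hits += abs(r) < 0.1
        assert hits >= 95

    def test_unit_effect_is_informative(self, full_study):
        labels = d.truth_labels(full_study["truth"])
        feats = d.simulate_features(full_study["truth"], effect_size=1.0,
                                    seed=0)
        rhos = [abs(stats.spearmanr(labels,
                                    feats.values[c].to_numpy()).statistic)
                for c in feats.names("dynamic")]
        assert max(rhos) > 0.3


class TestFlow:
    def test_zero_activity_single_component(self):
        ev = d.simulate_flow(0.0, n_events=20_000, seed=1)
        logd = np.log(ev["dye"])
        # a single log-normal: observed SD matches the component SD
        assert logd.std() == pytest.approx(0.45, abs=0.03)

    def test_no_bleach_time_invariant(self):
        ev = d.simulate_flow(0.5, bleach_rate=0.0, n_events=20_000, seed=2)
        half = len(ev) // 2
        p = stats.ks_2samp(ev["dye"][:half], ev["dye"][half:]).pvalue
        assert p > 0.01

    def test_zero_shift_indistinguishable(self):
        dark = d.simulate_flow(0.5, light_shift=0.0, n_events=20_000, seed=3)
        light = d.simulate_flow(0.5, light_shift=0.0, n_events=20_000, seed=4)
        assert stats.ks_2samp(dark["dye"], light["dye"]).pvalue > 0.01

    def test_invalid_activity(self):
        with pytest.raises(ValueError):
            d.simulate_flow(1.5, n_events=10, seed=0)

    def test_t_acq_strictly_increasing(self):
        ev = d.simulate_flow(0.5, n_events=100, seed=5)
        assert np.all(np.diff(ev["t_acq"]) > 0)
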