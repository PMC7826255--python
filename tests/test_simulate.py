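import numpy as np
import pytest

from editrace.classify import microhomology
from editrace.core import DataError, DonorSpec, EditOp, apply_allele, minus4_base
from editrace.kinetics import TimeCourse, fit_t50
from editrace.reads import merge_pairs
from editrace.simulate import (
    CELL_PROFILES,
    KineticClassParams,
    SimulationConfig,
    build_outcome_model,
    demo_timecourse_locus,
    random_amplicon,
    reads_from_frequencies,
    simulate_locus,
)

LN2 = np.log(2.0)


class TestKineticClassParams:
    def test_t50_identity(self):
        for t50 in (3.0, 6.2, 18.4, 40.0):
            kp = KineticClassParams.from_t50(t50)
            assert kp.t50 == pytest.approx(t50)

    def test_marginal_cdf_reaches_half_at_t50(self, rng):
        kp = KineticClassParams.from_t50(10.0)
        draws = kp.delta + rng.exponential(kp.mu, size=200_000)
        assert np.mean(draws <= kp.t50) == pytest.approx(0.5, abs=0.01)


class TestRandomAmplicon:
    def test_minus4_constraint(self):
        amp = random_amplicon(5, minus4="T")
        assert minus4_base(amp) == "T"

    def test_determinism(self):
        a = random_amplicon(17, minus4="A")
        b = random_amplicon(17, minus4="A")
        assert a.reference_sequence == b.reference_sequence

    def test_planted_microhomology_detected(self):
        amp = random_amplicon(3, planted_microhomologies=((3, 7),))
        cut = amp.cut_site
        s = cut - 7 // 2
        mh = microhomology(amp.reference_sequence, s, s + 7)
        assert mh.raw_length >= 3

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            random_amplicon(0, length=100)

    def test_bad_planting_rejected(self):
        with pytest.raises(DataError):
            random_amplicon(0, planted_microhomologies=((5, 3),))


class TestBuildOutcomeModel:
    def test_duplication_dominates_for_minus4_t(self):
        amp = random_amplicon(2, minus4="T")
        cfg = SimulationConfig(seed=2, cell_profile="T", depth=10)
        model = build_outcome_model(amp, cfg, np.random.default_rng(2))
        dup = max(model.outcomes, key=lambda o: o.weight)
        assert dup.label == "+T duplication"
        assert dup.weight == pytest.approx(0.27)

    def test_weights_form_a_distribution(self):
        amp = random_amplicon(8)
        cfg = SimulationConfig(seed=8, depth=10)
        model = build_outcome_model(amp, cfg, np.random.default_rng(8))
        assert sum(o.weight for o in model.outcomes) == pytest.approx(1.0)

    def test_ipsc_boosts_plus1(self):
        amp = random_amplicon(2, minus4="T")
        base = SimulationConfig(seed=2, cell_profile="T", depth=10)
        ipsc = SimulationConfig(seed=2, cell_profile="iPSC", depth=10)
        w_base = max(build_outcome_model(amp, base, np.random.default_rng(2)).outcomes,
                     key=lambda o: o.weight).weight
        w_ipsc = max(build_outcome_model(amp, ipsc, np.random.default_rng(2)).outcomes,
                     key=lambda o: o.weight).weight
        assert w_ipsc / w_base == pytest.approx(1.4)

    def test_hdr_present_iff_donor(self):
        amp = random_amplicon(2, minus4="T")
        donor = DonorSpec("TCGATAAG", amp.cut_site)
        without = build_outcome_model(
            amp, SimulationConfig(seed=2, depth=10), np.random.default_rng(2)
        )
        with_donor = build_outcome_model(
            amp, SimulationConfig(seed=2, depth=10, donor=donor), np.random.default_rng(2)
        )
        assert without.hdr is None and with_donor.hdr is not None

    def test_nhej_scale_semantics(self):
        amp = random_amplicon(2, minus4="T")
        plain = build_outcome_model(
            amp, SimulationConfig(seed=2, depth=10), np.random.default_rng(2)
        )
        inhibited = build_outcome_model(
            amp, SimulationConfig(seed=2, depth=10, nhej_scale=0.1),
            np.random.default_rng(2),
        )
        def ratio(model):
            nhej = sum(o.weight for o in model.outcomes if o.kinetic_class == "NHEJ")
            mmej = sum(o.weight for o in model.outcomes if o.kinetic_class != "NHEJ")
            return nhej / mmej
        assert ratio(inhibited) == pytest.approx(0.1 * ratio(plain), rel=1e-9)

    def test_kinetic_class_by_deletion_size(self):
        amp = random_amplicon(4, planted_microhomologies=((3, 4), (4, 12)))
        cfg = SimulationConfig(seed=4, depth=10)
        model = build_outcome_model(amp, cfg, np.random.default_rng(4))
        classes = {}
        for o in model.outcomes:
            if len(o.ops) == 1 and o.ops[0].kind == "deletion" and o.kinetic_class.startswith("MMEJ"):
                classes[o.ops[0].length] = o.kinetic_class
        assert classes.get(4) == "MMEJ_short"
        assert classes.get(12) == "MMEJ_long"


class TestSimulateLocus:
    def _model(self, seed=2, **kwargs):
        amp = random_amplicon(seed, minus4="T", planted_microhomologies=((4, 12),))
        cfg = SimulationConfig(seed=seed, depth=kwargs.pop("depth", 20_000), **kwargs)
        model = build_outcome_model(amp, cfg, np.random.default_rng(seed))
        return amp, cfg, model

    def test_depth_zero_empty(self):
        amp, cfg, model = self._model(depth=0)
        truth = simulate_locus(model, cfg)
        assert all(not table for table in truth.tables.values())

    def test_conservation_at_every_timepoint(self):
        amp, cfg, model = self._model()
        truth = simulate_locus(model, cfg)
        for t in cfg.timepoints:
            total = sum(truth.tables[t].values()) + truth.unedited_fraction(t)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_plus1_share_declines_from_4h_to_48h(self):
        amp, cfg, model = self._model(editable_fraction=0.5)
        truth = simulate_locus(model, cfg)
        dup_ops = next(o.ops for o in model.outcomes if "duplication" in o.label)
        shares = {}
        for t in (4.0, 48.0):
            edited = sum(truth.tables[t].values())
            shares[t] = truth.tables[t].get(dup_ops, 0.0) / edited
        assert shares[4.0] > shares[48.0]

    def test_hdr_hits_long_mmej_hardest(self):
        amp = random_amplicon(2, minus4="T", planted_microhomologies=((4, 12),))
        donor = DonorSpec("TCGATAAG", amp.cut_site)
        common = dict(depth=60_000, timepoints=(48.0,), editable_fraction=0.5)
        cfg_nd = SimulationConfig(seed=2, **common)
        cfg_d = SimulationConfig(seed=2, donor=donor, **common)
        model_nd = build_outcome_model(amp, cfg_nd, np.random.default_rng(2))
        model_d = build_outcome_model(amp, cfg_d, np.random.default_rng(2))
        truth_nd = simulate_locus(model_nd, cfg_nd, np.random.default_rng(9))
        truth_d = simulate_locus(model_d, cfg_d, np.random.default_rng(9))

        def share(truth, model, kclass):
            edited = sum(truth.tables[48.0].values())
            ops = [o.ops for o in model.outcomes if o.kinetic_class == kclass]
            return sum(truth.tables[48.0].get(op, 0.0) for op in ops) / edited

        drop_long = 1 - share(truth_d, model_d, "MMEJ_long") / share(
            truth_nd, model_nd, "MMEJ_long"
        )
        nhej_d = share(truth_d, model_d, "NHEJ")
        nhej_nd = share(truth_nd, model_nd, "NHEJ")
        drop_nhej = 1 - nhej_d / nhej_nd
        assert drop_long > 0.4
        assert drop_long > 3 * abs(drop_nhej)

    def test_determinism(self):
        amp, cfg, model = self._model(depth=500)
        a = simulate_locus(model, cfg, np.random.default_rng(5))
        b = simulate_locus(model, cfg, np.random.default_rng(5))
        assert a.tables == b.tables


class TestReadsFromFrequencies:
    def test_error_free_reads_reconstruct_alleles(self):
        amp = random_amplicon(2, minus4="T")
        cut = amp.cut_site
        cfg = SimulationConfig(seed=2, depth=200, error_rate=0.0, timepoints=(48.0,))
        freqs = {
            (EditOp(cut, cut, "insertion", "T"),): 0.5,
            (EditOp(cut - 3, cut + 2, "deletion"),): 0.25,
        }
        pairs, truth = reads_from_frequencies(amp, freqs, cfg, barcode="ACGTGTCA")
        merged, n_unmerged = merge_pairs(pairs)
        assert n_unmerged == 0
        fragments = {
            "ACGTGTCA" + apply_allele(amp, ops) for ops in freqs
        } | {"ACGTGTCA" + amp.reference_sequence}
        assert {m.seq for m in merged} <= fragments

    def test_binomial_counts(self):
        amp = random_amplicon(2, minus4="T")
        cut = amp.cut_site
        cfg = SimulationConfig(seed=7, depth=10_000, error_rate=0.0, timepoints=(48.0,))
        freqs = {(EditOp(cut, cut, "insertion", "T"),): 0.30}
        _, truth = reads_from_frequencies(amp, freqs, cfg)
        count = truth[f"I1@{cut}:T"]
        sigma = np.sqrt(10_000 * 0.3 * 0.7)
        assert abs(count - 3000) < 4 * sigma

    def test_same_seed_identical_reads(self):
        amp = random_amplicon(2, minus4="T")
        cut = amp.cut_site
        cfg = SimulationConfig(seed=3, depth=300, timepoints=(48.0,))
        freqs = {(EditOp(cut, cut, "insertion", "T"),): 0.3}
        a, _ = reads_from_frequencies(amp, freqs, cfg, rng=np.random.default_rng(3))
        b, _ = reads_from_frequencies(amp, freqs, cfg, rng=np.random.default_rng(3))
        assert a == b

    def test_fragment_too_short_errors(self):
        amp = random_amplicon(2, minus4="T", length=140)
        cut = amp.cut_site
        cfg = SimulationConfig(seed=2, depth=10, timepoints=(48.0,))
        freqs = {(EditOp(cut - 15, cut + 15, "deletion"),): 1.0}
        with pytest.raises(DataError, match="shorter"):
            reads_from_frequencies(amp, freqs, cfg)


class TestDemoLocus:
    def test_round_trips_and_plus1_on_top(self):
        amplicon, cfg, model, truth = demo_timecourse_locus(seed=1, depth=5000)
        table = truth.tables[48.0]
        top_ops = max(table, key=table.get)
        dup = next(o for o in model.outcomes if "duplication" in o.label)
        assert top_ops == dup.ops

    def test_plus1_faster_than_mh_deletion(self):
        # generating-level check across seeds: interpolated T50 of the +1
        # trajectory sits below the -4 microhomology deletion's
        wins = 0
        for seed in range(10):
            amplicon, cfg, model, truth = demo_timecourse_locus(seed=seed, depth=8000)
            dup = next(o for o in model.outcomes if "duplication" in o.label)
            mh_del = next(
                o for o in model.outcomes
                if o.ops[0].kind == "deletion" and o.ops[0].length == 4
                and o.kinetics.t50 == pytest.approx(16.0)
            )
            def t50_of(ops):
                pts = tuple((t, truth.tables[t].get(ops, 0.0)) for t in cfg.timepoints)
                fit = fit_t50(
                    TimeCourse(str(ops), pts, total_indels_final=1.0),
                    require_eligible=False,
                )
                return fit.t50
            if t50_of(dup.ops) < t50_of(mh_del.ops):
                wins += 1
        assert wins >= 9

    def test_cell_profiles_cover_paper_cell_types(self):
        assert set(CELL_PROFILES) == {"iPSC", "T", "K562", "U937"}


class TestCompetitionOrderingAcrossSeeds:
    def test_ordering_holds_in_most_seeds(self):
        # |drop(MMEJ_long)| > |drop(MMEJ_short)| > |drop(NHEJ +1)| on
        # generating-level tables, across independent seeds
        wins = 0
        for seed in range(5):
            amp = random_amplicon(seed, minus4="T",
                                  planted_microhomologies=((3, 4), (4, 12)))
            donor = DonorSpec("TCGATAAG", amp.cut_site)
            common = dict(depth=30_000, timepoints=(48.0,), editable_fraction=0.5)
            cfg_nd = SimulationConfig(seed=seed, **common)
            cfg_d = SimulationConfig(seed=seed, donor=donor, **common)
            m_nd = build_outcome_model(amp, cfg_nd, np.random.default_rng(seed))
            m_d = build_outcome_model(amp, cfg_d, np.random.default_rng(seed))
            t_nd = simulate_locus(m_nd, cfg_nd, np.random.default_rng(seed + 50))
            t_d = simulate_locus(m_d, cfg_d, np.random.default_rng(seed + 60))

            def drop(kclass):
                def share(truth, model):
                    edited = sum(truth.tables[48.0].values())
                    ops = [o.ops for o in model.outcomes if o.kinetic_class == kclass]
                    return sum(truth.tables[48.0].get(op, 0.0) for op in ops) / edited
                s_nd, s_d = share(t_nd, m_nd), share(t_d, m_d)
                return abs(1 - s_d / s_nd) if s_nd > 0 else 0.0

            dup_nd = next(o.ops for o in m_nd.outcomes if "duplication" in o.label)
            edited_nd = sum(t_nd.tables[48.0].values())
            edited_d = sum(t_d.tables[48.0].values())
            plus1_drop = abs(
                1 - (t_d.tables[48.0].get(dup_nd, 0.0) / edited_d)
                / (t_nd.tables[48.0].get(dup_nd, 1e-9) / edited_nd)
            )
            if drop("MMEJ_long") > drop("MMEJ_short") > plus1_drop:
                wins += 1
        assert wins >= 4
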