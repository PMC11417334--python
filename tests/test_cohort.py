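"""Chimera, labeling, clone dynamics, ablation and observation sampling."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from tfrtrace.cassette import (
    Fluorophore,
    ObservableState,
    RecombinationModel,
    state_distribution,
)
from tfrtrace.config import Donor, MarrowMix
from tfrtrace.cohort import (
    Clone,
    EmptyCompartmentWarning,
    UnderSeededWarning,
    apply_ablation,
    apply_labeling,
    evolve_clones,
    found_follicles,
    sample_observation,
    simulate_chimera,
)

YFP1 = ObservableState.single(Fluorophore.YFP)


class TestChimera:
    def test_three_donor_third_labelable(self, three_donor_mix):
        n = 30_000
        pop = simulate_chimera(three_donor_mix, n, seed=5)
        frac = pop["labelable"].mean()
        se = math.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(frac - 1 / 3) < 3 * se
        assert pop["foxp3"].all()
        assert (pop["state"] == "unlabeled").all()

    def test_single_donor_all_or_nothing(self):
        mix = MarrowMix((Donor("a", 1.0, confetti_labelable=True),))
        assert simulate_chimera(mix, 100, seed=0)["labelable"].all()
        mix = MarrowMix((Donor("a", 1.0),))
        assert not simulate_chimera(mix, 100, seed=0)["labelable"].any()

    def test_two_to_one_parts_ratio(self):
        mix = MarrowMix((Donor("yfp", 2.0), Donor("gfp", 1.0)))
        pop = simulate_chimera(mix, 30_000, seed=9)
        counts = pop["origin_genotype"].value_counts()
        ratio = counts["yfp"] / counts["gfp"]
        # delta-method SE of the ratio around 2.0
        se = 2.0 * math.sqrt(1 / counts["yfp"] + 1 / counts["gfp"])
        assert abs(ratio - 2.0) < 3 * se

    def test_empty_donor_list_rejected(self):
        with pytest.raises(ValueError):
            MarrowMix(donors=())

    def test_host_fraction_present(self):
        mix = MarrowMix((Donor("a", 1.0),), host_fraction=0.25)
        pop = simulate_chimera(mix, 40_000, seed=3)
        frac = (pop["origin_genotype"] == "host").mean()
        assert abs(frac - 0.25) < 3 * math.sqrt(0.25 * 0.75 / 40_000)


class TestLabeling:
    def test_r_one_labels_every_labelable_cell(self, confetti_only_mix):
        pop = simulate_chimera(confetti_only_mix, 1000, seed=1)
        labeled = apply_labeling(pop, RecombinationModel(1.0), seed=2)
        assert (labeled["state"] != "unlabeled").all()

    def test_labeled_fraction_matches_closed_form(self, confetti_only_mix):
        n = 100_000
        pop = simulate_chimera(confetti_only_mix, n, seed=1)
        labeled = apply_labeling(pop, RecombinationModel(0.6), seed=2)
        frac = (labeled["state"] != "unlabeled").mean()
        expected = 1 - 0.4**2  # 0.84
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_non_labelable_stay_unlabeled(self):
        mix = MarrowMix((Donor("plain", 1.0),))
        pop = simulate_chimera(mix, 500, seed=1)
        labeled = apply_labeling(pop, RecombinationModel(1.0), seed=2)
        assert (labeled["state"] == "unlabeled").all()

    def test_state_frequencies_match_distribution(self, confetti_only_mix):
        n = 100_000
        model = RecombinationModel(0.5, (0.1, 0.2, 0.3, 0.4))
        pop = simulate_chimera(confetti_only_mix, n, seed=1)
        labeled = apply_labeling(pop, model, seed=2)
        dist = state_distribution(model)
        freqs = labeled["state"].value_counts(normalize=True)
        for s, prob in zip(dist.states, dist.probs):
            se = math.sqrt(max(prob * (1 - prob), 1e-12) / n)
            assert abs(freqs.get(str(s), 0.0) - prob) < 3 * se + 1e-9


class TestFounding:
    def test_monoclonal_follicles(self, confetti_only_mix, config_factory):
        cfg = config_factory(confetti_only_mix, founders_per_follicle=1,
                             tzone_founders=0)
        pop = apply_labeling(
            simulate_chimera(confetti_only_mix, 2000, seed=1),
            cfg.recombination, seed=2,
        )
        clones = found_follicles(pop, cfg, seed=3)
        per_follicle = {}
        for c in clones:
            per_follicle.setdefault(c.follicle_id, []).append(c)
        assert len(per_follicle) == cfg.n_follicles
        assert all(len(v) == 1 for v in per_follicle.values())
        assert all(c.size == 1 for c in clones)

    def test_zero_follicles(self, confetti_only_mix, config_factory):
        cfg = config_factory(confetti_only_mix, n_follicles=0, tzone_founders=0)
        pop = simulate_chimera(confetti_only_mix, 100, seed=1)
        assert found_follicles(pop, cfg, seed=2) == []

    def test_under_seeded_pool_warns(self, confetti_only_mix, config_factory):
        cfg = config_factory(confetti_only_mix, n_follicles=50,
                             founders_per_follicle=10, tzone_founders=0)
        pop = simulate_chimera(confetti_only_mix, 100, seed=1)
        with pytest.warns(UnderSeededWarning):
            clones = found_follicles(pop, cfg, seed=2)
        assert len(clones) == 100  # founded with the available pool

    def test_expected_labeled_founders(self, three_donor_mix, config_factory):
        # 20 founders from a pool 1/3 labelable at r giving 0.84 labeled:
        # expected labeled founders 20 * (1/3) * 0.84 = 5.6
        cfg = config_factory(three_donor_mix, n_follicles=1,
                             founders_per_follicle=20, tzone_founders=0,
                             recombination=RecombinationModel(0.6))
        rng = np.random.default_rng(77)
        total = 0
        reps = 500
        for _ in range(reps):
            pop = apply_labeling(
                simulate_chimera(three_donor_mix, 2000, rng),
                cfg.recombination, rng,
            )
            clones = found_follicles(pop, cfg, rng)
            total += sum(1 for c in clones if c.labeled)
        p = (1 / 3) * 0.84
        se = math.sqrt(20 * p * (1 - p) * reps)
        assert abs(total - reps * 20 * p) < 3 * se


def _monoclonal_follicles(n, state=YFP1, size=1, genotype="c"):
    return [
        Clone(f"c{i}", "m1", "follicle", f"F{i:04d}", state, genotype, size)
        for i in range(n)
    ]


class TestEvolution:
    def test_no_godark_infinite_alpha_keeps_labeled_fraction(
        self, confetti_only_mix, config_factory
    ):
        # clones start large enough that neutral-drift noise during growth is
        # small relative to the exchangeability expectation being tested
        cfg = config_factory(confetti_only_mix, go_dark_rate=0.0,
                             homeostatic_target=200)
        clones = _monoclonal_follicles(100, size=50) + [
            Clone(f"u{i}", "m1", "follicle", f"F{i:04d}", ObservableState(()),
                  "c", 50)
            for i in range(100)
        ]
        snaps = evolve_clones(clones, cfg, 20, seed=4)
        def labeled_frac(cs):
            tot = sum(c.size for c in cs)
            return sum(c.size for c in cs if c.labeled) / tot
        f0, f20 = labeled_frac(snaps[0]), labeled_frac(snaps[20])
        assert f0 == 0.5
        assert abs(f20 - 0.5) < 0.05  # exchangeable growth preserves expectation

    def test_godark_geometric_survival(self, confetti_only_mix, config_factory):
        cfg = config_factory(confetti_only_mix, go_dark_rate=0.05,
                             homeostatic_target=50)
        n = 500
        snaps = evolve_clones(_monoclonal_follicles(n), cfg, 28, seed=42)
        surv = sum(1 for c in snaps[28] if c.labeled and c.size > 0)
        p = 0.95**28
        se = math.sqrt(n * p * (1 - p))
        assert abs(surv - n * p) < 3 * se
        # monotone waning in expectation: check a coarse day grid
        series = [sum(1 for c in snaps[d] if c.labeled) for d in (0, 10, 20, 28)]
        assert series[0] > series[-1]

    def test_oligoclonal_alpha_raises_dominance(self, confetti_only_mix,
                                                config_factory):
        from tfrtrace.stats import clonal_dominance

        cfg_oligo = config_factory(confetti_only_mix,
                                   expansion_concentration=0.1,
                                   homeostatic_target=100)
        rng = np.random.default_rng(6)
        states = [ObservableState.single(f) for f in Fluorophore]
        doms0, doms30 = [], []
        for rep in range(200):
            clones = [
                Clone(f"c{i}", "m1", "follicle", "F1",
                      states[i % 4], "c", 5)
                for i in range(20)
            ]
            snaps = evolve_clones(clones, cfg_oligo, 30, rng)
            for day, sink in ((0, doms0), (30, doms30)):
                counts = {}
                for c in snaps[day]:
                    if c.labeled and c.size:
                        counts[c.founder_state] = counts.get(c.founder_state, 0) + c.size
                sink.append(clonal_dominance(counts).value)
        assert np.mean(doms30) > np.mean(doms0)

    def test_clone_conservation_and_integrality(self, confetti_only_mix,
                                                config_factory):
        cfg = config_factory(confetti_only_mix, homeostatic_target=60)
        clones = _monoclonal_follicles(30)
        snaps = evolve_clones(clones, cfg, 15, seed=8)
        for day, cs in snaps.items():
            for c in cs:
                assert isinstance(c.size, int) and c.size >= 0
            total = sum(c.size for c in cs)
            assert total <= 30 * cfg.homeostatic_target


class TestAblation:
    def _mixed_clones(self, n_follicles, labeled_per=5, unlabeled_per=10,
                      target_size=10):
        clones = []
        for i in range(n_follicles):
            fid = f"F{i:04d}"
            for j in range(labeled_per):
                clones.append(Clone(f"L{i}.{j}", "m1", "follicle", fid,
                                    YFP1, "confetti", target_size))
            for j in range(unlabeled_per):
                clones.append(Clone(f"U{i}.{j}", "m1", "follicle", fid,
                                    ObservableState(()), "dtr", target_size))
        return clones

    def test_zero_efficiency_is_noop(self, config_factory):
        from tfrtrace.config import DtxSchedule

        mix = MarrowMix((Donor("confetti", 1.0, confetti_labelable=True),
                         Donor("dtr", 2.0, dtx_ablatable=True)))
        cfg = config_factory(mix, dtx=DtxSchedule(0, 3, 0.0),
                             expansion_mode="proportional",
                             homeostatic_target=150)
        clones = self._mixed_clones(10)
        out = apply_ablation(clones, cfg, seed=3, n_administrations=2)
        # sizes are redrawn to the target but origins/labels are untouched
        assert sum(c.size for c in out if c.origin_genotype == "dtr") > 0
        labeled_before = sum(c.size for c in clones if c.labeled)
        labeled_after = sum(c.size for c in out if c.labeled)
        assert abs(labeled_after - labeled_before) < 60

    def test_full_ablation_triples_labeled_count(self, config_factory):
        # 1/3 labeled confetti origin, 2/3 unlabeled ablatable origin;
        # efficiency-1 ablation + proportional restore to the original size
        # scales survivors by 3 in expectation.
        from tfrtrace.config import DtxSchedule, Donor, MarrowMix, ScenarioConfig

        mix = MarrowMix((Donor("confetti", 1.0, confetti_labelable=True),
                         Donor("dtr", 2.0, dtx_ablatable=True)))
        n_follicles = 200
        cfg = ScenarioConfig(marrow=mix, recombination=RecombinationModel(0.6),
                             seed=1, dtx=DtxSchedule(0, 3, 1.0),
                             expansion_mode="proportional",
                             homeostatic_target=150,
                             observation_days=(1,))
        clones = self._mixed_clones(n_follicles, labeled_per=5, unlabeled_per=10,
                                    target_size=10)
        out = apply_ablation(clones, cfg, seed=12, n_administrations=1)
        labeled = np.array([
            sum(c.size for c in out
                if c.follicle_id == f"F{i:04d}" and c.labeled)
            for i in range(n_follicles)
        ])
        # each follicle: 50 labeled of 150 -> ablation leaves 50 -> restore
        # to 150 => all 150 labeled
        assert labeled.mean() == pytest.approx(150, abs=1e-9)

    def test_partial_ablation_expected_enrichment(self):
        from tfrtrace.config import DtxSchedule, Donor, MarrowMix, ScenarioConfig

        mix = MarrowMix((Donor("confetti", 1.0, confetti_labelable=True),
                         Donor("dtr", 2.0, dtx_ablatable=True)))
        cfg = ScenarioConfig(marrow=mix, recombination=RecombinationModel(0.6),
                             seed=1, dtx=DtxSchedule(0, 3, 0.5),
                             expansion_mode="proportional",
                             homeostatic_target=150, observation_days=(1,))
        clones = self._mixed_clones(200, labeled_per=5, unlabeled_per=10,
                                    target_size=10)
        out = apply_ablation(clones, cfg, seed=12, n_administrations=1)
        labeled = np.array([
            sum(c.size for c in out
                if c.follicle_id == f"F{i:04d}" and c.labeled)
            for i in range(200)
        ])
        # expectation: 150 * 50/(50 + 100*0.5) = 75 per follicle
        se = labeled.std(ddof=1) / math.sqrt(len(labeled))
        assert abs(labeled.mean() - 75.0) < 3 * se + 1.0

    def test_all_ablated_warns_and_empties(self):
        from tfrtrace.config import DtxSchedule, Donor, MarrowMix, ScenarioConfig

        mix = MarrowMix((Donor("dtr", 1.0, dtx_ablatable=True),))
        cfg = ScenarioConfig(marrow=mix, recombination=RecombinationModel(0.6),
                             seed=1, dtx=DtxSchedule(0, 3, 1.0),
                             homeostatic_target=100, observation_days=(1,))
        clones = [Clone("a", "m1", "follicle", "F1", ObservableState(()),
                        "dtr", 10)]
        with pytest.warns(EmptyCompartmentWarning):
            out = apply_ablation(clones, cfg, seed=2, n_administrations=1)
        assert sum(c.size for c in out) == 0


class TestSampling:
    def test_census_when_sampling_exceeds_size(self, confetti_only_mix,
                                               config_factory):
        cfg = config_factory(confetti_only_mix, cells_sampled_per_follicle=999)
        clones = [Clone("a", "m1", "follicle", "F1", YFP1, "c", 7)]
        df = sample_observation(clones, cfg, day=0, seed=1)
        assert len(df) == 7
        assert (df["state"] == "YFP").all()

    def test_identity_misclassification_is_noop(self, confetti_only_mix,
                                                config_factory):
        cfg = config_factory(confetti_only_mix, misclassification=np.eye(10))
        clones = [Clone("a", "m1", "follicle", "F1", YFP1, "c", 20)]
        df = sample_observation(clones, cfg, day=0, seed=1)
        assert (df["state"] == "YFP").all()

    def test_misclassification_matrix_product(self, confetti_only_mix,
                                              config_factory):
        # observed frequencies = truth @ matrix, checked at n = 1e5
        from tfrtrace.cassette import enumerate_observable_states
        from tfrtrace.stats import table_to_counts

        k = 10
        m = np.full((k, k), 0.1 / 9)
        np.fill_diagonal(m, 0.9)
        cfg = config_factory(confetti_only_mix, misclassification=m,
                             cells_sampled_per_follicle=100_000)
        states = enumerate_observable_states(2)
        truth = np.zeros(k)
        clones = []
        for i, s in enumerate(states[:3]):
            clones.append(Clone(f"c{i}", "m1", "follicle", "F1", s, "c",
                                [50_000, 30_000, 20_000][i]))
            truth[i] = [0.5, 0.3, 0.2][i]
        df = sample_observation(clones, cfg, day=0, seed=3)
        observed = table_to_counts(df) / len(df)
        expected = truth @ m
        n = len(df)
        for o, e in zip(observed, expected):
            se = math.sqrt(max(e * (1 - e), 1e-12) / n)
            assert abs(o - e) < 3 * se + 1e-9

    def test_seed_determinism_byte_identical(self, confetti_only_mix,
                                             config_factory):
        cfg = config_factory(confetti_only_mix)
        def run():
            pop = apply_labeling(
                simulate_chimera(confetti_only_mix, 2000, cfg.seed),
                cfg.recombination, cfg.seed + 1,
            )
            clones = found_follicles(pop, cfg, cfg.seed + 2)
            snaps = evolve_clones(clones, cfg, 10, cfg.seed + 3)
            return sample_observation(snaps[10], cfg, 10, cfg.seed + 4).to_csv()
        assert run() == run()
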