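import math

import numpy as np
import pandas as pd
import pytest

from looplens import simulate
from looplens.simulate import CAP_ONLY, CLOSED, FREE, TAIL_ONLY


class TestFragment:
    def test_no_cuts_leaves_single_fragment(self, rng):
        cuts = simulate.fragment(1000, 1e-9, rng)
        frags = simulate.fragments_from_cuts(cuts, 1000)
        assert frags == [(0.0, 1000.0)]

    def test_amplicon_survival_matches_poisson_closed_form(self, rng):
        # P(no cut inside a 70-nt amplicon) = exp(-0.01*70) = 0.4966
        lam, span, n = 0.01, 70, 100_000
        k = rng.poisson(lam * 1000, n)
        survived = 0
        cuts = rng.uniform(0, 1000, int(k.sum()))
        mol = np.repeat(np.arange(n), k)
        inside = (cuts >= 300) & (cuts < 300 + span)
        survived = n - len(np.unique(mol[inside]))
        p_hat = survived / n
        p = math.exp(-lam * span)
        assert abs(p_hat - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_disjoint_amplicons_survive_independently(self, rng):
        # joint survival of disjoint intervals = exp(-lam*(L1+L2))
        lam, n, length = 0.005, 100_000, 2000
        k = rng.poisson(lam * length, n)
        cuts = rng.uniform(0, length, int(k.sum()))
        mol = np.repeat(np.arange(n), k)
        hit1 = np.zeros(n, bool)
        hit2 = np.zeros(n, bool)
        hit1[np.unique(mol[(cuts >= 100) & (cuts < 170)])] = True
        hit2[np.unique(mol[(cuts >= 1500) & (cuts < 1600)])] = True
        joint = np.mean(~hit1 & ~hit2)
        expected = math.exp(-lam * (70 + 100))
        assert abs(joint - expected) < 4 * math.sqrt(expected * (1 - expected) / n)


class TestAssignState:
    def test_degenerate_probabilities(self, rng):
        all_closed = simulate.TranscriptSim("t", 1000, 1.0, 0.0, 0.0)
        assert all(simulate.assign_state(all_closed, rng) == CLOSED for _ in range(50))
        all_free = simulate.TranscriptSim("t", 1000, 0.0, 0.0, 0.0)
        assert all(simulate.assign_state(all_free, rng) == FREE for _ in range(50))

    def test_frequencies_converge_to_probabilities(self, rng):
        tr = simulate.TranscriptSim("t", 1000, 0.25, 0.25, 0.25)
        n = 100_000
        states = np.array([simulate.assign_state(tr, rng) for _ in range(n)])
        se = 3 * math.sqrt(0.25 * 0.75 / n)
        for code in (CLOSED, CAP_ONLY, TAIL_ONLY, FREE):
            assert abs(np.mean(states == code) - 0.25) < se


class TestCapture:
    FRAGS = [(0.0, 300.0), (300.0, 700.0), (700.0, 1000.0)]

    def test_closed_state_full_co_capture(self, rng):
        kept = simulate.capture(self.FRAGS, CLOSED, "eIF4E", 1.0, 0.0, rng)
        assert kept == [True, False, True]

    def test_cap_only_keeps_five_prime_anchor(self, rng):
        kept = simulate.capture(self.FRAGS, CAP_ONLY, "eIF4E", 1.0, 0.0, rng)
        assert kept == [True, False, False]

    def test_tail_only_invisible_to_cap_pulldown(self, rng):
        kept = simulate.capture(self.FRAGS, TAIL_ONLY, "eIF4E", 1.0, 0.0, rng)
        assert kept == [False, False, False]

    def test_pab_anchor_is_three_prime(self, rng):
        kept = simulate.capture(self.FRAGS, TAIL_ONLY, "PAB1", 1.0, 0.0, rng)
        assert kept == [False, False, True]

    def test_free_molecules_only_background(self, rng):
        draws = [simulate.capture(self.FRAGS, FREE, "PAB1", 1.0, 1.0, rng) for _ in range(5)]
        assert all(all(k) for k in draws)  # beta=1 captures everything


class TestExpectedEnrichment:
    def test_no_capture_path_gives_zero(self):
        # PAB1 pulldown, 5' assay, no closed molecules, no background
        # only the e^(-λ·length) end-colocation tail remains, which is ~1e-9 here
        val = simulate.expected_enrichment(0.01, 2000, 0, 70, "PAB1", 0.0, 0.5, 0.3, 1.0, 0.0)
        assert val == pytest.approx(0.0, abs=1e-8)

    def test_ideal_limit_gives_closed_fraction_of_engaged(self):
        """With complete end separation (λ·length >> 1), perfect co-capture
        and no background, the 3'/5' ratio of a cap-factor IP equals
        p_closed/(p_closed + p_cap_only) — the estimator's ideal target."""
        lam, length = 0.02, 4000
        pc, pco = 0.2, 0.3
        e5 = simulate.expected_enrichment(lam, length, 0, 70, "eIF4E", pc, pco, 0.3, 1.0, 0.0)
        e3 = simulate.expected_enrichment(lam, length, length - 70, length, "eIF4E", pc, pco, 0.3, 1.0, 0.0)
        assert e3 / e5 == pytest.approx(pc / (pc + pco), rel=1e-6)

    def test_monotone_in_p_closed_and_co_capture(self):
        """The cap-factor distal/proximal expectation never decreases as the
        true closed fraction or the co-capture efficiency grows."""
        lam, length = 0.01, 2000

        def ratio(pc, c):
            e5 = simulate.expected_enrichment(lam, length, 0, 70, "eIF4E", pc, 0.5 - pc, 0.3, c, 0.002)
            e3 = simulate.expected_enrichment(
                lam, length, length - 70, length, "eIF4E", pc, 0.5 - pc, 0.3, c, 0.002
            )
            return e3 / e5

        for c in (0.3, 0.6, 1.0):
            vals = [ratio(pc, c) for pc in np.linspace(0.01, 0.49, 9)]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        for pc in (0.1, 0.25, 0.4):
            vals = [ratio(pc, c) for c in np.linspace(0.1, 1.0, 8)]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("factor", ["eIF4E", "PAB1"])
    def test_monte_carlo_agrees_with_formula(self, factor, rng):
        tr = simulate.TranscriptSim("t", 1500, 0.3, 0.25, 0.25)
        assays = simulate.default_assay_layout("t", 1500)
        lam, c, beta, n = 0.008, 0.7, 0.005, 60_000
        ip, inp = simulate.simulate_counts(tr, assays, factor, lam, c, beta, n, rng)
        for (aid, s, e, cls), n_ip, n_in in zip(assays, ip, inp):
            expected = simulate.expected_enrichment(
                lam, tr.length, s, e, factor, tr.p_closed, tr.p_cap_only, tr.p_tail_only, c, beta
            )
            p_ip = expected * math.exp(-lam * (e - s))  # capture probability
            assert abs(n_ip / n - p_ip) < 4 * math.sqrt(p_ip * (1 - p_ip) / n) + 1e-12, (aid, cls)


def test_vectorized_counts_match_single_molecule_reference(rng):
    """The fast population simulator and the per-molecule reference path
    (fragment → assign_state → capture) agree on capture frequencies."""
    tr = simulate.TranscriptSim("t", 800, 0.4, 0.2, 0.2)
    assays = (("a5", 0, 60, "five_prime"), ("a3", 740, 800, "three_prime"))
    lam, c, beta = 0.01, 0.6, 0.01
    n = 30_000

    ip_fast, in_fast = simulate.simulate_counts(tr, assays, "eIF4E", lam, c, beta, n, rng)

    ip_ref = np.zeros(len(assays))
    in_ref = np.zeros(len(assays))
    for _ in range(n):
        cuts = simulate.fragment(tr.length, lam, rng)
        frags = simulate.fragments_from_cuts(cuts, tr.length)
        state = simulate.assign_state(tr, rng)
        kept = simulate.capture(frags, state, "eIF4E", c, beta, rng)
        for j, (_aid, s, e, _cls) in enumerate(assays):
            # amplicon amplifiable iff it sits entirely in one fragment
            frag_idx = next((i for i, (a, b) in enumerate(frags) if a <= s and e <= b), None)
            if frag_idx is None:
                continue
            in_ref[j] += 1
            if kept[frag_idx]:
                ip_ref[j] += 1

    for j in range(len(assays)):
        p_fast, p_ref = ip_fast[j] / n, ip_ref[j] / n
        se = math.sqrt(p_ref * (1 - p_ref) / n)
        assert abs(p_fast - p_ref) < 4 * se * math.sqrt(2)
        s_fast, s_ref = in_fast[j] / n, in_ref[j] / n
        assert abs(s_fast - s_ref) < 4 * math.sqrt(s_ref * (1 - s_ref) / n) * math.sqrt(2)


class TestGenerateCtDataset:
    def test_noiseless_count_ratio_is_exact_delta_ct(self):
        """σ=0 at E=2: a 4-fold template ratio must give ΔCt of exactly 2."""
        tr = simulate.TranscriptSim("t", 1000, 0.0, 0.0, 0.0)
        cfg = simulate.SimulationConfig(
            transcripts=(tr,),
            factors=("eIF4E",),
            ct_noise_sd=0.0,
            efficiency_range=(2.0, 2.0),
            intercept_range=(30.0, 30.0),
            n_molecules=1000,
            n_bio=1,
            n_tech=1,
        )
        tables = simulate.generate_ct_dataset(cfg, seed=3)
        dil = tables["dilution"]
        a = dil[dil["assay_id"] == "t_5p"].set_index("dilution")["ct"]
        assert a[0.25] - a[1.0] == pytest.approx(2.0, abs=1e-9)  # 4-fold = 2 cycles at E=2

    def test_same_seed_byte_identical_tables(self, tmp_path):
        cfg = simulate.default_config(3, n_molecules=2000)
        t1 = simulate.generate_ct_dataset(cfg, seed=11)
        t2 = simulate.generate_ct_dataset(cfg, seed=11)
        for key in t1:
            pd.testing.assert_frame_equal(t1[key], t2[key])
        t3 = simulate.generate_ct_dataset(cfg, seed=12)
        assert not t3["ct"]["ct"].equals(t1["ct"]["ct"])

    def test_input_counts_bound_ip_counts(self, rng):
        """Captured fragments are a subset of the molecule's fragments, so
        per assay the IP channel can never exceed the input channel."""
        tr = simulate.TranscriptSim("t", 1500, 0.3, 0.3, 0.2)
        assays = simulate.default_assay_layout("t", 1500)
        ip, inp = simulate.simulate_counts(tr, assays, "PAB1", 0.01, 1.0, 0.5, 20_000, rng)
        assert (ip <= inp).all()

    def test_zero_expected_count_becomes_missing_ct(self):
        # a free-only transcript captures nothing in the IP with beta=0
        tr = simulate.TranscriptSim("t", 1000, 0.0, 0.0, 0.0)
        cfg = simulate.SimulationConfig(
            transcripts=(tr,), factors=("eIF4E",), background=0.0, n_molecules=500,
            n_bio=1, n_tech=2,
        )
        tables = simulate.generate_ct_dataset(cfg, seed=5)
        ct = tables["ct"]
        ip_rows = ct[ct["sample_id"].str.endswith("_IP")]
        assert ip_rows["ct"].isna().all()
        input_rows = ct[ct["sample_id"].str.endswith("_input")]
        assert input_rows["ct"].notna().all()

    def test_config_validation_rejects_bad_probabilities(self):
        tr = simulate.TranscriptSim("t", 1000, 0.9, 0.9, 0.0)
        with pytest.raises(ValueError, match="probabilities"):
            simulate.SimulationConfig(transcripts=(tr,)).validate()


def test_config_dict_round_trip():
    cfg = simulate.profile_demo_config()
    d = simulate.config_to_dict(cfg)
    back = simulate.config_from_dict(d)
    assert back.transcripts[0].p_closed == pytest.approx(cfg.transcripts[0].p_closed)
    assert back.co_capture_for("PAB1") == pytest.approx(cfg.co_capture_for("PAB1"))
    assert back.factors == cfg.factors
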