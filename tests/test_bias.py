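"""Hexamer bias estimation and the three correction methods.

Each corrector is checked against an independent brute-force evaluation of
its formula, position by position, and the Poisson gate against a log-gamma
PMF oracle.
"""

import math

import numpy as np
import pytest

import tn5foot as t
from tn5foot.bias import HINT_BACK, HINT_FWD
from tn5foot.hexamers import FLANK, hexamer_ids


# ---------------------------------------------------------------- oracles

def poisson_pmf_oracle(y, lam):
    """Poisson PMF via log-gamma, independent of scipy.stats.poisson."""
    return math.exp(y * math.log(lam) - lam - math.lgamma(y + 1))


def hint_oracle(y, b_pos, statistic="mean"):
    """Per-position brute-force HINT evaluation with truncated windows."""
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - HINT_BACK), min(n, i + HINT_FWD + 1)
        win_y = y[lo:hi].sum() / (hi - lo) if statistic == "mean" else float(y[lo:hi].sum())
        b_hat = b_pos[i] / b_pos[lo:hi].sum()
        out[i] = (y[i] + 1.0) / (win_y * b_hat + 1.0)
    return out


def bagfoot_oracle(y, b_pos):
    return np.array([yi / bi for yi, bi in zip(y, b_pos)])


def poisson_gated_oracle(y, b_pos, lam, genome_size, alpha):
    thr = alpha / genome_size
    return np.array(
        [yi / bi if poisson_pmf_oracle(yi, lam) < thr else float(yi) for yi, bi in zip(y, b_pos)]
    )


def neutral_position_bias(table, genome, start, end):
    """b(w(i)) over [start, end) with 1.0 where the hexamer window exits."""
    ids = hexamer_ids(genome)[start:end]
    return np.where(ids >= 0, table.b[np.clip(ids, 0, None)], 1.0)


# ---------------------------------------------------------------- estimation

class TestEstimateBias:
    def test_uniform_cuts_give_unit_bias_exactly(self):
        # one cut at every valid position: pc(w) == p(w), so b == 1 exactly
        g = t.generate_genome(400, 0.5, seed=31)
        counts = np.zeros(g.length, dtype=int)
        ids = hexamer_ids(g.sequence)
        counts[ids >= 0] = 1
        prof = t.CutProfile("synth", 0, counts, counts.sum())
        table = t.estimate_bias(prof, g.sequence)
        present = table.p > 0
        assert np.allclose(table.b[present], 1.0)

    def test_overrepresented_hexamer_ratio_oracle(self):
        # hexamer occupying 25% of positions but receiving 50% of cuts -> b = 2
        g = t.generate_genome(4000, 0.5, seed=32)
        ids = hexamer_ids(g.sequence)
        valid = np.flatnonzero(ids >= 0)
        target = ids[valid[0]]
        target_pos = valid[ids[valid] == target]
        other_pos = valid[ids[valid] != target]
        # choose counts so the target hexamer holds exactly 25% of positions
        # is not required; build frequencies directly instead: give the
        # target half of all cuts and spread the rest uniformly
        counts = np.zeros(g.length, dtype=int)
        counts[other_pos] = 1
        per_target, rem = divmod(len(other_pos), len(target_pos))
        counts[target_pos] = per_target
        counts[target_pos[:rem]] += 1
        prof = t.CutProfile("synth", 0, counts, counts.sum())
        table = t.estimate_bias(prof, g.sequence)
        pc_t, p_t = table.pc[target], table.p[target]
        assert table.b[target] == pytest.approx(pc_t / p_t)
        assert pc_t == pytest.approx(0.5, abs=1e-9)

    def test_recovers_planted_preference_of_two(self):
        # generator-side preference 2 for one hexamer; estimate within 3 SE
        g = t.generate_genome(50_000, 0.5, seed=33)
        bm = t.BiasModel.with_preference("ACGTAC", 2.0)
        fr = t.simulate_fragments(g, t.plant_landscape(g), bm, n_events=10**6, seed=34)
        counts = 2 * np.bincount(fr.events, minlength=g.length)
        prof = t.CutProfile("synth", 0, counts, counts.sum())
        table = t.estimate_bias(prof, g.sequence)
        b_hat = table["ACGTAC"]
        from tn5foot.hexamers import hexamer_index

        n_target_cuts = table.pc[hexamer_index("ACGTAC")] * table.metadata["total_cuts"]
        # delta-method SE of the count ratio; each event deposits 2 cuts at
        # one position, so the effective sample size is the event count
        se = 2.0 / np.sqrt(n_target_cuts / 2)
        assert abs(b_hat - 2.0) < 3 * se

    def test_zero_cuts_rejected(self):
        g = t.generate_genome(100, 0.5, seed=35)
        prof = t.CutProfile("synth", 0, np.zeros(100, dtype=int), 0)
        with pytest.raises(ValueError):
            t.estimate_bias(prof, g.sequence)

    def test_tsv_round_trip(self, tmp_path):
        g = t.generate_genome(2000, 0.5, seed=36)
        fr = t.simulate_fragments(g, t.plant_landscape(g), None, 5000, seed=37)
        counts = 2 * np.bincount(fr.events, minlength=g.length)
        table = t.estimate_bias(t.CutProfile("synth", 0, counts, counts.sum()), g.sequence)
        path = tmp_path / "bias.tsv"
        table.to_tsv(path)
        back = t.BiasTable.from_tsv(path)
        assert np.allclose(back.b, table.b)
        assert np.allclose(back.pc, table.pc)


# ---------------------------------------------------------------- correctors

@pytest.fixture(scope="module")
def toy():
    g = t.generate_genome(1200, 0.5, seed=41)
    rng = np.random.default_rng(42)
    b = t.BiasTable(b=rng.uniform(0.25, 4.0, 4096))
    return g, b


class TestHint:
    def test_zero_profile_maps_to_all_ones(self, toy):
        g, table = toy
        prof = t.CutProfile("synth", 0, np.zeros(300, dtype=int), 100)
        out = t.correct_hint(prof, table, g.sequence)
        assert np.allclose(out.counts, 1.0)

    def test_uniform_bias_uniform_counts_value(self, toy):
        # y = 1 everywhere, uniform bias: interior x = 2 / (1/50 + 1) = 100/51
        g, _ = toy
        prof = t.CutProfile("synth", 0, np.ones(300, dtype=int), 300)
        out = t.correct_hint(prof, t.BiasTable.uniform(), g.sequence)
        assert out.counts[150] == pytest.approx(100 / 51)

    def test_matches_brute_force_formula(self, toy):
        g, table = toy
        rng = np.random.default_rng(43)
        y = rng.integers(0, 40, 1000)
        prof = t.CutProfile("synth", 100, y, y.sum())
        out = t.correct_hint(prof, table, g.sequence)
        b_pos = neutral_position_bias(table, g.sequence, 100, 1100)
        assert np.allclose(out.counts, hint_oracle(y.astype(float), b_pos), rtol=0, atol=1e-12)

    def test_sum_statistic_alternate_matches_oracle(self, toy):
        g, table = toy
        rng = np.random.default_rng(44)
        y = rng.integers(0, 40, 500)
        prof = t.CutProfile("synth", 0, y, y.sum())
        out = t.correct_hint(prof, table, g.sequence, window_statistic="sum")
        b_pos = neutral_position_bias(table, g.sequence, 0, 500)
        assert np.allclose(out.counts, hint_oracle(y.astype(float), b_pos, "sum"), atol=1e-12)

    def test_output_always_positive(self, toy):
        g, table = toy
        rng = np.random.default_rng(45)
        y = rng.integers(0, 100, 800)
        out = t.correct_hint(t.CutProfile("synth", 0, y, y.sum()), table, g.sequence)
        assert (out.counts > 0).all()


class TestBagfoot:
    def test_unit_bias_is_identity(self, toy):
        g, _ = toy
        rng = np.random.default_rng(46)
        y = rng.integers(0, 20, 400)
        out = t.correct_bagfoot(t.CutProfile("synth", 0, y, y.sum()), t.BiasTable.uniform(), g.sequence)
        assert np.allclose(out.counts, y)

    @pytest.mark.parametrize("y,b,expected", [(10, 2.0, 5.0), (3, 0.5, 6.0)])
    def test_division_arithmetic(self, y, b, expected):
        g = t.generate_genome(50, 0.5, seed=47)
        table = t.BiasTable(b=np.full(4096, b))
        prof = t.CutProfile("synth", 0, np.full(50, y), 50 * y)
        out = t.correct_bagfoot(prof, table, g.sequence)
        assert out.counts[25] == pytest.approx(expected)

    def test_matches_brute_force_formula(self, toy):
        g, table = toy
        rng = np.random.default_rng(48)
        y = rng.integers(0, 40, 1000)
        prof = t.CutProfile("synth", 100, y, y.sum())
        out = t.correct_bagfoot(prof, table, g.sequence)
        b_pos = neutral_position_bias(table, g.sequence, 100, 1100)
        assert np.allclose(out.counts, bagfoot_oracle(y, b_pos), atol=1e-12)

    def test_flattens_naked_dna_bias(self):
        # on biased naked-DNA simulation the corrected profile is flatter
        g = t.generate_genome(20_000, 0.5, seed=49)
        prefs = np.exp(np.random.default_rng(50).normal(0, 0.5, 4096))
        bm = t.BiasModel(prefs)
        fr = t.simulate_fragments(g, t.plant_landscape(g), bm, n_events=400_000, seed=51)
        counts = 2 * np.bincount(fr.events, minlength=g.length)
        prof = t.CutProfile("synth", 0, counts, counts.sum())
        table = t.estimate_bias(prof, g.sequence)
        inner = slice(4, g.length - 4)
        corrected = t.correct_bagfoot(prof, table, g.sequence)
        cv = lambda x: x.std() / x.mean()
        assert cv(corrected.counts[inner]) < cv(counts[inner].astype(float))


class TestPoissonGate:
    def test_threshold_is_eight_at_study_scale(self):
        gate = t.PoissonGate(lam=0.1, genome_size=2.73e9, alpha=0.01)
        assert t.gate_threshold(gate) == 8
        # log-gamma PMF oracle around the boundary
        assert poisson_pmf_oracle(7, 0.1) > 0.01 / 2.73e9
        assert poisson_pmf_oracle(8, 0.1) < 0.01 / 2.73e9

    def test_threshold_matches_direct_pmf_scan(self):
        gate = t.PoissonGate(lam=0.01, genome_size=1e6, alpha=0.01)
        thr = 0.01 / 1e6
        y = 0
        while poisson_pmf_oracle(y, 0.01) >= thr:
            y += 1
        assert t.gate_threshold(gate) == y

    def test_huge_alpha_corrects_everything(self):
        gate = t.PoissonGate(lam=0.1, genome_size=10.0, alpha=1e9)
        assert t.gate_threshold(gate) == 0

    def test_lambda_above_one_needs_per_position_test(self):
        with pytest.raises(ValueError):
            t.gate_threshold(t.PoissonGate(lam=1.5, genome_size=1e9))

    def test_zero_counts_never_corrected(self, toy):
        g, table = toy
        prof = t.CutProfile("synth", 0, np.zeros(200, dtype=int), 100)
        gate = t.PoissonGate(lam=0.1, genome_size=2.73e9)
        out = t.correct_poisson_gated(prof, table, g.sequence, gate)
        assert (out.counts == 0).all()

    def test_composition_of_gate_and_division(self):
        # y=8 with b=2 corrects to 4; neighbouring y=3 is untouched
        g = t.generate_genome(60, 0.5, seed=52)
        table = t.BiasTable(b=np.full(4096, 2.0))
        counts = np.zeros(60, dtype=int)
        counts[30], counts[31] = 8, 3
        prof = t.CutProfile("synth", 0, counts, 11)
        gate = t.PoissonGate(lam=0.1, genome_size=2.73e9, alpha=0.01)
        out = t.correct_poisson_gated(prof, table, g.sequence, gate)
        assert out.counts[30] == pytest.approx(4.0)
        assert out.counts[31] == 3.0

    def test_matches_brute_force_formula(self, toy):
        g, table = toy
        rng = np.random.default_rng(53)
        y = rng.integers(0, 15, 1000)
        prof = t.CutProfile("synth", 100, y, y.sum())
        gate = t.PoissonGate(lam=0.2, genome_size=1e8, alpha=0.01)
        out = t.correct_poisson_gated(prof, table, g.sequence, gate)
        b_pos = neutral_position_bias(table, g.sequence, 100, 1100)
        assert np.allclose(out.counts, poisson_gated_oracle(y, b_pos, 0.2, 1e8, 0.01), atol=1e-12)

    def test_piecewise_equivalence_with_bagfoot(self, toy):
        # identical to BaGFoot at y >= y*, identity below
        g, table = toy
        rng = np.random.default_rng(54)
        y = rng.integers(0, 15, 1000)
        prof = t.CutProfile("synth", 0, y, y.sum())
        gate = t.PoissonGate(lam=0.2, genome_size=1e8, alpha=0.01)
        ystar = t.gate_threshold(gate)
        gated = t.correct_poisson_gated(prof, table, g.sequence, gate)
        bag = t.correct_bagfoot(prof, table, g.sequence)
        high, low = y >= ystar, y < ystar
        assert np.array_equal(gated.counts[high], bag.counts[high])
        assert np.array_equal(gated.counts[low], y[low].astype(float))


def test_all_three_correctors_match_oracles_on_random_profiles(toy):
    """Oracle equivalence over many random 1-kb profiles, full precision."""
    g, table = toy
    rng = np.random.default_rng(55)
    b_pos = neutral_position_bias(table, g.sequence, 0, 1000)
    gate = t.PoissonGate(lam=0.3, genome_size=2.73e9, alpha=0.01)
    for _ in range(25):
        y = rng.integers(0, 30, 1000)
        prof = t.CutProfile("synth", 0, y, y.sum())
        yf = y.astype(float)
        assert np.allclose(
            t.correct_hint(prof, table, g.sequence).counts, hint_oracle(yf, b_pos), atol=1e-12
        )
        assert np.allclose(
            t.correct_bagfoot(prof, table, g.sequence).counts, bagfoot_oracle(y, b_pos), atol=1e-12
        )
        assert np.allclose(
            t.correct_poisson_gated(prof, table, g.sequence, gate).counts,
            poisson_gated_oracle(y, b_pos, gate.lam, gate.genome_size, gate.alpha),
            atol=1e-12,
        )
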