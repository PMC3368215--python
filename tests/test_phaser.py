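import numpy as np
import pytest

from ibdphase.model_core import (
    IBDState,
    ModelParams,
    build_rate_matrix,
    emission_prob,
    stationary_distribution,
    transition_matrix,
)
from ibdphase.phaser import (
    IBDSegmentCall,
    build_graph,
    call_phase,
    extract_ibd_calls,
    ibd_cpt,
    impute,
    min_sum,
)
from ibdphase.prescan import PlausibleSegment

from conftest import matrix_from_dosages, uniform_map
from oracles import decoded_cost, joint_min_cost


def exact_params(**kw):
    """Parameters that make Min-Sum exact on trees (no attenuation)."""
    kw.setdefault("attenuation", 1.0)
    kw.setdefault("damping", 0.0)
    kw.setdefault("max_iters", 200)
    kw.setdefault("convergence_tol", 1e-10)
    kw.setdefault("min_markers", 1)
    return ModelParams(**kw)


class TestIbdCpt:
    def test_ibs_violation_concentrates_on_nonibd(self):
        # opposite homozygotes cannot share any haplotype
        cpt = ibd_cpt(3, 0, IBDState.S11, 0.001, 0.3, ModelParams())
        assert cpt[0] == pytest.approx(1.0)
        assert np.allclose(cpt[1:], 0.0)

    def test_zero_distance_keeps_previous_state(self):
        cpt = ibd_cpt(2, 2, IBDState.S11, 0.0, 0.3, ModelParams())
        assert cpt[IBDState.S11] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scalar_bayes_oracle(self, seed):
        rng = np.random.default_rng(seed)
        params = ModelParams()
        f = float(rng.uniform(0.05, 0.95))
        t = float(rng.uniform(0.0, 0.05))
        prev = int(rng.integers(0, 5))
        da, db = int(rng.integers(0, 4)), int(rng.integers(0, 4))
        Q = build_rate_matrix(params)
        trow = transition_matrix(Q, t, params.kappa)[prev]
        unnorm = np.array(
            [trow[s] * emission_prob(s, da, db, f) for s in range(5)]
        )
        expected = unnorm / unnorm.sum()
        assert np.allclose(ibd_cpt(da, db, prev, t, f, params), expected, atol=1e-12)

    def test_first_marker_uses_stationary(self):
        params = ModelParams()
        pi = stationary_distribution(params)
        f, da, db = 0.3, 0, 0
        unnorm = np.array([pi[s] * emission_prob(s, da, db, f) for s in range(5)])
        expected = unnorm / unnorm.sum()
        assert np.allclose(ibd_cpt(da, db, None, 0.01, f, params), expected, atol=1e-12)


class TestBuildGraph:
    def test_variable_and_cell_counts(self):
        geno = matrix_from_dosages(
            np.ones((2, 12), np.int8), np.full(12, 0.3)
        )
        gmap = uniform_map(12)
        seg = PlausibleSegment(0, 1, 5, 10, 0.9, 0.001)
        g = build_graph(geno, [seg], gmap, exact_params())
        assert g.n_hvars == 10  # 2 individuals x 5 markers
        assert g.n_cells == 5
        assert np.all(g.cell_marker == np.arange(5, 10))

    def test_overlapping_segments_share_diplotype_variables(self):
        geno = matrix_from_dosages(np.ones((3, 12), np.int8), np.full(12, 0.3))
        gmap = uniform_map(12)
        segs = [
            PlausibleSegment(0, 1, 2, 8, 0.9, 0.001),
            PlausibleSegment(0, 2, 4, 10, 0.9, 0.001),
        ]
        g = build_graph(geno, segs, gmap, exact_params())
        # individual 0 in the overlap is one variable used by both chains
        k01 = np.nonzero(g.cell_marker[: 6] == 5)[0][0]
        k02 = 6 + np.nonzero(g.cell_marker[6:] == 5)[0][0]
        assert g.cell_ha[k01] == g.cell_ha[k02] == g.cell_to_hvar[0, 5]
        # ind 0 covered on [2,10), ind 1 on [2,8), ind 2 on [4,10)
        assert g.n_hvars == 8 + 6 + 6

    def test_factor_tables_match_cpt_up_to_diplotype_terms(self):
        """cost_t realizes -log of transition x emission likelihood-ratio."""
        rng = np.random.default_rng(0)
        m = 6
        freqs = rng.uniform(0.1, 0.5, m)
        geno = matrix_from_dosages(rng.integers(0, 3, (2, m)).astype(np.int8), freqs)
        gmap = uniform_map(m, 0.01)
        params = exact_params()
        g = build_graph(geno, [PlausibleSegment(0, 1, 0, m, 0.9, 0.01)], gmap, params)
        Q = build_rate_matrix(params)
        for _ in range(20):
            j = int(rng.integers(1, m))
            pp, p = int(rng.integers(0, 5)), int(rng.integers(0, 5))
            da, db = int(rng.integers(0, 4)), int(rng.integers(0, 4))
            t = gmap.morgans[j] - gmap.morgans[j - 1]
            T = transition_matrix(Q, t, params.kappa)
            e = emission_prob(p, da, db, freqs[j])
            base = emission_prob(0, da, db, freqs[j])
            val = T[pp, p] * e / base
            expected = -np.log(val) if val > 0 else 1e3
            assert g.cost_t[j, pp, p, da, db] == pytest.approx(min(expected, 1e3), abs=1e-9)

    def test_empty_segment_list_gives_empty_graph(self):
        geno = matrix_from_dosages(np.ones((2, 5), np.int8), np.full(5, 0.3))
        g = build_graph(geno, [], uniform_map(5), exact_params())
        assert g.n_hvars == 0 and g.n_cells == 0


class TestMinSumExactness:
    @pytest.mark.parametrize("seed", range(10))
    def test_single_pair_map_matches_enumeration(self, seed):
        """On a cycle-free instance the decoded configuration attains the
        global energy minimum found by exhaustive enumeration."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 5))
        gmap = uniform_map(m, float(rng.uniform(0.002, 0.05)))
        freqs = rng.uniform(0.08, 0.5, m)
        dos = rng.integers(0, 3, (2, m)).astype(np.int8)
        geno = matrix_from_dosages(dos, freqs)
        params = exact_params(epsilon=float(rng.uniform(0.001, 0.05)))
        g = build_graph(geno, [PlausibleSegment(0, 1, 0, m, 0.9, 0.01)], gmap, params)
        res = min_sum(g, params)
        assert res.converged
        assert decoded_cost(g, res, geno) == pytest.approx(
            joint_min_cost(g, geno), abs=1e-6
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_three_individuals_map_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = 2
        gmap = uniform_map(m, 0.01)
        freqs = rng.uniform(0.1, 0.5, m)
        dos = rng.integers(0, 3, (3, m)).astype(np.int8)
        geno = matrix_from_dosages(dos, freqs)
        params = exact_params()
        segs = [
            PlausibleSegment(0, 1, 0, m, 0.9, 0.01),
            PlausibleSegment(0, 2, 0, m, 0.9, 0.01),
        ]
        g = build_graph(geno, segs, gmap, params)
        res = min_sum(g, params)
        assert decoded_cost(g, res, geno) == pytest.approx(
            joint_min_cost(g, geno), abs=1e-6
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_damping_reaches_same_decisions_as_undamped(self, seed):
        rng = np.random.default_rng(200 + seed)
        m = 4
        gmap = uniform_map(m, 0.01)
        freqs = rng.uniform(0.1, 0.5, m)
        dos = rng.integers(0, 3, (2, m)).astype(np.int8)
        geno = matrix_from_dosages(dos, freqs)
        seg = [PlausibleSegment(0, 1, 0, m, 0.9, 0.01)]
        g0 = build_graph(geno, seg, gmap, exact_params())
        res0 = min_sum(g0, exact_params())
        p_damped = exact_params(damping=0.5)
        g5 = build_graph(geno, seg, gmap, p_damped)
        res5 = min_sum(g5, p_damped)
        # both fixed points decode to configurations of the same (optimal)
        # energy; individual argmins may differ only at exact ties
        assert decoded_cost(g0, res0, geno) == pytest.approx(
            decoded_cost(g5, res5, geno), abs=1e-6
        )
        b0, b5 = res0.hbelief, res5.hbelief
        decided = np.abs(b0 - np.min(b0, axis=1, keepdims=True)).max(axis=1) > 1e-6
        tied0 = np.abs(np.sort(b0, axis=1)[:, 1] - np.sort(b0, axis=1)[:, 0]) < 1e-6
        check = decided & ~tied0
        assert np.array_equal(
            np.argmin(b0[check], axis=1), np.argmin(b5[check], axis=1)
        )

    def test_all_missing_leaves_everything_unphased(self):
        m = 6
        geno = matrix_from_dosages(np.full((2, m), -1, np.int8), np.full(m, 0.3))
        gmap = uniform_map(m)
        params = exact_params()
        g = build_graph(geno, [PlausibleSegment(0, 1, 0, m, 0.9, 0.01)], gmap, params)
        res = min_sum(g, params)
        phase = call_phase(res, geno, params)
        assert not phase.phased.any()
        phase = impute(res, geno, params, phase)
        assert not phase.imputed.any()
        assert np.all(phase.diplotypes == -1)


def _duo_cohort(seed=0, m=200, n_extra=6):
    """Two individuals sharing haplotype 1 across the chromosome, plus
    unrelated filler individuals to stabilize allele frequencies."""
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.1, 0.5, m)
    def hap():
        return (rng.random(m) < f).astype(np.int8)
    shared = hap()
    haps = [(shared, hap()), (shared, hap())]
    haps += [(hap(), hap()) for _ in range(n_extra)]
    truth = np.stack([np.stack(h, axis=1) for h in haps])  # (n, m, 2)
    dos = truth.sum(axis=2).astype(np.int8)
    freqs = dos.sum(axis=0) / (2.0 * len(haps))
    keep = (freqs > 0) & (freqs <= 0.5)  # keep minor orientation simple
    return (
        matrix_from_dosages(dos[:, keep], freqs[keep]),
        uniform_map(int(keep.sum()), 0.1),
        truth[:, keep, :],
    )


class TestCalling:
    def test_duo_long_range_phasing_deduction(self):
        """Het sites of one individual whose IBD partner is homozygous are
        phased with the shared allele on the shared haplotype."""
        geno, gmap, truth = _duo_cohort(seed=1)
        # a single sparse chain: use unattenuated messages so margins carry
        # the full flip cost
        params = ModelParams(min_markers=1, attenuation=1.0)
        seg = [PlausibleSegment(0, 1, 0, geno.n_markers, 0.99, gmap.length_morgans)]
        g = build_graph(geno, seg, gmap, params)
        res = min_sum(g, params)
        phase = call_phase(res, geno, params)
        for i in (0, 1):
            het = geno.dosages[i] == 1
            partner_hom = np.isin(geno.dosages[1 - i], (0, 2))
            called = het & partner_hom & phase.phased[i]
            assert called.sum() > 0.5 * (het & partner_hom).sum()
            # modulo the individual's global flip, calls match truth
            agree = phase.diplotypes[i, called, 0] == truth[i, called, 0]
            assert agree.mean() in (pytest.approx(0.0), pytest.approx(1.0)) or (
                agree.all() or (~agree).all()
            )

    def test_sites_outside_segments_stay_unphased(self):
        geno, gmap, _ = _duo_cohort(seed=2, m=60)
        params = ModelParams(min_markers=1)
        seg = [PlausibleSegment(0, 1, 0, 30, 0.99, 0.05)]
        g = build_graph(geno, seg, gmap, params)
        phase = call_phase(min_sum(g, params), geno, params)
        het_outside = (geno.dosages == 1).copy()
        het_outside[:2, :30] = False
        assert not (phase.phased & het_outside & (geno.dosages == 1)).any()

    def test_called_diplotypes_reproduce_observed_genotypes(self):
        geno, gmap, _ = _duo_cohort(seed=3)
        params = ModelParams(min_markers=1)
        seg = [PlausibleSegment(0, 1, 0, geno.n_markers, 0.99, gmap.length_morgans)]
        phase = call_phase(min_sum(build_graph(geno, seg, gmap, params), params), geno, params)
        obs = geno.dosages != -1
        called = phase.phased & obs
        dosage = phase.diplotypes[..., 0] + phase.diplotypes[..., 1]
        assert np.array_equal(dosage[called], geno.dosages[called])

    def test_margins_are_nonnegative_and_gate_calls(self):
        geno, gmap, _ = _duo_cohort(seed=4)
        params = ModelParams(min_markers=1, phase_margin=1e9)
        seg = [PlausibleSegment(0, 1, 0, geno.n_markers, 0.99, gmap.length_morgans)]
        phase = call_phase(min_sum(build_graph(geno, seg, gmap, params), params), geno, params)
        het = geno.dosages == 1
        assert not (phase.phased & het).any()  # impossible margin refuses all
        assert np.all(phase.margins >= 0.0)


class TestImputation:
    def test_missing_site_without_coverage_is_no_call(self):
        geno, gmap, _ = _duo_cohort(seed=5, m=60)
        dos = geno.dosages.copy()
        dos[0, 40] = -1  # outside the only segment
        geno2 = matrix_from_dosages(dos, geno.freqs)
        params = ModelParams(min_markers=1)
        seg = [PlausibleSegment(0, 1, 0, 30, 0.99, 0.05)]
        res = min_sum(build_graph(geno2, seg, gmap, params), params)
        phase = impute(res, geno2, params, call_phase(res, geno2, params))
        assert not phase.imputed[0, 40].any()

    def test_duo_imputes_shared_allele_from_homozygous_partner(self):
        geno, gmap, truth = _duo_cohort(seed=6)
        dos = geno.dosages.copy()
        # hide a genotype in the middle where the partner is homozygous
        mid = geno.n_markers // 2
        hidden = None
        for j in range(mid - 30, mid + 30):
            if dos[1, j] in (0, 2):
                hidden = j
                break
        dos[0, hidden] = -1
        geno2 = matrix_from_dosages(dos, geno.freqs)
        params = ModelParams(min_markers=1)
        seg = [PlausibleSegment(0, 1, 0, geno2.n_markers, 0.99, gmap.length_morgans)]
        res = min_sum(build_graph(geno2, seg, gmap, params), params)
        phase = impute(res, geno2, params, call_phase(res, geno2, params))
        assert phase.imputed[0, hidden].any()
        imputed_alleles = phase.diplotypes[0, hidden]
        shared_allele = truth[0, hidden, 0]
        assert shared_allele in imputed_alleles[imputed_alleles >= 0]


class TestExtractCalls:
    def _graph_with_path(self, states):
        m = len(states)
        geno = matrix_from_dosages(np.ones((2, m), np.int8), np.full(m, 0.3))
        gmap = uniform_map(m, 0.01)
        params = exact_params()
        g = build_graph(geno, [PlausibleSegment(0, 1, 0, m, 0.9, 0.01)], gmap, params)
        res = min_sum(g, params)
        res._viterbi = np.array(states, dtype=np.int8)
        return res, gmap

    def test_single_run_with_nonibd_flanks(self):
        res, gmap = self._graph_with_path([0, 0, 0, 1, 1, 1, 1, 1, 0, 0])
        calls = extract_ibd_calls(res, gmap)
        assert len(calls) == 1
        c = calls[0]
        assert (c.start, c.end, c.hap_a, c.hap_b) == (3, 8, 1, 1)
        assert c.n_markers == 5

    def test_flip_splits_into_two_adjacent_calls(self):
        res, gmap = self._graph_with_path([1, 1, 1, 2, 2, 2])
        calls = extract_ibd_calls(res, gmap)
        assert len(calls) == 2
        assert (calls[0].start, calls[0].end) == (0, 3)
        assert (calls[1].start, calls[1].end) == (3, 6)
        assert calls[0].end == calls[1].start
        assert (calls[0].hap_a, calls[0].hap_b) == (1, 1)
        assert (calls[1].hap_a, calls[1].hap_b) == (1, 2)
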