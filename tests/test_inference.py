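"""Inference engine: likelihood oracles, sampler internals, diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import ks_2samp

from opscr.demography import State
from opscr.inference import (
    StudyData, ModelParameters, Priors, MCMCConfig, PosteriorResult,
    prepare_from_synthetic, joint_loglik, marginal_loglik_forward,
    params_from_vector, run_mcmc, gelman_rubin, derive_collar_contrasts,
    _Sampler,
)
from opscr.simulate import flagship_config, generate_study


def tiny_study(seed=7, **kw):
    base = dict(core_extent=(0.0, 0.0, 20.0, 20.0), buffer_width=20.0,
                M=4, T=3, p0=0.4, collar_fraction=0.5, psi=0.6, gamma=0.3)
    base.update(kw)
    return generate_study(flagship_config(**base), seed)


def slice_individual(data: StudyData, i: int) -> StudyData:
    keep = data.y_ind == i
    return StudyData(
        habitat=data.habitat, detectors=data.detectors, T=data.T, M=1,
        individual_ids=[data.individual_ids[i]], n_detected=int(keep.any()),
        group=data.group[i:i + 1], region_of_group=data.region_of_group,
        gps=data.gps[i:i + 1], prev=data.prev[i:i + 1],
        masks=data.masks[i:i + 1],
        y_ind=np.zeros(keep.sum(), dtype=int), y_det=data.y_det[keep],
        y_season=data.y_season[keep], y_count=data.y_count[keep],
    )


def reference_params(data, sigma=5.0, tau=12.0, p0=0.3, h=0.12, w=0.2,
                     bh=-0.4, bw=-0.9):
    from opscr.demography import DemographicParams
    from opscr.movement import MovementParams
    from opscr.detection import DetectionParams

    G, T, C = data.n_groups, data.T, data.n_counties
    demo = DemographicParams(
        psi=np.full(G, 0.4), gamma=np.full((G, T - 1), 0.25),
        h0=np.full((G, T - 1), logit(h)), w0=np.full((G, T - 1), logit(w)),
        beta_h_gps=bh, beta_w_gps=bw)
    mov = [MovementParams(tau=tau, b_dens=0.4) for _ in range(G)]
    det = [DetectionParams(p0_intercept=np.full((C, T), logit(p0)), sigma=sigma,
                           beta_tracks=0.2, beta_roads=-0.1, beta_snow=0.15,
                           beta_prevdet=0.3, beta_gps=-0.3) for _ in range(G)]
    return ModelParameters(demographic=demo, movement=mov, detection=det)


class TestMarginalLikelihoodOracle:
    def test_forward_equals_exhaustive_path_enumeration(self):
        study = tiny_study()
        data = prepare_from_synthetic(study)
        params = reference_params(data)
        rng = np.random.default_rng(0)
        ac = rng.integers(0, data.habitat.n_cells, size=(data.M, data.T))
        got = marginal_loglik_forward(params, ac, data, local_radius=None)
        total = 0.0
        for i in range(data.M):
            di = slice_individual(data, i)
            terms = [
                joint_loglik(params, np.array([path]), ac[i:i + 1], di,
                             local_radius=None)
                for path in itertools.product([1, 2, 3, 4], repeat=data.T)
            ]
            terms = np.array(terms)
            finite = terms[np.isfinite(terms)]
            assert finite.size > 0
            total += np.log(np.exp(finite - finite.max()).sum()) + finite.max()
        assert got == pytest.approx(total, abs=1e-10)

    def test_certain_alive_marginal_equals_conditional(self):
        study = tiny_study(psi=1 - 1e-12, h=1e-12, w=1e-12, gamma=0.5,
                           collar_fraction=0.0)
        data = prepare_from_synthetic(study)
        # with inclusion certain, mortality off and negligible detectability,
        # the all-alive path carries all the marginal mass
        params = reference_params(data, h=1e-9, w=1e-9, p0=1e-8)
        params.demographic.psi[:] = 1 - 1e-12
        rng = np.random.default_rng(1)
        ac = rng.integers(0, data.habitat.n_cells, size=(data.M, data.T))
        z = np.full((data.M, data.T), int(State.ALIVE))
        assert marginal_loglik_forward(params, ac, data) == pytest.approx(
            joint_loglik(params, z, ac, data), abs=1e-6)

    def test_unique_legal_path_forced_by_evidence(self):
        study = tiny_study()
        data = prepare_from_synthetic(study)
        # force one individual's full path: alive, alive, culled
        data = StudyData(**{**data.__dict__})
        data.masks = data.masks.copy()
        data.masks[0] = np.array([[0, 1, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]],
                                 dtype=bool)
        params = reference_params(data)
        rng = np.random.default_rng(2)
        ac = rng.integers(0, data.habitat.n_cells, size=(data.M, data.T))
        di = slice_individual(data, 0)
        forced = np.array([[2, 2, 3]])
        marg_i = marginal_loglik_forward(params, ac[0:1], di)
        joint_i = joint_loglik(params, forced, ac[0:1], di)
        assert marg_i == pytest.approx(joint_i, abs=1e-9)


class TestJointLikelihood:
    def test_impossible_history_is_minus_inf(self):
        study = tiny_study(M=12, core_extent=(0.0, 0.0, 40.0, 40.0),
                           buffer_width=0.0)
        data = prepare_from_synthetic(study)
        assert len(data.y_ind) > 0
        params = reference_params(data)
        rng = np.random.default_rng(3)
        ac = rng.integers(0, data.habitat.n_cells, size=(data.M, data.T))
        i, t = int(data.y_ind[0]), int(data.y_season[0])
        z = np.full((data.M, data.T), int(State.ALIVE))
        z[i, t - 1] = int(State.UNBORN)
        assert joint_loglik(params, z, ac, data) == -np.inf

    def test_duplicating_an_individual_doubles_its_contribution(self):
        study = tiny_study()
        data = prepare_from_synthetic(study)
        params = reference_params(data)
        rng = np.random.default_rng(4)
        ac = rng.integers(0, data.habitat.n_cells, size=(1, data.T))
        di = slice_individual(data, 0)
        z = np.array([[2, 2, 2]])
        one = joint_loglik(params, z, ac, di)
        # duplicate the individual (same data rows twice)
        d2 = StudyData(
            habitat=di.habitat, detectors=di.detectors, T=di.T, M=2,
            individual_ids=di.individual_ids * 2, n_detected=2 * di.n_detected,
            group=np.repeat(di.group, 2), region_of_group=di.region_of_group,
            gps=np.repeat(di.gps, 2, axis=0), prev=np.repeat(di.prev, 2, axis=0),
            masks=np.repeat(di.masks, 2, axis=0),
            y_ind=np.concatenate([di.y_ind, np.ones_like(di.y_ind)]),
            y_det=np.tile(di.y_det, 2), y_season=np.tile(di.y_season, 2),
            y_count=np.tile(di.y_count, 2),
        )
        two = joint_loglik(params, np.repeat(z, 2, axis=0),
                           np.repeat(ac, 2, axis=0), d2)
        assert two == pytest.approx(2 * one, abs=1e-9)

    def test_likelihood_invariant_under_individual_permutation(self):
        study = tiny_study(M=6)
        data = prepare_from_synthetic(study)
        params = reference_params(data)
        rng = np.random.default_rng(5)
        ac = rng.integers(0, data.habitat.n_cells, size=(data.M, data.T))
        base = marginal_loglik_forward(params, ac, data)
        perm = rng.permutation(data.M)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(data.M)
        pdata = StudyData(
            habitat=data.habitat, detectors=data.detectors, T=data.T, M=data.M,
            individual_ids=[data.individual_ids[p] for p in perm],
            n_detected=data.n_detected, group=data.group[perm],
            region_of_group=data.region_of_group, gps=data.gps[perm],
            prev=data.prev[perm], masks=data.masks[perm],
            y_ind=inv[data.y_ind], y_det=data.y_det, y_season=data.y_season,
            y_count=data.y_count,
        )
        assert marginal_loglik_forward(params, ac[perm], pdata) \
            == pytest.approx(base, abs=1e-9)

    def test_likelihood_invariant_under_detector_relabeling(self):
        study = tiny_study()
        data = prepare_from_synthetic(study)
        params = reference_params(data)
        rng = np.random.default_rng(6)
        ac = rng.integers(0, data.habitat.n_cells, size=(data.M, data.T))
        base = marginal_loglik_forward(params, ac, data)
        from opscr.spatial import DetectorGrid
        perm = rng.permutation(data.detectors.n_detectors)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        det2 = DetectorGrid(
            detector_centres=data.detectors.detector_centres[perm],
            detector_size=data.detectors.detector_size,
            subdetector_size=data.detectors.subdetector_size,
            K=data.detectors.K[perm], county_id=data.detectors.county_id[perm],
            covariates={k: v[perm] for k, v in data.detectors.covariates.items()},
            cov_constants=data.detectors.cov_constants,
        )
        d2 = StudyData(**{**data.__dict__})
        d2.detectors = det2
        d2.y_det = inv[data.y_det]
        assert marginal_loglik_forward(params, ac, d2) \
            == pytest.approx(base, abs=1e-9)


class TestSamplerInternals:
    def test_cached_likelihoods_match_references_in_both_modes(self):
        cfg = flagship_config(core_extent=(0.0, 0.0, 60.0, 60.0),
                              buffer_width=20.0, M=40, T=4, p0=0.2)
        data = prepare_from_synthetic(generate_study(cfg, 7))
        assert len(data.y_ind) > 0
        for mode in ("marginal", "latent"):
            mc = MCMCConfig(n_chains=2, n_iterations=20, burn_in=10, mode=mode,
                            seed=5, local_radius_factor=None)
            smp = _Sampler(data, Priors(), mc, np.random.default_rng(11))
            for _ in range(5):
                smp.step(False)
            params = params_from_vector(smp.pv, data)
            if mode == "marginal":
                ref = marginal_loglik_forward(params, smp.s, data)
                assert smp.L_z + smp.L_mov == pytest.approx(ref, abs=1e-9)
            else:
                ref = joint_loglik(params, smp.z + 1, smp.s, data)
                got = smp.L_demo + smp.L_det + smp.L_mov
                assert got == pytest.approx(ref, abs=1e-9)

    def test_local_evaluation_matches_reference_at_same_radius(self):
        cfg = flagship_config(core_extent=(0.0, 0.0, 60.0, 60.0),
                              buffer_width=20.0, M=30, T=3, p0=0.25)
        data = prepare_from_synthetic(generate_study(cfg, 8))
        mc = MCMCConfig(n_chains=2, n_iterations=20, burn_in=10, mode="marginal",
                        seed=5, local_radius_factor=6.0)
        smp = _Sampler(data, Priors(), mc, np.random.default_rng(12))
        for _ in range(4):
            smp.step(False)
        params = params_from_vector(smp.pv, data)
        radius = 6.0 * float(smp.pv["sigma"][0])
        ref = marginal_loglik_forward(params, smp.s, data, local_radius=radius)
        assert smp.L_z + smp.L_mov == pytest.approx(ref, abs=1e-9)


class TestRunMcmc:
    def test_fixed_seed_reproduces_draws_exactly(self):
        data = prepare_from_synthetic(tiny_study(
            M=25, psi=0.3, gamma=0.1, core_extent=(0.0, 0.0, 40.0, 40.0),
            buffer_width=0.0))
        cfg = MCMCConfig(n_chains=2, n_iterations=60, burn_in=20, seed=9,
                         mode="latent")
        a = run_mcmc(data, cfg)
        b = run_mcmc(data, cfg)
        for n in a.param_names:
            assert np.array_equal(a.draws[n], b.draws[n])

    def test_prior_only_run_recovers_the_prior(self):
        # no individuals at all: the posterior is exactly the prior
        study = tiny_study(collar_fraction=0.0, p0=1e-6, psi=0.01, M=4)
        data = prepare_from_synthetic(study, M=4)
        empty = StudyData(
            habitat=data.habitat, detectors=data.detectors, T=data.T, M=0,
            individual_ids=[], n_detected=0, group=np.zeros(0, dtype=int),
            region_of_group=data.region_of_group,
            gps=np.zeros((0, data.T), dtype=int),
            prev=np.zeros((0, data.T), dtype=int),
            masks=np.ones((0, data.T, 4), dtype=bool),
            y_ind=np.zeros(0, dtype=int), y_det=np.zeros(0, dtype=int),
            y_season=np.zeros(0, dtype=int), y_count=np.zeros(0, dtype=int),
        )
        cfg = MCMCConfig(n_chains=2, n_iterations=4000, burn_in=500, seed=2,
                         mode="marginal")
        res = run_mcmc(empty, cfg)
        bw = res.draws["beta_w_gps"].ravel()       # prior: Normal(0, 2)
        assert abs(bw.mean()) < 0.5
        assert abs(bw.std() - 2.0) < 0.6
        sig = res.draws["sigma[0]"].ravel()        # prior: Uniform(0, 10)
        assert abs(sig.mean() - 5.0) < 1.2
        psi = res.draws["psi[0]"].ravel()          # prior: Uniform(0, 1)
        assert abs(psi.mean() - 0.5) < 0.12

    def test_augmentation_limit_triggers_error(self):
        study = tiny_study(psi=0.95, gamma=0.4, M=8, p0=0.5)
        data = prepare_from_synthetic(study, M=8)
        data_sat = StudyData(**{**data.__dict__})
        keep = data.n_detected
        assert keep >= 2
        data_sat.M = keep                    # no free augmentation slots
        data_sat.group = data.group[:keep]
        data_sat.gps = data.gps[:keep]
        data_sat.prev = data.prev[:keep]
        data_sat.masks = data.masks[:keep]
        data_sat.individual_ids = data.individual_ids[:keep]
        cfg = MCMCConfig(n_chains=2, n_iterations=80, burn_in=20, seed=3,
                         mode="latent")
        with pytest.raises(RuntimeError, match="augmentation limit"):
            run_mcmc(data_sat, cfg)


class TestStratification:
    def test_four_groups_fit_with_shared_collar_effects(self):
        from opscr.simulate import StudyConfig
        cfg = StudyConfig(
            core_extent=(0.0, 0.0, 80.0, 40.0), buffer_width=20.0,
            n_regions=2, n_sexes=2, n_counties=2, T=3, M=60,
            psi=0.4, gamma=0.15, p0=0.25, sigma=5.0, tau=10.0,
            collar_fraction=0.3,
        )
        study = generate_study(cfg, 13)
        data = prepare_from_synthetic(study)
        assert data.n_groups == 4
        mc = MCMCConfig(n_chains=2, n_iterations=80, burn_in=30, seed=6,
                        mode="marginal")
        smp = _Sampler(data, Priors(), mc, np.random.default_rng(0))
        for i in range(10):
            smp.step(i % 5 == 4)
        # movement never crosses regions
        region = data.region_of_group[data.group]
        assert np.array_equal(data.habitat.region_id[smp.s.ravel()],
                              np.repeat(region, data.T))
        # group-specific intercepts exist; the collar effects stay scalar
        names = smp.flat_names()
        assert "h0[3,1]" in names and "sigma[3]" in names
        assert names.count("beta_w_gps") == 1

    def test_ac_draw_export_round_trip(self, tmp_path):
        from opscr.inference import export_ac_draws
        data = prepare_from_synthetic(tiny_study(
            M=15, core_extent=(0.0, 0.0, 40.0, 40.0), buffer_width=0.0))
        cfg = MCMCConfig(n_chains=2, n_iterations=30, burn_in=10, seed=1,
                         mode="latent", save_ac=True)
        res = run_mcmc(data, cfg)
        assert res.ac_draws.shape == (2, 20, data.M, data.T)
        out = tmp_path / "ac.csv"
        export_ac_draws(res, data, out)
        df = pd.read_csv(out)
        assert len(df) == 2 * 20 * data.M * data.T
        assert set(df.columns) == {"chain", "iteration", "individual",
                                   "season", "cell", "x", "y"}
        assert df["cell"].between(0, data.habitat.n_cells - 1).all()


class TestGelmanRubin:
    def test_identical_chains_give_one(self):
        x = np.tile(np.sin(np.arange(200.0)), (4, 1))
        assert gelman_rubin(x) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_chains_diverge(self):
        rng = np.random.default_rng(0)
        x = np.stack([rng.normal(0, 1, 500), rng.normal(50, 1, 500)])
        assert gelman_rubin(x) > 10

    def test_matches_textbook_formula_on_random_chains(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 400))
        # independent textbook evaluation on the split chains
        n = 200
        halves = np.concatenate([x[:, :200], x[:, 200:]], axis=0)
        W = halves.var(axis=1, ddof=1).mean()
        B = n * halves.mean(axis=1).var(ddof=1)
        expected = max(1.0, np.sqrt(((n - 1) / n * W + B / n) / W))
        assert gelman_rubin(x) == pytest.approx(float(expected), abs=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestCollarContrasts:
    def _degenerate_result(self, h0, w0, bh, bw, n=400):
        names = ["h0[0,0]", "w0[0,0]", "beta_h_gps", "beta_w_gps"]
        vals = [h0, w0, bh, bw]
        draws = {k: np.full((2, n), v) for k, v in zip(names, vals)}
        return PosteriorResult(draws=draws, param_names=names, config={},
                               acceptance={}, n_detected=0, M=0)

    def test_zero_effects_give_zero_differences(self):
        res = self._degenerate_result(logit(0.10), logit(0.25), 0.0, 0.0)
        c = derive_collar_contrasts(res, 0, 2)
        for cause in ("h", "w", "overall"):
            assert c[cause]["diff_pp"]["median"] == pytest.approx(0.0, abs=1e-9)

    def test_reported_overall_difference_of_sixteen_points(self):
        # collared (h, w) = (0.07, 0.12) vs non-collared (0.10, 0.25)
        bh = logit(0.07) - logit(0.10)
        bw = logit(0.12) - logit(0.25)
        res = self._degenerate_result(logit(0.10), logit(0.25), bh, bw)
        c = derive_collar_contrasts(res, 0, 2)
        assert c["overall"]["diff_pp"]["median"] == pytest.approx(16.0, abs=1e-6)
        assert c["overall"]["noncollared"]["median"] == pytest.approx(0.35)
        assert c["overall"]["collared"]["median"] == pytest.approx(0.19)

    def test_summaries_equal_recomputation_from_raw_chains(self):
        rng = np.random.default_rng(2)
        names = ["h0[0,0]", "w0[0,0]", "beta_h_gps", "beta_w_gps"]
        draws = {k: rng.normal(-1.5, 0.4, size=(2, 300)) for k in names}
        res = PosteriorResult(draws=draws, param_names=names, config={},
                              acceptance={}, n_detected=0, M=0)
        c = derive_collar_contrasts(res, 0, 2)
        w_nc = expit(draws["w0[0,0]"].ravel())
        w_c = expit(draws["w0[0,0]"].ravel() + draws["beta_w_gps"].ravel())
        diff = 100 * (w_nc - w_c)
        assert c["w"]["diff_pp"]["median"] == pytest.approx(np.median(diff))
        assert c["w"]["diff_pp"]["lo"] == pytest.approx(np.quantile(diff, 0.025))

    def test_unknown_group_season_raises(self):
        res = self._degenerate_result(0.0, 0.0, 0.0, 0.0)
        with pytest.raises(KeyError):
            derive_collar_contrasts(res, group=3, season=2)


class TestModeEquivalence:
    def test_latent_and_marginal_modes_sample_the_same_posterior(self):
        cfg = flagship_config(core_extent=(0.0, 0.0, 40.0, 40.0),
                              buffer_width=0.0, M=30, T=3, p0=0.3,
                              collar_fraction=0.3, psi=0.4, gamma=0.2)
        data = prepare_from_synthetic(generate_study(cfg, 21))
        draws = {}
        for mode in ("marginal", "latent"):
            mc = MCMCConfig(n_chains=1, n_iterations=14_000, burn_in=3000,
                            thinning=1, mode=mode, seed=17)
            draws[mode] = run_mcmc(data, mc)
        for name in ("psi[0]", "sigma[0]", "p0_int[0,0]"):
            a = draws["marginal"].draws[name].ravel()
            b = draws["latent"].draws[name].ravel()
            ks = ks_2samp(a, b).statistic
            assert ks < 0.05, f"{name}: KS={ks:.3f}"
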