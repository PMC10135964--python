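import numpy as np
import pytest

from inspeq.chem_model import ChemicalModel, SpeciesDef
from inspeq.equilibrium import SolutionConditions, fraction_matrix
from inspeq.nmr_titration import (
    FitOptions,
    ShiftBasis,
    TitrationDataset,
    TitrationPoint,
    fit_titration,
    model_selection,
    predict_shifts,
    protonation_step_shifts,
)
from inspeq.synthetic_data import demo_shift_basis, gen_titration


MONO_BASIS = ShiftBasis({("L", "P"): 2.0, ("HL", "P"): 0.0})


def make_mono_dataset(model, log_beta=7.0, ph=np.arange(4.0, 10.01, 0.5)):
    m = model.with_log_betas({"HL": log_beta})
    return gen_titration(m, MONO_BASIS, ph, noise_sd_ppm=0.0, nuclei=("P",))


class TestPredictShifts:
    def test_single_species(self, toy_monoprotic):
        out = predict_shifts(toy_monoprotic, MONO_BASIS, SolutionConditions(1e-3, ph=12.0))
        assert out["P"] == pytest.approx(2.0, abs=1e-4)

    def test_fifty_fifty_average(self, toy_monoprotic):
        out = predict_shifts(toy_monoprotic, MONO_BASIS, SolutionConditions(1e-3, ph=7.0))
        assert out["P"] == pytest.approx(1.0, rel=1e-8)

    def test_upfield_with_decreasing_ph(self, toy_monoprotic):
        shifts = [
            predict_shifts(toy_monoprotic, MONO_BASIS, SolutionConditions(1e-3, ph=p))["P"]
            for p in np.arange(9.0, 5.0, -0.5)
        ]
        assert all(a > b for a, b in zip(shifts, shifts[1:]))

    def test_missing_basis_entry_raises(self, toy_monoprotic):
        basis = ShiftBasis({("L", "P"): 2.0})  # no HL entry
        with pytest.raises(KeyError, match="HL"):
            predict_shifts(toy_monoprotic, basis, SolutionConditions(1e-3, ph=7.0))

    def test_convexity_bounds(self, insp8_h):
        basis = demo_shift_basis(insp8_h)
        for ph in [3.0, 6.0, 9.0, 12.0]:
            out = predict_shifts(insp8_h, basis, SolutionConditions(1e-3, ph=ph))
            for nuc, val in out.items():
                col = [basis.get(s.id, nuc) for s in insp8_h.species]
                assert min(col) - 1e-9 <= val <= max(col) + 1e-9


class TestFitTitration:
    def test_noiseless_round_trip(self, toy_monoprotic):
        data = make_mono_dataset(toy_monoprotic)
        fit = fit_titration(data, toy_monoprotic, FitOptions(start={"HL": 6.3}))
        val, sd = fit.refined_log_betas["HL"]
        assert val == pytest.approx(7.0, abs=1e-6)
        assert fit.sigma < 1e-6
        assert fit.converged

    def test_matches_brute_force_scan(self, toy_monoprotic):
        # independent 1-D oracle: scan log beta, projecting shifts per trial
        data = make_mono_dataset(toy_monoprotic)
        y, w = data.observation_matrix()
        cond = data.conditions_template

        def ssq(log_beta):
            F, ids, _, _ = fraction_matrix(
                toy_monoprotic, cond, data.ph_values, {"HL": log_beta}
            )
            d, *_ = np.linalg.lstsq(F, y[:, 0], rcond=None)
            r = F @ d - y[:, 0]
            return float(r @ r)

        grid = np.arange(6.0, 8.0001, 0.001)
        best = grid[int(np.argmin([ssq(b) for b in grid]))]
        fit = fit_titration(data, toy_monoprotic, FitOptions(start={"HL": 6.3}))
        assert fit.refined_log_betas["HL"][0] == pytest.approx(best, abs=0.001)

    def test_recovers_first_protonation_constant(self, insp8_h):
        basis = demo_shift_basis(insp8_h)
        data = gen_titration(insp8_h, basis, noise_sd_ppm=0.02, seed=11)
        start = {
            s.id: s.log_beta + 0.5 for s in insp8_h.species if not s.is_free_ligand
        }
        fit = fit_titration(
            data, insp8_h, FitOptions(start=start, fixed_basis=basis)
        )
        assert fit.refined_log_betas["HL"][0] == pytest.approx(11.21, abs=0.1)

    def test_missing_observations_reduce_n_obs(self, toy_monoprotic):
        data = make_mono_dataset(toy_monoprotic)
        pts = list(data.points)
        pts[2] = TitrationPoint(ph=pts[2].ph, observed={"P": pts[2].observed["P"]})
        full_n = data.n_observations
        # blank two points entirely is not allowed (>=1 obs per point), so
        # drop the points instead
        reduced = TitrationDataset(
            points=tuple(pts[:5] + pts[7:]), nuclei=data.nuclei,
            conditions_template=data.conditions_template,
        )
        fit = fit_titration(reduced, toy_monoprotic, FitOptions(start={"HL": 6.5}))
        assert fit.n_obs == full_n - 2
        assert fit.refined_log_betas["HL"][0] == pytest.approx(7.0, abs=1e-6)

    def test_never_populated_species_flagged(self, toy_monoprotic):
        m = ChemicalModel(
            "toy+ghost", -1,
            (
                SpeciesDef("L", 0, 0, 0, 0.0),
                SpeciesDef("HL", 1, 0, 0, 7.0),
                SpeciesDef("H2L", 2, 0, 0, 6.0),  # stepwise log K = -1: never populated
            ),
        )
        data = make_mono_dataset(toy_monoprotic)
        fit = fit_titration(data, m, FitOptions(refine=("HL",), start={"HL": 6.8}))
        assert "H2L" in fit.undetermined_species
        assert ("H2L", "P") not in fit.refined_basis.delta

    def test_sigma_scaled_by_dof(self, toy_monoprotic):
        data = make_mono_dataset(toy_monoprotic)
        fit = fit_titration(data, toy_monoprotic, FitOptions(start={"HL": 6.9}))
        # 13 observations, 1 nonlinear + 2 shift parameters
        assert fit.n_obs == 13
        assert fit.n_params == 3

    def test_weights_respected(self, toy_monoprotic):
        data = make_mono_dataset(toy_monoprotic)
        pts = [
            TitrationPoint(p.ph, dict(p.observed), weight=0.0 if i == 3 else 1.0)
            for i, p in enumerate(data.points)
        ]
        # corrupt the zero-weighted point; fit must be unaffected
        pts[3].observed["P"] = 99.0
        d2 = TitrationDataset(tuple(pts), data.nuclei, data.conditions_template)
        fit = fit_titration(d2, toy_monoprotic, FitOptions(start={"HL": 6.7}))
        assert fit.refined_log_betas["HL"][0] == pytest.approx(7.0, abs=1e-5)


class TestModelSelection:
    def test_parsimony_tie_break(self, toy_monoprotic):
        data = make_mono_dataset(toy_monoprotic)
        bloated = ChemicalModel(
            "toy+spurious", -1,
            (
                SpeciesDef("L", 0, 0, 0, 0.0),
                SpeciesDef("HL", 1, 0, 0, 7.0),
                SpeciesDef("H2L", 2, 0, 0, 9.5),
            ),
        )
        ranked = model_selection(data, [bloated, toy_monoprotic])
        assert ranked[0].model.ligand_name == "toy-monoprotic"

    def test_diprotic_beats_monoprotic_on_diprotic_data(self, toy_diprotic, toy_monoprotic):
        basis = ShiftBasis({("L", "P"): 2.0, ("HL", "P"): 1.2, ("H2L", "P"): 0.0})
        data = gen_titration(
            toy_diprotic, basis, np.arange(3.0, 11.01, 0.5), noise_sd_ppm=0.0,
            nuclei=("P",),
        )
        ranked = model_selection(data, [toy_monoprotic, toy_diprotic])
        assert ranked[0].model.ligand_name == "toy-diprotic"
        assert ranked[0].fit.sigma < ranked[1].fit.sigma

    def test_single_candidate(self, toy_monoprotic):
        data = make_mono_dataset(toy_monoprotic)
        ranked = model_selection(data, [toy_monoprotic])
        assert len(ranked) == 1 and ranked[0].fit is not None

    def test_all_failing_raises(self, toy_monoprotic):
        data = make_mono_dataset(toy_monoprotic)
        # model whose pH grid cannot be solved is hard to make; use an
        # underdetermined fit instead (more parameters than observations)
        tiny = TitrationDataset(data.points[:2], data.nuclei, data.conditions_template)
        with pytest.raises(RuntimeError, match="all candidate models failed"):
            model_selection(tiny, [toy_monoprotic])


class TestProtonationStepShifts:
    def test_single_moving_nucleus(self):
        m = ChemicalModel(
            "x", -3,
            (SpeciesDef("L", 0, 0, 0, 0.0), SpeciesDef("HL", 1, 0, 0, 7.0)),
        )
        basis = ShiftBasis({
            ("L", "P2"): 1.0, ("L", "P3"): 1.0,
            ("HL", "P2"): 1.0, ("HL", "P3"): 0.0,
        })
        steps = protonation_step_shifts(m, basis)
        assert len(steps) == 1
        assert steps[0].inferred_sites == ("P3",)
        assert steps[0].delta_delta["P3"] == pytest.approx(-1.0)

    def test_demo_basis_first_step_sites(self, insp8_h):
        basis = demo_shift_basis(insp8_h)
        steps = protonation_step_shifts(insp8_h, basis)
        assert steps[0].inferred_sites == ("P1b", "P3", "P5b")

    def test_all_zero_is_degenerate(self):
        m = ChemicalModel(
            "x", -1,
            (SpeciesDef("L", 0, 0, 0, 0.0), SpeciesDef("HL", 1, 0, 0, 7.0)),
        )
        basis = ShiftBasis({("L", "P"): 1.0, ("HL", "P"): 1.0})
        steps = protonation_step_shifts(m, basis)
        assert steps[0].degenerate and steps[0].inferred_sites == ()

    def test_gap_in_ladder_rejected(self):
        m = ChemicalModel(
            "x", -2,
            (
                SpeciesDef("L", 0, 0, 0, 0.0),
                SpeciesDef("H2L", 2, 0, 0, 12.0),
            ),
        )
        with pytest.raises(ValueError, match="gap"):
            protonation_step_shifts(m, ShiftBasis({("L", "P"): 0.0, ("H2L", "P"): 0.0}))


class TestDatasetValidation:
    def test_duplicate_ph_rejected(self, toy_monoprotic):
        pt = TitrationPoint(7.0, {"P": 1.0})
        with pytest.raises(ValueError, match="distinct"):
            TitrationDataset((pt, pt), ("P",), SolutionConditions(1e-3))

    def test_empty_point_rejected(self):
        with pytest.raises(ValueError, match="no observations"):
            TitrationPoint(7.0, {})

    def test_nonfinite_shift_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            TitrationPoint(7.0, {"P": float("nan")})


class TestRecoveryProperty:
    def test_constants_within_three_sd_in_95_percent_of_replicates(self, insp8_h):
        # noise sd 0.02 ppm on the standard grid; demo basis held fixed
        basis = demo_shift_basis(insp8_h)
        ids = [s.id for s in insp8_h.species if not s.is_free_ligand]
        truth = {sid: insp8_h.get(sid).log_beta for sid in ids}
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            data = gen_titration(insp8_h, basis, noise_sd_ppm=0.02, seed=seed)
            start = {sid: truth[sid] + 0.5 for sid in ids}
            fit = fit_titration(data, insp8_h, FitOptions(start=start, fixed_basis=basis))
            ok = all(
                abs(fit.refined_log_betas[sid][0] - truth[sid])
                <= 3 * fit.refined_log_betas[sid][1]
                for sid in ids
            )
            hits += ok
        assert hits / n_rep >= 0.95
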