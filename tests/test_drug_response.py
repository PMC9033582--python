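"""Response surfaces, sensitivity calls, Bliss synergy, and 4PL fitting."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mano import (
    DoseGrid,
    GrowthInhibition,
    ResponseSurface,
    bliss_synergy,
    build_surface,
    classify_sensitivity,
    cross_resistance_summary,
    fit_4pl,
    make_panel,
    simulate_screen,
)
from mano.drug_response import four_pl


def _surface(survival, a=None, o=None, variant="V"):
    survival = np.asarray(survival, dtype=float)
    a = np.concatenate([[0.0], np.geomspace(1e-9, 1e-8, survival.shape[0] - 1)]) if a is None else a
    o = np.concatenate([[0.0], np.geomspace(1e-9, 1e-8, survival.shape[1] - 1)]) if o is None else o
    return ResponseSurface(variant, a, o, survival)


class TestDoseGrid:
    def test_default_grid_has_72_combinations(self):
        grid = DoseGrid.default()
        assert grid.n_combinations == 72
        assert grid.afatinib[0] == pytest.approx(500e-12)
        assert grid.afatinib[-1] == pytest.approx(50e-9)
        assert grid.osimertinib[0] == pytest.approx(100e-12)
        assert grid.osimertinib[-1] == pytest.approx(10e-6)

    def test_nonmonotone_levels_rejected(self):
        with pytest.raises(ValueError):
            DoseGrid(afatinib=(1e-9, 1e-9), osimertinib=(1e-9, 2e-9))


class TestBuildSurface:
    def test_flat_input_gives_flat_surface(self):
        grid = DoseGrid.default()
        conditions = grid.conditions()
        values = pd.DataFrame(1.0, index=["V"], columns=conditions.index)
        gi = GrowthInhibition(values, values * np.nan, conditions)
        surface = build_surface(gi, grid, "V")
        assert np.allclose(surface.survival, 1.0)
        assert not surface.missing.any()

    def test_missing_cells_flagged_not_imputed(self):
        grid = DoseGrid.default()
        conditions = grid.conditions().iloc[:-3]
        values = pd.DataFrame(1.0, index=["V"], columns=conditions.index)
        gi = GrowthInhibition(values, values * np.nan, conditions)
        surface = build_surface(gi, grid, "V")
        assert surface.missing.sum() == 3

    def test_unknown_variant_raises(self, screen_gi, screen_sim):
        with pytest.raises(KeyError):
            build_surface(screen_gi, screen_sim.grid, "NOT_A_VARIANT")

    def test_archetype_surfaces_qualitative(self, screen_sim, screen_gi):
        """Drug-sensitive clones are depleted at top doses; dual-resistant
        clones keep vehicle-like growth everywhere."""
        by_type = {}
        for clone in screen_sim.panel:
            by_type.setdefault(clone.archetype, clone.variant_id)
        sens = build_surface(screen_gi, screen_sim.grid, by_type["sensitive_both"])
        assert sens.survival[-1, 0] < 0.1 and sens.survival[0, -1] < 0.1
        # dual-resistant clone: monotherapy barely dents it
        res = build_surface(screen_gi, screen_sim.grid, by_type["resistant_both"])
        assert (res.survival[:, 0] > 0.5).all() and (res.survival[0, :] > 0.5).all()
        # drug-inert reference clone: vehicle-like growth over the whole grid
        inert = build_surface(screen_gi, screen_sim.grid, "KRAS_G12V")
        assert np.allclose(inert.survival, 1.0, atol=0.15)


class TestClassification:
    @pytest.mark.parametrize(
        "survival,category",
        [(1.0, "resistant"), (0.5, "resistant"), (0.49, "partially_resistant"),
         (0.2, "partially_resistant"), (0.19, "sensitive"), (0.0, "sensitive")],
    )
    def test_threshold_mapping(self, survival, category):
        surf = _surface(np.full((3, 3), survival))
        surf.survival[0, 0] = 1.0
        call = classify_sensitivity(surf, "afatinib")
        assert call.category == category

    def test_missing_reference_dose_is_undetermined(self):
        surf = _surface(np.full((3, 3), np.nan))
        assert classify_sensitivity(surf, "osimertinib").category == "undetermined"

    @settings(max_examples=50, deadline=None)
    @given(s1=st.floats(0, 1.5), s2=st.floats(0, 1.5))
    def test_monotone_in_survival(self, s1, s2):
        """Raising survival never moves a variant toward 'sensitive'."""
        rank = {"sensitive": 0, "partially_resistant": 1, "resistant": 2}
        lo, hi = sorted((s1, s2))
        calls = [
            classify_sensitivity(_surface(np.full((2, 2), s)), "afatinib").category
            for s in (lo, hi)
        ]
        assert rank[calls[0]] <= rank[calls[1]]


class TestCrossResistance:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["afatinib", "osimertinib"])

    def test_study_composition_summary(self):
        from mano import make_call_table

        summary = cross_resistance_summary(make_call_table(seed=0))
        assert summary["nonsensitive_any"] == {"n": 50, "pct": 17.7}
        assert summary["resistant_both"] == {"n": 3, "pct": 1.1}
        assert summary["nonsensitive_both"] == {"n": 21, "pct": 7.4}
        assert summary["afatinib_nonsensitive"]["osimertinib_sensitive_pct"] == 16.0
        assert summary["osimertinib_nonsensitive"]["afatinib_sensitive_pct"] == 54.3

    def test_empty_call_set(self):
        assert cross_resistance_summary(self._table([]))["n_variants"] == 0

    def test_undetermined_excluded_and_counts_conserved(self):
        rng = np.random.default_rng(1)
        cats = ["sensitive", "partially_resistant", "resistant", "undetermined"]
        rows = [(cats[i], cats[j]) for i, j in rng.integers(0, 4, (300, 2))]
        table = self._table(rows)
        s = cross_resistance_summary(table)
        four_cells = (
            (s["n_variants"] - s["nonsensitive_any"]["n"])
            + s["afatinib_nonsensitive"]["osimertinib_sensitive_n"]
            + s["osimertinib_nonsensitive"]["afatinib_sensitive_n"]
            + s["nonsensitive_both"]["n"]
        )
        assert four_cells + s["n_undetermined"] == len(table)


class TestBliss:
    def test_independence_identity(self):
        # E_a = 0.5, E_o = 0.4, observed combined inhibition 0.70 -> score 0
        surf = _surface([[1.0, 0.6], [0.5, 0.3]])
        result = bliss_synergy(surf)
        assert result.scores[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_null_drug_identity(self):
        # inert first drug: expected inhibition equals the second drug's own
        surf = _surface([[1.0, 0.35], [1.0, 0.35]])
        assert bliss_synergy(surf).mean_score == pytest.approx(0.0, abs=1e-12)

    def test_multiplicative_surfaces_score_exactly_zero(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            sa = rng.uniform(0, 1, 5)
            so = rng.uniform(0, 1, 6)
            surv = np.empty((6, 7))
            surv[:, 0] = np.concatenate([[1.0], sa])
            surv[0, :] = np.concatenate([[1.0], so])
            surv[1:, 1:] = sa[:, None] * so[None, :]
            scores = bliss_synergy(_surface(surv)).scores
            assert (scores == 0.0).all()  # exact, not approximate

    def test_agrees_with_brute_force_oracle(self):
        """Per-cell scores match an independent inhibition-space
        recomputation E_a + E_o - E_a*E_o on random surfaces."""
        rng = np.random.default_rng(34)
        for _ in range(200):
            surv = rng.uniform(0, 1, (5, 6))
            surv[0, 0] = 1.0
            result = bliss_synergy(_surface(surv))
            inh = 1.0 - surv
            for i in range(1, 5):
                for j in range(1, 6):
                    expected = inh[i, 0] + inh[0, j] - inh[i, 0] * inh[0, j]
                    oracle = 100.0 * ((1.0 - surv[i, j]) - expected)
                    assert abs(result.scores[i - 1, j - 1] - oracle) < 1e-12

    def test_out_of_range_cells_clipped_with_warning(self):
        surf = _surface([[1.0, 0.5], [1.3, 0.4]])
        with pytest.warns(UserWarning, match="clipped"):
            result = bliss_synergy(surf)
        assert result.clipped_cells == 1
        # clipped monotherapy survival 1.0 -> expected survival = s_o
        assert result.scores[0, 0] == pytest.approx(100 * (0.5 - 0.4))

    def test_epsilon_injection_shifts_scores_positive(self):
        """Clones with an interaction term score higher than Bliss-null
        clones analysed identically (synergy detection power)."""
        def mean_scores(eps):
            panel = make_panel(10, seed=21, epsilon=eps)
            sim = simulate_screen(panel, depth=300_000, seed=21)
            from mano import collapse_clones, relative_growth_inhibition, scale_to_reference

            counts = collapse_clones(sim.counts, sim.barcode_map)
            gi = relative_growth_inhibition(
                scale_to_reference(counts, "KRAS_G12V"), sim.counts.samples
            )
            out = []
            for clone in sim.panel:
                if clone.archetype != "sensitive_both":
                    continue
                surf = build_surface(gi, sim.grid, clone.variant_id)
                out.append(bliss_synergy(surf).mean_score)
            return np.mean(out)

        assert mean_scores(0.4) > mean_scores(0.0) + 3.0


class TestFourPL:
    def test_noiseless_recovery(self):
        doses = np.geomspace(1e-10, 1e-6, 8)
        y = four_pl(doses, 1.0, 0.0, 10e-9, 1.0)
        fit = fit_4pl(doses, y)
        assert fit.ic50 == pytest.approx(10e-9, rel=1e-3)
        assert fit.hill == pytest.approx(1.0, rel=1e-3)

    def test_midpoint_identity(self):
        assert four_pl(np.array([5e-9]), 1.0, 0.0, 5e-9, 2.7)[0] == pytest.approx(0.5)

    def test_noisy_simulation_median_error(self):
        """1% Gaussian noise, 8 doses: median relative IC50 error < 5%."""
        rng = np.random.default_rng(100)
        errors = []
        for _ in range(100):
            doses = np.geomspace(1e-10, 1e-6, 8)
            ic50 = 10 ** rng.uniform(-8.5, -7.0)
            hill = rng.uniform(0.8, 2.5)
            y = four_pl(doses, 1.0, 0.0, ic50, hill) + rng.normal(0, 0.01, 8)
            fit = fit_4pl(doses, y)
            errors.append(abs(fit.ic50 - ic50) / ic50)
        assert np.median(errors) < 0.05

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            fit_4pl(np.array([1e-9, 1e-8, 1e-7]), np.array([1.0, 0.5, 0.0]))
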