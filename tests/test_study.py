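"""Common-load convention, stress-change statistics, sweep orchestration."""

import numpy as np
import pytest

from conftest import column_model
from vertefem.fe_core import (
    assemble_and_solve,
    element_stresses,
    segment_stiffness,
    von_mises,
)
from vertefem.study import (
    COMMON_REACTION_N,
    StressChangeHistogram,
    TreatmentConfig,
    default_bin_edges,
    histogram,
    run_sweep,
    scale_to_common_load,
    stress_change,
)


class TestScaleToCommonLoad:
    def test_already_at_target_unchanged(self):
        model = column_model([100.0])
        res = assemble_and_solve(model, 0.01)  # reaction = 1 N
        out = scale_to_common_load(res, res.reaction)
        assert out.reaction == res.reaction
        assert np.array_equal(out.displacements, res.displacements)

    def test_halved_reaction_doubles_stresses(self):
        model = column_model([100.0, 50.0])
        res = assemble_and_solve(model, 0.1)
        out = scale_to_common_load(res, 2.0 * res.reaction)
        s1 = element_stresses(model, res)
        s2 = element_stresses(model, out)
        assert np.allclose(s2, 2.0 * s1)

    def test_stiffness_invariant(self):
        model = column_model([80.0, 120.0])
        res = assemble_and_solve(model, 0.1)
        out = scale_to_common_load(res, 1000.0)
        assert out.reaction == pytest.approx(1000.0)
        assert segment_stiffness(out).k == pytest.approx(segment_stiffness(res).k)

    def test_negative_reaction_rejected(self):
        model = column_model([100.0])
        res = assemble_and_solve(model, 0.01).scaled(-1.0)
        with pytest.raises(ValueError):
            scale_to_common_load(res, 1000.0)


def _common(res):
    return scale_to_common_load(res, COMMON_REACTION_N)


@pytest.fixture(scope="module")
def small_models(small_phantom, small_modulus):
    from vertefem.fe_core import build_model
    from vertefem.phantom import add_cement_region
    from vertefem.treatment import apply_augmentation

    _, labels = small_phantom
    lab_cem = add_cement_region(labels, "T12", 0.2)
    pre = build_model(lab_cem, small_modulus)
    post = apply_augmentation(pre, ("T12",))
    r_pre = _common(assemble_and_solve(pre, 0.5))
    r_post = _common(assemble_and_solve(post, 0.5))
    return pre, post, r_pre, r_post


class TestStressChange:
    def test_identical_models_zero_change(self, small_models):
        pre, _, r_pre, _ = small_models
        ch, n_undef, n_tot = stress_change(r_pre, r_pre, pre, pre, "L1")
        assert np.allclose(ch, 0.0, atol=1e-9)
        assert n_undef + len(ch) == n_tot

    def test_global_modulus_scaling_is_invisible_at_fixed_load(self, small_models):
        """Scaling every modulus by a common factor changes nothing at a
        fixed reaction force: stress at given load is scale-free."""
        pre, _, r_pre, _ = small_models
        scaled = pre.copy()
        scaled.elem_E = 2.0 * scaled.elem_E
        scaled.annulus = pre.annulus.scaled(2.0)
        r_scaled = _common(assemble_and_solve(scaled, 0.5))
        ch, _, _ = stress_change(r_pre, r_scaled, pre, scaled, "L1")
        assert np.max(np.abs(ch)) < 1e-6

    def test_hand_built_twenty_percent(self):
        """Uniform 10 MPa pre vs 12 MPa post stress -> +20% everywhere."""
        model = column_model([100.0, 100.0, 100.0])
        res = assemble_and_solve(model, 0.3)  # sigma_zz = -10 MPa
        res.reaction = COMMON_REACTION_N  # bypass rescaling for the fixture
        post = res.scaled(1.0)
        post.displacements = 1.2 * res.displacements  # 12 MPa
        post.reaction = COMMON_REACTION_N
        ch, n_undef, n_tot = stress_change(res, post, model, model, "T12")
        # the 1x1 column is labelled trabecular_T12 by column_model
        assert n_tot == 3 and n_undef == 0
        assert np.allclose(ch, 20.0, atol=1e-9)

    def test_mesh_mismatch_rejected(self, small_models):
        pre, _, r_pre, _ = small_models
        other = column_model([1.0])
        r_other = assemble_and_solve(other, 0.1)
        r_other.reaction = COMMON_REACTION_N
        with pytest.raises(ValueError, match="mesh"):
            stress_change(r_pre, r_other, pre, other, "L1")

    def test_requires_common_load(self, small_models):
        pre, post, r_pre, _ = small_models
        raw = assemble_and_solve(post, 0.5)
        with pytest.raises(ValueError, match="common"):
            stress_change(r_pre, raw, pre, post, "L1")


class TestHistogram:
    def test_all_zero_changes_in_zero_bin(self):
        h = histogram(np.zeros(50), 0, 50)
        edges = h.bin_edges
        zero_bin = np.searchsorted(edges, 0.0, side="right")
        assert h.fractions[zero_bin] == pytest.approx(1.0)
        assert h.undefined_fraction == 0.0

    def test_uniform_changes_match_direct_count(self):
        rng = np.random.default_rng(1)
        ch = rng.uniform(-150, 150, 1000)
        edges = default_bin_edges()
        h = histogram(ch, 0, 1000, bin_edges=edges)
        # brute-force count per bin, tails included
        full_edges = np.concatenate([[-np.inf], edges, [np.inf]])
        for b in range(len(full_edges) - 1):
            n = np.sum((ch >= full_edges[b]) & (ch < full_edges[b + 1]))
            assert h.fractions[b] == pytest.approx(n / 1000)

    def test_mass_conservation_with_undefined(self):
        ch = np.array([5.0, -20.0, 300.0])
        h = histogram(ch, 7, 10)
        assert h.fractions.sum() + h.undefined_fraction == pytest.approx(1.0)
        assert h.undefined_fraction == pytest.approx(0.7)

    def test_half_open_binning(self):
        # a change exactly at an edge belongs to the upper bin
        h = histogram(np.array([10.0]), 0, 1)
        edges = h.bin_edges
        bin_of_10 = np.searchsorted(edges, 10.0, side="right")
        assert h.fractions[bin_of_10] == pytest.approx(1.0)

    def test_bad_edges(self):
        with pytest.raises(ValueError):
            histogram(np.zeros(3), 0, 3, bin_edges=np.array([0.0, 0.0, 1.0]))

    def test_count_mismatch(self):
        with pytest.raises(ValueError):
            histogram(np.zeros(3), 1, 3)


@pytest.fixture(scope="module")
def sweep(small_spec, tmp_path_factory):
    cells = [
        TreatmentConfig(augmented_levels=(), label="untreated"),
        TreatmentConfig(augmented_levels=("L1",), label="augment_L1"),
    ]
    out = tmp_path_factory.mktemp("sweep")
    return run_sweep(cells, spec=small_spec, target_k=400.0, out_dir=out), out


class TestRunSweep:
    def test_untreated_cell_matches_calibration(self, sweep):
        result, _ = sweep
        untreated = next(r for r in result.records if r.config.label == "untreated")
        assert untreated.k == pytest.approx(result.calibration.achieved_k, rel=1e-6)
        assert result.calibration.converged

    def test_augmentation_stiffens(self, sweep):
        result, _ = sweep
        ks = {r.config.label: r.k for r in result.records}
        assert ks["augment_L1"] > ks["untreated"]

    def test_histogram_mass_conserved(self, sweep):
        result, _ = sweep
        augmented = next(r for r in result.records if r.config.label == "augment_L1")
        assert augmented.histograms  # untreated cells carry none
        for h in augmented.histograms.values():
            assert h.fractions.sum() + h.undefined_fraction == pytest.approx(1.0)

    def test_csv_outputs(self, sweep):
        result, out = sweep
        import pandas as pd

        stiff = pd.read_csv(out / "stiffness.csv")
        assert set(stiff["cell"]) == {r.config.describe() for r in result.records}
        hist = pd.read_csv(out / "histograms.csv")
        mass = hist.groupby(["cell", "vertebra"])["fraction"].sum()
        assert np.allclose(mass.values, 1.0)

    def test_no_failures(self, sweep):
        result, _ = sweep
        assert result.failures == []
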