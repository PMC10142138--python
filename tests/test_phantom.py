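"""Phantom rendering, rasterization and agent-effect models."""

import numpy as np
import pytest

from tumorcontrast import (AgentEffect, ContainmentError, Ellipse, PhantomSpec,
                           ValidationError, apply_agent, builtin_effects,
                           render_phantom, roi_means)


class TestRenderPhantom:
    def test_noiseless_compartment_values(self, small_phantom):
        """Tumor/tissue pixels carry exact baselines; background is zero."""
        t1w, t2w, rois = small_phantom
        background = ~(rois.tumor_mask | rois.tissue_mask)
        for img, baseline in ((t1w, 100.0), (t2w, 70.0)):
            assert np.all(img.pixels[rois.tumor_mask] == baseline)
            assert np.all(img.pixels[rois.tissue_mask] == baseline)
            assert np.all(img.pixels[background] == 0.0)
            # noiseless homogeneity: zero spread within each compartment
            assert img.pixels[rois.tumor_mask].std() == 0.0
            assert img.pixels[rois.tissue_mask].std() == 0.0

    def test_roi_means_equal_baselines(self, small_phantom):
        t1w, t2w, rois = small_phantom
        assert roi_means(t1w, rois) == (100.0, 100.0)
        assert roi_means(t2w, rois) == (70.0, 70.0)

    def test_masks_partition_grid(self, small_phantom):
        """Every pixel is exactly one of tumor, tissue, background."""
        _, _, rois = small_phantom
        assert not (rois.tumor_mask & rois.tissue_mask).any()
        assert rois.tumor_mask.any() and rois.tissue_mask.any()

    def test_geometry_independence_of_means(self):
        """Any containment-valid geometry gives identical noiseless ROI means."""
        spec = PhantomSpec(grid_width=120, grid_height=90,
                           tissue_ellipse=Ellipse(60, 45, 50, 35, rotation=30),
                           tumor_ellipse=Ellipse(70, 50, 12, 8, rotation=75))
        t1w, t2w, rois = render_phantom(spec)
        assert roi_means(t1w, rois) == (100.0, 100.0)
        assert roi_means(t2w, rois) == (70.0, 70.0)

    def test_tumor_outside_tissue_rejected(self):
        spec = PhantomSpec(tissue_ellipse=Ellipse(128, 128, 40, 30),
                           tumor_ellipse=Ellipse(200, 128, 30, 20))
        with pytest.raises(ContainmentError):
            render_phantom(spec)

    @pytest.mark.parametrize("kwargs", [
        {"grid_width": 0},
        {"grid_height": -5},
        {"s_t1w_tumor": -1.0},
        {"noise_sigma": -0.1},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            PhantomSpec(**kwargs)

    def test_nonpositive_semi_axes_rejected(self):
        with pytest.raises(ValidationError):
            Ellipse(10, 10, 0, 5)

    def test_noisy_mean_near_baseline_and_seed_deterministic(self):
        """Noisy tumor mean lies within 3 SE of 100 au; same seed, same pixels."""
        spec = PhantomSpec(noise_sigma=5.0, seed=42)
        t1w_a, _, rois = render_phantom(spec)
        t1w_b, _, _ = render_phantom(spec)
        np.testing.assert_array_equal(t1w_a.pixels, t1w_b.pixels)
        n = rois.tumor_mask.sum()
        se = 5.0 / np.sqrt(n)
        s_tu, _ = roi_means(t1w_a, rois)
        assert abs(s_tu - 100.0) < 3 * se
        # independent oracle: direct mean over the mask's pixel indices
        idx = np.argwhere(rois.tumor_mask)
        direct = np.mean([t1w_a.pixels[i, j] for i, j in idx])
        assert s_tu == pytest.approx(direct)

    def test_different_seeds_differ(self):
        a, _, _ = render_phantom(PhantomSpec(noise_sigma=5.0, seed=1))
        b, _, _ = render_phantom(PhantomSpec(noise_sigma=5.0, seed=2))
        assert not np.array_equal(a.pixels, b.pixels)

    def test_rician_noise_positive(self):
        spec = PhantomSpec(noise_sigma=5.0, noise_model="rician", seed=3)
        t1w, t2w, _ = render_phantom(spec)
        assert t1w.pixels.min() >= 0 and t2w.pixels.min() >= 0


class TestAgentEffects:
    def test_builtin_effects_are_the_three_targeted_agents(self):
        effects = {e.name: e for e in builtin_effects()}
        assert set(effects) == {"t1", "t2", "dual"}
        for e in effects.values():
            assert e.is_targeted
        assert effects["t1"].f_t1w_tumor == +0.5 and effects["t1"].f_t2w_tumor == 0
        assert effects["t2"].f_t2w_tumor == -0.5 and effects["t2"].f_t1w_tumor == 0
        # dual is t1 and t2 merged field-wise
        assert effects["dual"].f_t1w_tumor == effects["t1"].f_t1w_tumor
        assert effects["dual"].f_t2w_tumor == effects["t2"].f_t2w_tumor

    @pytest.mark.parametrize("agent,expected_tu", [
        ("t1", (150.0, 70.0)),
        ("t2", (100.0, 35.0)),
        ("dual", (150.0, 35.0)),
    ])
    def test_post_injection_means(self, small_phantom, agents, agent, expected_tu):
        t1w, t2w, rois = small_phantom
        p1, p2 = apply_agent(t1w, t2w, rois, agents[agent])
        assert roi_means(p1, rois)[0] == pytest.approx(expected_tu[0])
        assert roi_means(p2, rois)[0] == pytest.approx(expected_tu[1])
        # perfect targeting: tissue untouched
        assert roi_means(p1, rois)[1] == pytest.approx(100.0)
        assert roi_means(p2, rois)[1] == pytest.approx(70.0)

    def test_zero_effect_is_identity(self, small_phantom):
        t1w, t2w, rois = small_phantom
        p1, p2 = apply_agent(t1w, t2w, rois, AgentEffect("null"))
        np.testing.assert_array_equal(p1.pixels, t1w.pixels)
        np.testing.assert_array_equal(p2.pixels, t2w.pixels)

    @pytest.mark.parametrize("f", [-0.5, -0.2, 0.3, 0.5, 1.0])
    def test_twice_applied_equals_composed_fraction(self, small_phantom, f):
        """Applying fraction f twice equals one application of (1+f)^2 - 1."""
        t1w, t2w, rois = small_phantom
        once = AgentEffect("a", f_t1w_tumor=f, f_t2w_tumor=f)
        twice_1, twice_2 = apply_agent(*apply_agent(t1w, t2w, rois, once),
                                       rois, once)
        comp = AgentEffect("aa", f_t1w_tumor=(1 + f) ** 2 - 1,
                           f_t2w_tumor=(1 + f) ** 2 - 1)
        one_1, one_2 = apply_agent(t1w, t2w, rois, comp)
        np.testing.assert_allclose(twice_1.pixels, one_1.pixels)
        np.testing.assert_allclose(twice_2.pixels, one_2.pixels)

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValidationError):
            AgentEffect("bad", f_t2w_tumor=-1.5)

    def test_composed_helper_matches_sequential(self, small_phantom, agents):
        t1w, t2w, rois = small_phantom
        seq = apply_agent(*apply_agent(t1w, t2w, rois, agents["t1"]),
                          rois, agents["t2"])
        merged = apply_agent(t1w, t2w, rois, agents["t1"].composed(agents["t2"]))
        np.testing.assert_allclose(seq[0].pixels, merged[0].pixels)
        np.testing.assert_allclose(seq[1].pixels, merged[1].pixels)
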