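"""Deposition-profile processing: edges, alignment, filtering, statistics."""

import numpy as np
import pytest

from clotflow.profiles import (DepositionProfile, align_profiles,
                               detect_edges, ensemble_stats, filter_spurious,
                               profile_center, profiles_from_dataframe,
                               profiles_to_dataframe)

GRID = np.arange(0.0, 600.5, 1.0)


def bump(center, half=60.0, height=10.0, grid=GRID):
    arg = (grid - center) / half
    v = np.where(np.abs(arg) < 1, height * np.cos(0.5 * np.pi * arg) ** 2, 0.0)
    return DepositionProfile(x=grid.copy(), value=v)


class TestDetectEdges:
    def test_symmetric_triangle_centers_at_peak(self):
        v = np.clip(30.0 - np.abs(GRID - 250.0), 0.0, None)
        p = DepositionProfile(x=GRID.copy(), value=v)
        assert profile_center(p) == pytest.approx(250.0, abs=0.5)

    def test_boxcar_edges(self):
        v = np.where((GRID >= 280) & (GRID <= 320), 5.0, 0.0)
        p = DepositionProfile(x=GRID.copy(), value=v)
        up, down = detect_edges(p)
        assert up == pytest.approx(280.0, abs=1.0)
        assert down == pytest.approx(320.0, abs=1.0)

    def test_lower_level_gives_wider_interval(self):
        p = bump(300.0)
        lo = detect_edges(p, level=0.1)
        hi = detect_edges(p, level=0.2)
        assert lo[0] <= hi[0] and lo[1] >= hi[1]

    def test_zero_profile_raises(self):
        p = DepositionProfile(x=GRID.copy(), value=np.zeros_like(GRID))
        with pytest.raises(ValueError, match="no accumulation"):
            detect_edges(p)


class TestAlignProfiles:
    def test_shifted_copies_collapse(self):
        profs = [bump(300.0 + s) for s in (-20.0, 0.0, 30.0)]
        ens = align_profiles(profs)
        vals = ens.values()
        peak = vals.max()
        for a in range(len(profs)):
            for b in range(a + 1, len(profs)):
                rms = np.sqrt(np.mean((vals[a] - vals[b]) ** 2))
                assert rms < 0.01 * peak

    def test_centered_profile_unchanged(self):
        p = bump(300.0)
        ens = align_profiles([p])
        np.testing.assert_allclose(ens.profiles[0].value, p.value, atol=1e-9)

    def test_alignment_is_idempotent(self):
        profs = [bump(300.0 + s) for s in (-15.0, 25.0)]
        once = align_profiles(profs)
        twice = align_profiles(once.profiles)
        np.testing.assert_allclose(twice.values(), once.values(), atol=1e-9)

    def test_random_shift_recovery(self):
        """Known U(-40, 40) µm shifts are recovered with r > 0.99."""
        rng = np.random.default_rng(42)
        shifts = rng.uniform(-40.0, 40.0, 20)
        profs = [bump(300.0 + s) for s in shifts]
        recovered = np.array([profile_center(p) - 300.0 for p in profs])
        r = np.corrcoef(shifts, recovered)[0, 1]
        assert r > 0.99


class TestFilterSpurious:
    def test_clean_profiles_kept(self):
        kept, rejected = filter_spurious([bump(290.0), bump(310.0)])
        assert len(kept) == 2 and not rejected

    def test_twin_peaks_rejected_with_reason(self):
        p = bump(250.0)
        twin = DepositionProfile(x=GRID.copy(),
                                 value=p.value + bump(450.0).value)
        kept, rejected = filter_spurious([twin])
        assert not kept and "peak" in rejected[0][1] or "outside" in rejected[0][1]

    def test_empty_input_empty_output(self):
        kept, rejected = filter_spurious([])
        assert kept == [] and rejected == []

    def test_rules_are_translation_invariant(self):
        """Filtering before vs after alignment keeps the same profiles."""
        rng = np.random.default_rng(5)
        profs = []
        for i in range(12):
            p = bump(300.0 + rng.uniform(-40, 40))
            if i % 4 == 0:
                p = DepositionProfile(
                    x=GRID.copy(),
                    value=p.value + bump(p.x[np.argmax(p.value)] + 160.0,
                                         half=30.0, height=8.0).value)
            profs.append(p)
        kept_before, _ = filter_spurious(profs)
        aligned = align_profiles(profs)
        kept_after, _ = filter_spurious(aligned.profiles)
        assert len(kept_before) == len(kept_after)


class TestEnsembleStats:
    def test_identical_profiles_have_zero_sd(self):
        ens = align_profiles([bump(300.0)] * 3)
        mean, sd, n = ensemble_stats(ens)
        assert n == 3
        assert np.all(sd <= 1e-12 * np.max(mean))

    def test_two_constant_profiles(self):
        a = DepositionProfile(x=GRID.copy(), value=np.zeros_like(GRID))
        b = DepositionProfile(x=GRID.copy(), value=np.full_like(GRID, 2.0))
        from clotflow.profiles import ProfileEnsemble
        ens = ProfileEnsemble(x=GRID, profiles=[a, b])
        mean, sd, n = ensemble_stats(ens)
        assert np.all(mean == 1.0)
        assert np.all(sd == pytest.approx(np.sqrt(2.0)))

    def test_single_profile_flags_undefined_sd(self):
        ens = align_profiles([bump(300.0)])
        mean, sd, n = ensemble_stats(ens)
        assert n == 1 and sd is None

    def test_sem_shrinks_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(11)

        def sem(n):
            reps = []
            for _ in range(200):
                vals = 10.0 + rng.normal(0, 1.0, n)
                reps.append(vals.mean())
            return np.std(reps)

        assert sem(40) < sem(10)
        assert sem(40) == pytest.approx(sem(10) / 2.0, rel=0.25)


class TestRoundTrip:
    def test_dataframe_round_trip(self):
        p = bump(300.0)
        p.condition, p.donor, p.repetition, p.time_s = "long_high", 1, 2, 400.0
        df = profiles_to_dataframe([p])
        back = profiles_from_dataframe(df)
        assert len(back) == 1
        np.testing.assert_allclose(back[0].value, p.value)
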