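"""Synthetic-data generator: determinism, ground truth, recoverability."""

import numpy as np
import pandas as pd
import pytest

from clotflow.profiles import (align_profiles, ensemble_stats,
                               filter_spurious, profile_center)
from clotflow.stats import SampleSet, compare_conditions
from clotflow.synth import (ConditionSpec, default_condition_specs,
                            generate_kinetics, generate_profiles)


def clean_spec(**kw):
    base = dict(name="short_low", surface_length=20.0, tf_density=0.1,
                peak_height_mean=7.5, peak_height_sd=0.0, noise_sd=0.0,
                center_jitter_sd=0.0, spurious_probability=0.0, donor_cv=0.0)
    base.update(kw)
    return ConditionSpec(**base)


class TestGenerateProfiles:
    def test_noise_free_profiles_are_identical(self):
        ds = generate_profiles(clean_spec(), seed=1)
        vals = np.vstack([p.value for p in ds.profiles])
        assert np.all(vals == vals[0])
        ens = align_profiles(ds.profiles)
        _, sd, _ = ensemble_stats(ens)
        assert np.all(sd <= 1e-12)

    def test_same_seed_is_bit_exact(self):
        spec = default_condition_specs()["long_high"]
        a = generate_profiles(spec, seed=42)
        b = generate_profiles(spec, seed=42)
        for pa, pb in zip(a.profiles, b.profiles):
            assert np.array_equal(pa.value, pb.value)
        assert a.ground_truth.equals(b.ground_truth)

    def test_ground_truth_covers_every_profile(self):
        spec = default_condition_specs()["short_high"]
        ds = generate_profiles(spec, times=(200.0, 400.0), seed=3)
        assert len(ds.ground_truth) == len(ds.profiles) == 5 * 4 * 2

    def test_peak_height_recovered_through_pipeline(self):
        """short/low spec: the pipeline-recovered mean peak height lands
        within 2 SD/sqrt(n) of the configured 7.5 µm."""
        spec = default_condition_specs()["short_low"]
        ds = generate_profiles(spec, seed=7)
        kept, _ = filter_spurious(ds.profiles)
        ens = align_profiles(kept)
        mean, sd, n = ensemble_stats(ens)
        recovered = mean.max()
        band = 2 * sd.max() / np.sqrt(n)
        assert abs(recovered - 7.5) < band

    def test_spurious_rate_matches_binomial_band(self):
        """Injection probability 0.2 over n=100 events: the filter rejects
        20% +- 8% (binomial 95% band)."""
        spec = default_condition_specs()["long_low"]
        spec = ConditionSpec(**{**spec.__dict__,
                                "spurious_probability": 0.2})
        ds = generate_profiles(spec, n_donors=25, n_reps=4, seed=11)
        kept, rejected = filter_spurious(ds.profiles)
        frac = len(rejected) / len(ds.profiles)
        assert 0.12 <= frac <= 0.28

    def test_filter_recall_and_precision_on_labels(self):
        spec = default_condition_specs()["long_high"]
        spec = ConditionSpec(**{**spec.__dict__,
                                "spurious_probability": 0.3})
        ds = generate_profiles(spec, n_donors=20, n_reps=4, seed=13)
        truth = ds.ground_truth.set_index(["donor", "repetition"])
        kept, rejected = filter_spurious(ds.profiles)
        rej_ids = {(p.donor, p.repetition) for p, _ in rejected}
        true_ids = {tuple(i) for i in
                    truth[truth["spurious"]].index.unique()}
        tp = len(rej_ids & true_ids)
        recall = tp / len(true_ids)
        precision = tp / max(len(rej_ids), 1)
        assert recall >= 0.9 and precision >= 0.9

    def test_center_recovery_correlates_with_injected_jitter(self):
        spec = default_condition_specs()["long_high"]
        ds = generate_profiles(ConditionSpec(**{**spec.__dict__,
                                                "spurious_probability": 0.0}),
                               n_donors=10, n_reps=2, seed=17)
        truth = ds.ground_truth["true_center"].to_numpy()
        centers = np.array([profile_center(p) for p in ds.profiles])
        assert np.corrcoef(truth, centers)[0, 1] > 0.99


class TestGenerateKinetics:
    def test_noise_free_plateau_ratio_is_exact(self):
        specs = {k: ConditionSpec(**{**v.__dict__, "donor_cv": 0.0})
                 for k, v in default_condition_specs().items()}
        df = generate_kinetics(specs, noise_cv=0.0, event_cv=0.0, seed=0)
        at450 = df[df["time_s"] == 450.0]
        med = at450.groupby(["condition", "analyte"])["value"].mean()
        ratio = med[("long_high", "thrombin")] / med[("short_low", "thrombin")]
        assert ratio == pytest.approx(20.0, rel=1e-9)

    def test_significance_pattern_of_combined_condition(self):
        """With default noise and N~20 per condition, long_high differs from
        every other condition at 450 s after Bonferroni, for thrombin and
        fibrin."""
        df = generate_kinetics(seed=2)
        at450 = df[df["time_s"] == 450.0]
        for analyte in ("thrombin", "fibrin"):
            sub = at450[at450["analyte"] == analyte]
            samples = {c: SampleSet(c, g["value"].to_numpy())
                       for c, g in sub.groupby("condition")}
            rep = compare_conditions(samples, "long_high")
            assert all(r["significant"] for r in rep.values()), analyte

    def test_identical_specs_rarely_flag_differences(self):
        """All four conditions identical: the pipeline flags no adjusted
        significance in most replicates (type-I control)."""
        base = default_condition_specs()["short_low"]
        # donor_cv = 0: calibration of the comparison machinery itself,
        # without the donor-clustering design effect that pooling ignores
        specs = {name: ConditionSpec(**{**base.__dict__, "name": name,
                                        "donor_cv": 0.0})
                 for name in ("short_low", "short_high", "long_low",
                              "long_high")}
        flags = 0
        for rep in range(30):
            df = generate_kinetics(specs, seed=100 + rep)
            at450 = df[(df["time_s"] == 450.0)
                       & (df["analyte"] == "thrombin")]
            samples = {c: SampleSet(c, g["value"].to_numpy())
                       for c, g in at450.groupby("condition")}
            out = compare_conditions(samples, "long_high")
            flags += any(r["significant"] for r in out.values())
        assert flags <= 6   # ~binomial(30, 0.05·3 joint) upper band
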