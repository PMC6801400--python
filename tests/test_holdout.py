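import numpy as np
import pytest

from pathsampler import (
    EmptyAcceptanceError,
    HoldoutConfig,
    SyntheticSpec,
    ValidationError,
    generate_bags,
    generate_two_class_dataset,
    run_holdout_sampler,
    top_probes,
)

from conftest import make_dataset, random_two_class


def sized_dataset(n_case, n_control, seed=0, **kwargs):
    spec = SyntheticSpec(n_samples_per_class=(n_case, n_control), n_probes=30,
                         n_informative=2, effect_size=3.0, seed=seed, **kwargs)
    return generate_two_class_dataset(spec)[0]


class TestGenerateBags:
    def test_75_25_arithmetic(self):
        ds = sized_dataset(15, 13)  # n = 28, as in a small clinical cohort
        bags = generate_bags(ds, n_bags=5, train_fraction=0.75, seed=0)
        for bag in bags:
            assert len(bag.train_sample_ids) == 21
            assert len(bag.validation_sample_ids) == 7

    def test_stratified_rounding_per_class(self):
        ds = sized_dataset(15, 13)
        bags = generate_bags(ds, n_bags=10, train_fraction=0.75, seed=1)
        for bag in bags:
            train = set(bag.train_sample_ids)
            n_case = sum(1 for s in train if ds.labels[s] == "case")
            n_ctrl = len(train) - n_case
            assert (n_case, n_ctrl) == (11, 10)  # round(11.25), round(9.75)

    def test_partition_properties(self):
        ds = sized_dataset(10, 10)
        for seed in range(5):
            for bag in generate_bags(ds, n_bags=20, seed=seed):
                train = set(bag.train_sample_ids)
                val = set(bag.validation_sample_ids)
                assert not train & val
                assert train | val == set(ds.sample_ids)

    def test_class_too_small_names_class(self):
        ds = make_dataset(
            np.arange(12.0).reshape(2, 6), ["g0", "g1"],
            [f"s{i}" for i in range(6)],
            ["case"] * 4 + ["control"] * 2,
        )
        with pytest.raises(ValidationError, match="control"):
            generate_bags(ds, n_bags=1, train_fraction=0.75)

    def test_reproducible_from_seed(self):
        ds = sized_dataset(10, 10)
        a = generate_bags(ds, n_bags=10, seed=3)
        b = generate_bags(ds, n_bags=10, seed=3)
        assert [x.train_sample_ids for x in a] == [x.train_sample_ids for x in b]


@pytest.fixture(scope="module")
def separable_run():
    spec = SyntheticSpec(n_samples_per_class=(14, 14), n_probes=120,
                         n_informative=3, effect_size=4.0, noise_sd=1.0, seed=31)
    ds, truth = generate_two_class_dataset(spec)
    cfg = HoldoutConfig(n_bags=200, validation_min_pct=100.0, seed=7)
    bags, posterior = run_holdout_sampler(ds, cfg)
    return ds, truth, bags, posterior


class TestRunHoldoutSampler:
    def test_separable_data_accepts_bags(self, separable_run):
        _, _, bags, posterior = separable_run
        assert posterior.n_accepted >= 1
        assert posterior.n_accepted == sum(b.accepted for b in bags)

    def test_top_posterior_probes_are_planted(self, separable_run):
        """With a strong effect, only planted probes dominate the posterior.

        Not every planted probe need appear: one separating probe already
        yields a length-1 minimal signature, so redundant planted probes can
        be skipped; but nothing un-planted may outrank the planted ones.
        """
        _, truth, _, posterior = separable_run
        ranked = sorted(posterior.frequencies.items(), key=lambda kv: -kv[1])
        n_top = sum(1 for _, f in ranked if f >= 0.1)
        top = [p for p, _ in ranked[:n_top]]
        assert set(top) <= set(truth.informative_probe_ids)
        assert len(top) >= 1

    def test_vacuous_threshold_accepts_all(self):
        ds = sized_dataset(8, 8, seed=2)
        cfg = HoldoutConfig(n_bags=25, validation_min_pct=0.0, seed=2)
        bags, posterior = run_holdout_sampler(ds, cfg)
        assert posterior.n_accepted == 25

    def test_same_seed_identical(self):
        ds = sized_dataset(8, 8, seed=3)
        cfg = HoldoutConfig(n_bags=30, validation_min_pct=0.0, seed=5)
        a = run_holdout_sampler(ds, cfg)
        b = run_holdout_sampler(ds, cfg)
        assert [x.signature.probe_ids for x in a[0]] == \
            [x.signature.probe_ids for x in b[0]]
        assert a[1].frequencies == b[1].frequencies

    def test_empty_acceptance_raises(self):
        # null data with a 10-sample validation fold: a perfect bag is
        # essentially impossible, so the threshold of 100 empties Mtol
        spec = SyntheticSpec(n_samples_per_class=(20, 20), n_probes=40,
                             n_informative=0, seed=4)
        ds, _ = generate_two_class_dataset(spec)
        cfg = HoldoutConfig(n_bags=10, validation_min_pct=100.0, seed=1)
        with pytest.raises(EmptyAcceptanceError):
            run_holdout_sampler(ds, cfg)

    def test_no_leakage_from_validation_fold(self):
        """Perturbing validation-fold values must not change a bag's signature."""
        ds = sized_dataset(10, 10, seed=6)
        cfg = HoldoutConfig(n_bags=3, validation_min_pct=0.0, seed=11)
        bags, _ = run_holdout_sampler(ds, cfg)
        perturbed = ds.values.copy()
        rng = np.random.default_rng(0)
        val_ids = list(bags[0].validation_sample_ids)
        perturbed.loc[:, val_ids] += rng.normal(0, 5, size=(ds.n_probes, len(val_ids)))
        ds2 = make_dataset(perturbed.to_numpy(), ds.probe_ids, ds.sample_ids,
                           list(ds.labels))
        bags2, _ = run_holdout_sampler(ds2, cfg)
        assert bags2[0].signature.probe_ids == bags[0].signature.probe_ids
        assert bags2[0].train_sample_ids == bags[0].train_sample_ids

    def test_counting_identity(self, separable_run):
        _, _, bags, posterior = separable_run
        accepted = [frozenset(b.signature.probe_ids) for b in bags if b.accepted]
        total_slots = sum(len(s) for s in accepted)
        lhs = sum(posterior.frequencies.values()) * posterior.n_accepted
        assert lhs == pytest.approx(total_slots)
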