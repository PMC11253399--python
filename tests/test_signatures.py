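"""Catalogue building and simplex-constrained exposure fitting."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ithkit.io_formats import CHANNELS96, SignatureMatrix
from ithkit.signatures import (
    CatalogVector,
    DEFAULT_COHORT_SIGNATURES,
    ExposureVector,
    build_catalog,
    fit_exposures,
    group_exposures,
    population_signature_profile,
    refit_with_pruning,
    select_cohort_signatures,
    signature_presence,
)
from ithkit.synthetic_data import (
    mixture_from_names,
    sample_mutations_from_signature,
    synthetic_signature_matrix,
)
from ithkit.io_formats import MutationRecord, Timepoint, sbs96_channel


def toy_matrix(columns: list[np.ndarray], names=None) -> SignatureMatrix:
    names = names or [f"S{i}" for i in range(len(columns))]
    probs = np.column_stack([c / c.sum() for c in columns])
    return SignatureMatrix(CHANNELS96, names, probs)


def grid_search_fit(catalog: CatalogVector, matrix: SignatureMatrix, step: float):
    """Dense simplex grid-search oracle for <=3-signature problems."""
    c = catalog.frequencies()
    P = matrix.probs
    S = matrix.n_signatures
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    best, best_err = None, np.inf
    if S == 2:
        combos = ((w, 1 - w) for w in ticks)
    elif S == 3:
        combos = ((a, b, 1 - a - b) for a, b in itertools.product(ticks, ticks) if a + b <= 1 + 1e-12)
    else:
        raise ValueError("oracle supports 2 or 3 signatures")
    for w in combos:
        w = np.clip(np.asarray(w), 0, 1)
        err = float(((P @ w - c) ** 2).sum())
        if err < best_err:
            best, best_err = w, err
    return best


def spike(channel: int, weight=1.0) -> np.ndarray:
    v = np.full(96, 0.001)
    v[channel] = weight
    return v


class TestFitExposures:
    def test_catalog_proportional_to_one_column(self, signature_matrix):
        col = signature_matrix.probs[:, 3]
        catalog = CatalogVector(np.round(col * 10_000))
        exposure = fit_exposures(catalog, signature_matrix)
        assert exposure.weights[3] > 0.99
        assert exposure.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_two_signature_mixture(self):
        matrix = toy_matrix([spike(0), spike(50)])
        c = 0.7 * matrix.probs[:, 0] + 0.3 * matrix.probs[:, 1]
        exposure = fit_exposures(CatalogVector(c * 1e6), matrix)
        np.testing.assert_allclose(exposure.weights, [0.7, 0.3], atol=1e-6)
        oracle = grid_search_fit(CatalogVector(c * 1e6), matrix, step=1e-3)
        np.testing.assert_allclose(exposure.weights, oracle, atol=2e-3)

    def test_single_signature_matrix_gives_weight_one(self, signature_matrix):
        matrix = signature_matrix.subset(["SBS5"])
        catalog = CatalogVector(np.ones(96))
        assert fit_exposures(catalog, matrix).weights.tolist() == [1.0]

    def test_agrees_with_grid_search_on_three_signatures(self, rng):
        matrix = toy_matrix([spike(0), spike(33), spike(70)])
        w_true = np.array([0.5, 0.35, 0.15])
        counts = rng.multinomial(4000, matrix.probs @ w_true)
        catalog = CatalogVector(counts)
        exposure = fit_exposures(catalog, matrix)
        oracle = grid_search_fit(catalog, matrix, step=1e-2)
        np.testing.assert_allclose(exposure.weights, oracle, atol=1e-2)

    def test_zero_catalog_raises(self, signature_matrix):
        with pytest.raises(ValueError):
            fit_exposures(CatalogVector(np.zeros(96)), signature_matrix)

    def test_weights_are_probability_vector(self, signature_matrix, rng):
        for _ in range(5):
            counts = rng.integers(0, 50, size=96)
            counts[rng.integers(96)] += 100
            exp = fit_exposures(CatalogVector(counts), signature_matrix)
            assert np.all(exp.weights >= 0)
            assert exp.weights.sum() == pytest.approx(1.0, abs=1e-8)


class TestBuildCatalog:
    def test_empty_records(self):
        catalog = build_catalog([])
        assert catalog.n_mutations == 0 and catalog.counts.sum() == 0

    def _record(self, pos, ref, alt, ctx, sample="S1"):
        return MutationRecord(
            tumour_id="T",
            sample_id=sample,
            timepoint=Timepoint.PRE,
            region_label="T1",
            chrom="chr1",
            pos=pos,
            ref_allele=ref,
            alt_allele=alt,
            alt_count=5,
            depth=40,
            trinucleotide_context=ctx,
            channel=sbs96_channel(ref, alt, ctx),
        )

    def test_identical_records_stack_one_channel(self):
        records = [self._record(100 + i, "C", "A", "ACA") for i in range(10)]
        catalog = build_catalog(records)
        assert catalog.counts[sbs96_channel("C", "A", "ACA")] == 10
        assert catalog.n_mutations == 10

    def test_matches_per_record_oracle(self, rng):
        bases = "ACGT"
        records = []
        for i in range(200):
            ref = bases[rng.integers(4)]
            alt = bases[rng.integers(4)]
            if alt == ref:
                alt = bases[(bases.index(ref) + 1) % 4]
            ctx = bases[rng.integers(4)] + ref + bases[rng.integers(4)]
            records.append(self._record(1000 + i, ref, alt, ctx))
        catalog = build_catalog(records)
        expected = np.zeros(96)
        for r in records:
            expected[sbs96_channel(r.ref_allele, r.alt_allele, r.trinucleotide_context)] += 1
        np.testing.assert_array_equal(catalog.counts, expected)


class TestCohortSelection:
    def test_threshold_forced_single_sample(self):
        exposures = {"S1": ExposureVector(["A", "B"], np.array([0.95, 0.05]))}
        assert select_cohort_signatures(exposures) == {"A"}

    def test_union_over_samples(self):
        exposures = {
            "S1": ExposureVector(["A", "B", "C"], np.array([0.90, 0.10, 0.0])),
            "S2": ExposureVector(["A", "B", "C"], np.array([0.55, 0.05, 0.40])),
        }
        assert select_cohort_signatures(exposures) == {"A", "B", "C"}

    def test_matches_brute_force_scan(self, rng):
        names = [f"S{i}" for i in range(6)]
        exposures = {}
        for s in range(8):
            w = rng.dirichlet(np.ones(6))
            exposures[f"samp{s}"] = ExposureVector(names, w)
        expected = {
            n
            for exp in exposures.values()
            for n, w in zip(exp.names, exp.weights)
            if w >= 0.10
        }
        assert select_cohort_signatures(exposures) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_cohort_signatures({})


class TestRefitWithPruning:
    def test_small_weights_pruned_to_single_signature(self):
        # catalogue is ~93% signature 0 with traces of two near-collinear others
        matrix = toy_matrix([spike(0), spike(1), spike(2)])
        c = 0.93 * matrix.probs[:, 0] + 0.04 * matrix.probs[:, 1] + 0.03 * matrix.probs[:, 2]
        exposure = refit_with_pruning(CatalogVector(c * 1e5), matrix)
        assert exposure.names == ["S0"]
        assert exposure.weights.tolist() == [1.0]

    def test_all_above_threshold_is_fixed_point(self, signature_matrix):
        matrix = signature_matrix.subset(["SBS2", "SBS17a"])
        c = 0.6 * matrix.probs[:, 0] + 0.4 * matrix.probs[:, 1]
        exposure = refit_with_pruning(CatalogVector(c * 1e5), matrix)
        assert set(exposure.names) == {"SBS2", "SBS17a"}
        np.testing.assert_allclose(sorted(exposure.weights), [0.4, 0.6], atol=0.01)

    def test_output_is_fixed_point_of_one_more_round(self, signature_matrix, rng):
        matrix = signature_matrix.subset(list(DEFAULT_COHORT_SIGNATURES[:6]))
        counts = rng.multinomial(3000, matrix.probs @ rng.dirichlet(np.ones(6)))
        exposure = refit_with_pruning(CatalogVector(counts), matrix)
        assert np.all(exposure.weights >= 0.05) or len(exposure.names) == 1
        again = refit_with_pruning(CatalogVector(counts), matrix.subset(exposure.names))
        assert again.names == exposure.names
        np.testing.assert_allclose(again.weights, exposure.weights, atol=1e-6)

    def test_cascading_prune_matches_iterated_grid_oracle(self):
        """A sparse toy where removing one signature drags another below 5%."""
        matrix = toy_matrix([spike(0), spike(10), spike(20)])
        P = matrix.probs
        c = 0.90 * P[:, 0] + 0.055 * P[:, 1] + 0.045 * P[:, 2]
        catalog = CatalogVector(c * 1e5)

        # independent oracle: iterate {grid-search fit; drop <5%} to a fixed point
        names = list(matrix.names)
        active = matrix
        while True:
            w = (
                grid_search_fit(catalog, active, step=1e-3)
                if active.n_signatures > 1
                else np.array([1.0])
            )
            keep = w >= 0.05
            if not keep.any():
                keep[np.argmax(w)] = True
            if keep.all():
                break
            names = [n for n, k in zip(names, keep) if k]
            active = matrix.subset(names)
        exposure = refit_with_pruning(catalog, matrix)
        assert exposure.names == names
        np.testing.assert_allclose(exposure.weights, w, atol=2e-3)


class TestGroupsAndPresence:
    def test_group_weight_is_member_sum(self):
        exp = ExposureVector(["SBS2", "SBS13", "SBS5"], np.array([0.1, 0.15, 0.75]))
        grouped = group_exposures(exp)
        assert grouped["APOBEC"] == pytest.approx(0.25)
        assert grouped["SBS5"] == pytest.approx(0.75)

    def test_absent_group_is_zero_and_total_conserved(self, rng):
        names = ["SBS5", "SBS17a", "SBS40"]
        w = rng.dirichlet(np.ones(3))
        grouped = group_exposures(ExposureVector(names, w))
        assert grouped["APOBEC"] == 0.0
        assert grouped["MMR/MSI"] == 0.0
        assert sum(grouped.values()) == pytest.approx(1.0)

    def test_presence_follows_pruning_survival(self):
        surviving = ExposureVector(["SBS2", "SBS5"], np.array([0.06, 0.94]))
        assert signature_presence(surviving, "APOBEC")
        pruned = ExposureVector(["SBS5"], np.array([1.0]))
        assert not signature_presence(pruned, "APOBEC")


class TestParameterRecovery:
    def test_mixture_recovered_within_3pct(self, signature_matrix, rng):
        """Mean absolute exposure error <= 0.03 on 5,000-mutation catalogues."""
        names = ["SBS1", "SBS5", "SBS17a", "SBS2", "SBS18"]
        matrix = signature_matrix.subset(names)
        errors = []
        for _ in range(3):
            w_true = rng.dirichlet(np.full(5, 2.0))
            counts = rng.multinomial(5000, matrix.probs @ w_true)
            exposure = fit_exposures(CatalogVector(counts), matrix)
            errors.append(np.abs(exposure.weights - w_true).mean())
        assert np.mean(errors) <= 0.03

    def test_platinum_population_recovered(self, context_index, signature_matrix, rng):
        """A population drawn from SBS35 refits to SBS35 when platinum is allowed."""
        mixture = mixture_from_names(signature_matrix, {"SBS35": 1.0})
        sites = sample_mutations_from_signature(mixture, 600, context_index, rng)
        records = [
            MutationRecord(
                tumour_id="T",
                sample_id="P1",
                timepoint=Timepoint.POST,
                region_label="P1",
                chrom=c,
                pos=p,
                ref_allele=ref,
                alt_allele=alt,
                alt_count=10,
                depth=60,
                trinucleotide_context=ctx,
                channel=ch,
            )
            for c, p, ref, alt, ctx, ch in sites
        ]
        with_pt = population_signature_profile(
            records, signature_matrix, include_platinum=True
        )
        assert with_pt.exposure.weight("SBS35") >= 0.8
        without = population_signature_profile(
            records, signature_matrix, include_platinum=False
        )
        assert "SBS35" not in without.exposure.names

    def test_small_population_flagged_low_confidence(self, signature_matrix):
        matrix = signature_matrix.subset(["SBS5"])
        records = []
        for i in range(10):
            records.append(
                MutationRecord(
                    tumour_id="T",
                    sample_id="S",
                    timepoint=Timepoint.PRE,
                    region_label="T1",
                    chrom="chr1",
                    pos=100 + i,
                    ref_allele="C",
                    alt_allele="A",
                    alt_count=5,
                    depth=30,
                    trinucleotide_context="ACA",
                    channel=sbs96_channel("C", "A", "ACA"),
                )
            )
        profile = population_signature_profile(records, signature_matrix)
        assert profile.low_confidence and profile.n_mutations == 10
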