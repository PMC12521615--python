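"""Binding modes, enrichment, likelihood, penalty, and ddG scoring."""

import json
import math

import numpy as np
import pytest

from pepfer import (
    BindingMode,
    CountTable,
    RegularizationConfig,
    enrichment,
    load_model,
    log_likelihood,
    nonspecific_sum,
    penalty,
    relative_affinity,
    save_model,
    specific_sum,
)
from pepfer.errors import (
    ConfigurationError,
    MalformedInputError,
    NotNormalizedError,
)
from pepfer.fitting import normalize
from pepfer.library import ALPHABET
from pepfer.model import N_AA, batch_enrichment, ddg, encode_peptides

from conftest import random_mode, random_model, random_peptides, random_table


def oracle_specific_sum(peptide, mode, design):
    """Brute-force loop over all flank-overlapping windows."""
    f = mode.flank_depth
    ext = (
        (design.protein_flank_left[-f:] if f else "")
        + peptide
        + (design.protein_flank_right[:f] if f else "")
    )
    total = 0.0
    for x in range(len(ext) - mode.width + 1):
        window = ext[x : x + mode.width]
        score = sum(
            mode.coeffs[j, ALPHABET.index(aa)] for j, aa in enumerate(window)
        )
        total += math.exp(score)
    return total


def oracle_nonspecific_sum(peptide, mode):
    total = 0.0
    for x in range(len(peptide) - mode.width + 1):
        window = peptide[x : x + mode.width]
        score = sum(
            mode.coeffs[j, ALPHABET.index(aa)] for j, aa in enumerate(window)
        )
        if mode.position_bias is not None:
            score += mode.position_bias[x]
        total += math.exp(score)
    return total


def oracle_log_likelihood(tables, model):
    total = 0.0
    for c, table in enumerate(tables):
        rp = model.per_round[c]
        rho = math.exp(rp.depth_log_ratio)
        contrib = 0.0
        for seq, (ki, kb) in table.rows().items():
            kappa = (
                math.exp(rp.log_alpha_ns)
                * oracle_nonspecific_sum(seq, model.nonspecific)
                + math.exp(rp.log_alpha_s)
                * oracle_specific_sum(seq, model.specific, model.design)
            )
            q = rho * kappa
            contrib += ki * math.log(1 / (1 + q)) + kb * math.log(q / (1 + q))
        total += contrib / table.k_total
    return total


class TestSpecificSum:
    def test_zero_coeffs_single_offset(self, tiny_design):
        mode = BindingMode(width=5, coeffs=np.zeros((5, N_AA)), flank_depth=0)
        assert specific_sum("ACDEF", mode, tiny_design) == 1.0

    def test_offset_count_with_flanks(self, design_x5yx5):
        # L=11, w=11, f=5 -> L + 2f - w + 1 = 11 offsets
        mode = BindingMode(width=11, coeffs=np.zeros((11, N_AA)), flank_depth=5)
        assert specific_sum("ACDEFYGHIKL", mode, design_x5yx5) == 11.0

    def test_matches_oracle_small(self, tiny_design, rng):
        mode = random_mode(rng, width=3)
        value = specific_sum("ACDEF", mode, tiny_design)
        assert value == pytest.approx(
            oracle_specific_sum("ACDEF", mode, tiny_design), rel=1e-12
        )

    def test_matches_oracle_many(self, design_x5yx5, rng):
        for _ in range(50):
            f = int(rng.integers(0, 6))
            mode = random_mode(rng, width=11, flank_depth=f)
            pep = random_peptides(rng, design_x5yx5, 1)[0]
            assert specific_sum(pep, mode, design_x5yx5) == pytest.approx(
                oracle_specific_sum(pep, mode, design_x5yx5), rel=1e-12
            )

    def test_bad_letter_rejected(self, tiny_design):
        mode = BindingMode(width=5, coeffs=np.zeros((5, N_AA)))
        with pytest.raises(MalformedInputError):
            specific_sum("ACDEZ", mode, tiny_design)


class TestNonspecificSum:
    def test_zero_coeffs_counts_offsets(self):
        mode = BindingMode(
            width=3, coeffs=np.zeros((3, N_AA)), position_bias=np.zeros(9)
        )
        assert nonspecific_sum("ACDEFYGHIKL", mode) == 9.0

    def test_width_one_with_bias(self):
        mode = BindingMode(
            width=1,
            coeffs=np.zeros((1, N_AA)),
            position_bias=np.full(11, math.log(2)),
        )
        assert nonspecific_sum("ACDEFYGHIKL", mode) == pytest.approx(22.0)

    def test_matches_oracle(self, design_x5yx5, rng):
        for _ in range(50):
            w = int(rng.integers(1, 4))
            mode = random_mode(rng, width=w, n_bias=11 - w + 1)
            pep = random_peptides(rng, design_x5yx5, 1)[0]
            assert nonspecific_sum(pep, mode) == pytest.approx(
                oracle_nonspecific_sum(pep, mode), rel=1e-12
            )


class TestEnrichment:
    def test_ns_zero_leaves_specific_only(self, design_x5yx5, rng):
        model = random_model(rng, design_x5yx5)
        model.per_round[0].log_alpha_ns = -np.inf  # alpha_NS = 0
        pep = random_peptides(rng, design_x5yx5, 1)[0]
        expected = math.exp(model.per_round[0].log_alpha_s) * specific_sum(
            pep, model.specific, design_x5yx5
        )
        assert enrichment(pep, model, 0) == pytest.approx(expected, rel=1e-12)

    def test_uniform_affinity_when_specific_off(self, design_x5yx5, rng):
        model = random_model(rng, design_x5yx5)
        model.per_round[0].log_alpha_s = -np.inf
        model.nonspecific.coeffs[:] = 0.0
        model.nonspecific.position_bias[:] = 0.0
        peps = random_peptides(rng, design_x5yx5, 5)
        values = {enrichment(p, model, 0) for p in peps}
        assert len({round(v, 12) for v in values}) == 1

    def test_sum_of_mode_oracles(self, design_x5yx5, rng):
        model = random_model(rng, design_x5yx5, flank_depth=3)
        rp = model.per_round[0]
        pep = random_peptides(rng, design_x5yx5, 1)[0]
        expected = math.exp(rp.log_alpha_ns) * oracle_nonspecific_sum(
            pep, model.nonspecific
        ) + math.exp(rp.log_alpha_s) * oracle_specific_sum(
            pep, model.specific, design_x5yx5
        )
        assert enrichment(pep, model, 0) == pytest.approx(expected, rel=1e-12)

    def test_bad_round_index(self, design_x5yx5, rng):
        model = random_model(rng, design_x5yx5)
        with pytest.raises(ConfigurationError):
            enrichment("ACDEFYGHIKL", model, 3)


class TestLogLikelihood:
    def test_single_row_closed_form(self, design_x5yx5, rng):
        # counts (1,1) with rho*kappa = 1 -> (1/2)(ln 1/2 + ln 1/2) = ln 1/2
        model = random_model(rng, design_x5yx5)
        pep = random_peptides(rng, design_x5yx5, 1)[0]
        kappa = enrichment(pep, model, 0)
        model.per_round[0].depth_log_ratio = -math.log(kappa)
        table = CountTable(1, design_x5yx5, [pep], [1], [1])
        assert log_likelihood([table], model) == pytest.approx(
            math.log(0.5), rel=1e-12
        )

    def test_input_only_vanishes_at_small_kappa(self, design_x5yx5, rng):
        model = random_model(rng, design_x5yx5)
        pep = random_peptides(rng, design_x5yx5, 1)[0]
        table = CountTable(1, design_x5yx5, [pep], [50], [0])
        model.per_round[0].depth_log_ratio = -40.0  # rho*kappa -> 0
        assert abs(log_likelihood([table], model)) < 1e-10

    def test_matches_oracle(self, design_x5yx5, rng):
        model = random_model(rng, design_x5yx5, n_rounds=2, flank_depth=2)
        tables = [
            random_table(rng, design_x5yx5, n=6, round_id=1),
            random_table(rng, design_x5yx5, n=4, round_id=2),
        ]
        assert log_likelihood(tables, model) == pytest.approx(
            oracle_log_likelihood(tables, model), rel=1e-12
        )

    def test_row_permutation_invariance(self, design_x5yx5, rng):
        model = random_model(rng, design_x5yx5)
        table = random_table(rng, design_x5yx5, n=8)
        perm = rng.permutation(table.n_unique)
        shuffled = CountTable(
            table.round_id,
            design_x5yx5,
            [table.sequences[i] for i in perm],
            table.counts_input[perm],
            table.counts_bound[perm],
        )
        assert log_likelihood([table], model) == pytest.approx(
            log_likelihood([shuffled], model), rel=1e-12
        )

    def test_table_reordering_with_matched_params(self, design_x5yx5, rng):
        model = random_model(rng, design_x5yx5, n_rounds=2)
        t1 = random_table(rng, design_x5yx5, n=6, round_id=1)
        t2 = random_table(rng, design_x5yx5, n=6, round_id=2)
        swapped = model.copy()
        swapped.per_round = [model.per_round[1], model.per_round[0]]
        assert log_likelihood([t1, t2], model) == pytest.approx(
            log_likelihood([t2, t1], swapped), rel=1e-12
        )

    def test_misalignment_rejected(self, design_x5yx5, rng):
        model = random_model(rng, design_x5yx5, n_rounds=1)
        tables = [random_table(rng, design_x5yx5), random_table(rng, design_x5yx5)]
        with pytest.raises(ConfigurationError):
            log_likelihood(tables, model)


class TestPenalty:
    def test_zero_model_zero_l2(self, design_x5yx5, rng):
        model = random_model(rng, design_x5yx5)
        model.specific.coeffs[:] = 0.0
        model.nonspecific.coeffs[:] = 0.0
        model.nonspecific.position_bias[:] = 0.0
        config = RegularizationConfig(
            lambda_l2=1.0, barrier_weight=0.0, dirichlet_count=0.0
        )
        assert penalty(model, config) == 0.0

    def test_barrier_at_cap(self, design_x5yx5, rng):
        model = random_model(rng, design_x5yx5)
        model.specific.coeffs[:] = 0.0
        model.nonspecific.coeffs[:] = 0.0
        model.nonspecific.position_bias[:] = 0.0
        model.specific.coeffs[0, 0] = 8.0  # == barrier cap B
        config = RegularizationConfig(
            lambda_l2=0.0, barrier_weight=0.5, barrier_cap=8.0, dirichlet_count=0.0
        )
        n_coef = model.specific.coeffs.size + model.nonspecific.coeffs.size + 11 - 3 + 1
        # cell at cap: exp(0) + exp(-16); every zero cell: 2 exp(-8)
        expected = 0.5 * (
            1.0 + math.exp(-16.0) + (n_coef - 1) * 2 * math.exp(-8.0)
        )
        assert penalty(model, config) == pytest.approx(expected, rel=1e-12)

    def test_all_weights_zero(self, design_x5yx5, rng):
        model = random_model(rng, design_x5yx5)
        config = RegularizationConfig(
            lambda_l2=0.0, barrier_weight=0.0, dirichlet_count=0.0
        )
        assert penalty(model, config) == 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ConfigurationError):
            RegularizationConfig(lambda_l2=-1.0)

    def test_dirichlet_term_positive(self, design_x5yx5, rng):
        model = random_model(rng, design_x5yx5)
        table = random_table(rng, design_x5yx5)
        config = RegularizationConfig(
            lambda_l2=0.0, barrier_weight=0.0, dirichlet_count=5.0
        )
        assert penalty(model, config, [table]) > 0.0


class TestGaugeProperty:
    def test_column_shift_absorbed_by_alpha(self, design_x5yx5, rng):
        model = random_model(rng, design_x5yx5, flank_depth=4)
        peps = random_peptides(rng, design_x5yx5, 20)
        before = [enrichment(p, model, 0) for p in peps]
        shifted = model.copy()
        c = 0.7
        shifted.specific.coeffs[3, :] += c
        shifted.per_round[0].log_alpha_s -= c
        after = [enrichment(p, shifted, 0) for p in peps]
        assert np.allclose(before, after, rtol=1e-10)


class TestDdgAndAffinity:
    def _normalized_model(self, rng, design):
        return normalize(random_model(rng, design))

    def test_argmax_peptide_scores_one(self, design_x5yx5, rng):
        model = self._normalized_model(rng, design_x5yx5)
        best = "".join(
            ALPHABET[int(np.argmax(model.specific.coeffs[p]))]
            for p in range(11)
        )
        assert ddg(best, model) == pytest.approx(0.0, abs=1e-12)
        assert relative_affinity(best, model) == pytest.approx(1.0)

    def test_single_substitution_additivity(self, design_x5yx5, rng):
        model = self._normalized_model(rng, design_x5yx5)
        best = "".join(
            ALPHABET[int(np.argmax(model.specific.coeffs[p]))]
            for p in range(11)
        )
        mutant = best[:2] + ("A" if best[2] != "A" else "C") + best[3:]
        diff = (
            model.specific.coeffs[2, ALPHABET.index(best[2])]
            - model.specific.coeffs[2, ALPHABET.index(mutant[2])]
        )
        assert relative_affinity(mutant, model) == pytest.approx(
            math.exp(-diff), rel=1e-12
        )

    def test_affinity_in_unit_interval(self, design_x5yx5, rng):
        model = self._normalized_model(rng, design_x5yx5)
        for pep in random_peptides(rng, design_x5yx5, 200):
            aff = relative_affinity(pep, model)
            assert 0.0 < aff <= 1.0 + 1e-12

    def test_unnormalized_model_rejected(self, design_x5yx5, rng):
        model = random_model(rng, design_x5yx5)
        with pytest.raises(NotNormalizedError):
            ddg("ACDEFYGHIKL", model)


class TestSerialization:
    def test_roundtrip_bit_exact(self, design_x5yx5, rng, tmp_path):
        model = random_model(rng, design_x5yx5, n_rounds=3, flank_depth=5)
        model.specific.constrained_cells = {(5, i): -10.0 for i in range(N_AA)}
        model.specific.constrained_cells[(5, ALPHABET.index("Y"))] = 0.0
        model.specific.apply_frozen()
        path = tmp_path / "m.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.specific.coeffs, model.specific.coeffs)
        np.testing.assert_array_equal(
            back.nonspecific.coeffs, model.nonspecific.coeffs
        )
        np.testing.assert_array_equal(
            back.nonspecific.position_bias, model.nonspecific.position_bias
        )
        for a, b in zip(back.per_round, model.per_round):
            assert a == b
        assert back.design == model.design
        assert back.specific.constrained_cells == model.specific.constrained_cells

    def test_save_is_deterministic(self, design_x5yx5, rng, tmp_path):
        model = random_model(rng, design_x5yx5)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_model(model, p1)
        save_model(model, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_schema_fields(self, design_x5yx5, rng, tmp_path):
        model = random_model(rng, design_x5yx5)
        path = tmp_path / "m.json"
        save_model(model, path)
        data = json.loads(path.read_text())
        assert data["format_version"] == 1
        assert data["alphabet"] == "ACDEFGHIKLMNPQRSTVWY"
        assert len(data["specific"]["coeffs"]) == 11
        assert len(data["per_round"]) == 1


class TestBatchConsistency:
    def test_batch_matches_scalar(self, design_x5yx5, rng):
        model = random_model(rng, design_x5yx5, flank_depth=5)
        peps = random_peptides(rng, design_x5yx5, 30)
        batch = batch_enrichment(encode_peptides(peps), model, 0)
        singles = [enrichment(p, model, 0) for p in peps]
        assert np.allclose(batch, singles, rtol=1e-12)
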