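"""PCR simulator: amplification recursion, partitioning, read emission."""

import numpy as np
import pytest

from mprachim.design import Clone, PlasmidLibrary, build_read_layout, random_library
from mprachim.simulate import (
    EmptyCarryoverError,
    ErrorModel,
    ProtocolParams,
    amplify,
    emit_fastq,
    expected_chimeric_fraction,
    partition_templates,
    run_protocol,
    switch_prob_for_target,
    _bulk_closed_form,
)


def poisson_pmf_series(lam: float, j: int) -> float:
    """Poisson pmf from the series definition (independent of scipy)."""
    out = np.exp(-lam)
    for i in range(1, j + 1):
        out *= lam / i
    return out


class TestAmplify:
    def test_total_doubles_every_cycle(self, small_library, rng):
        comp = {(i, small_library.clone_roi_id[i]): 1.0 for i in range(10)}
        for cycles in (1, 5, 12):
            pool = amplify(comp, cycles, 0.2, small_library)
            assert pool.total == pytest.approx(10 * 2.0**cycles, rel=1e-12)

    def test_zero_switch_keeps_input_species(self, small_library):
        comp = [(0, small_library.clone_roi_id[0]), (1, small_library.clone_roi_id[1])]
        pool = amplify(comp, 8, 0.0, small_library)
        assert pool.chimeric_mass == 0.0
        d = pool.as_dict()
        assert set(d) == {
            (small_library.clones[0].bc, small_library.clones[0].roi),
            (small_library.clones[1].bc, small_library.clones[1].roi),
        }
        assert all(v == pytest.approx(2.0**8) for v in d.values())

    def test_lone_clone_cannot_form_chimeras(self, small_library):
        comp = {(3, small_library.clone_roi_id[3]): 5.0}
        pool = amplify(comp, 10, 0.5, small_library)
        assert pool.chimeric_mass == 0.0

    def test_two_clone_one_cycle_chimeric_fraction_matches_per_molecule_oracle(
        self, two_clone_library, rng
    ):
        """Expected chimeric fraction p/4 for two equal templates, one cycle.

        Oracle: brute-force per-molecule simulation.  Each of the two molecules
        synthesizes one copy; with probability p the copy's ROI is redrawn from
        the population's ROI marginal (uniform over the two), giving a chimera
        with probability 1/2.
        """
        p = 0.3
        reps = 100_000
        switched = rng.random((reps, 2)) < p
        landed_other = rng.random((reps, 2)) < 0.5
        chimeric_copies = (switched & landed_other).sum(axis=1)
        mc = chimeric_copies.mean() / 4.0
        se = chimeric_copies.std(ddof=1) / 4.0 / np.sqrt(reps)

        comp = [(0, two_clone_library.clone_roi_id[0]), (1, two_clone_library.clone_roi_id[1])]
        pool = amplify(comp, 1, p, two_clone_library)
        assert pool.chimeric_fraction == pytest.approx(p / 4.0, rel=1e-12)
        assert abs(pool.chimeric_fraction - mc) < 3 * se

    def test_recursion_matches_closed_form(self, small_library, rng):
        """Per-cycle recursion equals the rank-1 closed form exactly."""
        idx = rng.integers(0, len(small_library), size=6)
        species = np.unique(idx * len(small_library.roi_seqs) + small_library.clone_roi_id[idx])
        counts = rng.integers(1, 4, size=species.size).astype(float)
        recursion = amplify(
            {(s // len(small_library.roi_seqs), s % len(small_library.roi_seqs)): c
             for s, c in zip(species, counts)},
            7,
            0.05,
            small_library,
        )
        closed = _bulk_closed_form(small_library, species, counts, 7, 0.05).materialize()
        a = recursion.as_dict()
        b = closed.as_dict()
        assert set(a) == set(b)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-10)


class TestPartition:
    def test_conventional_single_compartment(self, small_library):
        params = ProtocolParams(mode="conventional", template_molecules=100)
        part = partition_templates(small_library, params, 0)
        assert part.n_compartments == 1
        assert len(list(part.compartments())) == 1
        assert part.molecule_clone.size == 100

    def test_two_templates_land_apart(self, two_clone_library):
        params = ProtocolParams(mode="emulsion", template_molecules=2, micelle_count=10**9)
        part = partition_templates(two_clone_library, params, 5)
        assert (part.occupancy_counts() == 1).all()

    def test_multiple_occupancy_matches_poisson_series(self, small_library):
        """Fraction of multiply occupied micelles agrees with the Poisson
        closed form (series-defined pmf) within 3 SE at lambda = 0.002."""
        T, M = 20_000, 10_000_000
        lam = T / M
        params = ProtocolParams(mode="emulsion", template_molecules=T, micelle_count=M)
        part = partition_templates(small_library, params, 9)
        observed = int((part.occupancy_counts() >= 2).sum())
        p_ge2 = 1.0 - poisson_pmf_series(lam, 0) - poisson_pmf_series(lam, 1)
        expected = M * p_ge2
        assert abs(observed - expected) <= 3 * np.sqrt(expected)
        # and the lambda/2 small-occupancy approximation holds
        assert p_ge2 / (1.0 - poisson_pmf_series(lam, 0)) == pytest.approx(lam / 2, rel=0.01)


class TestRunProtocol:
    @pytest.mark.parametrize("mode", ["conventional", "emulsion"])
    def test_zero_switch_zero_chimeras(self, small_library, mode):
        params = ProtocolParams(
            mode=mode,
            template_molecules=2000,
            micelle_count=10**6,
            cycles_round1=6,
            cycles_round2=5,
            switch_prob=0.0,
        )
        pool = run_protocol(small_library, params, 2)
        assert pool.chimeric_mass == 0.0

    def test_conventional_matches_bulk_recursion_oracle(self, rng):
        """Final chimeric fraction of a bulk two-round run matches the
        single-compartment expected-value recursion closed form."""
        library = random_library(200, seed=8)
        p = 0.01
        params = ProtocolParams(
            mode="conventional",
            template_molecules=2000,
            cycles_round1=6,
            cycles_round2=5,
            carryover_fraction=0.1,
            switch_prob=p,
        )
        pool = run_protocol(library, params, 3)
        expected = expected_chimeric_fraction(library, p, 11)
        assert pool.chimeric_fraction == pytest.approx(expected, rel=0.1)

    def test_switch_prob_for_target_inverts_expected_fraction(self, small_library):
        for target in (0.003, 0.015):
            p = switch_prob_for_target(small_library, target, 33)
            assert expected_chimeric_fraction(small_library, p, 33) == pytest.approx(target)

    def test_empty_carryover_raises(self, two_clone_library):
        params = ProtocolParams(
            mode="conventional",
            template_molecules=1,
            cycles_round1=1,
            cycles_round2=1,
            carryover_fraction=1e-6,
        )
        with pytest.raises(EmptyCarryoverError):
            run_protocol(two_clone_library, params, 0)

    def test_chimeric_fraction_monotone_in_switch_prob(self):
        """Raising switch_prob never decreases the expected chimeric percent."""
        library = random_library(100, seed=5)
        fractions = []
        for p in (1e-4, 1e-3, 1e-2, 5e-2):
            params = ProtocolParams(
                mode="conventional",
                template_molecules=5000,
                cycles_round1=8,
                cycles_round2=8,
                switch_prob=p,
            )
            fractions.append(run_protocol(library, params, 4).chimeric_fraction)
        assert all(a < b for a, b in zip(fractions, fractions[1:]))


class TestEmitFastq:
    def test_round_trip_single_clone_no_errors(self, two_clone_library, rng, tmp_path):
        comp = {(0, two_clone_library.clone_roi_id[0]): 1.0}
        pool = amplify(comp, 5, 0.0, two_clone_library)
        path = tmp_path / "reads.fastq"
        truth = emit_fastq(pool, "A_1", 200, ErrorModel(sub_rate=0.0), rng, path)
        layout = build_read_layout(two_clone_library.design)
        clone = two_clone_library.clones[0]
        lines = path.read_text().splitlines()
        assert len(lines) == 4 * 200
        for seq in lines[1::4]:
            assert seq[layout.bc[0] : layout.bc[1]] == clone.bc
            assert seq[layout.roi[0] : layout.roi[1]] == clone.roi
        assert not truth.chimeric.any()
        assert not truth.mutated.any()

    def test_substitution_rate_recovered(self, small_library, rng, tmp_path):
        """Observed per-base mismatch rate within 3 binomial SE of sub_rate."""
        comp = {(i, small_library.clone_roi_id[i]): 1.0 for i in range(len(small_library))}
        pool = amplify(comp, 3, 0.0, small_library)
        n_reads, rate = 100_000, 1e-3
        path = tmp_path / "reads.fastq"
        truth = emit_fastq(pool, "A_2", n_reads, ErrorModel(sub_rate=rate), rng, path)
        design = small_library.design
        expected_by_bc = {
            c.bc: design.read_template("A_2", c.bc, c.roi) for c in small_library.clones
        }
        seqs = path.read_text().splitlines()[1::4]
        mismatches = sum(
            sum(a != b for a, b in zip(seq, expected_by_bc[bc]))
            for seq, bc in zip(seqs, truth.bc)
        )
        n_bases = n_reads * design.read_length
        se = np.sqrt(rate * (1 - rate) * n_bases)
        assert abs(mismatches - rate * n_bases) <= 3 * se

    def test_chimeric_read_fraction_matches_pool(self, rng, tmp_path):
        """Binomial sampling: truth-table chimeric fraction within 3 SE of the
        pool's chimeric abundance fraction."""
        library = random_library(300, seed=2)
        p = switch_prob_for_target(library, 0.015, 16)
        params = ProtocolParams(
            mode="conventional",
            template_molecules=3000,
            cycles_round1=8,
            cycles_round2=8,
            switch_prob=p,
        )
        pool = run_protocol(library, params, 6)
        n_reads = 200_000
        truth = emit_fastq(
            pool, "A_1", n_reads, ErrorModel(sub_rate=0.0), rng, tmp_path / "r.fastq"
        )
        f = pool.chimeric_fraction
        se = np.sqrt(f * (1 - f) / n_reads)
        assert abs(truth.chimeric.mean() - f) <= 3 * se

    def test_byte_identical_given_seed(self, small_library, tmp_path):
        params = ProtocolParams(
            mode="conventional", template_molecules=1000, cycles_round1=5,
            cycles_round2=5, switch_prob=1e-3,
        )
        blobs = []
        for name in ("a", "b"):
            rng = np.random.default_rng(99)
            pool = run_protocol(small_library, params, rng)
            path = tmp_path / f"{name}.fastq"
            emit_fastq(pool, "A_1", 5000, ErrorModel(sub_rate=1e-3), rng, path)
            blobs.append(path.read_bytes())
        assert blobs[0] == blobs[1]
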