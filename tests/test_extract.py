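"""Read demultiplexing, fixed-layout extraction and tallying."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mprachim.design import LibraryDesign, build_read_layout, random_library
from mprachim.extract import (
    ALL_STATUSES,
    ExtractedPair,
    STATUS_BAD_ANCHOR,
    STATUS_BAD_ALPHABET,
    STATUS_BAD_INDEX,
    STATUS_OK,
    STATUS_TOO_SHORT,
    UNASSIGNED,
    demultiplex,
    extract_pair,
    hamming,
    parse_fastq,
    tally_pairs,
)
from mprachim.simulate import ErrorModel, ProtocolParams, amplify, emit_fastq, run_protocol


def _mutate(seq: str, positions: list[int]) -> str:
    out = list(seq)
    for pos in positions:
        out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


class TestDemultiplex:
    def test_exact_index_hits_sample(self, design71):
        read = design71.read_template("A_1", "A" * 18, "ACGTACGT")
        assert read.startswith("TTCGGAGT")
        assert demultiplex(read, design71) == "A_1"

    def test_n_bases_unassigned(self, design71):
        read = "N" * 8 + design71.read_template("A_1", "A" * 18, "ACGTACGT")[8:]
        assert demultiplex(read, design71) == UNASSIGNED

    def test_hamming1_matches_exhaustive_scan(self, design71, rng):
        """One-mismatch indexes resolve to the sample the brute-force Hamming
        scan over all 8 indexes picks (or UNASSIGNED on ties)."""
        samples = list(design71.index_table)
        for _ in range(50):
            name = samples[rng.integers(len(samples))]
            idx = design71.index_table[name]
            pos = int(rng.integers(8))
            mutated = _mutate(idx, [pos])
            read = mutated + design71.read_template(name, "A" * 18, "ACGTACGT")[8:]
            dists = {s: hamming(mutated, i) for s, i in design71.index_table.items()}
            within = [s for s, d in dists.items() if d <= 1]
            expected = within[0] if len(within) == 1 else UNASSIGNED
            assert demultiplex(read, design71) == expected

    def test_ambiguous_index_unassigned(self):
        design = LibraryDesign(index_table={"x": "AAAAAAAA", "y": "AAAAAAAT"})
        read = design.read_template("x", "A" * 18, "ACGTACGT")
        # AAAAAAAA is Hamming-0 from x and Hamming-1 from y -> ambiguous
        assert demultiplex(read, design) == UNASSIGNED
        assert extract_pair("r", read, design).status == STATUS_BAD_INDEX


class TestExtractPair:
    def test_clean_read_round_trip(self, design71):
        read = design71.read_template("A_3", "ACGT" * 4 + "AC", "TTTTCCCC")
        pair = extract_pair("r1", read, design71)
        assert pair == ExtractedPair("r1", "A_3", "ACGT" * 4 + "AC", "TTTTCCCC", STATUS_OK)

    def test_short_read_too_short(self, design83):
        read = design83.read_template("A_1", "A" * 18, "ACGTACGT")[:100]
        assert extract_pair("r", read, design83).status == STATUS_TOO_SHORT

    def test_three_anchor_mismatches_rejected(self, design71):
        """Anchor tolerance boundary checked against a direct Hamming count."""
        layout = build_read_layout(design71)
        read = design71.read_template("A_1", "A" * 18, "ACGTACGT")
        for n_mut, expected in [(2, STATUS_OK), (3, STATUS_BAD_ANCHOR)]:
            mutated = _mutate(read, [layout.forward_anchor[0] + k for k in range(n_mut)])
            anchor = mutated[layout.forward_anchor[0] : layout.forward_anchor[1]]
            assert hamming(anchor, design71.forward_anchor) == n_mut
            assert extract_pair("r", mutated, design71).status == expected

    def test_spacer_mismatches_beyond_tolerance_rejected(self, design71):
        layout = build_read_layout(design71)
        read = design71.read_template("A_1", "A" * 18, "ACGTACGT")
        ok = _mutate(read, [layout.spacer[0] + 2 * k for k in range(5)])
        bad = _mutate(read, [layout.spacer[0] + 2 * k for k in range(6)])
        assert extract_pair("r", ok, design71).status == STATUS_OK
        assert extract_pair("r", bad, design71).status == STATUS_BAD_ANCHOR

    def test_n_in_bc_bad_alphabet(self, design71):
        layout = build_read_layout(design71)
        read = design71.read_template("A_1", "A" * 18, "ACGTACGT")
        read = read[: layout.bc[0]] + "N" + read[layout.bc[0] + 1 :]
        assert extract_pair("r", read, design71).status == STATUS_BAD_ALPHABET


class TestTally:
    def test_identical_pairs_counted_once(self):
        pairs = [ExtractedPair(f"r{i}", "A_1", "A" * 18, "ACGTACGT", STATUS_OK) for i in range(10)]
        result = tally_pairs(pairs)
        assert result.tallies == {"A_1": {"A" * 18: {"ACGTACGT": 10}}}
        assert result.status_counts[STATUS_OK] == 10

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from(ALL_STATUSES), max_size=60))
    def test_status_counters_partition_input(self, statuses):
        """Conservation: every read lands in exactly one status counter."""
        pairs = [
            ExtractedPair(f"r{i}", "A_1", "A" * 18 if s == STATUS_OK else None,
                          "ACGTACGT" if s == STATUS_OK else None, s)
            for i, s in enumerate(statuses)
        ]
        result = tally_pairs(pairs)
        assert sum(result.status_counts.values()) == len(statuses)
        n_tallied = sum(
            n for bcs in result.tallies.values() for rois in bcs.values() for n in rois.values()
        )
        assert n_tallied == result.status_counts[STATUS_OK]


class TestSimulatorRoundTrip:
    def test_error_free_reads_match_truth_crosstab_exactly(self, tmp_path, rng):
        """At sub_rate 0 the per-(bc, roi) tallies equal the truth-table
        cross-tabulation and no read fails to parse."""
        library = random_library(100, seed=12)
        params = ProtocolParams(
            mode="conventional", template_molecules=2000, cycles_round1=6,
            cycles_round2=6, switch_prob=5e-3,
        )
        pool = run_protocol(library, params, rng)
        path = tmp_path / "sim.fastq"
        truth = emit_fastq(pool, "A_5", 20_000, ErrorModel(sub_rate=0.0), rng, path)
        result = tally_pairs(parse_fastq(path, library.design))
        assert result.status_counts[STATUS_OK] == 20_000
        expected = truth.groupby(["bc", "roi"]).size()
        observed = {
            (bc, roi): n
            for bc, rois in result.tallies["A_5"].items()
            for roi, n in rois.items()
        }
        assert observed == expected.to_dict()

    def test_gzip_input_supported(self, tmp_path, rng, small_library):
        comp = {(0, small_library.clone_roi_id[0]): 1.0}
        pool = amplify(comp, 4, 0.0, small_library)
        path = tmp_path / "sim.fastq.gz"
        emit_fastq(pool, "A_1", 100, ErrorModel(sub_rate=0.0), rng, path)
        result = tally_pairs(parse_fastq(path, small_library.design))
        assert result.status_counts[STATUS_OK] == 100
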