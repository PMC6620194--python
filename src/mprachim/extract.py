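"""Fixed-layout parsing of amplicon reads into (sample, BC, ROI) triples.

The amplicon is fully constant outside the BC and ROI, so reads are sliced at
the fixed offsets of :func:`mprachim.design.build_read_layout` rather than
aligned.  A read is accepted only if its sample index matches a known index
within 1 mismatch (uniquely), the forward anchor matches within 2 mismatches
and the spacer within 5; the tolerances scale roughly with element length at
~1% per-base error and are configurable.  Reads are handled on the sequencing
strand only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from mprachim.design import LibraryDesign, ReadLayout, build_read_layout

UNASSIGNED = "UNASSIGNED"

STATUS_OK = "ok"
STATUS_BAD_INDEX = "bad_index"
STATUS_BAD_ANCHOR = "bad_anchor"
STATUS_BAD_ALPHABET = "bad_alphabet"
STATUS_TOO_SHORT = "too_short"
ALL_STATUSES = (
    STATUS_OK,
    STATUS_BAD_INDEX,
    STATUS_BAD_ANCHOR,
    STATUS_BAD_ALPHABET,
    STATUS_TOO_SHORT,
)

_NON_ACGT = str.maketrans("", "", "ACGT")


class ExtractedPair(NamedTuple):
    read_id: str
    sample: str
    bc: str | None
    roi: str | None
    status: str


@dataclass(frozen=True)
class Tolerances:
    """Maximum mismatches allowed in each constant region."""

    index: int = 1
    anchor: int = 2
    spacer: int = 5


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _within(a: str, b: str, max_mismatch: int) -> bool:
    if a == b:  # fast path: most reads are error-free in the constant regions
        return True
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > max_mismatch:
                return False
    return True


def demultiplex(
    seq: str, design: LibraryDesign, max_mismatch: int = 1
) -> str:
    """Sample name whose index matches the read's index interval, or UNASSIGNED.

    A read is assigned only if exactly one index matches within
    ``max_mismatch``; ambiguous matches are UNASSIGNED (cross-talk between
    samples is worse than read loss).
    """
    layout = build_read_layout(design)
    if len(seq) < layout.index[1]:
        return UNASSIGNED
    observed = seq[layout.index[0] : layout.index[1]]
    hit = None
    for sample, index in design.index_table.items():
        if _within(observed, index, max_mismatch):
            if hit is not None:
                return UNASSIGNED
            hit = sample
    return hit if hit is not None else UNASSIGNED


class _Parser:
    """Pre-computed layout slices for fast per-read extraction."""

    def __init__(self, design: LibraryDesign, tolerances: Tolerances):
        self.design = design
        self.tol = tolerances
        self.layout: ReadLayout = build_read_layout(design)
        self.exact_index = {v: k for k, v in design.index_table.items()}
        # Exact-match shortcut is only safe for indexes no other index can
        # reach within the mismatch tolerance (else the match is ambiguous).
        self.safe_index = {
            idx: name
            for idx, name in self.exact_index.items()
            if all(
                hamming(idx, other) > tolerances.index
                for other in self.exact_index
                if other != idx
            )
        }

    def demux(self, seq: str) -> str:
        observed = seq[self.layout.index[0] : self.layout.index[1]]
        sample = self.safe_index.get(observed)
        if sample is not None:
            return sample
        hit = None
        for idx, name in self.exact_index.items():
            if _within(observed, idx, self.tol.index):
                if hit is not None:
                    return UNASSIGNED
                hit = name
        return hit if hit is not None else UNASSIGNED

    def __call__(self, read_id: str, seq: str) -> ExtractedPair:
        lay = self.design
        layout = self.layout
        if len(seq) < layout.roi[1]:
            return ExtractedPair(read_id, UNASSIGNED, None, None, STATUS_TOO_SHORT)
        sample = self.demux(seq)
        if sample == UNASSIGNED:
            return ExtractedPair(read_id, UNASSIGNED, None, None, STATUS_BAD_INDEX)
        anchor = seq[layout.forward_anchor[0] : layout.forward_anchor[1]]
        spacer = seq[layout.spacer[0] : layout.spacer[1]]
        if not _within(anchor, lay.forward_anchor, self.tol.anchor) or not _within(
            spacer, lay.spacer, self.tol.spacer
        ):
            return ExtractedPair(read_id, sample, None, None, STATUS_BAD_ANCHOR)
        bc = seq[layout.bc[0] : layout.bc[1]]
        roi = seq[layout.roi[0] : layout.roi[1]]
        if bc.translate(_NON_ACGT) or roi.translate(_NON_ACGT):
            return ExtractedPair(read_id, sample, None, None, STATUS_BAD_ALPHABET)
        return ExtractedPair(read_id, sample, bc, roi, STATUS_OK)


def extract_pair(
    read_id: str,
    seq: str,
    design: LibraryDesign,
    tolerances: Tolerances | None = None,
) -> ExtractedPair:
    """Parse a single read; failures are statuses, never exceptions."""
    return _Parser(design, tolerances or Tolerances())(read_id, seq)


def parse_fastq(
    path: str | Path,
    design: LibraryDesign,
    tolerances: Tolerances | None = None,
) -> Iterator[ExtractedPair]:
    """Stream ExtractedPairs from a FASTQ or FASTQ.gz file."""
    parser = _Parser(design, tolerances or Tolerances())
    opener = gzip.open if str(path).endswith(".gz") else open
    try:
        with opener(path, "rt") as fh:
            for title, seq, _qual in FastqGeneralIterator(fh):
                yield parser(title.split()[0], seq)
    except OSError as exc:
        raise OSError(f"while reading {path}: {exc}") from exc


class TallyResult(NamedTuple):
    """Per-sample (BC -> ROI -> count) tallies plus parse-status counters."""

    tallies: dict[str, dict[str, dict[str, int]]]
    status_counts: dict[str, int]


def tally_pairs(pairs: Iterable[ExtractedPair]) -> TallyResult:
    """Count status=ok pairs per sample; every read lands in exactly one counter."""
    tallies: dict[str, dict[str, dict[str, int]]] = {}
    status_counts = {s: 0 for s in ALL_STATUSES}
    for pair in pairs:
        status_counts[pair.status] += 1
        if pair.status != STATUS_OK:
            continue
        by_bc = tallies.setdefault(pair.sample, {})
        by_roi = by_bc.setdefault(pair.bc, {})
        by_roi[pair.roi] = by_roi.get(pair.roi, 0) + 1
    return TallyResult(tallies, status_counts)


def write_tally_tsv(result: TallyResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tbc\troi\tcount\n")
        for sample in sorted(result.tallies):
            for bc in sorted(result.tallies[sample]):
                for roi, n in sorted(result.tallies[sample][bc].items()):
                    fh.write(f"{sample}\t{bc}\t{roi}\t{n}\n")


def write_status_tsv(result: TallyResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("status\tcount\n")
        for status in ALL_STATUSES:
            fh.write(f"{status}\t{result.status_counts[status]}\n")
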