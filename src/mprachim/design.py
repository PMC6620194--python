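"""Amplicon layout and plasmid-library containers.

The sequenced single-end read runs, 5' to 3', through an 8-bp sample index,
a constant forward anchor, the 18-bp barcode (BC), a constant spacer (71 or
83 bp depending on the library), the 8-bp region of interest (ROI) and finally
the constant reverse region.  Every other module slices reads at the fixed
offsets computed here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

DNA_ALPHABET = "ACGT"
_NON_ACGT = str.maketrans("", "", DNA_ALPHABET)

#: Constant region between the sample index and the BC (target-specific forward).
DEFAULT_FORWARD_ANCHOR = "GACACTCGAGGATCGAG"
#: Constant region immediately 3' of the ROI (target-specific reverse).
DEFAULT_REVERSE_ANCHOR = "CCCTAGAAAGATAATCATATTGT"
#: Transposase-adapter sequence that follows the reverse anchor on the
#: sequenced strand; used only to pad simulated reads to full length.
READ_TAIL_FILL = "CTGTCTCTTATACACATCTCCGAGCCCACGAGAC"

#: Default 8-bp sample indexes of the indexed forward primers.
DEFAULT_INDEX_TABLE: dict[str, str] = {
    "A_1": "TTCGGAGT",
    "A_2": "ACTCATTT",
    "A_3": "GGGATCCG",
    "A_5": "CAAGATAA",
    "A_6": "GGACAACG",
    "A_7": "AGCGAGCT",
    "A_8": "CTGCACGT",
    "A_9": "GCACTAGT",
}

# The spacer's internal sequence is library-specific and user-supplied in real
# designs; these defaults are fixed pseudorandom sequences drawn once from
# seed 0 (the 71-mer is the prefix of the 83-mer).
DEFAULT_SPACER_83 = (
    "TGGCCAAAATGTGGTGGGGTCTGACTGATGTAATAGACCCCAAAAGGGCGTCCTTTCGTGTGGCTAGGTGCCCCGTATGCGGC"
)
DEFAULT_SPACER_71 = DEFAULT_SPACER_83[:71]


class LayoutOverflowError(ValueError):
    """The amplicon elements do not fit inside the read length."""


def _check_dna(name: str, seq: str) -> None:
    if not seq or seq.translate(_NON_ACGT):
        raise ValueError(f"{name} must be a non-empty A/C/G/T string, got {seq!r}")


@dataclass(frozen=True)
class ReadLayout:
    """Half-open 0-based intervals of each amplicon element within a read."""

    index: tuple[int, int]
    forward_anchor: tuple[int, int]
    bc: tuple[int, int]
    spacer: tuple[int, int]
    roi: tuple[int, int]

    @property
    def span(self) -> int:
        return self.roi[1] - self.index[0]


@dataclass(frozen=True)
class LibraryDesign:
    """Blueprint of the BC-ROI amplicon and of the multiplexed samples.

    Parameters
    ----------
    bc_length, roi_length, index_length:
        Element lengths in nucleotides (defaults 18, 8, 8).
    spacer:
        Constant sequence separating BC and ROI (71 or 83 bp by default).
    forward_anchor, reverse_anchor:
        Constant regions flanking the variable elements.
    index_table:
        Sample name -> 8-bp index sequence.
    read_length:
        Single-end read length (151 by default).
    pad:
        Number of bases preceding the sample index in the read (0 by default;
        records the possibility of extra adapter bases on real data).
    """

    bc_length: int = 18
    roi_length: int = 8
    index_length: int = 8
    spacer: str = DEFAULT_SPACER_71
    forward_anchor: str = DEFAULT_FORWARD_ANCHOR
    reverse_anchor: str = DEFAULT_REVERSE_ANCHOR
    index_table: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_INDEX_TABLE)
    )
    read_length: int = 151
    pad: int = 0

    def __post_init__(self) -> None:
        for n, v in (
            ("bc_length", self.bc_length),
            ("roi_length", self.roi_length),
            ("index_length", self.index_length),
        ):
            if int(v) < 1:
                raise ValueError(f"{n} must be >= 1, got {v}")
        _check_dna("spacer", self.spacer)
        _check_dna("forward_anchor", self.forward_anchor)
        _check_dna("reverse_anchor", self.reverse_anchor)
        if self.pad < 0:
            raise ValueError("pad must be >= 0")
        if not self.index_table:
            raise ValueError("index_table must contain at least one sample")
        seen: dict[str, str] = {}
        for sample, idx in self.index_table.items():
            _check_dna(f"index[{sample}]", idx)
            if len(idx) != self.index_length:
                raise ValueError(
                    f"index of sample {sample} has length {len(idx)}, "
                    f"expected {self.index_length}"
                )
            if idx in seen:
                raise ValueError(f"duplicate index {idx} ({seen[idx]}, {sample})")
            seen[idx] = sample
        # Validate that the read reaches through the ROI.
        build_read_layout(self)

    @property
    def amplicon_core_length(self) -> int:
        return (
            self.index_length
            + len(self.forward_anchor)
            + self.bc_length
            + len(self.spacer)
            + self.roi_length
        )

    def read_template(self, sample: str, bc: str, roi: str) -> str:
        """Error-free read for one molecule of (``bc``, ``roi``) in ``sample``.

        The sequence past the ROI is filled with the reverse anchor followed by
        the adapter fill, truncated at ``read_length``.
        """
        index = self.index_table[sample]
        core = "N" * self.pad + index + self.forward_anchor + bc + self.spacer + roi
        tail = self.reverse_anchor + READ_TAIL_FILL * 4
        return (core + tail)[: self.read_length]

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["index_table"] = dict(self.index_table)
        Path(path).write_text(yaml.safe_dump({"design": data}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LibraryDesign":
        data = yaml.safe_load(Path(path).read_text())["design"]
        return cls(**data)


def build_read_layout(design: LibraryDesign) -> ReadLayout:
    """Half-open 0-based intervals of index/anchor/BC/spacer/ROI in a read.

    Raises
    ------
    LayoutOverflowError
        If the ROI would end past ``read_length``.
    """
    start = design.pad
    bounds = []
    for length in (
        design.index_length,
        len(design.forward_anchor),
        design.bc_length,
        len(design.spacer),
        design.roi_length,
    ):
        bounds.append((start, start + length))
        start += length
    if bounds[-1][1] > design.read_length:
        raise LayoutOverflowError(
            f"amplicon needs {bounds[-1][1]} nt but read_length is {design.read_length}"
        )
    return ReadLayout(*bounds)


@dataclass(frozen=True)
class Clone:
    """One plasmid clone: a unique barcode coupled to a region of interest."""

    bc: str
    roi: str


class PlasmidLibrary:
    """A weighted collection of BC-ROI clones used as PCR template.

    Barcodes are unique across clones; ROI sequences may repeat (8-mers drawn
    at random collide for libraries of realistic size).
    """

    def __init__(
        self,
        design: LibraryDesign,
        clones: Iterable[Clone],
        weights: np.ndarray | None = None,
    ) -> None:
        self.design = design
        self.clones = list(clones)
        if not self.clones:
            raise ValueError("library must contain at least one clone")
        bcs = [c.bc for c in self.clones]
        if len(set(bcs)) != len(bcs):
            raise ValueError("barcodes must be unique across clones")
        for c in self.clones:
            _check_dna("bc", c.bc)
            _check_dna("roi", c.roi)
            if len(c.bc) != design.bc_length or len(c.roi) != design.roi_length:
                raise ValueError(f"clone {c} does not match the design lengths")
        if weights is None:
            weights = np.ones(len(self.clones))
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(self.clones),):
            raise ValueError("weights must have one entry per clone")
        if not np.all(np.isfinite(weights)) or np.any(weights <= 0):
            raise ValueError("weights must be positive and finite")
        self.weights = weights / weights.sum()

        # ROI sequences deduplicated: species bookkeeping in the simulator is
        # done on (clone index, ROI-sequence id) pairs.
        self.roi_seqs: list[str] = sorted({c.roi for c in self.clones})
        roi_id = {r: i for i, r in enumerate(self.roi_seqs)}
        self.clone_roi_id = np.array([roi_id[c.roi] for c in self.clones])

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def bcs(self) -> list[str]:
        return [c.bc for c in self.clones]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("bc\troi\n")
            for c in self.clones:
                fh.write(f"{c.bc}\t{c.roi}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, design: LibraryDesign) -> "PlasmidLibrary":
        clones = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["bc", "roi"]:
                raise ValueError(f"unexpected header in {path}: {header}")
            for line in fh:
                bc, roi = line.rstrip("\n").split("\t")[:2]
                clones.append(Clone(bc, roi))
        return cls(design, clones)

    def to_fasta(self, path: str | Path, sample: str | None = None) -> None:
        """Write full error-free amplicon reads, one per clone."""
        if sample is None:
            sample = next(iter(self.design.index_table))
        with open(path, "w") as fh:
            for i, c in enumerate(self.clones):
                fh.write(f">clone_{i} bc={c.bc} roi={c.roi}\n")
                fh.write(self.design.read_template(sample, c.bc, c.roi) + "\n")


def random_library(
    n_clones: int, design: LibraryDesign | None = None, seed: int = 0
) -> PlasmidLibrary:
    """Library of ``n_clones`` i.i.d. uniform random BC/ROI pairs.

    Barcodes are resampled on collision so they are unique; ROIs may repeat.
    Deterministic given ``seed``.
    """
    if design is None:
        design = LibraryDesign()
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if np.log(n_clones) > design.bc_length * np.log(4):
        raise ValueError(
            f"cannot draw {n_clones} unique barcodes of length {design.bc_length}"
        )
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)

    def draw(n: int, length: int) -> list[str]:
        codes = alphabet[rng.integers(0, 4, size=(n, length))]
        return [row.tobytes().decode() for row in codes]

    bcs: list[str] = []
    seen: set[str] = set()
    while len(bcs) < n_clones:
        for bc in draw(n_clones - len(bcs), design.bc_length):
            if bc not in seen:
                seen.add(bc)
                bcs.append(bc)
    rois = draw(n_clones, design.roi_length)
    return PlasmidLibrary(design, [Clone(b, r) for b, r in zip(bcs, rois)])
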