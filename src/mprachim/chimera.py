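"""Genuine-ROI calling and chimera quantification.

For every genuine barcode the associated ROI reads are tallied; the ROI
carried by strictly more than half of them is the genuine ROI.  Reads whose
ROI differs from the genuine one by exactly 1 nucleotide are attributed to
PCR/sequencing errors; reads at distance >= 2 are counted as chimeric PCR
products.  Sample-level summaries pool those per-barcode counts; barcodes with
no majority ROI are excluded from both numerator and denominator (the
``all-parsed`` denominator alternative keeps their reads in the denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mprachim.barcodes import BarcodeCluster
from mprachim.extract import hamming

UNDEFINED = None

__all__ = [
    "BCReport",
    "SampleReport",
    "call_genuine_roi",
    "classify_bc",
    "cluster_roi_counts",
    "bc_reports",
    "sample_summary",
    "average_conditions",
    "per_bc_histogram",
    "fold_change",
    "format_fold",
    "round_half_up",
]


@dataclass(frozen=True)
class BCReport:
    """Three-way read classification for one genuine barcode."""

    genuine_bc: str
    genuine_roi: str | None
    n_genuine: int
    n_error: int
    n_chimeric: int

    @property
    def total(self) -> int:
        return self.n_genuine + self.n_error + self.n_chimeric

    @property
    def chimera_proportion(self) -> float:
        return self.n_chimeric / self.total if self.total else 0.0


@dataclass(frozen=True)
class SampleReport:
    """Sample-level roll-up of per-barcode chimera counts."""

    condition: str
    n_genuine_bcs: int
    total_read_count: int
    chimeric_read_count: int

    @property
    def chimeric_read_percent(self) -> float:
        if self.total_read_count == 0:
            return 0.0
        return 100.0 * self.chimeric_read_count / self.total_read_count


def call_genuine_roi(roi_counts: Mapping[str, int]) -> str | None:
    """ROI carried by strictly more than half of the reads, else None.

    The inequality is strict: an exact 50% tie yields no genuine ROI.
    """
    total = sum(roi_counts.values())
    if total <= 0:
        raise ValueError("roi_counts must contain at least one read")
    best_roi, best_n = max(roi_counts.items(), key=lambda kv: kv[1])
    return best_roi if 2 * best_n > total else UNDEFINED


def classify_bc(
    genuine_bc: str,
    roi_counts: Mapping[str, int],
    genuine_roi: str,
    error_dist: int = 1,
) -> BCReport:
    """Partition a barcode's reads into genuine / error / chimeric.

    Distance 0 from the genuine ROI is genuine, 1..``error_dist`` is an
    amplification or sequencing error, anything farther is chimeric.
    """
    n_genuine = n_error = n_chimeric = 0
    for roi, n in roi_counts.items():
        d = hamming(roi, genuine_roi)
        if d == 0:
            n_genuine += n
        elif d <= error_dist:
            n_error += n
        else:
            n_chimeric += n
    return BCReport(genuine_bc, genuine_roi, n_genuine, n_error, n_chimeric)


def cluster_roi_counts(
    clusters: Iterable[BarcodeCluster],
    tally: Mapping[str, Mapping[str, int]],
) -> dict[str, dict[str, int]]:
    """ROI tallies per genuine barcode, pooled over cluster members.

    ``tally`` maps observed barcode -> (ROI -> count) for one sample, as
    produced by :func:`mprachim.extract.tally_pairs`.
    """
    out: dict[str, dict[str, int]] = {}
    for cluster in clusters:
        counts: dict[str, int] = {}
        for member in cluster.members:
            for roi, n in tally.get(member, {}).items():
                counts[roi] = counts.get(roi, 0) + n
        out[cluster.genuine_bc] = counts
    return out


def bc_reports(
    roi_counts_by_bc: Mapping[str, Mapping[str, int]],
    error_dist: int = 1,
) -> tuple[list[BCReport], int]:
    """Classify every genuine barcode; returns reports and the read count of
    barcodes whose genuine ROI is undefined (majority tie)."""
    reports: list[BCReport] = []
    undefined_reads = 0
    for bc, counts in roi_counts_by_bc.items():
        if not counts:
            continue
        roi = call_genuine_roi(counts)
        if roi is UNDEFINED:
            undefined_reads += sum(counts.values())
            continue
        reports.append(classify_bc(bc, counts, roi, error_dist))
    return reports, undefined_reads


def sample_summary(
    reports: Sequence[BCReport],
    condition: str,
    undefined_reads: int = 0,
    denominator: str = "defined-roi",
) -> SampleReport:
    """Pool per-barcode counts into the sample-level chimeric percentage.

    ``denominator="defined-roi"`` (default) counts only reads of barcodes with
    a defined genuine ROI; ``"all-parsed"`` adds ``undefined_reads`` to the
    denominator.
    """
    if denominator not in ("defined-roi", "all-parsed"):
        raise ValueError("denominator must be 'defined-roi' or 'all-parsed'")
    if not reports:
        raise ValueError("no barcodes with a defined genuine ROI")
    total = sum(r.total for r in reports)
    if denominator == "all-parsed":
        total += undefined_reads
    chimeric = sum(r.n_chimeric for r in reports)
    return SampleReport(condition, len(reports), total, chimeric)


def average_conditions(
    percents_by_condition: Mapping[str, Sequence[float]],
) -> dict[str, float]:
    """Unweighted arithmetic mean of the percentages within each condition."""
    out: dict[str, float] = {}
    for condition, values in percents_by_condition.items():
        values = list(values)
        if not values:
            raise ValueError(f"condition {condition!r} has no values")
        out[condition] = float(np.mean(values))
    return out


def per_bc_histogram(
    replicate_reports: Sequence[Mapping[str, BCReport]],
    bins: int = 50,
) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    """Histogram of per-barcode chimera proportion averaged across replicates.

    Only barcodes present in every replicate are used.  Returns bin counts,
    bin edges (``bins`` equal-width bins on [0, 1]) and the per-barcode mean
    proportions.  Bin counts sum to the number of shared barcodes.
    """
    if not replicate_reports:
        raise ValueError("need at least one replicate")
    shared = set(replicate_reports[0])
    for rep in replicate_reports[1:]:
        shared &= set(rep)
    means = pd.Series(
        {
            bc: float(np.mean([rep[bc].chimera_proportion for rep in replicate_reports]))
            for bc in sorted(shared)
        },
        dtype=float,
    )
    counts, edges = np.histogram(means.to_numpy(), bins=bins, range=(0.0, 1.0))
    return counts, edges, means


def fold_change(percent_a: float, percent_b: float) -> float:
    """Plain ratio a/b of two chimeric percentages."""
    if percent_b == 0:
        raise ZeroDivisionError("reference percentage is zero")
    return percent_a / percent_b


def format_fold(ratio: float) -> str:
    """Fold change to two significant figures, as reported in summaries."""
    return f"{ratio:.2g}"


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding used to match tabulated report precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
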