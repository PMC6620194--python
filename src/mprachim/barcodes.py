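"""Genuine-barcode calling by greedy directional Hamming collapse.

Sequencing and PCR substitutions scatter reads of one true barcode over a
cloud of near-identical variants.  Candidates are processed in descending read
count (ties lexicographic); each either seeds a new cluster or, if it lies
within ``max_subs`` substitutions of an already-seeded barcode with a strictly
greater count, joins that cluster (nearest seed; among equidistant seeds the
more abundant, then lexicographically smallest).  Clusters supported by fewer
than ``min_reads`` total reads are discarded.  Distances are Hamming only:
equal lengths, no indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "BarcodeCluster",
    "collapse_barcodes",
    "filter_genuine",
    "intersect_replicates",
]


@dataclass
class BarcodeCluster:
    """A genuine barcode with its substitution-variant members.

    ``members`` maps every member barcode (including ``genuine_bc`` itself) to
    its read count; ``total_reads`` is the sum over members.
    """

    genuine_bc: str
    members: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.members.values())

    @property
    def genuine_count(self) -> int:
        return self.members[self.genuine_bc]


def _encode(bcs: list[str], length: int) -> np.ndarray:
    return np.frombuffer("".join(bcs).encode(), dtype=np.uint8).reshape(
        len(bcs), length
    )


def collapse_barcodes(
    bc_counts: Mapping[str, int],
    max_subs: int = 2,
    ambiguous: str = "nearest",
) -> list[BarcodeCluster]:
    """Collapse observed barcodes into clusters around their intact versions.

    Parameters
    ----------
    bc_counts:
        Observed barcode -> read count (counts >= 1, all equal length).
    max_subs:
        Maximum substitutions between a variant and its intact barcode.
    ambiguous:
        ``"nearest"`` (default) assigns a variant within reach of several seeds
        to the nearest / most abundant one; ``"drop"`` discards such variants
        (their reads appear in no cluster).

    Returns
    -------
    Clusters in seed order (descending seed count).  Clusters are always
    seeded by observed sequences, never by consensus construction.
    """
    if ambiguous not in ("nearest", "drop"):
        raise ValueError("ambiguous must be 'nearest' or 'drop'")
    if not bc_counts:
        return []
    lengths = {len(b) for b in bc_counts}
    if len(lengths) != 1:
        raise ValueError(f"barcodes must share one length, got lengths {sorted(lengths)}")
    (length,) = lengths
    if any(c < 1 for c in bc_counts.values()):
        raise ValueError("read counts must be >= 1")

    order = sorted(bc_counts, key=lambda b: (-bc_counts[b], b))
    codes = _encode(order, length)

    clusters: list[BarcodeCluster] = []
    seed_codes = np.empty((len(order), length), dtype=np.uint8)
    seed_counts = np.empty(len(order), dtype=np.int64)
    n_seeds = 0

    for i, bc in enumerate(order):
        count = bc_counts[bc]
        parent = None
        if n_seeds:
            d = np.count_nonzero(seed_codes[:n_seeds] != codes[i], axis=1)
            eligible = np.flatnonzero((d <= max_subs) & (seed_counts[:n_seeds] > count))
            if eligible.size:
                if ambiguous == "drop" and eligible.size > 1:
                    continue
                best = min(
                    eligible,
                    key=lambda j: (d[j], -seed_counts[j], clusters[j].genuine_bc),
                )
                parent = clusters[best]
        if parent is None:
            clusters.append(BarcodeCluster(bc, {bc: count}))
            seed_codes[n_seeds] = codes[i]
            seed_counts[n_seeds] = count
            n_seeds += 1
        else:
            parent.members[bc] = count
    return clusters


def filter_genuine(
    clusters: Iterable[BarcodeCluster], min_reads: int = 2
) -> set[str]:
    """Genuine barcodes of clusters supported by at least ``min_reads`` reads.

    The threshold applies to the cluster total (intact barcode plus variant
    members), not the intact sequence's own count.
    """
    return {c.genuine_bc for c in clusters if c.total_reads >= min_reads}


def filter_clusters(
    clusters: Iterable[BarcodeCluster], min_reads: int = 2
) -> list[BarcodeCluster]:
    return [c for c in clusters if c.total_reads >= min_reads]


def intersect_replicates(*genuine_sets: Iterable[str]) -> set[str]:
    """Barcodes called genuine in every replicate (the library-size statistic)."""
    if len(genuine_sets) < 2:
        raise ValueError("need at least two replicate sets")
    sets = [set(s) for s in genuine_sets]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def write_clusters_tsv(clusters: Iterable[BarcodeCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("genuine_bc\tmember_bc\tcount\n")
        for c in clusters:
            for member, n in sorted(c.members.items(), key=lambda kv: (-kv[1], kv[0])):
                fh.write(f"{c.genuine_bc}\t{member}\t{n}\n")
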