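"""Published reference measurements shipped with the package.

NGS-derived chimeric-read percentages from a two-round amplification study of
BC-ROI amplicons: a two-plasmid template system sequenced under three round-2
conditions, and two high-diversity MPRA libraries (71- and 83-bp spacers)
amplified by emulsion or conventional PCR at two elongation times.  Each
condition was sequenced in duplicate (replicates R1/R2).  These tables are the
worked-example inputs for :func:`mprachim.chimera.average_conditions` and
:func:`mprachim.chimera.fold_change`.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "two_plasmid_table",
    "library_table",
    "TWO_PLASMID_CONDITIONS",
    "LIBRARY_GROUPS",
]

# condition -> (combination, replicate) -> chimeric read percent.
_TWO_PLASMID_ROWS = [
    # (condition, combination, replicate, chimeric_percent)
    ("0.5ul_20cycles", "BC1-ROI2", "R1", 1.579),
    ("0.5ul_20cycles", "BC1-ROI2", "R2", 1.651),
    ("0.5ul_20cycles", "BC2-ROI1", "R1", 1.465),
    ("0.5ul_20cycles", "BC2-ROI1", "R2", 1.347),
    ("0.3ul_20cycles", "BC1-ROI2", "R1", 0.831),
    ("0.3ul_20cycles", "BC1-ROI2", "R2", 0.629),
    ("0.3ul_20cycles", "BC2-ROI1", "R1", 0.737),
    ("0.3ul_20cycles", "BC2-ROI1", "R2", 0.440),
    ("0.5ul_18cycles", "BC1-ROI2", "R1", 0.200),
    ("0.5ul_18cycles", "BC1-ROI2", "R2", 0.225),
    ("0.5ul_18cycles", "BC2-ROI1", "R1", 0.230),
    ("0.5ul_18cycles", "BC2-ROI1", "R2", 0.211),
]

#: Printed per-replicate "Average" columns of the two-plasmid table, used to
#: check that the roll-up is the unweighted mean of the two combinations.
TWO_PLASMID_PRINTED_AVERAGES = {
    "0.5ul_20cycles": {"R1": 1.522, "R2": 1.499},
    "0.3ul_20cycles": {"R1": 0.784, "R2": 0.535},
    "0.5ul_18cycles": {"R1": 0.215, "R2": 0.218},
}

_LIBRARY_ROWS = [
    # (pcr_type, elongation_s, library, genuine_bcs_both_reps,
    #  reads_R1, reads_R2, pct_R1, pct_R2)
    ("emulsion", 10, "library-71", 22621, 526056, 497217, 0.580, 0.555),
    ("emulsion", 30, "library-71", 51650, 594511, 514941, 0.342, 0.310),
    ("emulsion", 30, "library-83", 38156, 371889, 456380, 0.261, 0.304),
    ("conventional", 30, "library-71", 85249, 776878, 784138, 0.336, 0.337),
    ("conventional", 30, "library-83", 52654, 788801, 809402, 0.295, 0.310),
]

#: Row keys of the two-plasmid conditions, round-2 template volume + cycles.
TWO_PLASMID_CONDITIONS = ("0.5ul_20cycles", "0.3ul_20cycles", "0.5ul_18cycles")

#: Comparison groups of the library table: (pcr_type, elongation time).
LIBRARY_GROUPS = (("emulsion", 10), ("emulsion", 30), ("conventional", 30))


def two_plasmid_table() -> pd.DataFrame:
    """Tidy two-plasmid chimeric percentages (one row per condition,
    chimeric combination and replicate)."""
    return pd.DataFrame(
        _TWO_PLASMID_ROWS,
        columns=["condition", "combination", "replicate", "chimeric_percent"],
    )


def library_table() -> pd.DataFrame:
    """MPRA-library chimeric percentages, one row per PCR condition and library."""
    return pd.DataFrame(
        _LIBRARY_ROWS,
        columns=[
            "pcr_type",
            "elongation_s",
            "library",
            "genuine_bcs_both_reps",
            "reads_R1",
            "reads_R2",
            "pct_R1",
            "pct_R2",
        ],
    )


def two_plasmid_percents_by_condition() -> dict[str, list[float]]:
    """All four per-replicate percentages of each two-plasmid condition."""
    df = two_plasmid_table()
    return {
        cond: df.loc[df.condition == cond, "chimeric_percent"].tolist()
        for cond in TWO_PLASMID_CONDITIONS
    }


def library_percents_by_group() -> dict[tuple[str, int], list[float]]:
    """All per-replicate percentages of each (PCR type, elongation) group."""
    df = library_table()
    out: dict[tuple[str, int], list[float]] = {}
    for pcr_type, elong in LIBRARY_GROUPS:
        sub = df[(df.pcr_type == pcr_type) & (df.elongation_s == elong)]
        out[(pcr_type, elong)] = sub.pct_R1.tolist() + sub.pct_R2.tolist()
    return out
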