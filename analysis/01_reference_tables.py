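#!/usr/bin/env python
"""Worked-example arithmetic on the shipped reference chimera measurements.

Averages the tabulated per-replicate chimeric-read percentages within each
PCR condition and forms the two headline fold changes: diverse library vs
two-plasmid template (chimera potential of diversity) and 10 s vs 30 s
elongation (effect of extension time).  Writes
results/reference_table_stats.tsv.
"""

from pathlib import Path

from mprachim import datasets
from mprachim.chimera import average_conditions, fold_change, format_fold, round_half_up

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

two_plasmid = datasets.two_plasmid_percents_by_condition()
groups = datasets.library_percents_by_group()
means = average_conditions(
    {**two_plasmid, **{f"{t}_{e}s": v for (t, e), v in groups.items()}}
)

rows = [("condition", "n_values", "mean_chimeric_pct")]
for cond, values in {**two_plasmid}.items():
    rows.append((cond, len(values), round_half_up(means[cond], 2)))
for (t, e), values in groups.items():
    rows.append((f"{t}_{e}s", len(values), round_half_up(means[f"{t}_{e}s"], 2)))

folds = [
    ("library_epcr_10s_vs_two_plasmid_best", means["emulsion_10s"], means["0.5ul_18cycles"]),
    ("elongation_10s_vs_30s", means["emulsion_10s"], means["emulsion_30s"]),
]

with open(OUT / "reference_table_stats.tsv", "w") as fh:
    for row in rows:
        fh.write("\t".join(map(str, row)) + "\n")
    fh.write("\ncomparison\tnumerator_pct\tdenominator_pct\tfold\n")
    for name, a, b in folds:
        fh.write(f"{name}\t{a:.4f}\t{b:.4f}\t{format_fold(fold_change(a, b))}\n")

print("condition means (chimeric reads, %):")
for cond, n, m in rows[1:]:
    print(f"  {cond:<20} {m:>5} (mean of {n} replicate values)")
print("fold changes:")
for name, a, b in folds:
    print(f"  {name}: {format_fold(fold_change(a, b))}")
print(f"written: {OUT / 'reference_table_stats.tsv'}")
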