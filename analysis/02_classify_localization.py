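#!/usr/bin/env python
"""Classify each miRNA as preferentially secreted, retained, or neutral.

Reads the abundance tables written by 01_simulate.py, reduces them to
percentage composition over the reliably detected miRNAs, compares
compartments with the equal-variance t-test under two-stage BKY FDR
(q < 0.05), and summarizes AU% and length by class.
"""

from pathlib import Path

from mirsort.io_formats import read_abundance_table, read_fasta
from mirsort.localization import classify_localization, compare_class_sequence_stats

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cell = read_abundance_table(ROOT / "data" / "cell.tsv", "CELL")
    sev = read_abundance_table(ROOT / "data" / "sev.tsv", "SEV")
    seqs = read_fasta(ROOT / "data" / "sequences.fa")

    table = classify_localization(cell, sev, q=0.05)
    table.to_tsv(ROOT / "localization.tsv")
    counts = table.counts
    n_tested = len(table.table) - counts["UNDETECTED"]
    print(f"tested {n_tested} miRNAs detected in at least one compartment:")
    for call in ("SEV_ENRICHED", "CELL_ENRICHED", "NEUTRAL"):
        print(f"  {call}: {counts[call]} ({100 * counts[call] / n_tested:.2f}%)")

    stats = compare_class_sequence_stats(table, seqs)
    stats.per_class.to_csv(ROOT / "class_sequence_stats.tsv", sep="\t", index=False)
    stats.tests.to_csv(ROOT / "class_sequence_tests.tsv", sep="\t", index=False)
    per = stats.per_class.set_index("class")
    au_test = stats.tests.set_index("statistic").loc["au_fraction"]
    print(
        f"mean AU%: sEV {100 * per.at['SEV_ENRICHED', 'mean_au_fraction']:.1f} "
        f"vs cell {100 * per.at['CELL_ENRICHED', 'mean_au_fraction']:.1f} "
        f"(t-test p = {au_test['p_value']:.2e})"
    )
    len_test = stats.tests.set_index("statistic").loc["length"]
    print(
        f"mean length: sEV {per.at['SEV_ENRICHED', 'mean_length']:.1f} nt "
        f"vs cell {per.at['CELL_ENRICHED', 'mean_length']:.1f} nt "
        f"(p = {len_test['p_value']:.2f})"
    )


if __name__ == "__main__":
    main()
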