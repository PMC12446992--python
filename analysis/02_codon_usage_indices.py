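"""Codon-usage-bias indices of the partner (bacterium-like) organism.

Computes per-gene GC/GC1/GC2/GC3, ENC, SCUO and PR2 coordinates, the
genome-level RSCU table for both organisms side by side, summary statistics
with the pairwise index correlation matrix, PR2 quadrant counts, and the
position of genes relative to the expected ENC-GC3 curve.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _data import RESULTS, require_dataset

import numpy as np

import cublink as cl


def main() -> None:
    data = require_dataset()
    out = RESULTS / "indices"
    out.mkdir(parents=True, exist_ok=True)

    query, _ = cl.read_and_qc(data / "query_cds.fasta")
    partner, qc = cl.read_and_qc(data / "partner_cds.fasta")
    print(f"QC: {qc.n_pass} partner sequences pass, {qc.n_fail} removed")

    table = cl.gene_index_table(partner)
    table.reset_index().to_csv(out / "partner_gene_indices.tsv", sep="\t", index=False)

    summary, r, p = cl.index_summary_and_correlations(table)
    summary.rename_axis("index").reset_index().to_csv(
        out / "partner_index_summary.tsv", sep="\t", index=False
    )
    r.rename_axis("index").reset_index().to_csv(
        out / "partner_index_correlations.tsv", sep="\t", index=False
    )

    print("partner organism index ranges:")
    for name in ("gc", "gc3", "enc", "scuo"):
        row = summary.loc[name]
        print(f"  {name:<5} min {row['min']:.4f}  mean {row['mean']:.4f}  "
              f"max {row['max']:.4f}")
    print(f"  ENC-GC3 correlation r = {r.loc['enc', 'gc3']:.3f}, "
          f"ENC-SCUO r = {r.loc['enc', 'scuo']:.3f}")

    expected = cl.enc_expected_curve(table["gc3"].to_numpy())
    below = int((table["enc"] < expected).sum())
    print(f"  {below} of {len(table)} genes fall below the expected ENC-GC3 curve "
          "(codon bias beyond mutation pressure alone)")

    quadrants = cl.indices.pr2_quadrant_counts(table)
    quadrants.rename_axis("quadrant").reset_index(name="n_genes").to_csv(
        out / "partner_pr2_quadrants.tsv", sep="\t", index=False
    )
    print("  PR2 quadrants:", dict(quadrants))

    rscu_table = cl.genome_rscu_table(
        {"query": cl.count_codons(query), "partner": cl.count_codons(partner)}
    )
    rscu_table.to_csv(out / "genome_rscu.tsv", sep="\t", index=False)
    shared = rscu_table[
        (rscu_table["codon"].str[2].isin(["A", "T"]))
        & (rscu_table["query"] > 1)
        & (rscu_table["partner"] > 1)
    ]
    print(f"  {len(shared)} A/T-ending codons preferred (RSCU > 1) by BOTH organisms")


if __name__ == "__main__":
    main()
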