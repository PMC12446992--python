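"""Host-adaptation of the partner organism to the query organism.

Computes per-gene CAI and RCDI of every partner (bacterium-like) gene
relative to the query (plant-like) reference codon usage, plus the
organism-level similarity index SiD on both supported bases.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _data import RESULTS, require_dataset

import cublink as cl


def main() -> None:
    data = require_dataset()
    out = RESULTS / "adaptation"
    out.mkdir(parents=True, exist_ok=True)

    query, _ = cl.read_and_qc(data / "query_cds.fasta")
    partner, _ = cl.read_and_qc(data / "partner_cds.fasta")
    query_counts = cl.count_codons(query)
    partner_counts = cl.count_codons(partner)

    adapt = cl.adaptation_table(partner_counts, query_counts)
    adapt.reset_index().to_csv(out / "partner_adaptation.tsv", sep="\t", index=False)

    sid_values = {
        basis: cl.sid(
            cl.organism_usage(query_counts, basis),
            cl.organism_usage(partner_counts, basis),
        )
        for basis in ("rscu", "frequency")
    }
    (out / "sid.json").write_text(json.dumps(sid_values, indent=1, sort_keys=True))

    print(f"partner CAI vs query reference: mean {adapt['cai'].mean():.4f}, "
          f"range {adapt['cai'].min():.4f} - {adapt['cai'].max():.4f}")
    print(f"partner RCDI vs query reference: mean {adapt['rcdi'].mean():.4f}, "
          f"range {adapt['rcdi'].min():.4f} - {adapt['rcdi'].max():.4f}")
    print(f"SiD (RSCU basis) = {sid_values['rscu']:.4f}; "
          f"SiD (frequency basis) = {sid_values['frequency']:.4f} "
          "(0 = identical usage direction, 0.5 = orthogonal)")


if __name__ == "__main__":
    main()
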