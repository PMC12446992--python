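"""Generate the synthetic study dataset with known ground truth.

Writes two CDS FASTA files, the four-group count matrix (gene ids matched to
the query organism so downstream stages can subset by screen results), two
DEG tables with exactly planted common calls, a Ct table, and the truth
record, all under results/data/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _data import DATA, DISPERSION, EFFECT, LAMBDA, N_GENES, N_PLANTED, RESCUE_PATTERN, SEED

import cublink as cl


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    plant, bact = cl.plant_like_model(), cl.bacterium_like_model()

    query, truth = cl.generate_cds_set(
        plant, N_GENES, partner_model=bact, n_planted=N_PLANTED, lam=LAMBDA,
        id_prefix="ATSYN", seed=SEED,
    )
    partner, _ = cl.generate_cds_set(bact, N_GENES, id_prefix="BASYN", seed=SEED + 1)
    cl.write_fasta(query, DATA / "query_cds.fasta")
    cl.write_fasta(partner, DATA / "partner_cds.fasta")

    sim = cl.simulate_counts(
        N_GENES, planted={RESCUE_PATTERN: N_PLANTED}, effect=EFFECT,
        dispersion=DISPERSION, seed=SEED + 2,
    )
    # counts describe the query organism's genes; half the rescue-planted
    # count genes are mapped onto planted similar-CUB genes, emulating the
    # study's finding that bacterium-responsive calcium-rescue genes are
    # enriched in (but not identical to) the similar-CUB subset
    import numpy as np

    map_rng = np.random.default_rng(SEED + 5)
    planted_g = sorted(sim.truth.planted_profiles["0,0,1,0"])
    other_g = [g for g in sim.counts.index if g not in set(planted_g)]
    similar_ids = sorted(truth.planted_similar)
    other_ids = [s.id for s in query if s.id not in set(similar_ids)]
    n_inside = len(planted_g) // 2
    inside = sorted(map_rng.choice(similar_ids, size=n_inside, replace=False))
    rescue_targets = inside + other_ids[: len(planted_g) - n_inside]
    remaining = [s.id for s in query if s.id not in set(rescue_targets)]
    rename = dict(zip(planted_g, rescue_targets)) | dict(zip(other_g, remaining))
    counts = sim.counts.rename(index=rename).sort_index()
    counts.rename_axis("gene_id").to_csv(DATA / "counts.tsv", sep="\t")
    sim.groups.rename_axis("sample").reset_index().to_csv(
        DATA / "groups.tsv", sep="\t", index=False
    )
    planted_rescue = sorted(rename[g] for g in sim.truth.planted_profiles["0,0,1,0"])

    a, b, deg_truth = cl.simulate_deg_tables(
        N_GENES, n_common_up=25, n_common_down=25, n_only_a=10, n_only_b=10,
        n_conflict=5, seed=SEED + 3,
    )
    a.to_csv(DATA / "deg_a.tsv", sep="\t", index=False)
    b.to_csv(DATA / "deg_b.tsv", sep="\t", index=False)

    ct = cl.simulate_ct_table(
        {"BGLU40": {"CaCl2": 4.0, "CaCl2+LZ04": 1.5},
         "HNL": {"CaCl2": 2.5, "CaCl2+LZ04": 2.0}},
        noise_sd=0.15, seed=SEED + 4,
    )
    ct.to_csv(DATA / "ct.tsv", sep="\t", index=False)

    record = {
        "seed": SEED,
        "lambda": LAMBDA,
        "planted_similar": list(truth.planted_similar),
        "planted_rescue": planted_rescue,
        "deg_truth": {k: list(v) for k, v in deg_truth.planted_degs["contrast"].items()},
    }
    (DATA / "truth.json").write_text(json.dumps(record, indent=1, sort_keys=True))

    print(f"wrote dataset to {DATA}")
    print(f"  query CDS: {len(query)} genes ({N_PLANTED} planted at lambda={LAMBDA})")
    print(f"  partner CDS: {len(partner)} genes")
    print(f"  counts: {counts.shape[0]} genes x {counts.shape[1]} samples "
          f"({N_PLANTED} planted on pattern {RESCUE_PATTERN}, effect {EFFECT}, "
          f"dispersion {DISPERSION})")
    print("  DEG tables: 25 common up, 25 common down, 5 direction conflicts planted")


if __name__ == "__main__":
    main()
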