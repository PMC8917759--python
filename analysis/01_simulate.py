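#!/usr/bin/env python
"""Generate every synthetic input for the downstream analyses.

Writes a 40-gene IAP family (proteins, gene models, domain scans, HMM
candidates, coverage, ground truth), three immune-challenge DE experiments
with planted status/sharing structure, and a 240-gene expression matrix with
four planted co-expression modules (one trait-associated).  Everything is
deterministic under the seed below.
"""

import json
from pathlib import Path

from oysteriap import synth

SEED = 42
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "synthetic"


def main() -> None:
    fam = synth.gen_family(n_genes=40, seed=SEED)
    fam.write(OUT / "family")
    n_iap = sum(v["is_iap"] for v in fam.truth["genes"].values())
    print(f"family: {n_iap} IAP genes "
          f"({len(fam.truth['haplotigs'])} haplotig copies, "
          f"{len(fam.truth['intronless'])} intronless, "
          f"{len(fam.truth['tandem_arrays'])} tandem arrays), "
          f"{len(fam.hmm_candidates) - n_iap} decoy candidates")

    statuses, planted_frac = synth.gen_shared_status_maps(
        ("expA", "expB", "expC"), n_shared=6, n_unique_per_experiment=3)
    bundles = synth.gen_de_tables(
        statuses, n_samples=8,
        comparisons=("c1_vs_control", "c2_vs_control"), seed=SEED)
    de_dir = OUT / "expression"
    de_dir.mkdir(parents=True, exist_ok=True)
    for exp_id, b in bundles.items():
        b["de"].to_csv(de_dir / f"de_{exp_id}.tsv", sep="\t", index=False)
        b["counts"].rename_axis("transcript_id").to_csv(
            de_dir / f"counts_{exp_id}.tsv", sep="\t")
        with open(de_dir / f"gene_transcripts_{exp_id}.json", "w") as fh:
            json.dump(b["gene_transcripts"], fh, indent=2, sort_keys=True)
    with open(de_dir / "truth.json", "w") as fh:
        json.dump({"statuses": statuses,
                   "planted_shared_fraction": planted_frac},
                  fh, indent=2, sort_keys=True)
    print(f"expression statuses: 3 experiments, planted shared-DEG "
          f"fraction {planted_frac:.3f}")

    expr, trait, labels = synth.gen_expression(
        240, 20, (50, 50, 50, 50), within_correlation=0.7,
        trait_r=(0.8, 0.0, 0.0, 0.0), seed=SEED)
    net_dir = OUT / "network"
    net_dir.mkdir(parents=True, exist_ok=True)
    expr.rename_axis("gene_id").to_csv(net_dir / "expr.tsv", sep="\t",
                                       float_format="%.6g")
    trait.rename_axis("sample_id").to_frame().to_csv(
        net_dir / "trait.tsv", sep="\t")
    with open(net_dir / "module_truth.json", "w") as fh:
        json.dump({g: int(m) for g, m in zip(expr.index, labels)}, fh,
                  indent=2, sort_keys=True)
    print("network input: 240 genes x 20 samples, 4 planted modules "
          "(module 1 trait-associated at r = 0.8)")


if __name__ == "__main__":
    main()
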