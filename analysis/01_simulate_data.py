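"""Generate the synthetic study inputs with planted ground truth.

Produces a proteome with planted RR-TZF architectures (5 proteins per
class), a qPCR CT table emulating a salt-stress time course with planted
log2 fold changes, and a germination count table with planted rates.
Everything downstream (02-06) reads these files from results/simulated.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from rrtzf.io import write_fasta
from rrtzf.synth import (
    CLASS_NAMES,
    ProteomeSpec,
    generate_ct_table,
    generate_germination,
    generate_proteome,
)

# salt-stress time-course design: planted log2 fold changes vs untreated
CT_DESIGN = {"mock": 0.0, "NaCl_1h": 1.0, "NaCl_3h": 1.7, "NaCl_6h": 0.8}
GERMINATION_DESIGN = {
    ("Col0", "NaCl"): 0.60,
    ("attenuated", "NaCl"): 0.85,     # knock-down: more salt tolerant
    ("overexpressor", "NaCl"): 0.25,  # overexpression: more sensitive
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/simulated")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    spec = ProteomeSpec(counts={c: 5 for c in CLASS_NAMES}, seed=args.seed)
    res = generate_proteome(spec)
    write_fasta(res.records, out / "proteome.fasta")
    write_fasta(res.references.exemplars, out / "references.fasta")
    truth = pd.DataFrame([{
        "protein_id": t.protein_id, "class": t.class_name,
        "is_rr_tzf": t.is_rr_tzf, "group": t.group, "subgroup": t.subgroup,
    } for t in res.truth])
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    ct = generate_ct_table(CT_DESIGN, calibrator_group="mock",
                           noise_sd=0.15, n_bio=3, n_tech=3, seed=args.seed)
    ct.to_csv(out / "ct.tsv", sep="\t", index=False)

    germ = generate_germination(GERMINATION_DESIGN, total_seeds=75, n_rep=3,
                                seed=args.seed)
    germ.to_csv(out / "germination.tsv", sep="\t", index=False)

    (out / "design.json").write_text(json.dumps({
        "seed": args.seed, "proteins_per_class": 5,
        "ct_log2_fold_changes": CT_DESIGN,
        "germination_rates": {f"{g}|{c}": r for (g, c), r in GERMINATION_DESIGN.items()},
    }, indent=2) + "\n")
    print(f"wrote {len(res.records)} proteins, {len(ct)} CT rows, "
          f"{len(germ)} germination rows under {out}")


if __name__ == "__main__":
    main()
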