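#!/usr/bin/env python
"""Generate the synthetic study: genes, ground truth, fragments, spike-ins.

A two-condition (WT vs KO), three-replicate design over 200 genes with 10%
of genes each carrying a 2-fold transcription, stability or pausing-odds
effect. Bulky per-fragment files go to scratch/sim (regenerable); the
ground-truth table and design are echoed to results/sim for inspection.
"""

import shutil
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

import ttstall as t  # noqa: E402

SIM_DIR = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results" / "sim"


def main():
    cfg = t.SimConfig(
        n_genes=200,
        gene_length_range=(800, 8000),
        depth=60_000,
        seed=20260922,
        dispersion=0.05,
        frac_txn_change=0.1,
        frac_stab_change=0.1,
        frac_pause_change=0.1,
        effect_txn=0.5,
        effect_stab=2.0,
        effect_pause=2.0,
        pi_range=(0.3, 0.5),
    )
    world = t.write_simulation(SIM_DIR, cfg, straddler_rate=0.1, intergenic_rate=200.0)
    RESULTS.mkdir(parents=True, exist_ok=True)
    for name in ("truth.tsv", "design.tsv", "config.yaml"):
        shutil.copy(SIM_DIR / name, RESULTS / name)

    truth = world["truth"]
    frags = world["fragments"]
    print(f"wrote {len(world['genes'])} genes, {len(frags)} fragments -> {SIM_DIR}")
    print("effect classes:", truth["effect_class"].value_counts().to_dict())
    print("fragment categories:", frags["category"].value_counts().to_dict())
    print(f"truth/design echoed to {RESULTS}")


if __name__ == "__main__":
    main()
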