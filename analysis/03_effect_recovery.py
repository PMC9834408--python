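#!/usr/bin/env python
"""Compare the pipeline's calls with the generator's ground truth.

For each effect class the relevant statistic should recover the generating
2-fold change: nascent log2FC ~ -1 for transcription-halved genes,
stability shift ~ -1 for degradation-doubled genes (with a flat nascent
arm), and differential stalling index ~ +1 for pausing-odds-doubled genes.
Writes results/recovery_summary.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

PIPE = ROOT / "results" / "pipeline"
SIM = ROOT / "results" / "sim"


def main():
    if not (PIPE / "diffexpr_tt.tsv").exists():
        sys.exit("no pipeline output found; run analysis/02_run_pipeline.py first")
    truth = pd.read_csv(SIM / "truth.tsv", sep="\t", index_col=0)
    diff_tt = pd.read_csv(PIPE / "diffexpr_tt.tsv", sep="\t", index_col=0)
    stalling = pd.read_csv(PIPE / "stalling.tsv", sep="\t", index_col=0)
    stability = pd.read_csv(PIPE / "stability.tsv", sep="\t", index_col=0)

    rows = []
    for cls, frame, col, expected in [
        ("txn", diff_tt, "log2FC", -1.0),
        ("stab", stability, "delta", -1.0),
        ("stab", diff_tt, "log2FC", 0.0),
        ("pause", stalling, "dSI", 1.0),
        ("none", diff_tt, "log2FC", 0.0),
        ("none", stalling, "dSI", 0.0),
    ]:
        genes = truth.index[truth["effect_class"] == cls].intersection(frame.index)
        values = frame.loc[genes, col]
        rows.append(
            {
                "effect_class": cls,
                "statistic": col,
                "n_genes": len(genes),
                "median": values.median(),
                "q25": values.quantile(0.25),
                "q75": values.quantile(0.75),
                "expected": expected,
            }
        )
    summary = pd.DataFrame(rows)
    out = ROOT / "results" / "recovery_summary.tsv"
    summary.to_csv(out, sep="\t", index=False, float_format="%.4f")
    print(summary.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    print(f"\nwritten to {out}")

    de = diff_tt.join(truth["effect_class"])
    down_calls = de[de["call"] == "down"]
    tp = (down_calls["effect_class"] == "txn").sum()
    print(
        f"\nnascent 'down' calls: {len(down_calls)}, of which {tp} are true "
        "transcription-effect genes"
    )


if __name__ == "__main__":
    main()
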