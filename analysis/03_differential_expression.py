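#!/usr/bin/env python
"""Differential testing of all WT-referenced contrasts on both assays.

Runs the NB Wald test for KO, KO_KD and WT_KD against WT on the RNA and
RPF count layers and writes the six tables plus a summary of 2-fold,
padj < 0.05 calls per contrast (the volcano-plot headline numbers).
"""

import argparse
import json
from pathlib import Path

from riborescue import de_core


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/de"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sheet = de_core.SampleSheet.from_tsv(args.datadir / "sample_sheet.tsv")
    summary = {}
    for assay in ("RNA", "RPF"):
        cm = de_core.CountMatrix.from_tsv(
            args.datadir / f"counts_{assay.lower()}.tsv", assay=assay)
        for cond in ("KO", "KO_KD", "WT_KD"):
            de = de_core.wald_test(cm, sheet, "WT", cond)
            name = f"de_{cond.lower()}_{assay.lower()}"
            de_core.write_de_table(de, args.outdir / f"{name}.tsv")
            summary[name] = {
                "up": int((de["direction"] == "up").sum()),
                "down": int((de["direction"] == "down").sum()),
                "tested": int(len(de)),
            }
    (args.outdir / "de_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    for name, s in summary.items():
        print(f"{name}: {s['up']} up / {s['down']} down of {s['tested']} "
              "(|lfc| >= 1, padj < 0.05)")


if __name__ == "__main__":
    main()
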