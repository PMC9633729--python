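#!/usr/bin/env python
"""Translation-efficiency scatter data and event classification.

For each perturbed condition vs WT, computes per-gene TE (RPF/RNA) in
both conditions, the log2 TE shift, and the five-way event class from
the RNA and RPF differential calls; writes per-contrast tables and the
event count summaries (the pie-chart numbers).
"""

import argparse
import json
from pathlib import Path

from riborescue import de_core
from riborescue.te_events import event_summary, te_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--dedir", type=Path, default=Path("results/de"))
    ap.add_argument("--outdir", type=Path, default=Path("results/te"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sheet = de_core.SampleSheet.from_tsv(args.datadir / "sample_sheet.tsv")
    rna = de_core.CountMatrix.from_tsv(args.datadir / "counts_rna.tsv", "RNA")
    rpf = de_core.CountMatrix.from_tsv(args.datadir / "counts_rpf.tsv", "RPF")

    summaries = {}
    for cond in ("KO", "KO_KD", "WT_KD"):
        rna_de = de_core.read_de_table(
            args.dedir / f"de_{cond.lower()}_rna.tsv")
        rpf_de = de_core.read_de_table(
            args.dedir / f"de_{cond.lower()}_rpf.tsv")
        table = te_table(rna, rpf, sheet, "WT", cond, rna_de, rpf_de)
        table.to_csv(args.outdir / f"te_{cond.lower()}.tsv", sep="\t")
        summaries[cond] = event_summary(table["event_class"])
    (args.outdir / "event_summary.json").write_text(
        json.dumps(summaries, indent=2) + "\n")
    for cond, s in summaries.items():
        print(f"{cond} vs WT events: {json.dumps(s)}")


if __name__ == "__main__":
    main()
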