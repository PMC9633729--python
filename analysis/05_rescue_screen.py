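#!/usr/bin/env python
"""Three-criterion rescue-based target selection.

Applies the screen (2-fold knock-out response with adjusted p < 0.05 on
either layer; >= 25% rescue under double depletion; opposite-or-null
knock-down-only response) to the six contrast tables, writes the
per-gene calls and the criteria funnel, and scores the calls against
the simulation truth.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from riborescue import de_core
from riborescue.rescue_screen import ScreenConfig, screen_summary, select_targets


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--dedir", type=Path, default=Path("results/de"))
    ap.add_argument("--outdir", type=Path, default=Path("results/rescue"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    t = {name: de_core.read_de_table(args.dedir / f"de_{name}.tsv")
         for name in ("ko_rna", "ko_rpf", "ko_kd_rna", "ko_kd_rpf",
                      "wt_kd_rna", "wt_kd_rpf")}
    calls = select_targets(t["ko_rna"], t["ko_rpf"], t["ko_kd_rna"],
                           t["ko_kd_rpf"], t["wt_kd_rna"], t["wt_kd_rpf"],
                           ScreenConfig())
    calls.to_csv(args.outdir / "targets.tsv", sep="\t")
    funnel = screen_summary(calls)
    (args.outdir / "funnel.json").write_text(json.dumps(funnel, indent=2) + "\n")
    print("criteria funnel:", json.dumps(funnel))

    truth = pd.read_csv(args.datadir / "truth_genes.tsv", sep="\t",
                        index_col=0)
    merged = calls.join(truth)
    tp = int((merged["is_target"] & merged["is_true_target"]).sum())
    fp = int((merged["is_target"] & ~merged["is_true_target"]).sum())
    n_true = int(truth["is_true_target"].sum())
    print(f"vs truth: sensitivity {tp / n_true:.3f} "
          f"({tp}/{n_true} planted targets recovered), "
          f"false-discovery proportion {fp / max(1, tp + fp):.3f} "
          f"({fp}/{tp + fp} calls)")


if __name__ == "__main__":
    main()
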