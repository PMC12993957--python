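"""QC-vs-significance diagnostics from a finished pipeline run: Pearson and
Spearman correlations of per-stratum QC summaries against fit p-values and
the percent of cells inside the fitted polytope."""

import argparse
from pathlib import Path

import pandas as pd

from paretocell.pipeline import qc_significance_report

parser = argparse.ArgumentParser()
parser.add_argument("--fits", type=Path, default=Path("results/pipeline/fits.tsv"))
parser.add_argument("--out", type=Path, default=Path("results/qc_report.tsv"))
args = parser.parse_args()

fits = pd.read_csv(args.fits, sep="\t")
report = qc_significance_report(fits)
args.out.parent.mkdir(parents=True, exist_ok=True)
report.to_csv(args.out, sep="\t", index=False)
print(report.to_string(index=False))
strong = report[report["pearson_r"].abs() > 0.5]
print(f"\n{len(strong)} metric/outcome pairs with |r| > 0.5"
      + (": QC confound suspected" if len(strong) else " (no QC confound signal)"))
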