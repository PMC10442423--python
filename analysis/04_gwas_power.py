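"""Power comparison: quantitative vs dichotomized vs record-thinned GWAS.

Over 25 simulation seeds (N = 4000 GWAS + 2000 hold-out subjects,
M = 2000 SNPs, 20 causal, h2 = 0.25, prevalence 10%, record sensitivity
36%), counts genome-wide-significant clumped loci and
Bonferroni-significant PRS thresholds for each phenotype definition.
The expectation under the liability-threshold model: thresholding
discards severity information, and record under-reporting discards
cases, so power falls at each step.
"""

import json
from pathlib import Path

import pandas as pd

from oa_phenopower.evaluation import power_ordering
from oa_phenopower.io import write_tsv

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260922


def main():
    res = power_ordering(n_seeds=25, seed=SEED)
    rows = [
        {"phenotype": k, "mean_loci": res["mean_loci"][k],
         "mean_prs_significant_thresholds": res["mean_prs_significant_thresholds"][k]}
        for k in ("quant", "dichotomized", "ehr")
    ]
    write_tsv(pd.DataFrame(rows), OUT / "power_ordering.tsv")
    print(json.dumps(res, indent=2))
    ml = res["mean_loci"]
    ok = ml["quant"] > ml["dichotomized"] >= ml["ehr"]
    print(f"power ordering quant > dichotomized >= record holds: {ok}")
    print("table -> results/power_ordering.tsv")


if __name__ == "__main__":
    main()
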