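"""Regenerate tests/data/r_cox_oracle.json from R's survival package.

Run from the repository root (requires Rscript with the survival package):

    python tests/make_r_oracle.py

The JSON freezes coxph coefficient/SE estimates for the deterministic
datasets in _datasets.py, under both ties methods, so the suite can compare
against the R reference without invoking R at test time.
"""
import json
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from _datasets import small_cox_datasets

R_CODE = """
suppressMessages(library(survival))
args <- commandArgs(trailingOnly = TRUE)
df <- read.csv(args[1])
res <- list()
for (ties in c("efron", "breslow")) {
  fit <- coxph(Surv(entry, exit, status) ~ x1 + x2, data = df, ties = ties,
               control = coxph.control(eps = 1e-12, iter.max = 50))
  res[[ties]] <- c(coef(fit), sqrt(diag(vcov(fit))))
}
cat(jsonlite::toJSON(res, digits = 15))
"""


def main():
    datasets = small_cox_datasets()
    oracle = []
    with tempfile.TemporaryDirectory() as tmp:
        script = Path(tmp) / "fit.R"
        script.write_text(R_CODE)
        for i, d in enumerate(datasets):
            csv = Path(tmp) / f"d{i}.csv"
            pd.DataFrame({
                "entry": d["entry"], "exit": d["exit"], "status": d["status"],
                "x1": d["X"][:, 0], "x2": d["X"][:, 1],
            }).to_csv(csv, index=False)
            out = subprocess.run(
                ["Rscript", "--vanilla", str(script), str(csv)],
                capture_output=True, text=True, check=True,
            ).stdout
            parsed = json.loads(out)
            oracle.append({
                ties: {"coef": vals[:2], "se": vals[2:]}
                for ties, vals in parsed.items()
            })
    dest = Path(__file__).parent / "data" / "r_cox_oracle.json"
    dest.parent.mkdir(exist_ok=True)
    dest.write_text(json.dumps(
        {"source": "R survival::coxph, eps=1e-12", "n_datasets": len(oracle),
         "fits": oracle}, indent=1))
    print(f"wrote {dest} ({len(oracle)} datasets)")


if __name__ == "__main__":
    main()
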