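"""Fit per-substrate depletion rates (k_rel) from the simulated counts.

Reads counts_A.tsv / counts_B.tsv, applies the CLR transform and pooled OLS
per substrate, writes rates_A.tsv / rates_B.tsv, and reports recovery
against the simulation truth.
"""

from pathlib import Path

import pandas as pd
from scipy.stats import pearsonr

from pdcovar.kinetics import rates_from_counts
from pdcovar.synthetic import centered_rates

RESULTS = Path(__file__).resolve().parents[1] / "results"


def read_counts(path: Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.columns = [
        (e, int(r), float(t)) for e, r, t in (c.split("|") for c in table.columns)
    ]
    return table


def main() -> None:
    truth = pd.read_csv(RESULTS / "true_rates.tsv", sep="\t", index_col=0)
    for enz in ("A", "B"):
        counts = read_counts(RESULTS / f"counts_{enz}.tsv")
        fit = rates_from_counts(counts)[enz]
        fit.to_csv(RESULTS / f"rates_{enz}.tsv", sep="\t")
        expected = centered_rates(truth[enz]).loc[fit.index]
        r = pearsonr(fit.k_rel, expected).statistic
        print(f"enzyme {enz}: fitted 256 substrates, Pearson r vs truth = {r:.4f}")


if __name__ == "__main__":
    main()
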