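#!/usr/bin/env python
"""Call cold-responsive DEGs: TMM normalization + NB quasi-likelihood F-tests.

For each organ, counts are TMM-normalized and each post-treatment
timepoint is tested 4C vs 24C (matched timepoints, as the study design
requires).  DEGs are genes with BH-adjusted p < 0.01.  Writes per-contrast
DE tables and a normalized CPM matrix under results/de/.
"""

import pathlib

import pandas as pd

from coldclock.de import call_degs, dispersion_trend, nb_two_group_test
from coldclock.normalize import cpm, tmm_factors

DATA = pathlib.Path("results/data")
OUT = pathlib.Path("results/de")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = pd.read_csv(DATA / "counts.tsv", sep="\t", index_col=0)
    design = pd.read_csv(DATA / "design.csv")

    cpm_frames = []
    for organ in design["organ"].unique():
        dsub = design[design["organ"] == organ]
        csub = counts[dsub["sample_id"]]
        factors = tmm_factors(csub)
        groups = (dsub["timepoint"] + "_" + dsub["condition"]).to_numpy()
        disp = dispersion_trend(csub, groups)
        cpm_frames.append(cpm(csub, factors))
        for tp in dsub.loc[dsub["timepoint"] != "T0", "timepoint"].unique():
            tsub = dsub[dsub["timepoint"] == tp]
            amb = tsub.loc[tsub["condition"] == "ambient", "sample_id"].tolist()
            cold = tsub.loc[tsub["condition"] == "cold", "sample_id"].tolist()
            res = nb_two_group_test(csub, amb, cold, dispersions=disp, factors=factors)
            res.to_csv(OUT / f"de_{organ}_{tp}.tsv", sep="\t")
            n_deg = len(call_degs(res, 0.01))
            print(f"{organ} {tp}: {n_deg} DEGs at FDR < 0.01 "
                  f"(of {len(res)} genes tested)")
    pd.concat(cpm_frames, axis=1).to_csv(OUT / "cpm.tsv", sep="\t")


if __name__ == "__main__":
    main()
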