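#!/usr/bin/env python
"""Brain-behavior statistics: demographics, hubs, and edge screening.

Median-splits the cohort on age, reproduces the demographic comparisons
(gender chi-square, MPI and age t tests, age-MPI Pearson correlations), and
within each subgroup identifies mastication-related hubs (degree centrality
positively associated with MPI, partial correlation controlling age and
gender) and screens all 276 edges, uncorrected at alpha = 0.05.
"""

from pathlib import Path

import pandas as pd

from masticnet import io as mio
from masticnet.stats import (
    chi_square_2x2,
    identify_hubs,
    median_split,
    pearson_correlation,
    screen_edges,
    two_sample_t,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    phen = mio.read_phenotypes(RESULTS / "phenotypes.tsv")
    dc = pd.read_csv(RESULTS / "degree_centrality.tsv", sep="\t", index_col=0)
    weights = pd.read_csv(SCRATCH / "edge_weights.tsv", sep="\t", index_col=0)

    split = median_split(phen)
    phen = phen.assign(split_group=[split.assignment[s] for s in phen.subject_id])
    older = phen[phen.split_group == "older"]
    younger = phen[phen.split_group == "younger"]
    print(f"median split at {split.threshold_age:.1f} y/o: "
          f"{len(older)} older, {len(younger)} younger")

    table = [[int((g.gender == 'M').sum()), int((g.gender == 'F').sum())]
             for g in (older, younger)]
    chi2, _, p_chi = chi_square_2x2(table)
    t, df, p_t = two_sample_t(older.mpi, younger.mpi)
    r_all, p_all = pearson_correlation(phen.age, phen.mpi)
    r_old, p_old = pearson_correlation(older.age, older.mpi)
    print(f"gender balance: chi2(1)={chi2:.2f}, p={p_chi:.2f}  (counts {table})")
    print(f"MPI older vs younger: t={t:.2f}, df={df:.1f}, p={p_t:.2g}")
    print(f"age-MPI: all r={r_all:.2f} (p={p_all:.2g}); older r={r_old:.2f} (p={p_old:.2g})")

    for name, members in (("older", older), ("younger", younger)):
        hubs = identify_hubs(dc, members)
        screen = screen_edges(weights, members)
        mio.write_hub_table(hubs, RESULTS / f"hubs_{name}.tsv")
        mio.write_edge_table(screen, RESULTS / f"edges_{name}.tsv")
        flagged = hubs[hubs.is_hub]
        print(f"{name}: {len(flagged)} hub(s): {flagged.label.tolist()}; "
              f"{int(screen.significant.sum())}/276 edges significant (uncorrected)")
    print(f"tables -> {RESULTS}/hubs_*.tsv, {RESULTS}/edges_*.tsv")


if __name__ == "__main__":
    main()
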