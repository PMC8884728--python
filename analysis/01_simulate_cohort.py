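#!/usr/bin/env python
"""Generate the synthetic study cohort and its file-format fixtures.

Builds 10 serially passaged communities (8 metagenomic time points, ~10
species each, two strains per species) with gamma-distributed abundance
fluctuations and binomial read-sampling noise on SNP allele frequencies,
writes a per-species truth summary to results/, and dumps one community's
full VCF + abundance-table fixtures under scratch/ for the inference driver.
"""

import sys
from pathlib import Path

import pandas as pd

from straindyn.io import write_results
from straindyn.simulate import study_cohort, write_community_fixtures

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2027


def main() -> None:
    communities, observations = study_cohort(seed=SEED)
    rows = []
    for com in communities:
        for sp in com.species:
            rows.append(
                {
                    "community": com.community_id,
                    "species": sp.species_id,
                    "mean_abundance": sp.mean_abundance,
                    "n_strains": sp.n_strains,
                    "n_diff_snps": sp.n_diff_snps,
                    "n_shared_snps": sp.n_shared_snps,
                    "f_start": sp.strain_frequency[0],
                    "f_end": sp.strain_frequency[-1],
                }
            )
    summary = pd.DataFrame(rows)
    write_results({"cohort_truth_summary": summary}, ROOT / "results", overwrite=True)

    example = communities[0]
    paths = write_community_fixtures(
        example, observations[example.community_id], ROOT / "scratch" / "fixtures"
    )
    n_snps = summary[["n_diff_snps", "n_shared_snps"]].to_numpy().sum()
    print(f"cohort: {len(communities)} communities, {len(rows)} species records")
    print(f"total planted SNPs: {n_snps}")
    print(f"example fixtures for {example.community_id}: {len(paths['vcfs'])} VCFs + abundance TSV")


if __name__ == "__main__":
    main()
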