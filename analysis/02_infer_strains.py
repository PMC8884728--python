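#!/usr/bin/env python
"""Strain inference on the example community's VCF fixtures, checked
against planted truth.

Reads the per-time-point VCFs written by 01, applies the variant-call
filters (quality >= 20, depth >= 10, biallelic, persistence), clusters each
species' major-allele frequency trajectories by DTW k-means, and compares
the inferred strain models with the generating truth: cluster membership
accuracy and the RMSE of the recovered strain-frequency trajectory.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from straindyn.io import read_snp_vcf, write_results
from straindyn.simulate import study_cohort
from straindyn.strains import select_strain_model
from straindyn.variants import filter_snps

ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "scratch" / "fixtures"


def main() -> None:
    communities, _ = study_cohort()
    truth = communities[0]
    vcfs = sorted(FIXTURES.glob(f"{truth.community_id}_t*.vcf"))
    if not vcfs:
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    records = []
    for t, path in enumerate(vcfs):
        records.extend(read_snp_vcf(path, t))
    abundance = {sp.species_id: sp.abundance for sp in truth.species}
    trajectories, rejections = filter_snps(records, species_abundance=abundance)
    print(f"{len(records)} records -> {len(trajectories)} retained trajectories; "
          f"{len(rejections)} site rejections")

    rows = []
    for sp in truth.species:
        trajs = [t for t in trajectories if t.genome_id == sp.species_id]
        if not trajs:
            continue
        model = select_strain_model(trajs, seed=1)
        # planted membership is encoded in the VCF ID column (snp ids)
        true_diff = {t.snp_id for t in trajs if ":diff:" in t.snp_id}
        inferred = set(model.differentiating)
        correct = len(true_diff & inferred) + sum(
            1 for t in trajs if ":shared:" in t.snp_id and t.snp_id in set(model.shared)
        )
        if model.n_strains == 2:
            rmse = min(
                float(np.sqrt(np.nanmean((model.frequency - sp.strain_frequency) ** 2))),
                float(np.sqrt(np.nanmean((1 - model.frequency - sp.strain_frequency) ** 2))),
            )
        else:
            rmse = np.nan
        rows.append(
            {
                "species": sp.species_id,
                "true_strains": sp.n_strains,
                "inferred_strains": model.n_strains,
                "genetic_distance": model.genetic_distance,
                "membership_accuracy": correct / len(trajs),
                "frequency_rmse": rmse,
            }
        )
    table = pd.DataFrame(rows)
    write_results({"strain_models": table}, ROOT / "results", overwrite=True)
    print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    print(
        f"mean membership accuracy {table['membership_accuracy'].mean():.3f}; "
        f"mean frequency RMSE {table['frequency_rmse'].mean():.3f}"
    )


if __name__ == "__main__":
    main()
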