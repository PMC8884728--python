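#!/usr/bin/env python
"""Dynamical-correlation analyses of the synthetic cohort.

Infers strain models for every species in all 10 communities, builds
strain-level abundance tables, and reproduces the statistical analyses:
conspecific strain-strain coupling and its distribution, coupling versus
genetic distance, the fraction of species pairs dominated by interspecific
strain correlations (with the strain-label permutation null), gamma-null
interaction networks at both taxonomic levels, and eco-evolutionary
influence of major strains on their species.
"""

import itertools
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from straindyn.dynamics import (
    GammaNullSpec,
    coupling_distance_curve,
    detect_interactions,
    ecoevo_influence,
    gamma_null_correlations,
    interspecies_correlations,
    strain_coupling,
    strain_label_permutation_test,
)
from straindyn.io import write_results
from straindyn.simulate import study_cohort
from straindyn.strains import select_strain_model, strain_abundance_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    communities, observations = study_cohort()
    coupling_rows, density_rows, pair_flags = [], [], []
    ecoevo_species, ecoevo_freqs = {}, {}
    permutation_inputs, permutation_groups = {}, {}

    for com in communities:
        species_table = com.abundance_table
        trajs_by_species = {}
        for sp in com.species:
            trajs = [t for t in observations[com.community_id] if t.genome_id == sp.species_id]
            trajs_by_species[sp.species_id] = select_strain_model(trajs, seed=1)
        models = list(trajs_by_species.values())
        strains = strain_abundance_table(models, species_table)

        # conspecific coupling + permutation-test inputs
        for model in models:
            if model.n_strains != 2:
                continue
            s1 = strains.trajectory(f"{model.species_id}.s1")
            s2 = strains.trajectory(f"{model.species_id}.s2")
            c, label = strain_coupling(s1, s2)
            coupling_rows.append(
                {
                    "community": com.community_id,
                    "species": model.species_id,
                    "coupling": c,
                    "label": label,
                    "genetic_distance": model.genetic_distance,
                }
            )
            key = f"{com.community_id}:{model.species_id}"
            permutation_inputs[key] = (s1, s2)
            permutation_groups[key] = com.community_id

        # species pairs: strain vs species correlation magnitudes
        two_strain = [m for m in models if m.n_strains == 2]
        for ma, mb in itertools.combinations(two_strain, 2):
            sa = [strains.trajectory(f"{ma.species_id}.s{k}") for k in (1, 2)]
            sb = [strains.trajectory(f"{mb.species_id}.s{k}") for k in (1, 2)]
            _, _, exceeds = interspecies_correlations(
                species_table.trajectory(ma.species_id),
                species_table.trajectory(mb.species_id),
                sa,
                sb,
            )
            pair_flags.append(exceeds)

        # gamma-null interaction networks at both levels
        for level, table in (("species", species_table), ("strain", strains)):
            M = table.matrix
            means = M.mean(axis=1)
            variances = np.maximum(M.var(axis=1), 1e-8)
            spec = GammaNullSpec(
                means=tuple(means), variances=tuple(variances), n_sims=300, seed=7
            )
            null = gamma_null_correlations(spec, n_times=M.shape[1])
            observed = {}
            for i, j in itertools.combinations(range(len(table.taxa)), 2):
                a, b = table.taxa[i], table.taxa[j]
                if level == "strain" and a.split(".")[0] == b.split(".")[0]:
                    continue  # never conspecifics at the strain level
                r = abs(np.corrcoef(M[i], M[j])[0, 1])
                if np.isfinite(r):
                    observed[(a, b)] = r
            net = detect_interactions(observed, null, level=level, nodes=table.taxa)
            density_rows.append(
                {
                    "community": com.community_id,
                    "level": level,
                    "nodes": len(net.nodes),
                    "edges": len(net.edges),
                    "density": net.density,
                }
            )

        # eco-evolutionary influence inputs
        for model in two_strain:
            key = f"{com.community_id}:{model.species_id}"
            ecoevo_species[key] = species_table.trajectory(model.species_id)
            f = model.frequency
            ecoevo_freqs[key] = f if model.major_strain == 1 else 1 - f

    couplings = pd.DataFrame(coupling_rows)
    curve = coupling_distance_curve(
        couplings["genetic_distance"], couplings["coupling"], n_bins=6
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        perm = strain_label_permutation_test(
            permutation_inputs, n_perm=200, seed=3, groups=permutation_groups
        )
    influence = ecoevo_influence(ecoevo_species, ecoevo_freqs, n_shuffles=1000, seed=5)
    densities = pd.DataFrame(density_rows)

    frac_decoupled = (couplings["label"] == "decoupled").mean()
    frac_strain_dominant = float(np.mean(pair_flags))
    dens = densities.pivot_table(index="community", columns="level", values="density")
    density_gain = (dens["strain"] / dens["species"] - 1).mean()

    summary = pd.DataFrame(
        [
            {"statistic": "n_conspecific_pairs", "value": len(couplings)},
            {"statistic": "mean_coupling", "value": couplings["coupling"].mean()},
            {"statistic": "fraction_decoupled", "value": frac_decoupled},
            {"statistic": "fraction_strain_dominant_pairs", "value": frac_strain_dominant},
            {"statistic": "permutation_F_obs", "value": perm["F_obs"]},
            {"statistic": "permutation_null_mean", "value": perm["null_mean"]},
            {"statistic": "permutation_p", "value": perm["p_value"]},
            {"statistic": "mean_strain_density_gain", "value": density_gain},
            {"statistic": "fraction_ecoevo_influential", "value": influence.attrs["fraction_influential"]},
        ]
    )
    write_results(
        {
            "couplings": couplings,
            "coupling_distance_curve": curve,
            "network_densities": densities,
            "dynamics_summary": summary,
        },
        ROOT / "results",
        overwrite=True,
    )
    print(summary.to_string(index=False, float_format=lambda x: f"{x:.3f}"))


if __name__ == "__main__":
    main()
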