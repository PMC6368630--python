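#!/usr/bin/env python
"""Generate the synthetic inputs used by the downstream analysis scripts.

Emulated study conditions: a 50-position Class F-like receptor family with
a 10x cancer-enriched hotspot at 6.32; a 500-sequence alignment with fully
and partially conserved columns; an ensemble of five 7-helix bundles where
the 6.32-7.55 contact is planted in three; wild-type (3 replicates, 9 A)
vs mutant (4 replicates, 12 A) activation-distance trajectories; and two
noisy agonist curves with a planted 10-fold potency shift.
"""

from pathlib import Path

from classf_switch import io as cio
from classf_switch.simulate import (
    gen_dose_response,
    gen_helix_bundle,
    gen_msa,
    gen_trajectories,
    gen_variant_tables,
)

SEED = 2026
DATA = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)

    cancer, population, segmap, truth = gen_variant_tables(seed=SEED)
    cio.write_variants(cancer, DATA / "cancer_variants.tsv", truth)
    cio.write_variants(population, DATA / "population_variants.tsv", truth)
    cio.write_segment_map(segmap, DATA / "family_map.tsv")
    print(f"variant tables: 50 positions, hotspot {truth['hotspot']} "
          f"at {truth['enrichment']:g}x enrichment")

    msa = gen_msa(500, 60, {10: 1.0, 20: (0.5, 1), 30: 0.9}, seed=SEED)
    cio.write_msa(msa, DATA / "family_alignment.fasta")
    print("alignment: 500 sequences x 60 columns "
          "(columns 10/20/30 conserved at 1.0 / 0.5+1alt / 0.9)")

    bundle_maps = []
    for i in range(5):
        plants = [("6.32", "7.55")] if i < 3 else []
        bundle = gen_helix_bundle(
            planted_contacts=plants, seed=SEED + i, structure_id=f"SYN{i}"
        )
        cio.write_structure(bundle, DATA / f"bundle_SYN{i}.pdb")
        bundle_maps.append(bundle.segment_map)
    cio.write_segment_map(bundle_maps, DATA / "bundle_map.tsv")
    print("bundles: 5 structures, 6.32-7.55 contact planted in SYN0-SYN2")

    traj = gen_trajectories(n_frames=1000, seed=SEED)
    cio.write_distances(traj, DATA / "trajectory_distances.tsv",
                        {"seed": SEED, "n_frames": 1000})
    print("trajectories: WT 3 x 1000 frames (9 A), MUT 4 x 1000 frames (12 A)")

    wt, t_wt = gen_dose_response(params={"logEC50": -8.0}, noise_sd=0.05,
                                 seed=SEED, condition="WT")
    mut, t_mut = gen_dose_response(params={"logEC50": -9.0}, noise_sd=0.05,
                                   seed=SEED + 1, condition="R6.32A")
    import pandas as pd

    table = pd.concat([wt, mut], ignore_index=True)
    cio.write_distances(table, DATA / "dose_response.tsv",
                        {"logEC50_WT": t_wt["logEC50"],
                         "logEC50_R6.32A": t_mut["logEC50"]})
    print("dose-response: WT logEC50 -8.0 vs mutant -9.0 (10-fold shift), "
          "noise sd 0.05")


if __name__ == "__main__":
    main()
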