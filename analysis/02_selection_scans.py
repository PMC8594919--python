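#!/usr/bin/env python
"""Selection scans: per-site F_ST, PBS branches with empirical thresholds,
and the iHS haplotype scan on neutral and swept coalescent panels.

PBS uses the trio (source 1, source 2, outgroup): drifted source
populations mimic the focal/closely-related/outgroup design of a
three-population branch-length comparison. The iHS section scans a neutral
panel (calibration) and partial-sweep replicates (power), standardizing
sweep sites against the neutral panel's frequency bins.

Writes results/selection/{pbs_scan.tsv,ihs_neutral.tsv,ihs_sweeps.tsv}.
"""

import pathlib

import numpy as np
import pandas as pd

from coevoscan import selscan, simgen

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "selection"
SEED = 20240902


def pbs_scan():
    cfg = simgen.SimConfig(
        seed=SEED,
        f_source=(0.02, 0.02),
        f_outgroup=0.10,
        n_source=100,
        n_outgroup=100,
        n_admixed_female=5,
        n_admixed_male=5,
        n_background_chroms=8,
        n_background_variants=260,
        build_track=False,
    )
    trio = simgen.simulate_cohort(cfg)
    gm = trio.genotypes()
    f_ab = selscan.site_fst(gm, trio.panel, "SRC1", "SRC2")["fst"]
    f_ac = selscan.site_fst(gm, trio.panel, "SRC1", "OUT")["fst"]
    f_bc = selscan.site_fst(gm, trio.panel, "SRC2", "OUT")["fst"]
    branches = selscan.normalize_pbs(selscan.pbs(f_ab, f_ac, f_bc))
    branches.insert(0, "id", gm.ids)
    branches.insert(0, "pos", gm.positions)
    branches.insert(0, "chrom", gm.chroms)
    defined = branches[branches["defined"]]
    thr, emp_p = selscan.empirical_threshold(defined["pbs_a"].to_numpy(), 0.95)
    print(f"[pbs] {len(defined)} defined sites; focal-branch mean "
          f"{defined['pbs_a'].mean():.4f}, 95th percentile {thr:.4f}")
    print(f"[pbs] genome-wide WC F_ST source1-outgroup: "
          f"{selscan.genomewide_fst(gm, trio.panel, 'SRC1', 'OUT'):.4f}")
    branches.to_csv(OUT / "pbs_scan.tsv", sep="\t", index=False)


def ihs_scans():
    hm, gmap = simgen.simulate_haplotypes(
        n_samples=40, sequence_length=800_000, seed=SEED + 1
    )
    neutral = selscan.ihs_scan(hm, gmap, n_bins=25)
    neutral.to_csv(OUT / "ihs_neutral.tsv", sep="\t", index=False)
    nb = neutral[~neutral["boundary"]]
    thr = float(np.quantile(np.abs(neutral["ihs"]), 0.95))
    print(f"[ihs] neutral panel: {len(neutral)} scored sites, "
          f"|iHS|>2 fraction {(nb['ihs'].abs() > 2).mean():.3f}, 95th pct {thr:.2f}")

    rows = []
    for k in range(5):
        hs, gmap_s, pos = simgen.simulate_sweep(
            n_samples=40, sequence_length=800_000, s=0.05,
            end_frequency=0.6, seed=SEED + 10 + k,
        )
        j = list(hs.positions).index(pos)
        cm = np.interp(hs.positions, gmap_s.positions, gmap_s.cm)
        ihh = {}
        for name, allele in (("a", 0), ("d", 1)):
            sub = hs.haplotypes[hs.haplotypes[:, j] == allele]
            l, _ = selscan._ihh_one_side(sub, cm, hs.positions, j, -1, 0.05, 200_000)
            r, _ = selscan._ihh_one_side(sub, cm, hs.positions, j, +1, 0.05, 200_000)
            ihh[name] = l + r
        target = pd.DataFrame(
            {"daf": [hs.derived_allele_freq()[j]],
             "uihs": [np.log(ihh["a"] / ihh["d"])]}
        )
        z = selscan.standardize_ihs(target, reference=neutral, n_bins=25)["ihs"].iloc[0]
        rows.append({"replicate": k, "pos": pos, "daf": target["daf"].iloc[0],
                     "uihs": target["uihs"].iloc[0], "ihs_neutral_standardized": z,
                     "above_neutral_95th": bool(abs(z) > thr)})
    sweeps = pd.DataFrame(rows)
    sweeps.to_csv(OUT / "ihs_sweeps.tsv", sep="\t", index=False)
    print(f"[ihs] sweep sites above neutral 95th percentile: "
          f"{sweeps['above_neutral_95th'].sum()}/5")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    pbs_scan()
    ihs_scans()


if __name__ == "__main__":
    main()
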