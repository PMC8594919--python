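#!/usr/bin/env python
"""Local-ancestry confound checks for the long-range LD signal.

Reads the discovery cohort's RFMix-style track back from disk, computes
cM-weighted genome-wide ancestry proportions per sample, tests whether
carriers of the selected genotype combination have elevated focal ancestry
(Mann-Whitney U), and flags local ancestry enrichment of both gene regions
against the genome-wide 95th percentile of per-interval attribution.

Writes results/ancestry/{proportions.tsv,summary.json}.
"""

import json
import pathlib

from coevoscan import genio
from coevoscan.ancestry import (
    ancestry_genotype_test,
    genomewide_proportion,
    load_local_ancestry,
    local_enrichment,
)

ROOT = pathlib.Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohorts" / "discovery"
OUT = ROOT / "results" / "ancestry"

REGION_A = ("16", 4_012_650, 4_166_186)
REGION_B = ("16", 56_995_835, 57_017_756)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    track = load_local_ancestry(COHORT / "ancestry.msp.tsv")
    maps = genio.read_map_set(COHORT / "genetic_map.tsv")
    props = genomewide_proportion(track, maps)
    props.to_csv(OUT / "proportions.tsv", sep="\t")

    gm, _ = genio.load_vcf_region(str(COHORT / "cohort.vcf.gz"))
    gm = gm.subset_samples(track.samples)
    d1 = gm.dosages_for("focal_g1")
    d2 = gm.dosages_for("focal_g2")
    in_class = (d1 == 0) & (d2 == 0)  # the selected combination
    u, p = ancestry_genotype_test(props["Andean"].to_numpy(), in_class)

    summary = {
        "mean_proportions": props.mean().to_dict(),
        "selected_combination_carriers": int(in_class.sum()),
        "mwu_p_selected_vs_rest": p,
    }
    for label, span in (("region_a", REGION_A), ("region_b", REGION_B)):
        enr = local_enrichment(track, span, "Andean")
        summary[label] = {
            "andean_attribution": enr.region_attribution,
            "genomewide_95th": enr.threshold_95,
            "enriched": bool(enr.enriched),
        }
    with open(OUT / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    print(f"mean ancestry: { {k: round(v, 3) for k, v in props.mean().items()} }")
    print(f"selected-combination carriers: {in_class.sum()}; "
          f"Mann-Whitney p vs rest: {p:.3f}")
    for label in ("region_a", "region_b"):
        s = summary[label]
        print(f"{label}: Andean attribution {s['andean_attribution']:.3f} "
              f"(95th pct {s['genomewide_95th']:.3f}) -> enriched: {s['enriched']}")


if __name__ == "__main__":
    main()
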