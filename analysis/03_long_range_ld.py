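#!/usr/bin/env python
"""Long-range LD between the two gene regions, with all three nulls.

Loads the cohorts written by 01_simulate_cohorts.py back through the VCF /
panel / map readers (exercising the full file round trip), then computes:
cross-region genotype r2 for every SNP pair with the 99th-percentile
gene-pair threshold; the genotypic chi2 (4 d.f.) test with its permutation
p; the genome-wide matched-pair null (MAF / bp / cM windows); and the
sex-stratified scans plus the sex-label permutation test.

Writes results/lrld/{gene_pair_scan.tsv,matched_null.tsv,summary.json}.
"""

import json
import pathlib
import warnings

import numpy as np

from coevoscan import genio, lrld

ROOT = pathlib.Path(__file__).resolve().parents[1]
COHORTS = ROOT / "results" / "cohorts"
OUT = ROOT / "results" / "lrld"
SEED = 20240903

REGION_A = ("16", 4_012_650, 4_166_186)
REGION_B = ("16", 56_995_835, 57_017_756)


def load(name):
    d = COHORTS / name
    gm, _ = genio.load_vcf_region(str(d / "cohort.vcf.gz"))
    panel = genio.SamplePanel.from_tsv(d / "panel.tsv")
    maps = genio.read_map_set(d / "genetic_map.tsv")
    adm = panel.samples_for("ADM")
    return gm.subset_samples(adm), panel, maps


def region(gm, span):
    chrom, start, end = span
    keep = (gm.chroms == chrom) & (gm.positions >= start) & (gm.positions <= end)
    return gm.subset_variants(keep)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}
    for name in ("discovery", "replication"):
        gm, panel, maps = load(name)
        gm = genio.filter_variants(gm, maf_min=0.05, max_missing=0.10)
        gm_a, gm_b = region(gm, REGION_A), region(gm, REGION_B)
        d1 = gm.dosages_for("focal_g1")
        d2 = gm.dosages_for("focal_g2")
        sex = panel.sex_of(gm.samples)
        male = sex == "male"

        scan = lrld.gene_pair_scan(gm_a, gm_b)
        focal = scan.pairs[
            (scan.pairs.snp1 == "focal_g1") & (scan.pairs.snp2 == "focal_g2")
        ].iloc[0]
        chi2 = lrld.genotypic_chi2(d1, d2)
        p_perm, _ = lrld.permutation_p(lrld.chi2_stat, d1, d2, n_perm=999, seed=SEED)
        p_sex, d_obs, _ = lrld.sex_permutation_test(d1, d2, sex, n_perm=999, seed=SEED)

        entry = {
            "n": int(len(gm.samples)),
            "r2_all": float(focal["r2"]),
            "r2_male": lrld.r2_stat(d1[male], d2[male]),
            "r2_female": lrld.r2_stat(d1[~male], d2[~male]),
            "gene_pair_threshold_99": scan.threshold_99,
            "gene_pair_empirical_p": float(focal["gene_pair_empirical_p"]),
            "n_gene_pairs": scan.n_pairs,
            "chi2_4df": chi2.chi2,
            "chi2_df": chi2.df,
            "chi2_permutation_p": p_perm,
            "chi2_male": lrld.genotypic_chi2(d1[male], d2[male]).chi2,
            "chi2_female": lrld.genotypic_chi2(d1[~male], d2[~male]).chi2,
            "sex_difference_r2": d_obs,
            "sex_permutation_p": p_sex,
        }

        if name == "discovery":  # background chromosomes exist here
            scan.pairs.to_csv(OUT / "gene_pair_scan.tsv", sep="\t", index=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                matched = lrld.matched_pair_null(
                    gm, maps, d1, d2,
                    maf_window=(0.10, 0.40),
                    bp_window=(20e6, 75e6),
                    cm_window=(20.0, 90.0),
                    chroms=[c for c in maps if c != "16"],
                    n_pairs=3513,
                    seed=SEED,
                )
            matched.pairs.to_csv(OUT / "matched_null.tsv", sep="\t", index=False)
            entry["genomewide_empirical_p"] = matched.empirical_p
            entry["n_matched_pairs"] = matched.n_pairs

        summary[name] = {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                         for k, v in entry.items()}
        print(f"[{name}] n={entry['n']}: r2 all/male/female = "
              f"{entry['r2_all']:.3f}/{entry['r2_male']:.3f}/{entry['r2_female']:.3f}; "
              f"chi2_4 = {entry['chi2_4df']:.1f} (perm p {entry['chi2_permutation_p']:.3f}); "
              f"sex-permutation p = {entry['sex_permutation_p']:.3f}")

    with open(OUT / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    print(f"wrote {OUT}/summary.json")


if __name__ == "__main__":
    main()
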