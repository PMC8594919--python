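"""Two-locus association statistics between distant regions, with three
empirical null constructions.

The primary statistic is the genotype r-squared (squared Pearson correlation
of dosages on complete cases). Significance is assessed three ways, as in
two-locus co-evolution scans: (1) a gene-pair empirical p against the
distribution of r2 over all cross-region SNP pairs, with the 99th percentile
as the significance threshold; (2) a permutation p for the genotypic
chi-square (4 d.f.) test comparing the observed 3x3 genotype-combination
table with the product of its marginals; (3) a genome-wide empirical p
against SNP pairs matched to the focal pair on MAF, physical (bp) and
genetic (cM) separation. Sex-stratified variants of the scan plus a
sex-label permutation test for the male-female difference complete the
framework.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GeneticMap, GenotypeMatrix, MISSING, SamplePanel, interpolate_cm


def _complete_cases(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    g1 = np.where(g1 == MISSING, np.nan, g1)
    g2 = np.where(g2 == MISSING, np.nan, g2)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    return g1[ok], g2[ok]


def geno_r2(g1, g2) -> tuple[float, int]:
    """Squared Pearson correlation of dosage vectors on complete cases.

    Symmetric in its arguments and invariant to allele relabelling
    (g -> 2 - g). Returns (r2, n_complete); r2 is NaN when either vector is
    constant on the complete-case subset or fewer than 3 complete cases
    remain.
    """
    x, y = _complete_cases(g1, g2)
    n = x.size
    if n < 3:
        return float("nan"), n
    vx = x - x.mean()
    vy = y - y.mean()
    sxx = float(vx @ vx)
    syy = float(vy @ vy)
    if sxx == 0.0 or syy == 0.0:
        return float("nan"), n
    sxy = float(vx @ vy)
    return sxy * sxy / (sxx * syy), n


@dataclass
class Chi2Result:
    chi2: float
    df: int
    n: int
    observed: np.ndarray  # collapsed table
    expected: np.ndarray
    cell_excess: np.ndarray  # full 3x3 observed - expected (NaN where collapsed)
    collapsed: bool
    low_count: bool


def genotypic_chi2(g1, g2) -> Chi2Result:
    """Genotypic chi-square (4 d.f.) test of two-locus genotype combinations.

    Builds the complete-case 3x3 table of genotype combinations, computes
    E_ij = row_i * col_j / N and chi2 = sum (O-E)^2 / E over the cells. When
    a genotype class is absent at either SNP the table collapses to the
    observed classes and df adjusts to (r-1)(c-1); permutation inference is
    then preferred. N < 20 sets the low-count flag.
    """
    x, y = _complete_cases(g1, g2)
    n = x.size
    obs_full = np.zeros((3, 3))
    if n:
        np.add.at(obs_full, (x.astype(int), y.astype(int)), 1.0)
    rows = obs_full.sum(axis=1) > 0
    cols = obs_full.sum(axis=0) > 0
    obs = obs_full[np.ix_(rows, cols)]
    collapsed = obs.shape != (3, 3)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n if n else obs * np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = float(np.nansum((obs - expected) ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    excess_full = np.full((3, 3), np.nan)
    excess_full[np.ix_(rows, cols)] = obs - expected
    return Chi2Result(
        chi2=chi2,
        df=df,
        n=n,
        observed=obs,
        expected=expected,
        cell_excess=excess_full,
        collapsed=collapsed,
        low_count=n < 20,
    )


def chi2_stat(g1, g2) -> float:
    """Scalar convenience wrapper around genotypic_chi2 for permutation use."""
    return genotypic_chi2(g1, g2).chi2


def r2_stat(g1, g2) -> float:
    return geno_r2(g1, g2)[0]


def permutation_p(
    stat,
    g1,
    g2,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Permutation p-value for a two-locus statistic.

    ``g2`` is permuted across individuals within the complete-case index
    set, the statistic recomputed each time, and p = (k+1)/(n_perm+1) with
    k the number of null draws >= the observed value, so p is never 0 and is
    super-uniform under the null.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x, y = _complete_cases(g1, g2)
    observed = stat(x, y)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = stat(x, rng.permutation(y))
    k = int(np.sum(null >= observed))
    return (k + 1) / (n_perm + 1), null


@dataclass
class GenePairScan:
    pairs: pd.DataFrame  # snp1, snp2, r2, n, gene_pair_empirical_p
    threshold_99: float
    n_pairs: int


def gene_pair_scan(
    gm_a: GenotypeMatrix, gm_b: GenotypeMatrix, q: float = 0.99
) -> GenePairScan:
    """r2 for every cross-region SNP pair plus the gene-pair empirical null.

    The gene-pair empirical p of a pair is the fraction of all cross-region
    pairs whose r2 is >= its own; the q-th percentile of the r2 distribution
    (99th by default) is the significance threshold. Regions must not
    overlap.
    """
    if _regions_overlap(gm_a, gm_b):
        raise ValueError("gene_pair_scan: regions overlap")
    if set(gm_a.samples) != set(gm_b.samples):
        raise ValueError("gene_pair_scan: sample sets differ")
    if gm_b.samples != gm_a.samples:
        gm_b = gm_b.subset_samples(gm_a.samples)
    rows = []
    for i, va in enumerate(gm_a.variants):
        for j, vb in enumerate(gm_b.variants):
            r2, n = geno_r2(gm_a.dosage[:, i], gm_b.dosage[:, j])
            rows.append((va.id, vb.id, r2, n))
    pairs = pd.DataFrame(rows, columns=["snp1", "snp2", "r2", "n"])
    vals = pairs["r2"].to_numpy()
    ok = ~np.isnan(vals)
    ref = np.sort(vals[ok])
    total = ref.size
    if total == 0:
        raise ValueError("gene_pair_scan: no defined r2 values")
    emp = np.full(vals.shape, np.nan)
    emp[ok] = (total - np.searchsorted(ref, vals[ok], side="left")) / total
    pairs["gene_pair_empirical_p"] = emp
    return GenePairScan(
        pairs=pairs,
        threshold_99=float(np.quantile(ref, q, method="linear")),
        n_pairs=total,
    )


def _regions_overlap(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix) -> bool:
    if gm_a.n_variants == 0 or gm_b.n_variants == 0:
        return False
    for chrom in set(gm_a.chroms) & set(gm_b.chroms):
        pa = gm_a.positions[gm_a.chroms == chrom]
        pb = gm_b.positions[gm_b.chroms == chrom]
        if pa.min() <= pb.max() and pb.min() <= pa.max():
            return True
    return False


@dataclass
class MatchedNull:
    focal_snp1: str
    focal_snp2: str
    focal_value: float
    maf_window: tuple[float, float]
    bp_window: tuple[float, float]
    cm_window: tuple[float, float]
    chroms: list[str]
    values: np.ndarray
    pairs: pd.DataFrame  # chrom, pos1, pos2, id1, id2
    n_pairs: int
    n_qualifying: int
    empirical_p: float
    seed: int | None
    statistic: str = "r2"


def matched_pair_null(
    gm_genome: GenotypeMatrix,
    maps: dict[str, GeneticMap],
    focal_g1,
    focal_g2,
    maf_window: tuple[float, float] = (0.15, 0.30),
    bp_window: tuple[float, float] = (50e6, 60e6),
    cm_window: tuple[float, float] | None = None,
    cm_halfwidth: float = 10.0,
    focal_cm_distance: float | None = None,
    chroms: list[str] | None = None,
    n_pairs: int = 3513,
    seed: int = 0,
    statistic: str = "r2",
) -> MatchedNull:
    """Genome-wide empirical null from SNP pairs matched to the focal pair.

    Enumerates all same-chromosome SNP pairs whose two MAFs fall inside
    ``maf_window``, whose bp separation falls inside ``bp_window`` and whose
    cM separation falls inside ``cm_window`` (default: focal distance
    +/- ``cm_halfwidth``), then subsamples ``n_pairs`` of them without
    replacement with a fixed seed; if fewer qualify, all are used with a
    warning. The genome-wide empirical p of the focal statistic is the plain
    fraction of null values >= the observed one (reported as < 1/n when 0).
    """
    stat = {"r2": r2_stat, "chi2": chi2_stat}[statistic]
    focal_value = stat(np.asarray(focal_g1, float), np.asarray(focal_g2, float))
    if cm_window is None:
        if focal_cm_distance is None:
            raise ValueError("need cm_window or focal_cm_distance")
        cm_window = (focal_cm_distance - cm_halfwidth, focal_cm_distance + cm_halfwidth)
    if chroms is None:
        chroms = sorted(set(gm_genome.chroms), key=str)
    maf = gm_genome.maf()
    all_chroms = gm_genome.chroms
    all_pos = gm_genome.positions
    cand_pairs: list[tuple[int, int]] = []
    for chrom in chroms:
        if chrom not in maps:
            raise ValueError(f"no genetic map for chromosome {chrom}")
        idx = np.flatnonzero(
            (all_chroms == chrom)
            & (maf >= maf_window[0])
            & (maf <= maf_window[1])
        )
        if idx.size < 2:
            continue
        pos = all_pos[idx].astype(float)
        order = np.argsort(pos)
        idx, pos = idx[order], pos[order]
        cm = interpolate_cm(maps[chrom], pos)
        lo = np.searchsorted(pos, pos + bp_window[0], side="left")
        hi = np.searchsorted(pos, pos + bp_window[1], side="right")
        for a in range(idx.size):
            for b in range(lo[a], hi[a]):
                if a == b:
                    continue
                if cm_window[0] <= cm[b] - cm[a] <= cm_window[1]:
                    cand_pairs.append((idx[a], idx[b]))
    n_qualifying = len(cand_pairs)
    rng = np.random.default_rng(seed)
    if n_qualifying > n_pairs:
        take = rng.choice(n_qualifying, size=n_pairs, replace=False)
        chosen = [cand_pairs[t] for t in sorted(take)]
    else:
        if n_qualifying < n_pairs:
            warnings.warn(
                f"only {n_qualifying} qualifying pairs (< requested {n_pairs})",
                stacklevel=2,
            )
        chosen = cand_pairs
    values = np.array(
        [stat(gm_genome.dosage[:, i], gm_genome.dosage[:, j]) for i, j in chosen]
    )
    ok = ~np.isnan(values)
    values = values[ok]
    chosen = [p for p, keep in zip(chosen, ok) if keep]
    k = int(np.sum(values >= focal_value))
    emp_p = k / values.size if values.size else float("nan")
    pair_table = pd.DataFrame(
        {
            "chrom": [gm_genome.variants[i].chrom for i, _ in chosen],
            "id1": [gm_genome.variants[i].id for i, _ in chosen],
            "id2": [gm_genome.variants[j].id for _, j in chosen],
            "pos1": [gm_genome.variants[i].pos for i, _ in chosen],
            "pos2": [gm_genome.variants[j].pos for _, j in chosen],
            "value": values,
        }
    )
    return MatchedNull(
        focal_snp1="snp1",
        focal_snp2="snp2",
        focal_value=focal_value,
        maf_window=maf_window,
        bp_window=tuple(bp_window),
        cm_window=tuple(cm_window),
        chroms=list(chroms),
        values=values,
        pairs=pair_table,
        n_pairs=len(chosen),
        n_qualifying=n_qualifying,
        empirical_p=emp_p,
        seed=seed if isinstance(seed, int) else None,
        statistic=statistic,
    )


def sex_stratified_scan(
    gm_a: GenotypeMatrix, gm_b: GenotypeMatrix, panel: SamplePanel
) -> dict[str, GenePairScan]:
    """The gene-pair scan evaluated separately in males and females.

    The identical pair set is scored per stratum and gene-pair empirical
    p-values are computed within stratum. Samples with unknown sex are
    excluded (their count is reported via the returned scans' n fields).
    Strata with fewer than 10 samples are still scored but flagged.
    """
    out: dict[str, GenePairScan] = {}
    for sex in ("male", "female"):
        keep = [s for s in gm_a.samples if s in set(panel.samples_for(sex=sex))]
        if not keep:
            continue
        scan = gene_pair_scan(gm_a.subset_samples(keep), gm_b.subset_samples(keep))
        scan.pairs["stratum"] = sex
        scan.pairs["low_n"] = len(keep) < 10
        out[sex] = scan
    return out


def sex_difference_stat(g1, g2, is_male: np.ndarray, kind: str = "difference") -> float:
    """Observed male-female discrepancy in r2 (difference or log-ratio)."""
    r2_m = r2_stat(np.asarray(g1, float)[is_male], np.asarray(g2, float)[is_male])
    r2_f = r2_stat(np.asarray(g1, float)[~is_male], np.asarray(g2, float)[~is_male])
    if kind == "difference":
        return r2_m - r2_f
    if kind == "ratio":
        return np.log((r2_m + 1e-12) / (r2_f + 1e-12))
    raise ValueError(f"unknown sex-difference statistic {kind!r}")


def sex_permutation_test(
    g1,
    g2,
    sex,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    kind: str = "difference",
) -> tuple[float, float, np.ndarray]:
    """Two-sided permutation test for a sex difference in two-locus r2.

    Sex labels are shuffled across individuals preserving stratum sizes and
    the chosen discrepancy statistic D (default r2_male - r2_female) is
    recomputed; p = (k+1)/(n_perm+1) with k = #{|D_null| >= |D_obs|}.
    Returns (p, D_observed, null sample).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sex = np.asarray(sex)
    is_male = sex == "male"
    if is_male.all() or not is_male.any():
        raise ValueError("both sexes must be represented")
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    observed = sex_difference_stat(g1, g2, is_male, kind)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = sex_difference_stat(g1, g2, rng.permutation(is_male), kind)
    k = int(np.sum(np.abs(null) >= abs(observed)))
    return (k + 1) / (n_perm + 1), observed, null
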