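"""Synthetic admixed-cohort generator with ground-truth manifests.

The generator emulates the study design the rest of the package analyses:
an outgroup and two source populations drifted from a common ancestral
allele-frequency pool (Balding-Nichols drift, magnitude configurable to
produce target F_ST), and an admixed cohort assembled forward-in-time by
sampling ancestry tracts (recombination breakpoints Poisson in genetic
distance over the configured number of generations since admixture) over
two gene-sized regions ~50 Mb apart plus optional background chromosomes.
Optional sex-specific epistatic viability selection acts on one focal SNP
pair; expression and binary phenotypes with configurable SNP x SNP (x sex)
interaction effects are layered on top. Every artifact is deterministic
given the seed, and a truth manifest records the parameters and realized
quantities used by the recovery tests.

Within a source population, sites are drawn in linkage equilibrium; the
coalescent backend (`simulate_haplotypes` / `simulate_sweep`, msprime) is
used where realistic haplotype structure is needed (EHH/iHS fixtures).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestry import LocalAncestryTrack, write_local_ancestry
from .genio import (
    GeneticMap,
    GenotypeMatrix,
    HaplotypeMatrix,
    SamplePanel,
    VariantRecord,
    write_map_set,
    write_vcf,
)


class SimError(ValueError):
    pass


@dataclass
class Region:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_variants: int

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class SelectionConfig:
    """Per-sex 3x3 relative viabilities indexed by (dosage1, dosage2)."""

    viability_male: np.ndarray
    viability_female: np.ndarray

    def __post_init__(self):
        self.viability_male = np.asarray(self.viability_male, dtype=float)
        self.viability_female = np.asarray(self.viability_female, dtype=float)
        for v in (self.viability_male, self.viability_female):
            if v.shape != (3, 3) or (v < 0).any() or v.max() <= 0:
                raise SimError("viabilities must be a non-negative 3x3 table with a positive maximum")

def male_only_selection(advantage: float, cell: tuple[int, int] = (0, 0)) -> SelectionConfig:
    """Viability boost for one genotype combination in males only."""
    vm = np.ones((3, 3))
    vm[cell] = advantage
    return SelectionConfig(viability_male=vm, viability_female=np.ones((3, 3)))


def both_sex_selection(advantage: float, cell: tuple[int, int] = (0, 0)) -> SelectionConfig:
    """The same viability boost for one genotype combination in both sexes."""
    v = np.ones((3, 3))
    v[cell] = advantage
    return SelectionConfig(viability_male=v, viability_female=v.copy())


SELECTION_PRESETS = {
    "neutral": lambda: SelectionConfig(np.ones((3, 3)), np.ones((3, 3))),
    "weak": lambda: male_only_selection(1.5),
    "strong": lambda: male_only_selection(3.0),
    "weak_both": lambda: both_sex_selection(1.5),
    "strong_both": lambda: both_sex_selection(3.0),
}


@dataclass
class ExpressionConfig:
    beta_g1: float = 0.0
    beta_g2: float = 0.0
    beta_interaction: float = 0.0
    beta_interaction_male: float | None = None
    beta_interaction_female: float | None = None
    n_covariates: int = 5  # synthetic PC/PEER-like columns
    covariate_beta: float = 0.3
    noise_sd: float = 1.0


@dataclass
class BinaryTraitConfig:
    prevalence: float = 0.1
    logodds_g1: float = 0.0
    logodds_g2: float = 0.0
    logodds_interaction: float = 0.0
    logodds_interaction_male: float | None = None
    logodds_interaction_female: float | None = None


@dataclass
class SimConfig:
    seed: int = 0
    # cohort sizes; defaults are the "PEL-like" stratum sizes (44 F / 41 M)
    n_admixed_female: int = 44
    n_admixed_male: int = 41
    n_source: int = 60
    n_outgroup: int = 60
    admixture_proportions: tuple[float, ...] = (0.75, 0.25)
    ancestry_labels: tuple[str, ...] = ("Andean", "European")
    generations: int = 15
    # Balding-Nichols drift F per population (from the shared ancestral pool)
    f_source: tuple[float, ...] = (0.05, 0.05)
    f_outgroup: float = 0.10
    # two gene-sized regions ~50 Mb apart on one chromosome
    region_a: Region = field(
        default_factory=lambda: Region("16", 4_012_650, 4_166_186, 60)
    )
    region_b: Region = field(
        default_factory=lambda: Region("16", 56_995_835, 57_017_756, 30)
    )
    cm_per_mb: float = 1.15  # puts the inter-region gap at ~61 cM
    # focal SNP pair (one per region): alt-allele frequency, shared across
    # sources unless focal_drift is set
    focal_maf: float = 0.25
    focal_drift: bool = False
    # optional background chromosomes for genome-wide nulls
    n_background_chroms: int = 0
    background_span: tuple[int, int] = (1_000_000, 81_000_000)
    n_background_variants: int = 300
    selection: SelectionConfig | None = None
    build_track: bool = True

    def __post_init__(self):
        k = len(self.admixture_proportions)
        if k != len(self.ancestry_labels) or k != len(self.f_source):
            raise SimError("admixture proportions / labels / drift F lengths differ")
        if abs(sum(self.admixture_proportions) - 1) > 1e-9:
            raise SimError("admixture proportions must sum to 1")
        if min(self.n_admixed_female, self.n_admixed_male) < 0 or self.n_admixed < 1:
            raise SimError("cohort size must be positive")
        if self.n_source < 1 or self.n_outgroup < 1:
            raise SimError("population sizes must be positive")

    @property
    def n_admixed(self) -> int:
        return self.n_admixed_female + self.n_admixed_male

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimConfig":
        """Build a config from a YAML file mirroring the dataclass fields.

        Nested blocks: ``region_a``/``region_b`` (chrom, start, end,
        n_variants) and ``selection`` (either ``preset: <name>`` or explicit
        ``viability_male``/``viability_female`` 3x3 tables). List-valued
        fields accept YAML lists.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("region_a", "region_b"):
            if key in raw:
                raw[key] = Region(**raw[key])
        if "selection" in raw and raw["selection"] is not None:
            sel = raw["selection"]
            if isinstance(sel, str):
                raw["selection"] = SELECTION_PRESETS[sel]()
            elif "preset" in sel:
                raw["selection"] = SELECTION_PRESETS[sel["preset"]]()
            else:
                raw["selection"] = SelectionConfig(
                    viability_male=np.asarray(sel["viability_male"], float),
                    viability_female=np.asarray(sel["viability_female"], float),
                )
        for key in ("admixture_proportions", "ancestry_labels", "f_source",
                    "background_span"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def pel_like(seed: int = 0, **kw) -> SimConfig:
    """85 admixed samples (44 F / 41 M), the discovery-cohort scale."""
    return SimConfig(seed=seed, n_admixed_female=44, n_admixed_male=41, **kw)


def limaa_like(seed: int = 0, **kw) -> SimConfig:
    """3,243 admixed samples (1,302 F / 1,941 M), the replication scale."""
    kw.setdefault("build_track", False)
    return SimConfig(seed=seed, n_admixed_female=1302, n_admixed_male=1941, **kw)


@dataclass
class SyntheticTruth:
    seed: int
    focal_ids: tuple[str, str]
    focal_alt_freq_sources: list[list[float]]
    admixture_target: list[float]
    admixture_realized: pd.DataFrame | None
    selection_applied: bool
    male_cell_excess: np.ndarray | None
    female_cell_excess: np.ndarray | None
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        def _clean(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, pd.DataFrame):
                return {"index": list(x.index), "columns": list(x.columns), "data": x.to_numpy().tolist()}
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, dict):
                return {k: _clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_clean(v) for v in x]
            return x

        payload = {k: _clean(v) for k, v in dataclasses.asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class Cohort:
    haplotypes: HaplotypeMatrix  # all populations, all chromosomes
    panel: SamplePanel
    maps: dict[str, GeneticMap]
    track: LocalAncestryTrack | None
    truth: SyntheticTruth
    cfg: SimConfig

    def genotypes(
        self, population: str | None = None, region: tuple[str, int, int] | None = None
    ) -> GenotypeMatrix:
        gm = self.haplotypes.to_genotype_matrix()
        if population is not None:
            gm = gm.subset_samples(self.panel.samples_for(population))
        if region is not None:
            chrom, start, end = region
            keep = (gm.chroms == str(chrom)) & (gm.positions >= start) & (gm.positions <= end)
            gm = gm.subset_variants(keep)
        return gm

    def focal_dosages(self, population: str = "ADM") -> tuple[np.ndarray, np.ndarray]:
        gm = self.genotypes(population)
        i1, i2 = self.truth.focal_ids
        return gm.dosages_for(i1), gm.dosages_for(i2)

    def admixed_panel(self) -> SamplePanel:
        t = self.panel.table
        return SamplePanel(t[t["population"] == "ADM"].reset_index(drop=True))


def _balding_nichols(rng, p_anc: np.ndarray, f: float) -> np.ndarray:
    if f <= 0:
        return p_anc.copy()
    a = p_anc * (1 - f) / f
    b = (1 - p_anc) * (1 - f) / f
    return np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)


def _region_positions(rng, region: Region, focal_mid: bool) -> tuple[np.ndarray, int | None]:
    pos = rng.choice(
        np.arange(region.start, region.end + 1), size=region.n_variants, replace=False
    )
    pos.sort()
    focal_idx = None
    if focal_mid:
        focal_idx = region.n_variants // 2
    return pos.astype(np.int64), focal_idx


def _chromosome_layout(cfg: SimConfig, rng) -> tuple[dict, dict[str, GeneticMap], list[VariantRecord], dict]:
    """Site positions, maps and variant records for every chromosome."""
    chroms: dict[str, dict] = {}
    ra, rb = cfg.region_a, cfg.region_b
    if ra.chrom != rb.chrom or ra.end >= rb.start:
        raise SimError("region A must precede region B on the same chromosome")
    pos_a, fa = _region_positions(rng, ra, True)
    pos_b, fb = _region_positions(rng, rb, True)
    main_pos = np.concatenate([pos_a, pos_b])
    chroms[ra.chrom] = {
        "span": (ra.start, rb.end),
        "pos": main_pos,
        "focal": (fa, len(pos_a) + fb),
    }
    for k in range(cfg.n_background_chroms):
        name = str(k + 1)
        if name == ra.chrom:
            name = f"bg{k + 1}"
        lo, hi = cfg.background_span
        pos = rng.choice(np.arange(lo, hi + 1), size=cfg.n_background_variants, replace=False)
        pos.sort()
        chroms[name] = {"span": (lo, hi), "pos": pos.astype(np.int64), "focal": None}
    maps = {
        c: GeneticMap.uniform(d["span"][0], d["span"][1], cfg.cm_per_mb)
        for c, d in chroms.items()
    }
    variants: list[VariantRecord] = []
    focal_ids: list[str] = []
    for c, d in chroms.items():
        for j, p in enumerate(d["pos"]):
            vid = f"snp_{c}_{p}"
            if d["focal"] is not None and j in d["focal"]:
                vid = "focal_g1" if j == d["focal"][0] else "focal_g2"
                focal_ids.append(vid)
            # ref allele is the ancestral allele by construction
            variants.append(VariantRecord(c, int(p), vid, "A", "G", ancestral="A"))
    assert focal_ids == ["focal_g1", "focal_g2"]
    return chroms, maps, variants, {"focal_ids": ("focal_g1", "focal_g2")}


def _population_freqs(cfg: SimConfig, rng, chroms: dict) -> dict:
    """Ancestral, per-source and outgroup alt-allele frequencies per chrom."""
    out = {}
    for c, d in chroms.items():
        m = d["pos"].size
        p_anc = rng.uniform(0.05, 0.95, size=m)
        if d["focal"] is not None:
            for fi in d["focal"]:
                p_anc[fi] = cfg.focal_maf
        sources = []
        for f in cfg.f_source:
            ps = _balding_nichols(rng, p_anc, f)
            sources.append(ps)
        p_out = _balding_nichols(rng, p_anc, cfg.f_outgroup)
        if d["focal"] is not None and not cfg.focal_drift:
            for fi in d["focal"]:
                for ps in sources:
                    ps[fi] = cfg.focal_maf
                p_out[fi] = cfg.focal_maf
        out[c] = {"anc": p_anc, "sources": np.stack(sources), "out": p_out}
    return out


def _draw_diploids(rng, p: np.ndarray, n: int) -> np.ndarray:
    """(2n, m) binary haplotypes in linkage equilibrium at frequencies p."""
    return (rng.random((2 * n, p.size)) < p).astype(np.uint8)


def _admixed_haplotype(rng, cfg: SimConfig, chroms: dict, freqs: dict):
    """One haplotype: alleles per chromosome plus its ancestry tracts (cM)."""
    k = len(cfg.admixture_proportions)
    alleles = {}
    tracts = {}
    for c, d in chroms.items():
        lo, hi = d["span"]
        cm_len = (hi - lo) * cfg.cm_per_mb * 1e-6
        n_bk = rng.poisson(cfg.generations * cm_len / 100.0)
        bks = np.sort(rng.uniform(0.0, cm_len, size=n_bk))
        ancs = rng.choice(k, size=n_bk + 1, p=cfg.admixture_proportions)
        site_cm = (d["pos"] - lo) * cfg.cm_per_mb * 1e-6
        site_anc = ancs[np.searchsorted(bks, site_cm, side="right")]
        p_site = freqs[c]["sources"][site_anc, np.arange(d["pos"].size)]
        alleles[c] = (rng.random(d["pos"].size) < p_site).astype(np.uint8)
        tracts[c] = (bks, ancs, cm_len)
    return alleles, tracts


def _gen_admixed(rng, cfg: SimConfig, chroms, freqs, n_needed: dict[str, int]):
    """Admixed individuals by sex, with optional viability selection."""
    sel = cfg.selection
    focal_chrom = cfg.region_a.chrom
    f1, f2 = chroms[focal_chrom]["focal"]
    done = {s: [] for s in n_needed}
    max_attempts = 200 * sum(n_needed.values()) + 1000
    attempts = 0
    order = rng.permutation(
        ["female"] * n_needed["female"] + ["male"] * n_needed["male"]
    ) if sel is None else None
    while any(len(done[s]) < n_needed[s] for s in n_needed):
        attempts += 1
        if attempts > max_attempts:
            raise SimError(
                "viability selection failed to produce the requested cohort "
                "(a whole sex may be eliminated)"
            )
        if sel is None:
            sex = order[len(done["female"]) + len(done["male"])]
        else:
            sex = "female" if len(done["female"]) < n_needed["female"] else "male"
        h1 = _admixed_haplotype(rng, cfg, chroms, freqs)
        h2 = _admixed_haplotype(rng, cfg, chroms, freqs)
        if sel is not None:
            d1 = int(h1[0][focal_chrom][f1]) + int(h2[0][focal_chrom][f1])
            d2 = int(h1[0][focal_chrom][f2]) + int(h2[0][focal_chrom][f2])
            table = sel.viability_male if sex == "male" else sel.viability_female
            if rng.random() >= table[d1, d2] / table.max():
                continue
        done[sex].append((h1, h2))
    return done


def _union_track(cfg: SimConfig, chroms, per_sample_tracts, samples) -> LocalAncestryTrack:
    rows = []
    calls_cols = []
    for c, d in chroms.items():
        lo, hi = d["span"]
        cm_len = (hi - lo) * cfg.cm_per_mb * 1e-6
        bk_all = sorted(
            {0.0, cm_len}
            | {b for tr in per_sample_tracts for b in tr[c][0] if 0 < b < cm_len}
        )
        edges = np.asarray(bk_all)
        # near-coincident breakpoints can round to the same bp; merge them so
        # intervals stay strictly non-empty on the bp scale
        bp = np.round(lo + edges / (cfg.cm_per_mb * 1e-6)).astype(np.int64)
        keep = np.ones(edges.size, dtype=bool)
        last = bp[0]
        for i in range(1, edges.size):
            if bp[i] <= last:
                keep[i] = False
            else:
                last = bp[i]
        if not keep[-1]:  # the terminal edge must survive; merge leftwards
            prev = np.flatnonzero(keep[:-1])[-1]
            keep[-1] = True
            keep[prev] = False if bp[-1] <= bp[prev] else keep[prev]
        edges, bp = edges[keep], bp[keep]
        mids = (edges[:-1] + edges[1:]) / 2
        col = np.empty((edges.size - 1, len(per_sample_tracts)), dtype=np.int16)
        for h, tr in enumerate(per_sample_tracts):
            bks, ancs, _ = tr[c]
            col[:, h] = ancs[np.searchsorted(bks, mids, side="right")]
        for i in range(edges.size - 1):
            rows.append(
                {
                    "chrom": c,
                    "spos": int(bp[i]),
                    "epos": int(bp[i + 1]),
                    "sgpos": edges[i],
                    "egpos": edges[i + 1],
                }
            )
        calls_cols.append(col)
    intervals = pd.DataFrame(rows)
    calls = np.vstack(calls_cols)
    return LocalAncestryTrack(
        labels=list(cfg.ancestry_labels),
        samples=samples,
        intervals=intervals,
        calls=calls,
    )


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate the full synthetic study: populations, cohort, map, truth.

    Deterministic given cfg.seed. Sample order: outgroup, source
    populations, then the admixed cohort (females before males).
    """
    rng = np.random.default_rng(cfg.seed)
    chroms, maps, variants, meta = _chromosome_layout(cfg, rng)
    freqs = _population_freqs(cfg, rng, chroms)
    chrom_names = list(chroms)

    def _concat(pop_freq_key):
        return np.concatenate([freqs[c][pop_freq_key] for c in chrom_names])

    hap_blocks = []
    samples = []
    pops = []
    sexes = []
    # outgroup + sources (linkage equilibrium at drifted frequencies)
    out_p = np.concatenate([freqs[c]["out"] for c in chrom_names])
    hap_blocks.append(_draw_diploids(rng, out_p, cfg.n_outgroup))
    samples += [f"OUT{i:04d}" for i in range(cfg.n_outgroup)]
    pops += ["OUT"] * cfg.n_outgroup
    sexes += ["unknown"] * cfg.n_outgroup
    for k in range(len(cfg.f_source)):
        src_p = np.concatenate([freqs[c]["sources"][k] for c in chrom_names])
        hap_blocks.append(_draw_diploids(rng, src_p, cfg.n_source))
        samples += [f"SRC{k + 1}_{i:04d}" for i in range(cfg.n_source)]
        pops += [f"SRC{k + 1}"] * cfg.n_source
        sexes += ["unknown"] * cfg.n_source

    # admixed cohort (tract mosaic, optional viability selection)
    by_sex = _gen_admixed(
        rng,
        cfg,
        chroms,
        freqs,
        {"female": cfg.n_admixed_female, "male": cfg.n_admixed_male},
    )
    adm_rows = []
    hap_tracts = []
    adm_samples = []
    i = 0
    for sex in ("female", "male"):
        for h1, h2 in by_sex[sex]:
            adm_samples.append(f"ADM{i:04d}")
            sexes.append(sex)
            pops.append("ADM")
            for h in (h1, h2):
                adm_rows.append(np.concatenate([h[0][c] for c in chrom_names]))
                hap_tracts.append(h[1])
            i += 1
    samples += adm_samples
    hap_blocks.append(np.vstack(adm_rows))
    haps = np.vstack(hap_blocks)
    hm = HaplotypeMatrix(samples, variants, haps)
    panel = SamplePanel(
        pd.DataFrame({"sample": samples, "population": pops, "sex": sexes})
    )

    track = None
    realized = None
    if cfg.build_track:
        track = _union_track(cfg, chroms, hap_tracts, adm_samples)
        from .ancestry import genomewide_proportion

        realized = genomewide_proportion(track, maps)

    # realized focal allele freqs per source + per-sex genotype-combination excess
    f_ids = meta["focal_ids"]
    gm_adm = hm.to_genotype_matrix().subset_samples(adm_samples)
    d1 = gm_adm.dosages_for(f_ids[0])
    d2 = gm_adm.dosages_for(f_ids[1])
    adm_sex = np.array([sexes[samples.index(s)] for s in adm_samples])
    excess = {}
    for sex in ("male", "female"):
        m = adm_sex == sex
        if m.sum() >= 2:
            from .lrld import genotypic_chi2

            excess[sex] = genotypic_chi2(d1[m], d2[m]).cell_excess
        else:
            excess[sex] = None
    focal_src_freqs = [
        [float(freqs[cfg.region_a.chrom]["sources"][k][fi]) for fi in chroms[cfg.region_a.chrom]["focal"]]
        for k in range(len(cfg.f_source))
    ]
    truth = SyntheticTruth(
        seed=cfg.seed,
        focal_ids=f_ids,
        focal_alt_freq_sources=focal_src_freqs,
        admixture_target=list(cfg.admixture_proportions),
        admixture_realized=realized,
        selection_applied=cfg.selection is not None,
        male_cell_excess=excess["male"],
        female_cell_excess=excess["female"],
        extras={
            "focal_alt_freq_admixed": [float(np.mean(d1) / 2), float(np.mean(d2) / 2)],
        },
    )
    return Cohort(haplotypes=hm, panel=panel, maps=maps, track=track, truth=truth, cfg=cfg)


def apply_epistatic_viability_selection(
    cohort: Cohort, selection: SelectionConfig, seed: int = 0
) -> Cohort:
    """Thin an existing admixed cohort by sex-specific pair viabilities.

    Each admixed individual is retained with probability proportional to the
    viability of its focal genotype combination given its sex (sources and
    outgroup are untouched). Errors if a whole sex is eliminated.
    """
    rng = np.random.default_rng(seed)
    d1, d2 = cohort.focal_dosages("ADM")
    adm = cohort.panel.table[cohort.panel.table["population"] == "ADM"]
    sex = adm["sex"].to_numpy()
    keep = np.ones(len(adm), dtype=bool)
    for i in range(len(adm)):
        table = selection.viability_male if sex[i] == "male" else selection.viability_female
        keep[i] = rng.random() < table[int(d1[i]), int(d2[i])] / table.max()
    for s in ("male", "female"):
        if (sex == s).any() and not keep[sex == s].any():
            raise SimError(f"viability selection eliminated all {s}s")
    keep_samples = [s for s, k in zip(adm["sample"], keep) if k]
    others = cohort.panel.table[cohort.panel.table["population"] != "ADM"]["sample"]
    all_keep = list(others) + keep_samples
    idx = [cohort.haplotypes.samples.index(s) for s in all_keep]
    hap_idx = np.array([2 * i + k for i in idx for k in (0, 1)])
    hm = HaplotypeMatrix(
        all_keep, cohort.haplotypes.variants, cohort.haplotypes.haplotypes[hap_idx]
    )
    panel = SamplePanel(
        cohort.panel.table[cohort.panel.table["sample"].isin(all_keep)].reset_index(
            drop=True
        )
    )
    return Cohort(
        haplotypes=hm,
        panel=panel,
        maps=cohort.maps,
        track=cohort.track,
        truth=cohort.truth,
        cfg=cohort.cfg,
    )


def simulate_expression(
    cohort: Cohort, expr: ExpressionConfig, seed: int = 0
) -> tuple[pd.Series, pd.DataFrame]:
    """Expression vector with configured SNP x SNP (x sex) effects.

    y = b1*g1 + b2*g2 + b_int*g1*g2 (per-sex b_int when configured) +
    covariate effects + Gaussian noise; covariates are synthetic PC/PEER-like
    standard-normal columns with declared effect sizes.
    """
    rng = np.random.default_rng(seed)
    d1, d2 = cohort.focal_dosages("ADM")
    adm = cohort.admixed_panel()
    n = len(adm.samples)
    sex = adm.table["sex"].to_numpy()
    b_int = np.full(n, expr.beta_interaction)
    if expr.beta_interaction_male is not None:
        b_int[sex == "male"] = expr.beta_interaction_male
    if expr.beta_interaction_female is not None:
        b_int[sex == "female"] = expr.beta_interaction_female
    cov = rng.standard_normal((n, expr.n_covariates))
    y = (
        expr.beta_g1 * d1
        + expr.beta_g2 * d2
        + b_int * d1 * d2
        + cov.sum(axis=1) * expr.covariate_beta
        + rng.normal(0, expr.noise_sd, n)
    )
    cov_df = pd.DataFrame(
        cov, columns=[f"cov{j + 1}" for j in range(expr.n_covariates)], index=adm.samples
    )
    return pd.Series(y, index=adm.samples, name="expression"), cov_df


def simulate_binary_trait(
    cohort: Cohort, trait: BinaryTraitConfig, seed: int = 0
) -> tuple[pd.Series, float]:
    """Binary outcome under a logistic model with per-sex interaction effects.

    Genetic predictor columns are centered so the realized prevalence tracks
    the configured baseline. Degenerate all-case/all-control draws are
    resampled once, then raise.
    """
    if not 0 < trait.prevalence < 1:
        raise SimError("prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    d1, d2 = cohort.focal_dosages("ADM")
    adm = cohort.admixed_panel()
    n = len(adm.samples)
    sex = adm.table["sex"].to_numpy()
    b_int = np.full(n, trait.logodds_interaction)
    if trait.logodds_interaction_male is not None:
        b_int[sex == "male"] = trait.logodds_interaction_male
    if trait.logodds_interaction_female is not None:
        b_int[sex == "female"] = trait.logodds_interaction_female
    x1 = d1 - d1.mean()
    x2 = d2 - d2.mean()
    x12 = d1 * d2 - (d1 * d2).mean()
    eta = (
        np.log(trait.prevalence / (1 - trait.prevalence))
        + trait.logodds_g1 * x1
        + trait.logodds_g2 * x2
        + b_int * x12
    )
    p = 1 / (1 + np.exp(-eta))
    for attempt in range(2):
        y = (rng.random(n) < p).astype(int)
        if 0 < y.sum() < n:
            return pd.Series(y, index=adm.samples, name="case"), float(y.mean())
    raise SimError("degenerate all-case or all-control draw (twice)")


def write_outputs(cohort: Cohort, outdir: str | os.PathLike, overwrite: bool = False, bgzip: bool = True) -> dict[str, str]:
    """Write VCF + map TSV + panel TSV + msp-style ancestry + truth JSON.

    Files are readable back by genio/ancestry and byte-identical given the
    same seed. Errors on an existing non-empty directory unless overwrite.
    """
    outdir = os.fspath(outdir)
    if os.path.isdir(outdir) and os.listdir(outdir) and not overwrite:
        raise SimError(f"output directory {outdir} is not empty (pass overwrite=True)")
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    paths["vcf"] = write_vcf(
        cohort.haplotypes, os.path.join(outdir, "cohort.vcf"), bgzip=bgzip
    )
    paths["map"] = os.path.join(outdir, "genetic_map.tsv")
    write_map_set(cohort.maps, paths["map"])
    paths["panel"] = os.path.join(outdir, "panel.tsv")
    cohort.panel.to_tsv(paths["panel"])
    if cohort.track is not None:
        paths["msp"] = os.path.join(outdir, "ancestry.msp.tsv")
        write_local_ancestry(cohort.track, paths["msp"])
    paths["truth"] = os.path.join(outdir, "truth.json")
    cohort.truth.to_json(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# Coalescent backend (haplotype-structure fixtures for EHH/iHS)


def _ts_to_haplotypes(ts, chrom: str = "1") -> HaplotypeMatrix:
    import tskit  # noqa: F401  (msprime dependency)

    keep = []
    for site in ts.sites():
        if len(site.mutations) == 1:
            keep.append(site.id)
    positions = []
    cols = []
    variants = []
    last_pos = -1
    for var in ts.variants():
        if var.site.id not in keep:
            continue
        pos = int(var.site.position) + 1
        if pos <= last_pos:
            continue
        last_pos = pos
        g = var.genotypes
        if g.min() < 0 or g.max() > 1:
            continue
        positions.append(pos)
        cols.append(g.astype(np.uint8))
        variants.append(
            VariantRecord(chrom, pos, f"msp_{chrom}_{pos}", "A", "G", ancestral="A")
        )
    haps = np.stack(cols, axis=1)
    n = haps.shape[0] // 2
    samples = [f"msp{i:04d}" for i in range(n)]
    return HaplotypeMatrix(samples, variants, haps, polarized=True)


def simulate_haplotypes(
    n_samples: int = 50,
    sequence_length: float = 1_000_000,
    ne: float = 10_000,
    mu: float = 1.25e-8,
    recomb: float = 1e-8,
    seed: int = 1,
) -> tuple[HaplotypeMatrix, GeneticMap]:
    """Neutral coalescent haplotypes with realistic LD (msprime backend)."""
    import msprime

    ts = msprime.sim_ancestry(
        samples=n_samples,
        population_size=ne,
        sequence_length=sequence_length,
        recombination_rate=recomb,
        random_seed=seed,
    )
    ts = msprime.sim_mutations(
        ts, rate=mu, random_seed=seed + 1, model=msprime.BinaryMutationModel()
    )
    hm = _ts_to_haplotypes(ts)
    gmap = GeneticMap.uniform(1, int(sequence_length), cm_per_mb=recomb * 1e8)
    return hm, gmap


def simulate_sweep(
    n_samples: int = 50,
    sequence_length: float = 1_000_000,
    ne: float = 10_000,
    mu: float = 1.25e-8,
    recomb: float = 1e-8,
    s: float = 0.05,
    end_frequency: float = 0.6,
    seed: int = 1,
) -> tuple[HaplotypeMatrix, GeneticMap, int]:
    """Partial hard sweep at the sequence midpoint (msprime sweep model).

    The selected mutation is planted on the tree node whose sample count is
    closest to end_frequency, at an unused integer position next to the
    sweep coordinate. Returns (haplotypes, map, swept bp position 1-based).
    """
    import msprime

    position = sequence_length / 2
    sweep = msprime.SweepGenicSelection(
        position=position,
        start_frequency=1.0 / (2 * ne),
        end_frequency=end_frequency,
        s=s,
        dt=1e-6,
    )
    ts = msprime.sim_ancestry(
        samples=n_samples,
        population_size=ne,
        sequence_length=sequence_length,
        recombination_rate=recomb,
        model=[sweep, msprime.StandardCoalescent()],
        random_seed=seed,
    )
    ts = msprime.sim_mutations(
        ts, rate=mu, random_seed=seed + 1, model=msprime.BinaryMutationModel()
    )
    tables = ts.dump_tables()
    used = {int(site.position) for site in ts.sites()}
    pos_int = int(position)
    while pos_int in used:
        pos_int += 1
    tree = ts.at(position)
    target = round(end_frequency * ts.num_samples)
    best, best_err = None, None
    for u in tree.nodes():
        ns = tree.num_samples(u)
        if ns in (0, ts.num_samples):
            continue
        err = abs(ns - target)
        if best is None or err < best_err:
            best, best_err = u, err
    site_id = tables.sites.add_row(position=pos_int, ancestral_state="0")
    tables.mutations.add_row(site=site_id, node=best, derived_state="1")
    tables.sort()
    ts = tables.tree_sequence()
    hm = _ts_to_haplotypes(ts)
    gmap = GeneticMap.uniform(1, int(sequence_length), cm_per_mb=recomb * 1e8)
    return hm, gmap, pos_int + 1
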