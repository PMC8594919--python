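"""Genotype/haplotype I/O, variant filters and genetic-map interpolation.

External files follow field conventions: VCF (optionally bgzipped and
tabix-indexed) for genotypes, a whitespace/tab-delimited two-column
(bp, cM) file per chromosome for genetic maps (a three-column variant with
a leading chromosome column holds a whole map set), and a plain TSV for the
sample panel. Coordinates in files are 1-based (VCF convention); interval
arithmetic inside the package uses half-open 0-based intervals, converted
at the boundary.

Missing dosages are encoded with the dedicated sentinel ``MISSING`` (-1),
never 0; all two-locus statistics downstream are complete-case per pair of
variants.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

SEXES = ("male", "female", "unknown")


class GenioError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP with optional ancestral-allele annotation."""

    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str
    ancestral: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise GenioError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise GenioError(f"variant {self.id}: ref == alt ({self.ref})")

    @property
    def polarizable(self) -> bool:
        """True when the ancestral allele is known and matches ref or alt."""
        return self.ancestral in (self.ref, self.alt)


@dataclass
class GenotypeMatrix:
    """Sample x variant alternate-allele dosage matrix (0/1/2, MISSING=-1)."""

    samples: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray  # (n_samples, n_variants) int8

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise GenioError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        ok = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not ok.all():
            raise GenioError("dosage entries must be in {0,1,2,MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    @property
    def ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant, on non-missing calls."""
        d = np.ma.masked_equal(self.dosage, MISSING)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.asarray(d.mean(axis=0).filled(np.nan)) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)

    def dosages_for(self, variant_id: str) -> np.ndarray:
        try:
            j = self.ids.index(variant_id)
        except ValueError:
            raise GenioError(f"variant {variant_id!r} not in matrix") from None
        return self.dosage[:, j].astype(float)

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = _sample_indices(self.samples, samples)
        return GenotypeMatrix(list(samples), self.variants, self.dosage[idx])

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.samples,
            [self.variants[j] for j in keep],
            self.dosage[:, keep],
        )


@dataclass
class HaplotypeMatrix:
    """Phased 2n x m binary haplotypes; rows (2i, 2i+1) belong to sample i.

    When ``polarized`` is true, allele 0 is ancestral and 1 derived, and
    non-polarizable variants have been excluded.
    """

    samples: list[str]
    variants: list[VariantRecord]
    haplotypes: np.ndarray  # (2*n_samples, n_variants) uint8
    polarized: bool = False
    n_dropped_polarize: int = 0

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape[0] % 2:
            raise GenioError("haplotype row count must be even")
        if self.haplotypes.shape != (2 * len(self.samples), len(self.variants)):
            raise GenioError("haplotype shape inconsistent with samples/variants")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise GenioError("haplotypes must be binary")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def derived_allele_freq(self) -> np.ndarray:
        if not self.polarized:
            raise GenioError("derived allele frequency requires polarized haplotypes")
        return self.haplotypes.mean(axis=0)

    def to_genotype_matrix(self) -> GenotypeMatrix:
        dos = (
            self.haplotypes[0::2].astype(np.int8) + self.haplotypes[1::2].astype(np.int8)
        )
        return GenotypeMatrix(self.samples, self.variants, dos)


@dataclass
class GeneticMap:
    """Monotone bp -> cM interpolator for one chromosome."""

    positions: np.ndarray  # 1-based bp, strictly increasing
    cm: np.ndarray  # non-decreasing

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=float)
        if self.positions.size == 0:
            raise GenioError("empty genetic map")
        if self.positions.size != self.cm.size:
            raise GenioError("genetic map positions/cm length mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise GenioError("map positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise GenioError("map cM must be non-decreasing")

    @classmethod
    def uniform(cls, start: int, end: int, cm_per_mb: float = 1.0) -> "GeneticMap":
        pos = np.array([start, end], dtype=np.int64)
        return cls(pos, (pos - start) * cm_per_mb * 1e-6)

    @property
    def length_cm(self) -> float:
        return float(self.cm[-1] - self.cm[0])

    def to_tsv(self, path: str | os.PathLike) -> None:
        pd.DataFrame({"pos": self.positions, "cm": self.cm}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "GeneticMap":
        df = _read_map_table(path)
        if df.shape[1] != 2:
            raise GenioError(f"expected two columns (bp, cM) in {path}")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def _read_map_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    # optional header row: non-numeric first row
    if not np.issubdtype(np.asarray(df.iloc[0, -1:]).dtype, np.number):
        df = pd.read_csv(path, sep=r"\s+", comment="#")
    return df


def read_map_set(path: str | os.PathLike) -> dict[str, GeneticMap]:
    """Read a three-column (chrom, bp, cM) file into per-chromosome maps."""
    df = _read_map_table(path)
    if df.shape[1] != 3:
        raise GenioError(f"expected three columns (chrom, bp, cM) in {path}")
    df.columns = ["chrom", "pos", "cm"]
    return {
        str(chrom): GeneticMap(g["pos"].to_numpy(), g["cm"].to_numpy())
        for chrom, g in df.groupby("chrom", sort=False)
    }


def write_map_set(maps: dict[str, GeneticMap], path: str | os.PathLike) -> None:
    frames = [
        pd.DataFrame({"chrom": c, "pos": m.positions, "cm": m.cm})
        for c, m in maps.items()
    ]
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def interpolate_cm(gmap: GeneticMap, positions) -> np.ndarray:
    """Linear interpolation of bp positions onto the cM scale.

    Positions beyond the map ends clamp to the terminal cM values (np.interp
    semantics), so extrapolation never produces values outside the map range.
    """
    positions = np.asarray(positions, dtype=float)
    return np.interp(positions, gmap.positions.astype(float), gmap.cm)


@dataclass
class SamplePanel:
    """Sample metadata: population label, sex, optional ancestry proportions."""

    table: pd.DataFrame  # columns: sample, population, sex, [ancestry...]

    def __post_init__(self):
        req = {"sample", "population", "sex"}
        if not req.issubset(self.table.columns):
            raise GenioError(f"panel must have columns {sorted(req)}")
        bad = set(self.table["sex"]) - set(SEXES)
        if bad:
            raise GenioError(f"unknown sex labels: {sorted(bad)}")
        if self.table["sample"].duplicated().any():
            raise GenioError("duplicate sample ids in panel")
        anc = self.ancestry_columns
        if anc:
            props = self.table[anc].to_numpy(dtype=float)
            if (props < 0).any() or np.abs(props.sum(axis=1) - 1).max() > 1e-6:
                raise GenioError("ancestry proportions must be >= 0 and sum to 1")
        self.table = self.table.reset_index(drop=True)

    @property
    def ancestry_columns(self) -> list[str]:
        return [
            c for c in self.table.columns if c not in ("sample", "population", "sex")
        ]

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def samples_for(self, population: str | None = None, sex: str | None = None) -> list[str]:
        t = self.table
        if population is not None:
            if population not in set(t["population"]):
                raise GenioError(f"population {population!r} not in panel")
            t = t[t["population"] == population]
        if sex is not None:
            if sex not in SEXES:
                raise GenioError(f"unknown sex {sex!r}")
            t = t[t["sex"] == sex]
        return list(t["sample"])

    def sex_of(self, samples: Sequence[str]) -> np.ndarray:
        m = dict(zip(self.table["sample"], self.table["sex"]))
        missing = [s for s in samples if s not in m]
        if missing:
            raise GenioError(f"samples not in panel: {missing[:5]}")
        return np.array([m[s] for s in samples])

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "SamplePanel":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample": str}))


def _sample_indices(have: Sequence[str], want: Sequence[str]) -> list[int]:
    lookup = {s: i for i, s in enumerate(have)}
    missing = [s for s in want if s not in lookup]
    if missing:
        raise GenioError(f"samples not found: {missing[:5]}")
    return [lookup[s] for s in want]


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse 'chrom:start-end' (1-based inclusive)."""
    try:
        chrom, span = region.rsplit(":", 1)
        start, end = (int(x.replace(",", "")) for x in span.split("-"))
    except Exception:
        raise GenioError(f"malformed region {region!r}; expected chrom:start-end")
    if start < 1 or end < start:
        raise GenioError(f"invalid region bounds in {region!r}")
    return chrom, start, end


def _is_biallelic_snp(ref: str, alts: tuple) -> bool:
    if len(alts) != 1:
        return False
    alt = alts[0]
    return (
        len(ref) == 1
        and len(alt) == 1
        and ref in "ACGT"
        and alt in "ACGT"
    )


def load_vcf_region(
    path: str | os.PathLike,
    region: str | None = None,
    samples: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, HaplotypeMatrix | None]:
    """Load biallelic SNPs from a VCF region into dosage/haplotype matrices.

    Only biallelic SNP records are retained (indels, CNVs and multiallelic
    records are dropped). If every retained record is fully phased a
    HaplotypeMatrix is returned alongside the GenotypeMatrix; otherwise the
    second element is None. Region queries use the tabix index when present
    and fall back to streaming the whole file otherwise.
    """
    from cyvcf2 import VCF

    path = os.fspath(path)
    if not os.path.exists(path):
        raise GenioError(f"VCF not found: {path}")
    vcf = VCF(path, samples=list(samples) if samples is not None else None)
    file_samples = list(vcf.samples)
    if samples is not None:
        missing = set(samples) - set(file_samples)
        if missing:
            raise GenioError(f"samples not in VCF: {sorted(missing)[:5]}")
        # cyvcf2 keeps VCF order; remember how to reorder to the request
        reorder = _sample_indices(file_samples, samples)
        out_samples = list(samples)
    else:
        reorder = list(range(len(file_samples)))
        out_samples = file_samples

    indexed = os.path.exists(path + ".tbi") or os.path.exists(path + ".csi")
    if region is not None:
        chrom, start, end = parse_region(region)
        it = vcf(region) if indexed else iter(vcf)
    else:
        chrom = start = end = None
        it = iter(vcf)

    variants: list[VariantRecord] = []
    gt_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    all_phased = True
    for v in it:
        if region is not None and not indexed:
            if v.CHROM != chrom or not (start <= v.POS <= end):
                continue
        if v.is_indel or v.is_sv or not _is_biallelic_snp(v.REF, tuple(v.ALT)):
            continue
        anc = v.INFO.get("AA")
        if anc is not None:
            anc = str(anc).split("|")[0].strip().upper() or None
        variants.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                id=v.ID or f"{v.CHROM}:{v.POS}",
                ref=v.REF,
                alt=v.ALT[0],
                ancestral=anc,
            )
        )
        g = np.array(v.genotypes, dtype=object)  # rows: [a1, a2, phased] (diploid)
        alleles = np.array([row[:-1] for row in g], dtype=np.int16)
        if alleles.shape[1] != 2:
            raise GenioError(f"mixed or non-diploid ploidy at {v.CHROM}:{v.POS}")
        phased = np.array([row[-1] for row in g], dtype=bool)
        miss = (alleles < 0).any(axis=1)
        dos = alleles.clip(0).sum(axis=1).astype(np.int8)
        dos[miss] = MISSING
        gt_rows.append(dos)
        if all_phased and phased.all() and not miss.any():
            hap_rows.append(alleles.astype(np.uint8).reshape(-1))
        else:
            all_phased = False

    n = len(out_samples)
    if variants:
        dosage = np.stack(gt_rows, axis=1)[reorder]
    else:
        dosage = np.zeros((n, 0), dtype=np.int8)
    gm = GenotypeMatrix(out_samples, variants, dosage)
    hm = None
    if all_phased and variants:
        haps = np.stack(hap_rows, axis=1)  # (2n, m) in file sample order
        hap_reorder = np.array(
            [2 * i + k for i in reorder for k in (0, 1)], dtype=int
        )
        hm = HaplotypeMatrix(out_samples, variants, haps[hap_reorder])
    return gm, hm


def write_vcf(
    data: GenotypeMatrix | HaplotypeMatrix,
    path: str | os.PathLike,
    bgzip: bool = False,
) -> str:
    """Write a minimal well-formed VCF (phased when given haplotypes).

    With ``bgzip=True`` the file is bgzip-compressed and tabix-indexed via
    htslib; the returned path then carries the .gz suffix.
    """
    import pysam

    path = os.fspath(path)
    if isinstance(data, HaplotypeMatrix):
        samples, variants = data.samples, data.variants
        sep = "|"
        def cell(j, i):
            return f"{data.haplotypes[2 * i, j]}{sep}{data.haplotypes[2 * i + 1, j]}"
    else:
        samples, variants = data.samples, data.variants
        sep = "/"
        _CELL = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        def cell(j, i):
            return _CELL[int(data.dosage[i, j])]

    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    for c in dict.fromkeys(v.chrom for v in variants):
        buf.write(f"##contig=<ID={c}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(samples) + "\n")
    order = sorted(range(len(variants)), key=lambda j: (variants[j].chrom, variants[j].pos))
    for j in order:
        v = variants[j]
        info = f"AA={v.ancestral}" if v.ancestral else "."
        row = [v.chrom, str(v.pos), v.id, v.ref, v.alt, ".", "PASS", info, "GT"]
        row += [cell(j, i) for i in range(len(samples))]
        buf.write("\t".join(row) + "\n")

    plain = path[:-3] if path.endswith(".gz") else path
    with open(plain, "w") as fh:
        fh.write(buf.getvalue())
    if bgzip or path.endswith(".gz"):
        gz = plain + ".gz"
        pysam.tabix_compress(plain, gz, force=True)
        pysam.tabix_index(gz, preset="vcf", force=True)
        os.remove(plain)
        return gz
    return plain


def filter_variants(
    gm: GenotypeMatrix, maf_min: float = 0.05, max_missing: float = 0.10
) -> GenotypeMatrix:
    """Keep variants with MAF >= maf_min and missingness <= max_missing.

    MAF is min(p, 1-p) of the alternate-allele frequency computed on
    non-missing calls only. Idempotent.
    """
    if not 0 <= maf_min <= 0.5:
        raise GenioError("maf_min must be in [0, 0.5]")
    if not 0 <= max_missing <= 1:
        raise GenioError("max_missing must be in [0, 1]")
    maf = gm.maf()
    with np.errstate(invalid="ignore"):
        keep = (maf >= maf_min) & (gm.missing_fraction() <= max_missing)
    keep &= ~np.isnan(maf)
    if not keep.any():
        warnings.warn("all variants removed by filter", stacklevel=2)
    return gm.subset_variants(keep)


def polarize(hm: HaplotypeMatrix) -> HaplotypeMatrix:
    """Re-code haplotypes so allele 0 is ancestral, dropping non-polarizable sites.

    Sites whose ancestral annotation is neither ref nor alt (or absent) are
    excluded and counted in ``n_dropped_polarize``. Idempotent: a polarized
    matrix passes through unchanged.
    """
    if hm.polarized:
        return hm
    if all(v.ancestral is None for v in hm.variants):
        raise GenioError("no ancestral annotation at any site; cannot polarize")
    keep, flip = [], []
    for j, v in enumerate(hm.variants):
        if not v.polarizable:
            continue
        keep.append(j)
        flip.append(v.ancestral == v.alt)
    keep = np.array(keep, dtype=int)
    flip = np.array(flip, dtype=bool)
    haps = hm.haplotypes[:, keep].copy()
    haps[:, flip] ^= 1
    variants = []
    for j, do_flip in zip(keep, flip):
        v = hm.variants[j]
        if do_flip:
            # swap ref/alt so allele 0 (= ancestral) stays the REF allele
            variants.append(replace(v, ref=v.alt, alt=v.ref))
        else:
            variants.append(v)
    return HaplotypeMatrix(
        hm.samples,
        variants,
        haps,
        polarized=True,
        n_dropped_polarize=hm.n_variants - keep.size,
    )


def genotype_frequencies(
    gm: GenotypeMatrix,
    panel: SamplePanel,
    by: Sequence[str] = ("population",),
) -> pd.DataFrame:
    """Per-group genotype and allele frequencies (one row per variant x group).

    ``by`` may contain "population" and/or "sex". Groups with no samples are
    omitted. Frequencies are computed on non-missing calls; rows carry the
    genotype counts, genotype frequencies, alternate-allele frequency and N.
    """
    for key in by:
        if key not in ("population", "sex"):
            raise GenioError(f"cannot group by {key!r}")
    meta = panel.table.set_index("sample").loc[gm.samples]
    groups = meta.groupby(list(by), sort=True, observed=True).groups
    rows = []
    for gkey, sample_idx in groups.items():
        if not isinstance(gkey, tuple):
            gkey = (gkey,)
        idx = [gm.samples.index(s) for s in sample_idx]
        sub = gm.dosage[idx]
        for j, v in enumerate(gm.variants):
            d = sub[:, j]
            d = d[d != MISSING]
            n = d.size
            if n == 0:
                continue
            counts = np.bincount(d, minlength=3)
            row = {
                "chrom": v.chrom,
                "pos": v.pos,
                "id": v.id,
                **dict(zip(by, gkey)),
                "n": n,
                "n_hom_ref": int(counts[0]),
                "n_het": int(counts[1]),
                "n_hom_alt": int(counts[2]),
                "freq_hom_ref": counts[0] / n,
                "freq_het": counts[1] / n,
                "freq_hom_alt": counts[2] / n,
                "alt_allele_freq": (counts[1] + 2 * counts[2]) / (2 * n),
            }
            rows.append(row)
    return pd.DataFrame(rows)
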