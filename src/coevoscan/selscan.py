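"""Per-site F_ST, population branch statistics and the EHH/iHH/iHS scan.

F_ST uses the Weir & Cockerham (1984) per-site estimator on two populations
with genotype (heterozygosity-aware) data, matching the behaviour of the
standard per-site F_ST tools. PBS branches are built from pairwise F_ST via
T = -log(1 - F_ST); normalized branches use PBSn = PBS / (1 + sum of the
three branches) with branches floored at zero first. The haplotype scan
computes extended haplotype homozygosity (EHH) around each core SNP,
integrates it over genetic distance to iHH for ancestral and derived cores,
and standardizes ln(iHH_A / iHH_D) within derived-allele-frequency bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GeneticMap, GenotypeMatrix, HaplotypeMatrix, MISSING, SamplePanel, interpolate_cm

# F_ST >= 1 - 1e-12 would send T to infinity; cap the branch transform there.
T_MAX = -np.log(1e-12)


def _pop_stats(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant (n, p, het frequency) on non-missing diploid calls."""
    d = np.ma.masked_equal(dosage, MISSING)
    n = (~d.mask).sum(axis=0) if np.ma.is_masked(d) else np.full(d.shape[1], d.shape[0])
    n = np.asarray(n, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = np.asarray(d.mean(axis=0).filled(np.nan)) / 2.0
        h = np.asarray((d == 1).sum(axis=0)) / np.where(n > 0, n, np.nan)
    return n, p, h


def site_fst(
    gm: GenotypeMatrix, panel: SamplePanel, pop_a: str, pop_b: str
) -> pd.DataFrame:
    """Weir & Cockerham (1984) per-site F_ST between two populations.

    Complete-case per site and per population. Sites monomorphic for the
    same allele in both populations are undefined (NaN, ``defined`` False),
    not 0. Negative estimates are reported as-is; downstream branch
    transforms clamp them.
    """
    sub_a = gm.subset_samples(panel.samples_for(pop_a))
    sub_b = gm.subset_samples(panel.samples_for(pop_b))
    n1, p1, h1 = _pop_stats(sub_a.dosage)
    n2, p2, h2 = _pop_stats(sub_b.dosage)
    fst, defined = wc_fst_two_pop(n1, p1, h1, n2, p2, h2)
    return pd.DataFrame(
        {
            "chrom": gm.chroms,
            "pos": gm.positions,
            "id": gm.ids,
            "fst": fst,
            "defined": defined,
            "n_a": n1.astype(int),
            "n_b": n2.astype(int),
        }
    )


def _wc_components(n1, p1, h1, n2, p2, h2):
    """WC-1984 variance components (a, b, c) for r=2 populations."""
    n1, p1, h1, n2, p2, h2 = map(np.asarray, (n1, p1, h1, n2, p2, h2))
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    return a, b, c


def wc_fst_two_pop(n1, p1, h1, n2, p2, h2) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-site WC-1984 theta-hat for r=2 populations.

    Arguments are per-site sample sizes (diploid individuals), alternate
    allele frequencies and observed heterozygote frequencies.
    """
    a, b, c = _wc_components(n1, p1, h1, n2, p2, h2)
    n1, p1, h1, n2, p2, h2 = map(np.asarray, (n1, p1, h1, n2, p2, h2))
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        fst = np.where(denom != 0, a / denom, np.nan)
    usable = (n1 >= 2) & (n2 >= 2) & np.isfinite(p1) & np.isfinite(p2)
    # monomorphic for the same allele in both populations -> undefined
    poly = ~((p1 == p2) & np.isin(p1, (0.0, 1.0)) & (h1 == 0) & (h2 == 0))
    defined = usable & poly & np.isfinite(fst)
    return np.where(defined, fst, np.nan), defined


def genomewide_fst(
    gm: GenotypeMatrix, panel: SamplePanel, pop_a: str, pop_b: str
) -> float:
    """Multi-locus WC-1984 F_ST as the ratio of summed variance components.

    The ratio-of-averages combination (sum a / sum (a+b+c)) is the standard
    way to combine WC components across loci and is far less biased than
    averaging per-site ratios.
    """
    sub_a = gm.subset_samples(panel.samples_for(pop_a))
    sub_b = gm.subset_samples(panel.samples_for(pop_b))
    a, b, c = _wc_components(*_pop_stats(sub_a.dosage), *_pop_stats(sub_b.dosage))
    return float(np.nansum(a) / np.nansum(a + b + c))


def _branch_t(fst: np.ndarray) -> np.ndarray:
    """T = -log(1 - F_ST), with negatives clamped to 0 and T capped at T_MAX."""
    f = np.clip(np.asarray(fst, dtype=float), 0.0, 1.0 - 1e-12)
    return -np.log1p(-f)


def pbs(fst_ab, fst_ac, fst_bc) -> pd.DataFrame:
    """Raw PBS branch lengths for populations A, B, C from pairwise F_ST.

    PBS_A = (T_AB + T_AC - T_BC) / 2 and cyclic analogues. Sites where any
    pairwise F_ST is undefined (NaN) are undefined. Negative raw branches
    are reported.
    """
    t_ab, t_ac, t_bc = _branch_t(fst_ab), _branch_t(fst_ac), _branch_t(fst_bc)
    nan = np.isnan(np.asarray(fst_ab, float)) | np.isnan(np.asarray(fst_ac, float)) | np.isnan(
        np.asarray(fst_bc, float)
    )
    out = pd.DataFrame(
        {
            "pbs_a": (t_ab + t_ac - t_bc) / 2,
            "pbs_b": (t_ab + t_bc - t_ac) / 2,
            "pbs_c": (t_ac + t_bc - t_ab) / 2,
        }
    )
    out[nan] = np.nan
    out["defined"] = ~nan
    return out


def normalize_pbs(pbs_df: pd.DataFrame) -> pd.DataFrame:
    """Normalized branches PBSn_X = PBS_X / (1 + PBS_A + PBS_B + PBS_C).

    Branches are floored at 0 before normalization, which shrinks positions
    with large branches in all three populations.
    """
    floored = pbs_df[["pbs_a", "pbs_b", "pbs_c"]].clip(lower=0)
    denom = 1.0 + floored.sum(axis=1)
    out = pbs_df.copy()
    for col in ("pbs_a", "pbs_b", "pbs_c"):
        out[col + "_norm"] = floored[col] / denom
    return out


def empirical_threshold(values, q: float = 0.95) -> tuple[float, np.ndarray]:
    """Genome-wide empirical threshold and per-site empirical p-values.

    threshold is the q-th percentile under the linear-interpolation
    convention (numpy default); the per-site empirical p of a value v is the
    fraction of genome-wide values >= v. NaNs are excluded from the
    reference distribution; their p is NaN.
    """
    values = np.asarray(values, dtype=float)
    ref = values[~np.isnan(values)]
    if ref.size == 0:
        raise ValueError("empirical_threshold: no defined values")
    threshold = float(np.quantile(ref, q, method="linear"))
    order = np.sort(ref)
    # count of ref >= v  ==  N - searchsorted_left(v)
    emp_p = np.full(values.shape, np.nan)
    ok = ~np.isnan(values)
    emp_p[ok] = (ref.size - np.searchsorted(order, values[ok], side="left")) / ref.size
    return threshold, emp_p


# ---------------------------------------------------------------------------
# EHH / iHH / iHS


def ehh_curve(
    hm: HaplotypeMatrix, core_index: int, core_allele: int
) -> tuple[np.ndarray, np.ndarray]:
    """EHH at every variant for haplotypes carrying ``core_allele`` at the core.

    EHH(x) = sum_h C(n_h, 2) / C(n_core, 2) over haplotype classes h defined
    by identity on all variants between the core and x (inclusive). Returns
    (variant indices 0..m-1, EHH values); EHH(core) = 1 and the curve is
    non-increasing away from the core. Requires >= 2 core haplotypes.
    """
    carriers = hm.haplotypes[:, core_index] == core_allele
    n = int(carriers.sum())
    if n < 2:
        raise ValueError("fewer than 2 haplotypes carry the core allele")
    sub = hm.haplotypes[carriers]
    m = hm.n_variants
    ehh = np.empty(m)
    ehh[core_index] = 1.0
    denom = n * (n - 1) / 2
    for direction in (1, -1):
        labels = np.zeros(n, dtype=np.int64)
        j = core_index + direction
        while 0 <= j < m:
            labels = _refine(labels, sub[:, j])
            counts = np.bincount(labels)
            ehh[j] = (counts * (counts - 1)).sum() / 2 / denom
            j += direction
    return np.arange(m), ehh


def _refine(labels: np.ndarray, column: np.ndarray) -> np.ndarray:
    """Split haplotype-identity classes by the alleles in one more column."""
    _, new = np.unique(labels * 2 + column, return_inverse=True)
    return new


def integrate_ihh(
    cm: np.ndarray,
    ehh: np.ndarray,
    cutoff: float = 0.05,
) -> tuple[float, bool]:
    """Trapezoidal area under one outward EHH arm over genetic distance.

    ``cm`` and ``ehh`` run from the core (ehh[0] must be 1) outward in one
    direction. Integration stops where EHH first drops below ``cutoff``,
    linearly interpolating the crossing point; if the cutoff is never
    reached before the data end, the area is truncated there and the
    boundary flag is set.
    """
    cm = np.abs(np.asarray(cm, dtype=float) - float(cm[0]))
    ehh = np.asarray(ehh, dtype=float)
    if ehh[0] != 1.0:
        raise ValueError("EHH arm must start at 1 at the core")
    area = 0.0
    for k in range(1, ehh.size):
        e0, e1 = ehh[k - 1], ehh[k]
        x0, x1 = cm[k - 1], cm[k]
        if e1 < cutoff:
            # interpolate crossing where ehh == cutoff
            frac = (e0 - cutoff) / (e0 - e1) if e0 != e1 else 0.0
            xc = x0 + frac * (x1 - x0)
            area += 0.5 * (e0 + cutoff) * (xc - x0)
            return area, False
        area += 0.5 * (e0 + e1) * (x1 - x0)
        if e1 == 0.0:  # fully decayed: nothing left to truncate
            return area, False
    return area, True


def _ihh_one_side(
    sub: np.ndarray,
    cm: np.ndarray,
    pos: np.ndarray,
    core: int,
    direction: int,
    cutoff: float,
    max_gap_bp: int,
    block: int = 256,
) -> tuple[float, bool]:
    """iHH for one allele class on one side of the core.

    Equivalent to ehh_curve + integrate_ihh but stops early at the cutoff, a
    large physical gap, or the data end (the latter two set the boundary
    flag). EHH only changes at columns that split a haplotype class, so the
    arm scans ahead in vectorized blocks for the next splitting column and
    adds constant-EHH rectangles in between; haplotypes in singleton classes
    are pruned (they can never rejoin a class).
    """
    n, m = sub.shape
    denom = n * (n - 1) / 2
    order = np.arange(n)  # active haplotypes grouped by class
    sizes = np.array([n])
    area = 0.0
    e_prev = 1.0
    j = core
    boundary_gap = False
    blk = 8  # adaptive: grows while no split is found, shrinks near splits
    while True:
        if direction == 1:
            nxt = np.arange(j + 1, min(m, j + 1 + blk))
        else:
            nxt = np.arange(j - 1, max(-1, j - 1 - blk), -1)
        if nxt.size == 0:
            return area, True
        # physical gap rule: stop before the first step spanning > max_gap_bp
        prev_pos = np.concatenate([[pos[j]], pos[nxt[:-1]]])
        bad = np.abs(pos[nxt] - prev_pos) > max_gap_bp
        if bad.any():
            cutpt = int(np.argmax(bad))
            nxt = nxt[:cutpt]
            boundary_gap = True
            if nxt.size == 0:
                return area, True
        starts = np.concatenate([[0], np.cumsum(sizes[:-1])])
        seg = sub[np.ix_(order, nxt)]
        csum = np.add.reduceat(seg, starts, axis=0)
        mixed = (csum > 0) & (csum < sizes[:, None])
        anysplit = mixed.any(axis=0)
        if not anysplit.any():
            area += e_prev * abs(cm[nxt[-1]] - cm[j])
            j = nxt[-1]
            if boundary_gap or (direction == 1 and j == m - 1) or (
                direction == -1 and j == 0
            ):
                return area, True
            blk = min(blk * 2, block)
            continue
        t = int(np.argmax(anysplit))
        blk = int(np.clip(2 * (t + 1), 8, block))
        if t > 0:
            area += e_prev * abs(cm[nxt[t - 1]] - cm[j])
            j = nxt[t - 1]
        jn = nxt[t]
        # split classes by the allele at jn (stable within-class ordering)
        labels = np.repeat(np.arange(sizes.size), sizes)
        key = labels * 2 + sub[order, jn]
        perm = np.argsort(key, kind="stable")
        order = order[perm]
        sizes = np.bincount(key)
        sizes = sizes[sizes > 0]
        e = float((sizes * (sizes - 1)).sum() / 2) / denom
        dx = abs(cm[jn] - cm[j])
        if e < cutoff:
            frac = (e_prev - cutoff) / (e_prev - e) if e_prev != e else 0.0
            area += 0.5 * (e_prev + cutoff) * dx * frac
            return area, False
        area += 0.5 * (e_prev + e) * dx
        if e == 0.0:
            return area, False
        # prune singleton classes
        if (sizes == 1).any():
            keep_cls = sizes >= 2
            member_keep = np.repeat(keep_cls, sizes)
            order = order[member_keep]
            sizes = sizes[keep_cls]
            if sizes.size == 0:
                return area, False
        e_prev = e
        j = jn


def ihs_scan(
    hm: HaplotypeMatrix,
    gmap: GeneticMap,
    maf_min: float = 0.05,
    cutoff: float = 0.05,
    n_bins: int = 50,
    max_gap_bp: int = 200_000,
) -> pd.DataFrame:
    """iHS for every variant with derived-allele frequency in [maf_min, 1-maf_min].

    unstandardized iHS = ln(iHH_ancestral / iHH_derived); standardization
    subtracts the mean and divides by the SD within ``n_bins`` equal-width
    derived-allele-frequency bins, so standardized values are comparable
    across frequencies. Bins with < 2 variants are left unstandardized and
    flagged. |iHS| > 2 is the conventional genome-wide significance level.
    """
    if not hm.polarized:
        raise ValueError("ihs_scan requires polarized haplotypes")
    daf = hm.derived_allele_freq()
    pos = hm.positions
    cm = interpolate_cm(gmap, pos)
    rows = []
    for j in range(hm.n_variants):
        if not (maf_min <= daf[j] <= 1 - maf_min):
            continue
        anc = hm.haplotypes[:, j] == 0
        der = ~anc
        if anc.sum() < 2 or der.sum() < 2:
            continue
        vals = {}
        boundary = False
        for name, mask in (("ihh_a", anc), ("ihh_d", der)):
            sub = hm.haplotypes[mask]
            left, bl = _ihh_one_side(sub, cm, pos, j, -1, cutoff, max_gap_bp)
            right, br = _ihh_one_side(sub, cm, pos, j, +1, cutoff, max_gap_bp)
            vals[name] = left + right
            boundary |= bl or br
        if vals["ihh_a"] <= 0 or vals["ihh_d"] <= 0:
            continue
        rows.append(
            {
                "chrom": hm.variants[j].chrom,
                "pos": int(pos[j]),
                "id": hm.variants[j].id,
                "daf": daf[j],
                "ihh_a": vals["ihh_a"],
                "ihh_d": vals["ihh_d"],
                "uihs": np.log(vals["ihh_a"] / vals["ihh_d"]),
                "boundary": boundary,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["ihs"] = df["bin"] = df["standardized"] = []
        return df
    df = standardize_ihs(df, maf_min=maf_min, n_bins=n_bins)
    return df.reset_index(drop=True)


def standardize_ihs(
    df: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    maf_min: float = 0.05,
    n_bins: int = 50,
) -> pd.DataFrame:
    """Standardize unstandardized iHS within derived-allele-frequency bins.

    With ``reference`` given, bin means and SDs come from the reference
    scan's ``uihs`` values (e.g. a neutral genome-wide panel) instead of the
    target's own — the usual way a candidate region is scored against a
    genome-wide empirical distribution. Bins with < 2 reference variants
    leave their targets unstandardized (flag False).
    """
    df = df.copy()
    ref = df if reference is None else reference
    edges = np.linspace(maf_min, 1 - maf_min, n_bins + 1)

    def _bins(frame):
        return np.clip(np.digitize(frame["daf"], edges) - 1, 0, n_bins - 1)

    df["bin"] = _bins(df)
    ref_bins = _bins(ref)
    df["ihs"] = df["uihs"]
    df["standardized"] = False
    for b in np.unique(df["bin"]):
        rb = ref["uihs"].to_numpy()[ref_bins == b]
        if rb.size >= 2 and rb.std(ddof=1) > 0:
            sel = df["bin"] == b
            df.loc[sel, "ihs"] = (df.loc[sel, "uihs"] - rb.mean()) / rb.std(ddof=1)
            df.loc[sel, "standardized"] = True
    return df
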