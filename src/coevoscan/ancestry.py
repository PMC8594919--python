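"""Downstream summaries of local-ancestry (RFMix-style) output.

Consumes per-interval, per-haplotype ancestry calls in the RFMix v2
``.msp.tsv`` dialect: a first comment line declaring the subpopulation
codes, a header line ``#chm spos epos sgpos egpos n snps <sample>.0
<sample>.1 ...`` and one row per interval with integer ancestry codes. The
module computes cM-weighted genome-wide ancestry proportions per sample,
rank tests for ancestry differences between genotype classes, and local
ancestry enrichment against the genome-wide 95th-percentile.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GeneticMap


class AncestryError(ValueError):
    pass


@dataclass
class LocalAncestryTrack:
    """Per-haplotype ancestry intervals for a cohort.

    ``intervals`` columns: chrom, spos, epos (bp, half-open), sgpos, egpos
    (cM); ``calls`` is (n_intervals, 2 * n_samples) of integer codes into
    ``labels``; haplotype columns (2i, 2i+1) belong to ``samples[i]``.
    """

    labels: list[str]
    samples: list[str]
    intervals: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.intervals), 2 * len(self.samples)):
            raise AncestryError("calls shape inconsistent with intervals/samples")
        if self.calls.size and (self.calls.min() < 0 or self.calls.max() >= len(self.labels)):
            raise AncestryError("ancestry code outside declared label set")
        for chrom, g in self.intervals.groupby("chrom", sort=False):
            g = g.sort_values("spos")
            if (g["epos"] <= g["spos"]).any():
                raise AncestryError(f"empty/inverted interval on {chrom}")
            overlap = g["spos"].to_numpy()[1:] < g["epos"].to_numpy()[:-1]
            if overlap.any():
                k = int(np.flatnonzero(overlap)[0])
                raise AncestryError(
                    f"overlapping intervals on {chrom} near bp {int(g['spos'].iloc[k + 1])}"
                )

    @property
    def cm_lengths(self) -> np.ndarray:
        return (self.intervals["egpos"] - self.intervals["sgpos"]).to_numpy(float)


def load_local_ancestry(path: str | os.PathLike) -> LocalAncestryTrack:
    """Parse an RFMix v2 msp.tsv-style file into a LocalAncestryTrack."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#Subpopulation order/codes:"):
            raise AncestryError("missing subpopulation code line")
        codes = {}
        for tok in first.split(":", 1)[1].strip().split():
            name, _, num = tok.partition("=")
            if not num.isdigit():
                raise AncestryError(f"malformed ancestry code {tok!r}")
            codes[int(num)] = name
        labels = [codes[k] for k in sorted(codes)]
        if sorted(codes) != list(range(len(codes))):
            raise AncestryError("ancestry codes must be 0..K-1")
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        body = pd.read_csv(fh, sep="\t", header=None, names=header)
    hap_cols = header[6:]
    samples = []
    for c in hap_cols[::2]:
        if not c.endswith(".0"):
            raise AncestryError(f"unexpected haplotype column {c!r}")
        samples.append(c[:-2])
    expected = [f"{s}.{k}" for s in samples for k in (0, 1)]
    if hap_cols != expected:
        raise AncestryError("haplotype columns must come in sample.0/sample.1 pairs")
    intervals = body[header[:5]].copy()
    intervals.columns = ["chrom", "spos", "epos", "sgpos", "egpos"]
    intervals["chrom"] = intervals["chrom"].astype(str)
    return LocalAncestryTrack(
        labels=labels,
        samples=samples,
        intervals=intervals,
        calls=body[hap_cols].to_numpy(),
    )


def write_local_ancestry(track: LocalAncestryTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        codes = " ".join(f"{name}={k}" for k, name in enumerate(track.labels))
        fh.write(f"#Subpopulation order/codes: {codes}\n")
        cols = ["chm", "spos", "epos", "sgpos", "egpos", "n snps"] + [
            f"{s}.{k}" for s in track.samples for k in (0, 1)
        ]
        fh.write("#" + "\t".join(cols) + "\n")
        iv = track.intervals
        for r in range(len(iv)):
            row = [
                str(iv["chrom"].iloc[r]),
                str(int(iv["spos"].iloc[r])),
                str(int(iv["epos"].iloc[r])),
                f"{iv['sgpos'].iloc[r]:.6f}",
                f"{iv['egpos'].iloc[r]:.6f}",
                "1",
            ] + [str(int(c)) for c in track.calls[r]]
            fh.write("\t".join(row) + "\n")


def genomewide_proportion(
    track: LocalAncestryTrack, maps: dict[str, GeneticMap] | None = None
) -> pd.DataFrame:
    """cM-weighted genome-wide ancestry proportion per sample.

    Within each chromosome, a sample's proportion of an ancestry is the
    fraction of haplotype-cM assigned to it (each haplotype contributes half
    the sample's weight); genome-wide values average the per-chromosome
    proportions with weights proportional to chromosome cM length. When
    ``maps`` is given, chromosome lengths come from the maps (every track
    chromosome must be present); otherwise the track's own genetic positions
    are used. Rows sum to 1.
    """
    n_samples, n_lab = len(track.samples), len(track.labels)
    chrom_props = {}
    chrom_weights = {}
    for chrom, g in track.intervals.groupby("chrom", sort=False):
        idx = g.index.to_numpy()
        lengths = (g["egpos"] - g["sgpos"]).to_numpy(float)
        if maps is not None:
            if chrom not in maps:
                raise AncestryError(f"chromosome {chrom} missing from map set")
            total = maps[chrom].length_cm
        else:
            total = float(g["egpos"].max() - g["sgpos"].min())
        hap_cm = np.zeros((2 * n_samples, n_lab))
        calls = track.calls[idx]
        for k in range(n_lab):
            hap_cm[:, k] = (lengths[:, None] * (calls == k)).sum(axis=0)
        samp_cm = hap_cm[0::2] + hap_cm[1::2]
        covered = samp_cm.sum(axis=1, keepdims=True)
        chrom_props[chrom] = samp_cm / covered
        chrom_weights[chrom] = total
    w = np.array([chrom_weights[c] for c in chrom_props])
    w = w / w.sum()
    stacked = np.stack([chrom_props[c] for c in chrom_props])  # (n_chrom, n, K)
    props = np.tensordot(w, stacked, axes=(0, 0))
    return pd.DataFrame(props, index=track.samples, columns=track.labels)


def ancestry_genotype_test(
    proportions: pd.Series | np.ndarray, in_focal_class: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: ancestry proportion, focal class vs rest.

    Exact null distribution for small untied samples (both groups <= 25),
    normal approximation with tie correction otherwise. Returns (U, p).
    """
    proportions = np.asarray(proportions, dtype=float)
    in_focal_class = np.asarray(in_focal_class, dtype=bool)
    a = proportions[in_focal_class]
    b = proportions[~in_focal_class]
    if a.size == 0 or b.size == 0:
        raise AncestryError("both genotype groups must be non-empty")
    has_ties = np.unique(proportions).size < proportions.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EnrichmentResult:
    region_attribution: float
    threshold_95: float
    enriched: bool
    interval_attributions: pd.DataFrame  # chrom, spos, epos, attribution


def local_enrichment(
    track: LocalAncestryTrack,
    region: tuple[str, int, int],
    ancestry_label: str,
    q: float = 0.95,
) -> EnrichmentResult:
    """Flag a region whose cohort-level ancestry attribution is in the top 5%.

    The per-interval attribution is the fraction of haplotypes assigned to
    ``ancestry_label`` in that interval, computed genome-wide; the region is
    enriched iff the (cM-weighted) attribution over intervals it overlaps
    exceeds the genome-wide q-th percentile of interval attributions.
    """
    if ancestry_label not in track.labels:
        raise AncestryError(f"unknown ancestry label {ancestry_label!r}")
    k = track.labels.index(ancestry_label)
    attr = (track.calls == k).mean(axis=1)
    iv = track.intervals
    table = iv[["chrom", "spos", "epos"]].copy()
    table["attribution"] = attr
    chrom, start, end = region
    mask = (iv["chrom"] == str(chrom)) & (iv["epos"] > start) & (iv["spos"] < end)
    if not mask.any():
        raise AncestryError(f"region {region} outside track coverage")
    w = (iv.loc[mask, "egpos"] - iv.loc[mask, "sgpos"]).to_numpy(float)
    if w.sum() == 0:
        w = np.ones_like(w)
    region_attr = float(np.average(attr[mask.to_numpy()], weights=w))
    threshold = float(np.quantile(attr, q, method="linear"))
    return EnrichmentResult(
        region_attribution=region_attr,
        threshold_95=threshold,
        enriched=region_attr > threshold,
        interval_attributions=table,
    )
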