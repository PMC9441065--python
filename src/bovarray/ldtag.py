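"""Pairwise LD, windowed array tagging and LD decay.

r² between two sites is computed on phased haplotypes by direct haplotype
counting: with alternate-allele frequencies pA, pB and haplotype frequency
pAB, D = pAB - pA*pB and r² = D² / (pA(1-pA) pB(1-pB)). This equals the
squared Pearson correlation of the two haplotype allele vectors. A composite
(genotype-dosage correlation) mode is provided for unphased inputs.

A whole-genome variant is *tagged* by an array if some array site within a
±window (default 500 kb, PLINK-style pair window) has r² strictly above the
threshold (default 0.8) with it; array sites themselves count as tagged
(r² = 1 with self). Tagging proportions are reported both including and
excluding the array sites from numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vcfio import ArrayManifest, HaplotypePanel, VariantTable, intersect_sites


@dataclass
class LDResult:
    """One site pair's LD record. ``defined`` is False for monomorphic sites."""

    i: int
    j: int
    pA: float
    pB: float
    pAB: float
    D: float
    r2: float
    distance_bp: int
    defined: bool


def pairwise_r2(panel: HaplotypePanel, i: int, j: int,
                positions: np.ndarray | None = None) -> LDResult:
    """Exact haplotype-counting r² between sites i and j of a phased panel."""
    x = panel.alleles[i].astype(float)
    y = panel.alleles[j].astype(float)
    pA = x.mean()
    pB = y.mean()
    pAB = (x * y).mean()
    D = pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    defined = denom > 0
    r2 = (D * D / denom) if defined else np.nan
    dist = int(abs(positions[i] - positions[j])) if positions is not None else 0
    return LDResult(i, j, pA, pB, pAB, D, r2, dist, defined)


def genotype_r2(dosages: np.ndarray, i: int, j: int) -> float:
    """Composite LD: squared Pearson correlation of diploid dosages (unphased
    inputs; mirrors PLINK's genotype-correlation r² on unphased data)."""
    x = dosages[i].astype(float)
    y = dosages[j].astype(float)
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def _r2_one_vs_block(x: np.ndarray, block: np.ndarray) -> np.ndarray:
    """r² of haplotype vector x (H,) against rows of block (S, H)."""
    H = x.shape[0]
    pA = x.mean()
    pB = block.mean(axis=1)
    pAB = block @ x / H
    D = pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, D * D / denom, np.nan)
    return r2


@dataclass
class TaggingSummary:
    """Per-variant best-tag results plus aggregate proportions.

    ``per_site`` has one row per polymorphic panel variant: position, MAF,
    best r² to any array site in the window, tagged flag, is_array flag and
    any strata columns. Proportions are reported with array sites included
    (tagged by definition) and excluded.
    """

    per_site: pd.DataFrame
    proportion_tagged: float
    proportion_tagged_excl_array: float
    window_bp: int
    r2_threshold: float

    def by(self, columns) -> pd.DataFrame:
        g = self.per_site.groupby(columns, observed=True)["tagged"]
        out = g.agg(["mean", "size"]).rename(
            columns={"mean": "proportion_tagged", "size": "n_sites"}
        )
        return out.reset_index()


def tagging_summary(
    panel: HaplotypePanel,
    site_table: VariantTable,
    manifest: ArrayManifest | np.ndarray,
    window_bp: int = 500_000,
    r2_threshold: float = 0.8,
    strata: pd.DataFrame | None = None,
) -> TaggingSummary:
    """Best r² of every polymorphic panel variant against array sites in a
    ±window, and the proportion tagged (best r² strictly above threshold).

    ``manifest`` may be an ArrayManifest (matched to the panel on chrom/pos)
    or a boolean/index array over panel sites. Sites monomorphic in the
    evaluated haplotypes are excluded from the evaluation set.
    """
    if len(site_table) != panel.n_sites:
        raise ValueError("site table and panel disagree on site count")
    if isinstance(manifest, ArrayManifest):
        ia, _ = intersect_sites(site_table, manifest)
        array_idx = ia
    else:
        manifest = np.asarray(manifest)
        array_idx = np.flatnonzero(manifest) if manifest.dtype == bool else manifest

    pos = site_table.pos
    chrom = site_table.chrom
    X = panel.alleles
    freq = X.mean(axis=1)
    poly = (freq > 0) & (freq < 1)

    best = np.full(panel.n_sites, np.nan)
    is_array = np.zeros(panel.n_sites, dtype=bool)
    is_array[array_idx] = True
    best[is_array & poly] = 1.0

    array_poly = np.asarray([a for a in array_idx if poly[a]], dtype=np.int64)
    # per-chromosome windows: positions are sorted within each chromosome
    for c in pd.unique(chrom):
        cmask = chrom == c
        cidx = np.flatnonzero(cmask)
        cpos = pos[cidx]
        for a in array_poly[cmask[array_poly]]:
            lo = np.searchsorted(cpos, pos[a] - window_bp, side="left")
            hi = np.searchsorted(cpos, pos[a] + window_bp, side="right")
            block = cidx[lo:hi]
            r2 = _r2_one_vs_block(X[a].astype(float), X[block].astype(float))
            cur = best[block]
            best[block] = np.where(np.isnan(r2), cur, np.fmax(cur, r2))

    eval_mask = poly
    df = pd.DataFrame(
        {
            "chrom": chrom[eval_mask],
            "pos": pos[eval_mask],
            "maf": np.minimum(freq, 1 - freq)[eval_mask],
            "best_r2": best[eval_mask],
            "is_array": is_array[eval_mask],
        }
    )
    df["tagged"] = df["is_array"] | (df["best_r2"] > r2_threshold)
    if strata is not None:
        for col in strata.columns:
            df[col] = np.asarray(strata[col])[eval_mask]
    prop = float(df["tagged"].mean()) if len(df) else np.nan
    non_array = df[~df["is_array"]]
    prop_excl = float(non_array["tagged"].mean()) if len(non_array) else np.nan
    return TaggingSummary(df, prop, prop_excl, window_bp, r2_threshold)


def ld_decay(
    panel: HaplotypePanel,
    positions: np.ndarray,
    distance_bins: np.ndarray,
    max_sites: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean r² per distance bin over all site pairs within the last bin edge.

    Positions are assumed to come from a single chromosome (callers split
    multi-chromosome panels first).
    ``distance_bins`` are ascending bp edges; pair (i, j) lands in the bin
    containing |pos_i - pos_j|. Monomorphic (undefined) pairs are excluded.
    ``max_sites`` subsamples sites to bound the pair count. Empty bins get
    NaN with count 0.
    """
    edges = np.asarray(distance_bins, dtype=float)
    if edges.ndim != 1 or len(edges) < 2:
        raise ValueError("need at least two bin edges")
    idx = np.arange(panel.n_sites)
    freq = panel.alleles.mean(axis=1)
    idx = idx[(freq > 0) & (freq < 1)]
    if max_sites is not None and len(idx) > max_sites:
        rng = rng or np.random.default_rng(0)
        idx = np.sort(rng.choice(idx, size=max_sites, replace=False))
    if len(idx) < 2:
        raise ValueError("need >= 2 polymorphic sites")
    pos = np.asarray(positions)[idx]
    X = panel.alleles[idx].astype(float)
    max_dist = edges[-1]

    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for k in range(len(idx) - 1):
        hi = np.searchsorted(pos, pos[k] + max_dist, side="right")
        if hi <= k + 1:
            continue
        block = slice(k + 1, hi)
        r2 = _r2_one_vs_block(X[k], X[block])
        d = pos[block] - pos[k]
        ok = ~np.isnan(r2)
        which = np.digitize(d[ok], edges) - 1
        valid = (which >= 0) & (which < len(edges) - 1)
        np.add.at(sums, which[valid], r2[ok][valid])
        np.add.at(counts, which[valid], 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "mean_r2": mean,
            "n_pairs": counts,
        }
    )
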