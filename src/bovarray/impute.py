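"""Li–Stephens HMM imputation with leave-one-out dosages and accuracy metrics.

Each target haplotype is modelled as an imperfect mosaic of the K reference
haplotypes. The hidden state at site m is the template being copied;
templates switch between adjacent sites with probability

    s_m = 1 - exp(-rho_scale * d_m / K)

for an inter-site gap of d_m bp (uniform choice of the new template,
including the current one), and the observed allele matches the template
with probability 1 - eps. Emissions apply only at the target's typed sites;
the posterior copying probabilities at every reference site are obtained by
a scaled forward–backward pass in O(K * M), and the posterior alternate
allele probability is the template-posterior-weighted panel allele.

Diploid dosage is the sum of the two haplotype posteriors. The leave-one-out
(LOO) dosage at a typed site is the dosage recomputed with that site's own
emission hidden — the quantity behind the empirical R² (ER²) accuracy
statistic. Because hiding one emission leaves the forward messages before
the site and the backward messages after it unchanged, the LOO posterior can
be read off the shared forward/backward arrays; a naive re-run per site is
kept as the definitional cross-check.

Accuracy statistics follow the standard masked-imputation conventions:
ER² per typed site is the squared Pearson correlation across samples between
the true genotype (0/1/2) and the LOO dosage; dosage R² per untyped site is
the squared correlation between true genotype and imputed dosage. Sites with
zero variance in either vector are flagged undefined and excluded from
aggregates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vcfio import (
    GenotypeMatrix,
    HaplotypePanel,
    MISSING,
    VariantTable,
    intersect_sites,
)

logger = logging.getLogger(__name__)


@dataclass
class LiStephensParams:
    """Copying-model parameters.

    eps — per-site emission mismatch probability, in (0, 0.5);
    rho_scale — population-scaled recombination factor (default 4e-8 * Ne
    with Ne = 100): switch probability 1 - exp(-rho_scale * d / K) per gap;
    min_switch — floor on the per-gap switch probability.
    """

    eps: float = 1e-3
    rho_scale: float = 4e-6
    min_switch: float = 1e-8

    def __post_init__(self):
        if not (0.0 < self.eps < 0.5):
            raise ValueError("eps must be in (0, 0.5)")
        if self.rho_scale <= 0:
            raise ValueError("rho_scale must be > 0")

    def switch_probabilities(self, positions: np.ndarray, K: int) -> np.ndarray:
        gaps = np.diff(np.asarray(positions, dtype=float))
        s = 1.0 - np.exp(-self.rho_scale * gaps / K)
        return np.clip(s, self.min_switch, 1.0 - 1e-12)


@dataclass
class ImputationResult:
    """Posterior dosages over the full reference grid.

    ``dosages`` is sites x samples in [0, 2]; ``loo_dosages`` holds
    leave-one-out dosages at typed sites (NaN elsewhere); ``typed_mask``
    marks the sites at which the targets carried emissions.
    """

    dosages: np.ndarray
    loo_dosages: np.ndarray
    typed_mask: np.ndarray
    samples: list[str]
    params: LiStephensParams
    provenance: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[0]


# ---------------------------------------------------------------------------
# Core forward–backward engine


def _emission(ref_alleles: np.ndarray, obs: np.ndarray, eps: float) -> np.ndarray:
    """(K, H) emission factors at one typed site."""
    match = ref_alleles[:, None] == obs[None, :]
    return np.where(match, 1.0 - eps, eps)


def _fb_engine(
    ref: np.ndarray,
    typed_idx: np.ndarray,
    obs: np.ndarray,
    positions: np.ndarray,
    params: LiStephensParams,
    want_loo: bool = True,
):
    """Scaled forward–backward for H target haplotypes sharing a typed grid.

    ref: (M, K) panel alleles; obs: (T, H) observed alleles at typed sites.
    Returns (allele posterior (M, H), loo posterior (T, H) or None).
    """
    M, K = ref.shape
    T, H = obs.shape
    if T and (typed_idx.min() < 0 or typed_idx.max() >= M):
        raise ValueError("typed indices outside the reference grid")
    if T == 0:
        logger.warning("target typed at zero sites: returning prior-only posteriors")
        freq = ref.mean(axis=1, dtype=float)
        return np.repeat(freq[:, None], H, axis=1), None
    s = params.switch_probabilities(positions, K)
    eps = params.eps
    is_typed = np.zeros(M, dtype=bool)
    is_typed[typed_idx] = True
    typed_rank = np.cumsum(is_typed) - 1  # site -> row of obs where typed

    reff = ref.astype(np.float64)
    fwd = np.empty((M, K, H))
    scale = np.empty((M, H))
    f = np.full((K, H), 1.0 / K)
    if is_typed[0]:
        f = f * _emission(ref[0], obs[0], eps)
    c = f.sum(axis=0)
    f = f / c
    fwd[0] = f
    scale[0] = c
    for m in range(1, M):
        sm = s[m - 1]
        f = (1.0 - sm) * f + (sm / K) * f.sum(axis=0)
        if is_typed[m]:
            f = f * _emission(ref[m], obs[typed_rank[m]], eps)
        c = f.sum(axis=0)
        f = f / c
        fwd[m] = f
        scale[m] = c

    post = np.empty((M, H))
    loo = np.empty((T, H)) if want_loo else None
    b = np.ones((K, H))

    def emit_posterior(m, bm):
        g = fwd[m] * bm
        g_sum = g.sum(axis=0)
        return (reff[m][:, None] * g).sum(axis=0) / g_sum

    def loo_posterior(m, bm):
        if m == 0:
            pred = np.full((K, H), 1.0 / K)
        else:
            fp = fwd[m - 1]
            sm = s[m - 1]
            pred = (1.0 - sm) * fp + (sm / K) * fp.sum(axis=0)
        g = pred * bm
        g_sum = g.sum(axis=0)
        return (reff[m][:, None] * g).sum(axis=0) / g_sum

    post[M - 1] = emit_posterior(M - 1, b)
    if want_loo and is_typed[M - 1]:
        loo[typed_rank[M - 1]] = loo_posterior(M - 1, b)
    for m in range(M - 2, -1, -1):
        nb = b
        if is_typed[m + 1]:
            nb = nb * _emission(ref[m + 1], obs[typed_rank[m + 1]], eps)
        sm = s[m]
        b = ((1.0 - sm) * nb + (sm / K) * nb.sum(axis=0)) / scale[m + 1]
        post[m] = emit_posterior(m, b)
        if want_loo and is_typed[m]:
            loo[typed_rank[m]] = loo_posterior(m, b)
    return post, loo


def impute_haplotype(
    target_alleles: np.ndarray,
    typed_idx: np.ndarray,
    reference: np.ndarray,
    positions: np.ndarray,
    params: LiStephensParams,
    mask_emission_at: int | None = None,
) -> np.ndarray:
    """Posterior allele-1 probability over all reference sites for one target.

    ``target_alleles`` are the observed alleles at ``typed_idx`` (indices
    into the reference site grid). ``mask_emission_at`` hides a single typed
    site's emission — the naive leave-one-out definition.
    """
    typed_idx = np.asarray(typed_idx, dtype=np.int64)
    obs = np.asarray(target_alleles, dtype=np.uint8)
    if mask_emission_at is not None:
        keep = typed_idx != mask_emission_at
        typed_idx = typed_idx[keep]
        obs = obs[keep]
    post, _ = _fb_engine(
        np.asarray(reference), typed_idx, obs[:, None], np.asarray(positions), params,
        want_loo=False,
    )
    return post[:, 0]


def template_posteriors(
    target_alleles: np.ndarray,
    typed_idx: np.ndarray,
    reference: np.ndarray,
    positions: np.ndarray,
    params: LiStephensParams,
) -> np.ndarray:
    """Full (M, K) template posterior matrix for one target haplotype.

    Small-scale variant kept for exact comparison against path enumeration;
    posteriors are normalized per site.
    """
    ref = np.asarray(reference)
    M, K = ref.shape
    typed_idx = np.asarray(typed_idx, dtype=np.int64)
    obs = np.asarray(target_alleles, dtype=np.uint8)[:, None]
    s = params.switch_probabilities(positions, K)
    eps = params.eps
    is_typed = np.zeros(M, dtype=bool)
    is_typed[typed_idx] = True
    typed_rank = np.cumsum(is_typed) - 1

    fwd = np.empty((M, K))
    scale = np.empty(M)
    f = np.full(K, 1.0 / K)
    if is_typed[0]:
        f = f * _emission(ref[0], obs[0], eps)[:, 0]
    scale[0] = f.sum()
    fwd[0] = f / scale[0]
    for m in range(1, M):
        f = (1 - s[m - 1]) * fwd[m - 1] + (s[m - 1] / K) * fwd[m - 1].sum()
        if is_typed[m]:
            f = f * _emission(ref[m], obs[typed_rank[m]], eps)[:, 0]
        scale[m] = f.sum()
        fwd[m] = f / scale[m]
    gamma = np.empty((M, K))
    b = np.ones(K)
    gamma[M - 1] = fwd[M - 1] * b
    for m in range(M - 2, -1, -1):
        nb = b
        if is_typed[m + 1]:
            nb = nb * _emission(ref[m + 1], obs[typed_rank[m + 1]], eps)[:, 0]
        b = ((1 - s[m]) * nb + (s[m] / K) * nb.sum()) / scale[m + 1]
        gamma[m] = fwd[m] * b
    return gamma / gamma.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Cohort-level imputation


class SiteMismatchError(ValueError):
    """Target sites not nested in the reference grid; carries a diff report."""

    def __init__(self, missing: pd.DataFrame):
        self.missing = missing
        super().__init__(
            f"{len(missing)} target sites absent from the reference grid; "
            f"first offenders:\n{missing.head().to_string(index=False)}"
        )


def _nest_sites(inner: VariantTable, outer: VariantTable) -> np.ndarray:
    """Map inner sites into the outer grid, raising with a diff on failure."""
    ii, io = intersect_sites(inner, outer)
    if len(ii) < len(inner):
        matched = np.zeros(len(inner), dtype=bool)
        matched[ii] = True
        raise SiteMismatchError(inner.df.loc[~matched, ["chrom", "pos", "id"]])
    out = np.empty(len(inner), dtype=np.int64)
    out[ii] = io
    return out


def impute_cohort(
    targets: HaplotypePanel,
    target_sites: VariantTable,
    reference: HaplotypePanel,
    reference_sites: VariantTable,
    params: LiStephensParams | None = None,
    want_loo: bool = True,
    max_chunk_bytes: int = 256 * 1024 * 1024,
) -> ImputationResult:
    """Impute phased targets typed at a subset of the reference site grid.

    Diploid dosage = sum of the two haplotype allele posteriors. If the
    target site set is not nested in the reference grid a
    :class:`SiteMismatchError` carrying the offending sites is raised.
    """
    params = params or LiStephensParams()
    if len(target_sites) == 0:
        raise ValueError("empty target site set")
    typed_idx = _nest_sites(target_sites, reference_sites)
    M, K = reference.n_sites, reference.n_haplotypes
    positions = reference_sites.pos
    obs = targets.alleles  # (T, 2N)
    n_haps = obs.shape[1]

    chunk = max(2, int(max_chunk_bytes // (M * K * 8)))
    chunk -= chunk % 2  # keep haplotype pairs together
    chunk = max(chunk, 2)
    dos = np.empty((M, n_haps))
    loo = np.full((M, n_haps), np.nan) if want_loo else None
    for lo in range(0, n_haps, chunk):
        hi = min(lo + chunk, n_haps)
        post, loo_chunk = _fb_engine(
            reference.alleles, typed_idx, obs[:, lo:hi], positions, params,
            want_loo=want_loo,
        )
        dos[:, lo:hi] = post
        if want_loo and loo_chunk is not None:
            loo[typed_idx, lo:hi] = loo_chunk

    dosage = dos[:, 0::2] + dos[:, 1::2]
    typed_mask = np.zeros(M, dtype=bool)
    typed_mask[typed_idx] = True
    if want_loo:
        loo_d = loo[:, 0::2] + loo[:, 1::2]
    else:
        loo_d = np.full((M, targets.n_samples), np.nan)
    return ImputationResult(
        dosage, loo_d, typed_mask, list(targets.samples), params,
        provenance={"K": K, "n_typed": len(typed_idx)},
    )


def harden_posteriors(
    post: np.ndarray, panel_freq: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Call haplotype alleles from posteriors; ties go to the allele with the
    higher panel frequency."""
    calls = post > threshold
    ties = post == threshold
    if np.any(ties):
        prefer_alt = (panel_freq >= 0.5)[:, None]
        calls = np.where(ties, prefer_alt, calls)
    return calls.astype(np.uint8)


def two_step_impute(
    targets: HaplotypePanel,
    target_sites: VariantTable,
    intermediate: HaplotypePanel,
    intermediate_sites: VariantTable,
    final: HaplotypePanel,
    final_sites: VariantTable,
    params: LiStephensParams | None = None,
    harden: bool = True,
) -> ImputationResult:
    """Two-step imputation: sparse array -> dense array grid -> full sequence.

    Step 1 imputes the targets to the intermediate (dense-array) grid and —
    by default — hardens per-haplotype alleles at posterior > 0.5; step 2
    imputes the resulting dense haplotypes to the full grid against the
    final panel. Site sets must be nested (sparse within dense within full).
    Any intermediate-panel sample that also appears among the targets is
    removed from the panel first.
    """
    params = params or LiStephensParams()
    overlap = [s for s in intermediate.samples if s in set(targets.samples)]
    if overlap:
        logger.info("two_step: dropping %d overlap samples from intermediate panel", len(overlap))
        keep = [i for i, s in enumerate(intermediate.samples) if s not in set(overlap)]
        if not keep:
            raise ValueError("intermediate panel empty after overlap removal")
        intermediate = intermediate.subset_samples(np.asarray(keep))
    # validate nesting sparse within dense within full
    _nest_sites(target_sites, intermediate_sites)
    dense_in_full = _nest_sites(intermediate_sites, final_sites)

    hap_post = _haplotype_posteriors(targets, target_sites, intermediate,
                                     intermediate_sites, params)
    if harden:
        dense_alleles = harden_posteriors(hap_post, intermediate.alt_frequency())
    else:
        dense_alleles = (hap_post > 0.5).astype(np.uint8)
    dense_targets = HaplotypePanel(dense_alleles, list(targets.samples), targets.groups)
    result = impute_cohort(dense_targets, intermediate_sites, final, final_sites, params)
    sparse_mask = np.zeros(len(final_sites), dtype=bool)
    sparse_mask[_nest_sites(target_sites, final_sites)] = True
    result.provenance.update(
        {"two_step": True, "overlap_removed": len(overlap), "sparse_mask": sparse_mask}
    )
    return result


def _haplotype_posteriors(targets, target_sites, panel, panel_sites, params):
    """Per-haplotype allele posteriors over the panel grid (helper for step 1)."""
    typed_idx = _nest_sites(target_sites, panel_sites)
    post, _ = _fb_engine(
        panel.alleles, typed_idx, targets.alleles, panel_sites.pos, params,
        want_loo=False,
    )
    return post


# ---------------------------------------------------------------------------
# Accuracy metrics


DEFAULT_MAF_BIN_EDGES = np.concatenate([[0.01], np.arange(0.05, 0.501, 0.05)])


def maf_bin(maf: np.ndarray, edges: np.ndarray = DEFAULT_MAF_BIN_EDGES) -> pd.Categorical:
    """Half-open MAF bins (lo, hi]; the first bin is (0.01, 0.05] by default."""
    labels = [f"({edges[i]:.2f},{edges[i+1]:.2f}]" for i in range(len(edges) - 1)]
    idx = np.searchsorted(edges, maf, side="left") - 1
    idx = np.where((maf <= edges[0]) | (maf > edges[-1]), -1, idx)
    cats = pd.Categorical.from_codes(
        np.clip(idx, -1, len(labels) - 1), categories=labels, ordered=True
    )
    return cats


def _rowwise_sq_corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation per row; NaN where either row is constant."""
    x = x - x.mean(axis=1, keepdims=True)
    y = y - y.mean(axis=1, keepdims=True)
    sxx = (x * x).sum(axis=1)
    syy = (y * y).sum(axis=1)
    sxy = (x * y).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where((sxx > 0) & (syy > 0), (sxy * sxy) / (sxx * syy), np.nan)
    return r2


def accuracy(
    result: ImputationResult,
    truth: GenotypeMatrix,
    maf: np.ndarray,
    impact: np.ndarray | None = None,
    groups: list[str] | None = None,
    typed_subset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-site accuracy table: ER² at typed sites, dosage R² at untyped ones.

    ``maf`` is the stratification frequency (conventionally computed in the
    reference panel). ``typed_subset`` optionally restricts which typed sites
    get an ER² (e.g. the sparse-array sites of a two-step run). If ``groups``
    is given, per-group rows are emitted alongside the pooled 'all' scope.
    Undefined values (zero variance) are NaN and excluded from aggregates.
    """
    if truth.dosages.shape != result.dosages.shape:
        raise ValueError("truth not aligned to imputation result")
    if truth.n_samples < 2:
        raise ValueError("need >= 2 samples for correlation accuracy")
    typed = result.typed_mask if typed_subset is None else np.asarray(typed_subset)
    scopes = [("all", np.arange(truth.n_samples))]
    if groups is not None:
        garr = np.asarray(groups)
        scopes += [(g, np.flatnonzero(garr == g)) for g in pd.unique(garr)]

    frames = []
    t = truth.dosages.astype(float)
    t[truth.dosages == MISSING] = np.nan
    for scope, cols in scopes:
        if len(cols) < 2:
            continue
        tt = t[:, cols]
        ok = ~np.isnan(tt)
        tt = np.where(ok, tt, 0.0)  # sites with missing truth handled via masking below
        n_ok = ok.sum(axis=1)
        er2 = _masked_sq_corr(tt, result.loo_dosages[:, cols], ok)
        dr2 = _masked_sq_corr(tt, result.dosages[:, cols], ok)
        df = pd.DataFrame(
            {
                "site": np.arange(result.n_sites),
                "typed": typed,
                "maf": np.asarray(maf, dtype=float),
                "er2": np.where(typed & (n_ok >= 2), er2, np.nan),
                "dosage_r2": np.where(~result.typed_mask & (n_ok >= 2), dr2, np.nan),
                "group": scope,
                "n_samples": len(cols),
            }
        )
        if impact is not None:
            df["impact"] = np.asarray(impact)
        df["maf_bin"] = maf_bin(df["maf"].to_numpy())
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _masked_sq_corr(x, y, ok):
    """Row-wise squared correlation with a validity mask on x."""
    n = ok.sum(axis=1, keepdims=True).astype(float)
    n = np.maximum(n, 1.0)
    xm = (x * ok).sum(axis=1, keepdims=True) / n
    yv = np.where(ok, y, 0.0)
    ym = yv.sum(axis=1, keepdims=True) / n
    xc = np.where(ok, x - xm, 0.0)
    yc = np.where(ok, y - ym, 0.0)
    sxx = (xc * xc).sum(axis=1)
    syy = (yc * yc).sum(axis=1)
    sxy = (xc * yc).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where((sxx > 0) & (syy > 0), (sxy * sxy) / (sxx * syy), np.nan)


def aggregate_accuracy(
    table: pd.DataFrame,
    metric: str,
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Mean of a per-site metric over the requested grouping, NaNs excluded."""
    if by:
        g = table.groupby(by, observed=True)[metric]
        out = g.agg(value="mean", n_sites="count").reset_index()
    else:
        vals = table[metric].dropna()
        out = pd.DataFrame({"value": [vals.mean()], "n_sites": [len(vals)]})
    out["metric"] = metric
    return out
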