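"""Coordinate liftover and allele harmonization between genotype datasets.

Array genotype data routinely arrive on an older assembly, in TOP rather
than FORWARD coding, and with REF/ALT conventions that disagree with the
reference dataset they must be merged with. This module implements the three
repair steps:

* :func:`liftover` — table-driven coordinate remapping with optional strand
  complementation and collision/unmapped accounting;
* :func:`fill_missing_alleles` — fill absent REF/ALT annotations from an
  array manifest's allele codings;
* :func:`reconcile_alleles` — classify every query record against a
  reference panel as OK / SWAPPED / STRAND_FLIP / SWAPPED_AND_FLIP or one of
  the discard categories, and apply the implied genotype recoding.

Strand-ambiguous SNPs (A/T and C/G) are always discarded: a strand error at
such a site is indistinguishable from an allele swap, so no correction can
be applied faithfully.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .vcfio import (
    ArrayManifest,
    CoordinateMap,
    GenotypeMatrix,
    HaplotypePanel,
    MISSING,
    VariantTable,
    complement,
)

_BASES = frozenset("ACGT")
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class Outcome(str, Enum):
    OK = "OK"
    SWAPPED = "SWAPPED"
    STRAND_FLIP = "STRAND_FLIP"
    SWAPPED_AND_FLIP = "SWAPPED_AND_FLIP"
    AMBIGUOUS_DISCARDED = "AMBIGUOUS_DISCARDED"
    ABSENT_DISCARDED = "ABSENT_DISCARDED"
    NONBIALLELIC_DISCARDED = "NONBIALLELIC_DISCARDED"


KEPT_OUTCOMES = {Outcome.OK, Outcome.SWAPPED, Outcome.STRAND_FLIP, Outcome.SWAPPED_AND_FLIP}
RECODE_OUTCOMES = {Outcome.SWAPPED, Outcome.SWAPPED_AND_FLIP}


# ---------------------------------------------------------------------------
# Liftover


@dataclass
class LiftoverResult:
    table: VariantTable
    kept_index: np.ndarray  # rows of the input table, in output order
    dropped: pd.DataFrame  # columns: chrom, pos, id, reason


def liftover(variants: VariantTable, cmap: CoordinateMap) -> LiftoverResult:
    """Remap variant coordinates through a (chrom_old, pos_old) table.

    Unmapped sites are dropped (reason ``unmapped``). When two inputs map to
    one output key the later one (input order) is dropped as ``collision``.
    Strand-flagged rows have both alleles complemented. The output is
    re-sorted; ``kept_index`` maps output rows back to input rows so callers
    can reorder genotype matrices.
    """
    df = variants.df.copy()
    m = cmap.df.set_index(["chrom_old", "pos_old"])
    keys = list(zip(df["chrom"], df["pos"]))
    new_chrom, new_pos, flip, mapped = [], [], [], []
    for k in keys:
        if k in m.index:
            row = m.loc[k]
            new_chrom.append(row["chrom_new"])
            new_pos.append(int(row["pos_new"]))
            flip.append(bool(row["strand_flip"]))
            mapped.append(True)
        else:
            new_chrom.append(None)
            new_pos.append(-1)
            flip.append(False)
            mapped.append(False)
    mapped = np.asarray(mapped)

    reasons = np.where(mapped, "", "unmapped").astype(object)
    seen: set[tuple] = set()
    for i in np.flatnonzero(mapped):
        key = (new_chrom[i], new_pos[i])
        if key in seen:
            mapped[i] = False
            reasons[i] = "collision"
        else:
            seen.add(key)

    keep = np.flatnonzero(mapped)
    out = df.iloc[keep].copy()
    out["chrom"] = [new_chrom[i] for i in keep]
    out["pos"] = [new_pos[i] for i in keep]
    flip_arr = np.asarray(flip)[keep]
    if flip_arr.any():
        ref = out["ref"].to_numpy(object)
        alt = out["alt"].to_numpy(object)
        for j in np.flatnonzero(flip_arr):
            if ref[j] in _BASES:
                ref[j] = complement(ref[j])
            if alt[j] in _BASES:
                alt[j] = complement(alt[j])
        out["ref"] = ref
        out["alt"] = alt

    order = np.lexsort((out["pos"].to_numpy(), out["chrom"].astype(str).to_numpy()))
    out = out.iloc[order]
    kept_index = keep[order]
    dropped = df.loc[~mapped, ["chrom", "pos", "id"]].copy()
    dropped["reason"] = reasons[~mapped]
    return LiftoverResult(VariantTable(out), kept_index, dropped.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Missing-allele fill from a manifest


def fill_missing_alleles(
    variants: VariantTable, manifest: ArrayManifest, coding: str = "forward"
) -> tuple[VariantTable, pd.DataFrame]:
    """Fill missing REF/ALT from the manifest's stated allele coding.

    Records keyed by ``id``. If only one allele is missing, the other is
    matched against the coding pair and the complementary member fills the
    gap; if both are missing, (alleleA, alleleB) is used as (ref, alt).
    Already-complete records are untouched. Records whose id is absent from
    the manifest, or whose present allele does not appear in the coding
    pair, are left unfilled and flagged.
    """
    if coding not in ("forward", "top"):
        raise ValueError("coding must be 'forward' or 'top'")
    a_col, b_col = (
        ("alleleA_fwd", "alleleB_fwd") if coding == "forward" else ("alleleA_top", "alleleB_top")
    )
    lookup = manifest.df.set_index("id")[[a_col, b_col]]
    df = variants.df.copy()
    ref = df["ref"].to_numpy(object)
    alt = df["alt"].to_numpy(object)
    ids = df["id"].to_numpy(object)
    flags = []
    for i in range(len(df)):
        r = ref[i] if ref[i] in _BASES else None
        a = alt[i] if alt[i] in _BASES else None
        if r is not None and a is not None:
            continue
        if ids[i] not in lookup.index:
            flags.append({"id": ids[i], "reason": "id_not_in_manifest"})
            continue
        pair = tuple(lookup.loc[ids[i]])
        if r is None and a is None:
            ref[i], alt[i] = pair
        elif r is not None:
            if r == pair[0]:
                alt[i] = pair[1]
            elif r == pair[1]:
                alt[i] = pair[0]
            else:
                flags.append({"id": ids[i], "reason": "ref_not_in_coding"})
        else:
            if a == pair[0]:
                ref[i] = pair[1]
            elif a == pair[1]:
                ref[i] = pair[0]
            else:
                flags.append({"id": ids[i], "reason": "alt_not_in_coding"})
    df["ref"] = ref
    df["alt"] = alt
    return VariantTable(df, validate=False), pd.DataFrame(flags, columns=["id", "reason"])


# ---------------------------------------------------------------------------
# Allele reconciliation against a reference dataset


def classify_pair(q_ref, q_alt, r_ref, r_alt) -> Outcome:
    """Classify one query allele pair against the reference pair.

    Ambiguous query pairs (A/T, C/G) are discarded regardless of match; the
    remaining categories follow from set identities: equal -> OK, reversed ->
    SWAPPED, complemented -> STRAND_FLIP, reverse-complemented ->
    SWAPPED_AND_FLIP, anything else unresolvable.
    """
    if (
        q_ref not in _BASES
        or q_alt not in _BASES
        or q_ref == q_alt
    ):
        return Outcome.NONBIALLELIC_DISCARDED
    if (q_ref, q_alt) in _AMBIGUOUS:
        return Outcome.AMBIGUOUS_DISCARDED
    if r_ref is None or r_alt is None:
        return Outcome.ABSENT_DISCARDED
    if r_ref not in _BASES or r_alt not in _BASES or r_ref == r_alt:
        return Outcome.NONBIALLELIC_DISCARDED
    if (q_ref, q_alt) == (r_ref, r_alt):
        return Outcome.OK
    if (q_ref, q_alt) == (r_alt, r_ref):
        return Outcome.SWAPPED
    if (q_ref, q_alt) == (complement(r_ref), complement(r_alt)):
        return Outcome.STRAND_FLIP
    if (q_ref, q_alt) == (complement(r_alt), complement(r_ref)):
        return Outcome.SWAPPED_AND_FLIP
    return Outcome.NONBIALLELIC_DISCARDED


@dataclass
class ReconcileResult:
    """Per-record outcomes plus the corrected (kept-record) dataset."""

    outcomes: pd.DataFrame  # chrom, pos, id, outcome, ref, alt (corrected; None if dropped)
    table: VariantTable  # kept records, corrected alleles
    genotypes: GenotypeMatrix | HaplotypePanel | None
    kept_index: np.ndarray

    def counts(self) -> pd.Series:
        return self.outcomes["outcome"].value_counts()


def reconcile_alleles(
    query: VariantTable,
    reference: VariantTable,
    genotypes: GenotypeMatrix | HaplotypePanel | None = None,
) -> ReconcileResult:
    """Classify and correct every query record against the reference.

    Matching is by (chrom, pos). SWAPPED / SWAPPED_AND_FLIP records have
    genotypes recoded g -> 2-g (haplotype alleles a -> 1-a); STRAND_FLIP
    complements the alleles without touching genotypes. Discarded records
    are removed from the corrected dataset.
    """
    ref_lookup = {
        (c, p): (r, a)
        for c, p, r, a in zip(reference.chrom, reference.pos, reference.ref, reference.alt)
    }
    rows = []
    outcomes = []
    for i in range(len(query)):
        qr, qa = query.ref[i], query.alt[i]
        key = (query.chrom[i], query.pos[i])
        rr, ra = ref_lookup.get(key, (None, None))
        oc = classify_pair(qr, qa, rr, ra)
        outcomes.append(oc)
        corrected = (rr, ra) if oc in KEPT_OUTCOMES else (None, None)
        rows.append(
            {
                "chrom": query.chrom[i],
                "pos": query.pos[i],
                "id": query.ids[i],
                "outcome": oc.value,
                "ref": corrected[0],
                "alt": corrected[1],
                "recoded": oc in RECODE_OUTCOMES,
            }
        )
    out_df = pd.DataFrame(rows)
    kept = np.flatnonzero([oc in KEPT_OUTCOMES for oc in outcomes])
    corrected_table = query.df.iloc[kept].copy()
    corrected_table["ref"] = out_df["ref"].iloc[kept].to_numpy()
    corrected_table["alt"] = out_df["alt"].iloc[kept].to_numpy()
    table = VariantTable(corrected_table)

    corrected_data = None
    if genotypes is not None:
        recode = np.asarray([oc in RECODE_OUTCOMES for oc in outcomes])[kept]
        if isinstance(genotypes, HaplotypePanel):
            alleles = genotypes.alleles[kept].copy()
            alleles[recode] = 1 - alleles[recode]
            corrected_data = HaplotypePanel(alleles, genotypes.samples, genotypes.groups)
        else:
            d = genotypes.dosages[kept].copy()
            block = d[recode]
            d[recode] = np.where(block == MISSING, MISSING, 2 - block)
            gq = genotypes.gq[kept] if genotypes.gq is not None else None
            corrected_data = GenotypeMatrix(d, genotypes.samples, genotypes.groups, gq)
    return ReconcileResult(out_df, table, corrected_data, kept)
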