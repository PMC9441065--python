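"""Variant/genotype data model and file I/O.

The in-memory containers used throughout the package live here:

* :class:`VariantTable` — per-site metadata (chrom, pos, id, ref, alt, qual),
  always sorted by (chrom, pos) with 1-based coordinates.
* :class:`GenotypeMatrix` — diploid alternate-allele dosages in {0, 1, 2},
  with -1 encoding a missing call, plus optional per-call GQ.
* :class:`HaplotypePanel` — phased binary haplotypes, two columns per sample.
* :class:`ArrayManifest` — an array design with TOP/FORWARD allele codings.
* :class:`CoordinateMap` — a table-driven stand-in for assembly liftover.

VCF reading uses cyvcf2; writing uses pysam. Only biallelic SNVs are
modelled: other records are skipped on read with a counted warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
_BASES = frozenset("ACGT")

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class VcfioError(ValueError):
    """Raised for malformed inputs or contract violations in this module."""


# ---------------------------------------------------------------------------
# VariantTable


class VariantTable:
    """Per-site variant metadata, sorted by (chrom, pos), 1-based positions.

    Wraps a pandas DataFrame with columns ``chrom, pos, id, ref, alt`` and
    optionally ``qual`` and ``call_rate``. Keys (chrom, pos, ref, alt) must
    be unique; SNV alleles must be single bases in {A, C, G, T} (missing
    alleles may be encoded as ``None`` prior to harmonization).
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.reset_index(drop=True).copy()
        for col in VARIANT_COLUMNS:
            if col not in df.columns:
                raise VcfioError(f"VariantTable missing column {col!r}")
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        order = np.lexsort((df["pos"].to_numpy(), df["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(df))):
            df = df.iloc[order].reset_index(drop=True)
        self.df = df
        self._sort_order = order
        if validate:
            self._validate()

    def _validate(self) -> None:
        keys = self.df[["chrom", "pos", "ref", "alt"]]
        if keys.duplicated().any():
            raise VcfioError("duplicate (chrom, pos, ref, alt) keys")
        for col in ("ref", "alt"):
            alleles = self.df[col].dropna()
            bad = ~alleles.isin(list(_BASES))
            if bad.any():
                raise VcfioError(
                    f"non-SNV {col} alleles: {sorted(alleles[bad].unique())}"
                )
        if (self.df["pos"] < 1).any():
            raise VcfioError("positions must be 1-based (>= 1)")

    # -- convenience accessors ------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy()

    @property
    def ref(self) -> np.ndarray:
        return self.df["ref"].to_numpy()

    @property
    def alt(self) -> np.ndarray:
        return self.df["alt"].to_numpy()

    def key_frame(self) -> pd.DataFrame:
        return self.df[["chrom", "pos"]]

    def subset(self, index: np.ndarray) -> "VariantTable":
        return VariantTable(self.df.iloc[np.asarray(index)], validate=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantTable):
            return NotImplemented
        return self.df[VARIANT_COLUMNS].equals(other.df[VARIANT_COLUMNS])

    @classmethod
    def from_arrays(
        cls,
        chrom,
        pos,
        ids=None,
        ref=None,
        alt=None,
        qual=None,
    ) -> "VariantTable":
        n = len(pos)
        df = pd.DataFrame(
            {
                "chrom": np.broadcast_to(np.asarray(chrom, dtype=object), n)
                if np.ndim(chrom) == 0
                else chrom,
                "pos": pos,
                "id": ids if ids is not None else [f"snp{i:07d}" for i in range(n)],
                "ref": ref if ref is not None else [None] * n,
                "alt": alt if alt is not None else [None] * n,
            }
        )
        if qual is not None:
            df["qual"] = qual
        return cls(df)


def alt_allele_frequency(dosages: np.ndarray) -> np.ndarray:
    """Alternate-allele frequency per site from a dosage matrix.

    Missing calls (coded -1) are excluded; an all-missing site gets NaN.
    """
    d = np.asarray(dosages)
    valid = d != MISSING
    n_alleles = 2 * valid.sum(axis=1)
    alt_count = np.where(valid, d, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, alt_count / np.maximum(n_alleles, 1), np.nan)
    return freq


def minor_allele_frequency(dosages: np.ndarray) -> np.ndarray:
    """MAF per site; monomorphic sites get 0, all-missing sites NaN."""
    p = alt_allele_frequency(dosages)
    return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# GenotypeMatrix / HaplotypePanel


@dataclass
class GenotypeMatrix:
    """Diploid dosages, sites x samples, values in {0, 1, 2} or -1 (missing)."""

    dosages: np.ndarray
    samples: list[str]
    groups: list[str] | None = None
    gq: np.ndarray | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.samples):
            raise VcfioError("dosage matrix shape does not match sample list")
        if self.groups is not None and len(self.groups) != len(self.samples):
            raise VcfioError("group labels do not match sample list")

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def maf(self) -> np.ndarray:
        return minor_allele_frequency(self.dosages)

    def subset_sites(self, index) -> "GenotypeMatrix":
        gq = self.gq[np.asarray(index)] if self.gq is not None else None
        return GenotypeMatrix(self.dosages[np.asarray(index)], self.samples, self.groups, gq)

    def subset_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        samples = [self.samples[i] for i in index]
        groups = [self.groups[i] for i in index] if self.groups else None
        gq = self.gq[:, index] if self.gq is not None else None
        return GenotypeMatrix(self.dosages[:, index], samples, groups, gq)


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes, sites x (2 * samples).

    Haplotype columns 2j and 2j+1 belong to sample j. Collapsing haplotype
    pairs by summation reproduces the diploid GenotypeMatrix.
    """

    alleles: np.ndarray
    samples: list[str]
    groups: list[str] | None = None

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2 or self.alleles.shape[1] != 2 * len(self.samples):
            raise VcfioError("haplotype count must equal 2 x sample count")
        if self.groups is not None and len(self.groups) != len(self.samples):
            raise VcfioError("group labels do not match sample list")

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    def to_genotypes(self) -> GenotypeMatrix:
        d = self.alleles[:, 0::2].astype(np.int8) + self.alleles[:, 1::2]
        return GenotypeMatrix(d, list(self.samples), self.groups)

    def alt_frequency(self) -> np.ndarray:
        return self.alleles.mean(axis=1)

    def maf(self) -> np.ndarray:
        p = self.alt_frequency()
        return np.minimum(p, 1.0 - p)

    def subset_sites(self, index) -> "HaplotypePanel":
        return HaplotypePanel(self.alleles[np.asarray(index)], list(self.samples), self.groups)

    def subset_samples(self, index) -> "HaplotypePanel":
        index = np.asarray(index)
        hap_cols = np.stack([2 * index, 2 * index + 1], axis=1).ravel()
        samples = [self.samples[i] for i in index]
        groups = [self.groups[i] for i in index] if self.groups else None
        return HaplotypePanel(self.alleles[:, hap_cols], samples, groups)

    def sample_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise VcfioError(f"samples not in panel: {missing[:5]}")
        return np.array([lookup[n] for n in names], dtype=np.int64)


# ---------------------------------------------------------------------------
# ArrayManifest / CoordinateMap

MANIFEST_COLUMNS = [
    "id",
    "chrom",
    "pos",
    "alleleA_top",
    "alleleB_top",
    "alleleA_fwd",
    "alleleB_fwd",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(base: str) -> str:
    return _COMPLEMENT[base]


@dataclass
class ArrayManifest:
    """An array design: site identifiers, positions and allele codings."""

    df: pd.DataFrame

    def __post_init__(self):
        for col in MANIFEST_COLUMNS:
            if col not in self.df.columns:
                raise VcfioError(f"manifest missing column {col!r}")
        self.df = self.df.reset_index(drop=True).copy()
        self.df["chrom"] = self.df["chrom"].astype(str)
        self.df["pos"] = self.df["pos"].astype(np.int64)
        if self.df["id"].duplicated().any():
            raise VcfioError("manifest ids must be unique")
        top = self.df[["alleleA_top", "alleleB_top"]].to_numpy()
        fwd = self.df[["alleleA_fwd", "alleleB_fwd"]].to_numpy()
        for t, f in zip(top, fwd):
            same = tuple(t) == tuple(f)
            comp = tuple(t) == (_COMPLEMENT[f[0]], _COMPLEMENT[f[1]])
            if not (same or comp):
                raise VcfioError(
                    f"TOP/FORWARD codings not complement-consistent: {t} vs {f}"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    def to_csv(self, path) -> None:
        self.df[MANIFEST_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ArrayManifest":
        return cls(pd.read_csv(Path(path), dtype={"chrom": str}))


@dataclass
class CoordinateMap:
    """Injective (chrom_old, pos_old) -> (chrom_new, pos_new) remap table."""

    df: pd.DataFrame

    COLUMNS = ["chrom_old", "pos_old", "chrom_new", "pos_new", "strand_flip"]

    def __post_init__(self):
        df = self.df.copy()
        if "strand_flip" not in df.columns:
            df["strand_flip"] = False
        for col in self.COLUMNS[:4]:
            if col not in df.columns:
                raise VcfioError(f"coordinate map missing column {col!r}")
        df["chrom_old"] = df["chrom_old"].astype(str)
        df["chrom_new"] = df["chrom_new"].astype(str)
        df["strand_flip"] = df["strand_flip"].astype(bool)
        if df[["chrom_old", "pos_old"]].duplicated().any():
            raise VcfioError("coordinate map keys must be unique")
        self.df = df.reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.df[self.COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CoordinateMap":
        return cls(pd.read_csv(Path(path), dtype={"chrom_old": str, "chrom_new": str}))


# ---------------------------------------------------------------------------
# VCF reading


def read_vcf(path):
    """Read a VCF of biallelic SNVs.

    Returns ``(VariantTable, HaplotypePanel)`` when every non-missing call is
    phased, else ``(VariantTable, GenotypeMatrix)``. Multiallelic and non-SNV
    records are skipped; the count is logged and attached to the returned
    table as ``table.skipped_records``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    geno_rows = []
    gq_rows = []
    skipped = 0
    any_gq = False
    has_gq_header = "GQ" in vcf.raw_header
    all_phased = True
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        if v.REF not in _BASES or v.ALT[0] not in _BASES:
            skipped += 1
            continue
        rows.append(
            (str(v.CHROM), v.POS, v.ID or ".", v.REF, v.ALT[0], v.QUAL)
        )
        gts = v.genotypes  # list of [a0, a1, phased]
        geno_rows.append([(g[0], g[1], bool(g[2])) for g in gts])
        gq = v.format("GQ") if has_gq_header else None
        if gq is not None:
            any_gq = True
            gq_rows.append(np.asarray(gq, dtype=float).reshape(-1))
        else:
            gq_rows.append(None)
    vcf.close()
    if not rows:
        raise VcfioError(f"no biallelic SNV records in {path}")
    df = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt", "qual"])
    table = VariantTable(df)
    order = table._sort_order

    n_sites, n_samples = len(rows), len(samples)
    a = np.zeros((n_sites, 2 * n_samples), dtype=np.int16)
    for i, calls in enumerate(geno_rows):
        for j, (a0, a1, phased) in enumerate(calls):
            a[i, 2 * j] = a0
            a[i, 2 * j + 1] = a1
            if not phased and a0 >= 0 and a1 >= 0:
                all_phased = False
    a = a[order]
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNV records", skipped)
    table.skipped_records = skipped

    if all_phased:
        alleles = np.where(a < 0, 0, a).astype(np.uint8)
        if (a < 0).any():
            # phased panels must be complete; missing haplotype alleles are
            # not representable, so fall back to a genotype matrix
            all_phased = False
        else:
            return table, HaplotypePanel(alleles, samples)

    dos = np.where((a[:, 0::2] < 0) | (a[:, 1::2] < 0), MISSING, a[:, 0::2] + a[:, 1::2])
    gq = None
    if any_gq:
        gq = np.full((n_sites, n_samples), np.nan)
        for i, row in enumerate(gq_rows):
            if row is not None:
                gq[i] = row
        gq = gq[order]
    return table, GenotypeMatrix(dos.astype(np.int8), samples, gq=gq)


# ---------------------------------------------------------------------------
# VCF writing


def write_vcf(path, table: VariantTable, data, dosage: np.ndarray | None = None,
              loo_dosage: np.ndarray | None = None, typed_mask: np.ndarray | None = None,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a VCF 4.2 file for a HaplotypePanel (phased GT) or GenotypeMatrix.

    ``dosage`` (sites x samples, float) is emitted as FORMAT/DS; ``loo_dosage``
    as FORMAT/LDS at typed sites (``typed_mask`` marks them, NaN elsewhere).
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##source=bovarray')
    chroms = pd.unique(table.chrom)
    for c in chroms:
        length = None if contig_lengths is None else contig_lengths.get(str(c))
        if length is None:
            length = int(table.pos[table.chrom == c].max()) + 1
        header.contigs.add(str(c), length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    if dosage is not None:
        header.formats.add("DS", 1, "Float", "Posterior alternate-allele dosage")
    if loo_dosage is not None:
        header.formats.add("LDS", 1, "Float", "Leave-one-out dosage at typed sites")

    is_panel = isinstance(data, HaplotypePanel)
    samples = data.samples
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        qual = table.df["qual"].to_numpy() if "qual" in table.df.columns else None
        for i in range(len(table)):
            rec = out.new_record(
                contig=str(table.chrom[i]),
                start=int(table.pos[i]) - 1,  # pysam is 0-based internally
                stop=int(table.pos[i]),
                alleles=(table.ref[i] or "N", table.alt[i] or "N"),
                id=str(table.ids[i]),
            )
            if qual is not None and qual[i] is not None and not pd.isna(qual[i]):
                rec.qual = float(qual[i])
            for j, s in enumerate(samples):
                smp = rec.samples[s]
                if is_panel:
                    smp["GT"] = (int(data.alleles[i, 2 * j]), int(data.alleles[i, 2 * j + 1]))
                    smp.phased = True
                else:
                    g = int(data.dosages[i, j])
                    if g == MISSING:
                        smp["GT"] = (None, None)
                    else:
                        smp["GT"] = (1, 1) if g == 2 else ((0, 1) if g == 1 else (0, 0))
                if dosage is not None:
                    smp["DS"] = float(dosage[i, j])
                if loo_dosage is not None and (typed_mask is None or typed_mask[i]):
                    smp["LDS"] = float(loo_dosage[i, j])
            out.write(rec)


# ---------------------------------------------------------------------------
# Site intersection and tabular reports


def intersect_sites(a: VariantTable, b) -> tuple[np.ndarray, np.ndarray]:
    """Aligned index vectors of sites shared by (chrom, pos) between two tables.

    ``b`` may be a VariantTable or an ArrayManifest. Allele compatibility is
    not enforced here — that is the harmonizer's job. Matches are returned in
    ``a``'s sort order; an empty intersection yields two empty arrays.
    """
    bdf = b.df if isinstance(b, (VariantTable, ArrayManifest)) else b
    left = a.df[["chrom", "pos"]].reset_index().rename(columns={"index": "ia"})
    right = bdf[["chrom", "pos"]].reset_index().rename(columns={"index": "ib"})
    merged = left.merge(right, on=["chrom", "pos"], how="inner", sort=False)
    merged = merged.sort_values("ia", kind="stable")
    return merged["ia"].to_numpy(np.int64), merged["ib"].to_numpy(np.int64)


def write_report(records, path, format: str = "csv") -> None:
    """Write tabular records as CSV (RFC 4180) or JSON with stable columns.

    Floats are rendered at 6 significant digits.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False, float_format="%.6g")
    elif format == "json":
        def _conv(v):
            if isinstance(v, (np.floating, float)):
                return float(f"{v:.6g}")
            if isinstance(v, np.integer):
                return int(v)
            return v
        rows = [{k: _conv(v) for k, v in row.items()} for row in df.to_dict("records")]
        path.write_text(json.dumps(rows, indent=1))
    else:
        raise VcfioError(f"unknown report format {format!r}")


def read_report(path, format: str = "csv") -> pd.DataFrame:
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path)
    return pd.DataFrame(json.loads(path.read_text()))
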