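"""Locus-restricted VCF parsing, depth-ratio genotype calling and site filtering.

The panel is effectively homozygous (selfing *Aegilops tauschii*), so each
sample/site cell is called ``REF``, ``ALT`` or ``MISSING`` from the ratio of
alternate-allele read depth (DV) to total depth (DP), gated on site QUAL.
Intermediate ratios are treated as noise and become ``MISSING`` with a
het-ambiguous flag rather than heterozygous calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REF",
    "ALT",
    "MISSING",
    "FLAG_LOW_QUAL",
    "FLAG_LOW_DEPTH",
    "FLAG_HET_AMBIGUOUS",
    "LocusDefinition",
    "CallThresholds",
    "VariantSite",
    "GenotypeMatrix",
    "LocusRecords",
    "read_vcf_region",
    "call_genotype",
    "call_genotypes",
    "apply_site_filters",
    "find_duplicates",
    "hamming",
    "HammingResult",
]

REF: int = 0
ALT: int = 1
MISSING: int = -1

FLAG_LOW_QUAL = 0x1
FLAG_LOW_DEPTH = 0x2
FLAG_HET_AMBIGUOUS = 0x4

#: region tags, in genomic order around the two genes
REGIONS = ("flank-x", "coding-x", "flank-y", "coding-y")
CODING_REGIONS = ("coding-x", "coding-y")


@dataclass(frozen=True)
class LocusDefinition:
    """Two linked genes on one chromosome plus symmetric flanks.

    Coordinates are 1-based closed intervals (VCF/GFF convention).
    """

    chrom: str
    gene_x: tuple[int, int]
    gene_y: tuple[int, int]
    flank: int = 2500
    strand_x: str = "+"
    strand_y: str = "+"

    def __post_init__(self) -> None:
        for name, (s, e) in (("gene_x", self.gene_x), ("gene_y", self.gene_y)):
            if s > e:
                raise ValueError(f"{name}: start > end ({s} > {e})")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if not (self.gene_x[1] < self.gene_y[0] or self.gene_y[1] < self.gene_x[0]):
            raise ValueError("gene_x and gene_y overlap")
        for st in (self.strand_x, self.strand_y):
            if st not in "+-":
                raise ValueError(f"bad strand {st!r}")

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "gene_x": list(self.gene_x),
            "gene_y": list(self.gene_y),
            "flank": self.flank,
            "strand_x": self.strand_x,
            "strand_y": self.strand_y,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LocusDefinition":
        return cls(
            d["chrom"],
            tuple(d["gene_x"]),
            tuple(d["gene_y"]),
            int(d.get("flank", 2500)),
            d.get("strand_x", "+"),
            d.get("strand_y", "+"),
        )

    def region_of(self, chrom: str, pos: int) -> str | None:
        """Region tag for a 1-based position, or None when outside the locus.

        Coding assignment wins over flank; with the default 2.5 kb flanks and
        genes tens of kb apart the flank windows do not overlap, but if they
        did, the x gene's flank takes precedence (x first in genomic order).
        """
        if chrom != self.chrom:
            return None
        (xs, xe), (ys, ye) = self.gene_x, self.gene_y
        if xs <= pos <= xe:
            return "coding-x"
        if ys <= pos <= ye:
            return "coding-y"
        if xs - self.flank <= pos <= xe + self.flank:
            return "flank-x"
        if ys - self.flank <= pos <= ye + self.flank:
            return "flank-y"
        return None


@dataclass(frozen=True)
class CallThresholds:
    """QUAL / depth gates and the DV/DP ratio cutoffs for homozygous calls.

    The ratio cutoffs (0.2 / 0.8) are symmetric, conventional values for
    inbred panels and are deliberately configurable.
    """

    qual_min: float = 40.0
    ratio_homref_max: float = 0.2
    ratio_homalt_min: float = 0.8
    depth_min: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.ratio_homref_max < self.ratio_homalt_min <= 1):
            raise ValueError("require 0 <= ratio_homref_max < ratio_homalt_min <= 1")
        if self.qual_min < 0:
            raise ValueError("qual_min must be >= 0")


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    region: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")


@dataclass
class LocusRecords:
    """Raw locus-restricted records: per-site DP/DV across a fixed sample set."""

    samples: list[str]
    sites: list[VariantSite]
    dp: np.ndarray  # (n_sites, n_samples) int
    dv: np.ndarray  # (n_sites, n_samples) int


@dataclass
class GenotypeMatrix:
    """Sites x samples matrix of {REF, ALT, MISSING} calls with provenance flags."""

    sites: list[VariantSite]
    samples: list[str]
    calls: np.ndarray  # (n_sites, n_samples) int8
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.flags is None:
            self.flags = np.zeros_like(self.calls, dtype=np.uint8)
        self.flags = np.asarray(self.flags, dtype=np.uint8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError("calls shape inconsistent with sites/samples")
        if self.flags.shape != self.calls.shape:
            raise ValueError("flags shape inconsistent with calls")
        keys = [(s.chrom, s.pos) for s in self.sites]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("sites must be strictly increasing by (chrom, pos)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_mask(self, regions) -> np.ndarray:
        regions = set(regions)
        return np.array([s.region in regions for s in self.sites], dtype=bool)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        sites = [s for s, keep in zip(self.sites, mask) if keep]
        return GenotypeMatrix(sites, list(self.samples), self.calls[mask], self.flags[mask])

    def restrict_regions(self, regions) -> "GenotypeMatrix":
        return self.subset_sites(self.site_mask(regions))

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.sites],
                "pos": [s.pos for s in self.sites],
                "ref": [s.ref for s in self.sites],
                "alt": [s.alt for s in self.sites],
                "qual": [s.qual for s in self.sites],
                "region": [s.region for s in self.sites],
            }
        )
        calls_df = pd.DataFrame(self.calls, columns=self.samples)
        pd.concat([df, calls_df], axis=1).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        meta = ["chrom", "pos", "ref", "alt", "qual", "region"]
        samples = [c for c in df.columns if c not in meta]
        sites = [
            VariantSite(r.chrom, int(r.pos), r.ref, r.alt, float(r.qual), r.region)
            for r in df.itertuples()
        ]
        return cls(sites, samples, df[samples].to_numpy(dtype=np.int8))

    def sites_to_bed(self, path) -> None:
        """BED export: 0-based half-open conversion happens only here."""
        with open(path, "w") as fh:
            for s in self.sites:
                fh.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.region}\n")


def read_vcf_region(vcf_source, locus: LocusDefinition) -> LocusRecords:
    """Read a VCF and keep records inside the two gene-plus-flank windows.

    Multiallelic records are split into one record per ALT allele.  DV is read
    from the DV FORMAT field when present, otherwise derived from AD as the
    per-ALT depth.  Records on chromosomes other than the locus chromosome are
    ignored; an entirely absent locus chromosome yields an empty result with a
    warning.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_source))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"cannot read VCF {vcf_source}: {exc}") from exc
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    dp_rows: list[np.ndarray] = []
    dv_rows: list[np.ndarray] = []
    saw_chrom = False
    for lineno, var in enumerate(vcf, start=1):
        if var.CHROM != locus.chrom:
            continue
        saw_chrom = True
        region = locus.region_of(var.CHROM, var.POS)
        if region is None:
            continue
        try:
            dp = var.format("DP")
            if dp is None:
                raise ValueError("missing DP FORMAT field")
            dp = np.asarray(dp, dtype=np.int64).reshape(len(samples), -1)[:, 0]
            dv_field = var.format("DV")
            ad = None if dv_field is not None else var.format("AD")
            if dv_field is None and ad is None:
                raise ValueError("missing both DV and AD FORMAT fields")
            alts = var.ALT or []
            for ai, alt in enumerate(alts):
                if dv_field is not None:
                    dv = np.asarray(dv_field, dtype=np.int64).reshape(len(samples), -1)[:, 0]
                else:
                    dv = np.asarray(ad, dtype=np.int64).reshape(len(samples), -1)[:, ai + 1]
                dv = np.clip(dv, 0, None)
                qual = float(var.QUAL) if var.QUAL is not None else 0.0
                sites.append(VariantSite(var.CHROM, var.POS, var.REF, alt, qual, region))
                dp_rows.append(np.clip(dp, 0, None))
                dv_rows.append(dv)
        except ValueError as exc:
            raise ValueError(f"malformed VCF record at line ~{lineno} ({var.CHROM}:{var.POS}): {exc}") from exc
    if not saw_chrom:
        warnings.warn(f"locus chromosome {locus.chrom!r} absent from VCF", stacklevel=2)
    n = len(sites)
    dp_arr = np.vstack(dp_rows) if n else np.zeros((0, len(samples)), dtype=np.int64)
    dv_arr = np.vstack(dv_rows) if n else np.zeros((0, len(samples)), dtype=np.int64)
    return LocusRecords(samples, sites, dp_arr, dv_arr)


def call_genotype(dp: int, dv: int, qual: float, t: CallThresholds = CallThresholds()) -> int:
    """Call one cell from (DP, DV, QUAL). QUAL must be strictly > qual_min."""
    if dv > dp:
        raise ValueError(f"DV ({dv}) exceeds DP ({dp})")
    if dv < 0 or dp < 0:
        raise ValueError("negative depth")
    if qual <= t.qual_min or dp < t.depth_min:
        return MISSING
    ratio = dv / dp
    if ratio <= t.ratio_homref_max:
        return REF
    if ratio >= t.ratio_homalt_min:
        return ALT
    return MISSING  # het-ambiguous


def call_genotypes(records: LocusRecords, t: CallThresholds = CallThresholds()) -> GenotypeMatrix:
    """Vectorised :func:`call_genotype` over a :class:`LocusRecords` block."""
    dp, dv = records.dp, records.dv
    if np.any(dv > dp):
        i, j = np.argwhere(dv > dp)[0]
        raise ValueError(
            f"DV exceeds DP for sample {records.samples[j]!r} at "
            f"{records.sites[i].chrom}:{records.sites[i].pos}"
        )
    n_sites, n_samples = dp.shape
    calls = np.full((n_sites, n_samples), MISSING, dtype=np.int8)
    flags = np.zeros((n_sites, n_samples), dtype=np.uint8)
    qual = np.array([s.qual for s in records.sites])[:, None]
    low_qual = np.broadcast_to(qual <= t.qual_min, dp.shape)
    low_depth = dp < t.depth_min
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dp > 0, dv / np.maximum(dp, 1), np.nan)
    ok = ~(low_qual | low_depth)
    calls[ok & (ratio <= t.ratio_homref_max)] = REF
    calls[ok & (ratio >= t.ratio_homalt_min)] = ALT
    het = ok & (ratio > t.ratio_homref_max) & (ratio < t.ratio_homalt_min)
    flags[het] |= FLAG_HET_AMBIGUOUS
    flags[low_qual] |= FLAG_LOW_QUAL
    flags[low_depth & ~low_qual] |= FLAG_LOW_DEPTH
    return GenotypeMatrix(records.sites, list(records.samples), calls, flags)


def apply_site_filters(
    m: GenotypeMatrix, maf_min: float = 0.01, miss_max: float = 0.90
) -> GenotypeMatrix:
    """Drop monomorphic sites, rare-minor-allele sites and near-empty sites.

    A site is retained when it is polymorphic among called samples, its minor
    allele frequency over non-missing calls is >= ``maf_min`` and its missing
    fraction is <= ``miss_max``.  Idempotent; the sample set is unchanged.
    """
    if m.n_samples == 0:
        raise ValueError("matrix has zero samples")
    if not (0 <= maf_min < 1):
        raise ValueError("maf_min must be in [0, 1)")
    if not (0 < miss_max <= 1):
        raise ValueError("miss_max must be in (0, 1]")
    called = m.calls != MISSING
    n_called = called.sum(axis=1)
    n_alt = (m.calls == ALT).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, n_alt / np.maximum(n_called, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    miss_frac = 1 - n_called / m.n_samples
    keep = (n_called > 0) & (maf > 0) & (maf >= maf_min) & (miss_frac <= miss_max)
    return m.subset_sites(keep)


def find_duplicates(calls, samples=None, identity_min: float = 0.998):
    """Group samples whose call identity exceeds ``identity_min``.

    ``calls`` is (n_samples, n_sites) with MISSING == -1, or a DataFrame with
    samples as columns.  Identity for a pair is matching calls / co-called
    sites; pairs with no co-called sites are skipped with a warning.  Returns
    the connected components of the pair graph (singletons included), each
    sorted, ordered by their smallest member.
    """
    import networkx as nx

    if isinstance(calls, pd.DataFrame):
        samples = list(calls.columns)
        calls = calls.to_numpy().T
    calls = np.asarray(calls)
    if samples is None:
        samples = [str(i) for i in range(calls.shape[0])]
    n = len(samples)
    g = nx.Graph()
    g.add_nodes_from(samples)
    called = calls != MISSING
    for i in range(n):
        co = called[i] & called[i + 1 :]
        n_co = co.sum(axis=1)
        match = ((calls[i] == calls[i + 1 :]) & co).sum(axis=1)
        for k, j in enumerate(range(i + 1, n)):
            if n_co[k] == 0:
                warnings.warn(
                    f"no co-called sites for pair ({samples[i]}, {samples[j]}); skipped",
                    stacklevel=2,
                )
                continue
            if match[k] / n_co[k] > identity_min:
                g.add_edge(samples[i], samples[j])
    groups = [sorted(c) for c in nx.connected_components(g)]
    return sorted(groups, key=lambda grp: grp[0])


@dataclass(frozen=True)
class HammingResult:
    differences: int
    compared: int
    excluded: int

    def __int__(self) -> int:
        return self.differences


def hamming(a, b) -> HammingResult:
    """Count of co-called differing positions; missing positions excluded."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    co = (a != MISSING) & (b != MISSING)
    diff = int(((a != b) & co).sum())
    return HammingResult(diff, int(co.sum()), int((~co).sum()))
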