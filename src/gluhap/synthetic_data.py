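"""Structured synthetic panels with planted truth.

Emulates a resequenced selfing-diploid panel of three diverged lineages with
lineage-private haplotype pools at two tightly linked genes ~55 kb apart:
near-complete x-y linkage with rare planted recombinants, occasional
inter-lineage shared haplotypes, duplicated accessions, and DP/DV sequencing
noise.  Every downstream stage of the pipeline is testable against the
planted truth without any download.

Model sketch (per seed, fully deterministic):

* every site gets one of the six non-constant lineage allele patterns, so
  lineages differ at well over 30% of sites and no site is monomorphic by
  construction;
* within a lineage, haplotype j differs from the lineage base at one private
  coding site, so planted haplotypes are exactly recoverable at zero noise;
* flank sites carry the lineage base only (complete linkage with the coding
  haplotype), so widening the scope to the flanks adds no haplotypes;
* samples are fully homozygous; read depth is Poisson(mean_depth) clipped
  below at 2 (the panel emulated is sequenced >7x), and DV is binomial in
  the per-read miscall probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .kmer_lineage import margin_for
from .protein_effects import GeneModel
from .variant_core import LocusDefinition, VariantSite

__all__ = [
    "LINEAGES",
    "PanelConfig",
    "SyntheticTruth",
    "simulate_panel",
    "simulate_kmer_bins",
    "fixture_config",
]

LINEAGES = ("L1", "L2", "L3")

#: non-constant allele patterns over the three lineages
_PATTERNS = np.array(
    [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1)], dtype=np.int8
)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]

#: lineage collection-site centroids (lat, lon) and jitter sd in degrees.
#: L1 ranges widely across the species range, L2 hugs the SE Caspian shore,
#: L3 sits in Transcaucasia.
_CENTROIDS = {"L1": (36.5, 59.0), "L2": (36.8, 53.5), "L3": (41.6, 44.9)}
_JITTER_SD = {"L1": 4.0, "L2": 1.5, "L3": 1.0}


@dataclass(frozen=True)
class PanelConfig:
    """Study conditions for one synthetic panel.

    Defaults mirror the emulated diversity panel: 117/143/8 accessions in
    lineages 1/2/3, ~10x depth, 308 polymorphic sites split across the two
    coding regions (60 + 68) and the 2.5 kb flanks (180), two planted
    recombinants and one haplotype shared between lineages 1 and 2.
    """

    n_samples_per_lineage: tuple[int, int, int] = (117, 143, 8)
    n_haplotypes_x: tuple[int, int, int] = (13, 18, 1)
    n_haplotypes_y: tuple[int, int, int] = (13, 18, 1)
    n_sites_x: int = 60
    n_sites_y: int = 68
    n_sites_flank: int = 180
    recombinant_count: int = 2
    shared_haplotype_count: int = 1
    duplicate_pairs: int = 2
    mean_depth: float = 10.0
    error_rate: float = 0.002
    qual_low_fraction: float = 0.05
    n_genomewide_sites: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        ints = (
            *self.n_samples_per_lineage,
            *self.n_haplotypes_x,
            *self.n_haplotypes_y,
            self.n_sites_x,
            self.n_sites_y,
            self.n_sites_flank,
            self.recombinant_count,
            self.shared_haplotype_count,
            self.duplicate_pairs,
            self.n_genomewide_sites,
        )
        if any(v < 0 for v in ints):
            raise ValueError("all counts must be >= 0")
        total = sum(self.n_samples_per_lineage)
        if total == 0:
            raise ValueError("panel must contain at least one sample")
        if self.recombinant_count > total:
            raise ValueError("recombinant_count exceeds total samples")
        for l, (kx, ky, ns) in enumerate(
            zip(self.n_haplotypes_x, self.n_haplotypes_y, self.n_samples_per_lineage)
        ):
            if ns > 0 and (kx == 0 or ky == 0):
                raise ValueError(f"lineage {l + 1} has samples but an empty haplotype pool")
            if kx - 1 > self.n_sites_x or ky - 1 > self.n_sites_y:
                raise ValueError(
                    "haplotype pool larger than representable by the coding site count"
                )
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if not (0 <= self.qual_low_fraction <= 1):
            raise ValueError("qual_low_fraction must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")


def fixture_config(seed: int = 0) -> PanelConfig:
    """The bundled zero-noise panel: 11 observed combined haplotypes
    (4+4+1 planted pools plus the 2 recombinant pairings), 2 recombinants,
    1 shared haplotype and 1 duplicate pair."""
    return PanelConfig(
        n_samples_per_lineage=(20, 20, 6),
        n_haplotypes_x=(4, 4, 1),
        n_haplotypes_y=(4, 4, 1),
        n_sites_x=24,
        n_sites_y=24,
        n_sites_flank=32,
        recombinant_count=2,
        shared_haplotype_count=1,
        duplicate_pairs=1,
        mean_depth=12.0,
        error_rate=0.0,
        qual_low_fraction=0.0,
        n_genomewide_sites=2000,
        seed=seed,
    )


@dataclass
class SyntheticTruth:
    """Planted truth tables: the oracle for every downstream stage."""

    config: PanelConfig
    locus: LocusDefinition
    gene_x: GeneModel
    gene_y: GeneModel
    samples: pd.DataFrame  # sample, lineage, x_haplotype, y_haplotype, is_recombinant, duplicate_of
    sites: pd.DataFrame  # chrom, pos, region, ref, alt, is_coding, planted_effect
    haplotype_alleles: dict[str, np.ndarray]  # hap id -> alleles over its gene's sites
    genomewide: pd.DataFrame  # genome-wide call matrix, samples as columns

    # -- oracle helpers -------------------------------------------------
    def n_x_haplotypes(self) -> int:
        return self.samples["x_haplotype"].nunique()

    def n_y_haplotypes(self) -> int:
        return self.samples["y_haplotype"].nunique()

    def n_combined_haplotypes(self) -> int:
        return (
            self.samples[["x_haplotype", "y_haplotype"]].drop_duplicates().shape[0]
        )

    def recombinant_samples(self) -> list[str]:
        return sorted(self.samples.loc[self.samples["is_recombinant"], "sample"])

    def duplicate_groups(self) -> list[list[str]]:
        dup = self.samples[self.samples["duplicate_of"] != ""]
        return sorted(
            sorted([r.duplicate_of, r.sample]) for r in dup.itertuples()
        )

    def lineage_of(self, sample: str) -> str:
        row = self.samples.loc[self.samples["sample"] == sample]
        return str(row["lineage"].iloc[0])

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(out / "truth_samples.tsv", sep="\t", index=False)
        self.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
        self.genomewide.to_csv(out / "truth_genomewide.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# panel simulation


def _reference_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(_CODONS, size=n_codons - 2)
    return "ATG" + "".join(codons) + "TGA"


def _lineage_patterns(rng: np.random.Generator, n_sites: int, groups: dict) -> np.ndarray:
    """Per-site lineage base alleles; every lineage pair differs at >= 30%
    of sites within each coding region and overall."""
    for _ in range(200):
        pat = _PATTERNS[rng.integers(0, len(_PATTERNS), size=n_sites)]
        ok = True
        checks = list(groups.values()) + [np.arange(n_sites)]
        for idx in checks:
            if len(idx) == 0:
                continue
            sub = pat[idx]
            for a in range(3):
                for b in range(a + 1, 3):
                    if (sub[:, a] != sub[:, b]).mean() < 0.30:
                        ok = False
            if not ok:
                break
        if ok:
            return pat
    raise RuntimeError("could not draw sufficiently diverged lineage patterns")


def _planted_effect(cds: str, idx: int, alt_base: str) -> str:
    """Effect class by full-translation diff (independent of protein_effects)."""
    ref_prot = str(Seq(cds).translate())
    alt = cds[:idx] + alt_base + cds[idx + 1 :]
    alt_prot = str(Seq(alt).translate())
    if alt_prot == ref_prot:
        return "synonymous"
    k = idx // 3
    if k == 0:
        return "start-loss"
    if alt_prot[k] == "*":
        return "nonsense"
    if ref_prot[k] == "*":
        return "stop-loss"
    return "missense"


def simulate_panel(config: PanelConfig):
    """Generate (vcf_text, metadata, truth) for one panel.

    Byte-identical output under a fixed seed.  See the module docstring for
    the generative model.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # ---- locus geometry (paper-like chr1D coordinates, y on minus strand)
    len_x = 3 * (cfg.n_sites_x + 12)
    len_y = 3 * (cfg.n_sites_y + 12)
    gx_start = 419_306_988
    gx_end = gx_start + len_x - 1
    gy_start = gx_start + 57_027
    gy_end = gy_start + len_y - 1
    locus = LocusDefinition(
        "chr1D", (gx_start, gx_end), (gy_start, gy_end), flank=2500, strand_x="+", strand_y="-"
    )
    cds_x = _reference_cds(rng, len_x // 3)
    cds_y = _reference_cds(rng, len_y // 3)
    gene_x = GeneModel("Glu-D1x", "chr1D", ((gx_start, gx_end),), "+", cds_x)
    gene_y = GeneModel("Glu-D1y", "chr1D", ((gy_start, gy_end),), "-", cds_y)
    genome_y = str(Seq(cds_y).reverse_complement())  # genomic (+) strand bases of gene y

    # ---- site positions per region
    def _pick(lo: int, hi: int, k: int) -> np.ndarray:
        if k == 0:
            return np.array([], dtype=int)
        return np.sort(rng.choice(np.arange(lo, hi + 1), size=k, replace=False))

    fl = cfg.n_sites_flank
    quarters = [fl // 4 + (1 if i < fl % 4 else 0) for i in range(4)]
    pos_cx = _pick(gx_start, gx_end, cfg.n_sites_x)
    pos_cy = _pick(gy_start, gy_end, cfg.n_sites_y)
    pos_fx = np.concatenate(
        [_pick(gx_start - 2500, gx_start - 1, quarters[0]), _pick(gx_end + 1, gx_end + 2500, quarters[1])]
    )
    pos_fy = np.concatenate(
        [_pick(gy_start - 2500, gy_start - 1, quarters[2]), _pick(gy_end + 1, gy_end + 2500, quarters[3])]
    )
    # flank-x downstream window must not reach gene y
    assert gx_end + 2500 < gy_start - 2500 or fl == 0

    entries = []  # (pos, region)
    entries += [(int(p), "coding-x") for p in pos_cx]
    entries += [(int(p), "coding-y") for p in pos_cy]
    entries += [(int(p), "flank-x") for p in pos_fx]
    entries += [(int(p), "flank-y") for p in pos_fy]
    entries.sort()
    positions = np.array([p for p, _ in entries])
    regions = np.array([r for _, r in entries])
    n_sites = len(entries)

    # ---- REF/ALT alleles
    refs, alts, effects = [], [], []
    for pos, region in entries:
        if region == "coding-x":
            idx = pos - gx_start
            ref = cds_x[idx]
        elif region == "coding-y":
            ref = genome_y[pos - gy_start]
        else:
            ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        if region == "coding-x":
            effects.append(_planted_effect(cds_x, pos - gx_start, alt))
        elif region == "coding-y":
            cds_idx = gene_y.genomic_to_cds(pos)
            alt_coding = str(Seq(alt).complement())
            effects.append(_planted_effect(cds_y, cds_idx, alt_coding))
        else:
            effects.append("non-coding")
        refs.append(ref)
        alts.append(alt)

    # ---- lineage base alleles and planted haplotype pools
    region_idx = {r: np.where(regions == r)[0] for r in ("coding-x", "coding-y", "flank-x", "flank-y")}
    base = _lineage_patterns(
        rng, n_sites, {r: region_idx[r] for r in ("coding-x", "coding-y")}
    )  # (n_sites, 3)

    x_idx = np.concatenate([region_idx["coding-x"], region_idx["flank-x"]])
    y_idx = np.concatenate([region_idx["coding-y"], region_idx["flank-y"]])
    x_idx.sort()
    y_idx.sort()

    hap_x: dict[str, np.ndarray] = {}
    hap_y: dict[str, np.ndarray] = {}
    for l, lin in enumerate(LINEAGES):
        flips_x = rng.permutation(np.where(np.isin(x_idx, region_idx["coding-x"]))[0])
        flips_y = rng.permutation(np.where(np.isin(y_idx, region_idx["coding-y"]))[0])
        for j in range(cfg.n_haplotypes_x[l]):
            v = base[x_idx, l].copy()
            if j > 0:
                v[flips_x[j - 1]] ^= 1
            hap_x[f"{lin}.x{j}"] = v
        for j in range(cfg.n_haplotypes_y[l]):
            v = base[y_idx, l].copy()
            if j > 0:
                v[flips_y[j - 1]] ^= 1
            hap_y[f"{lin}.y{j}"] = v
    # planted haplotypes must be globally distinct over coding sites
    for pool, idx_set, coding in (
        (hap_x, x_idx, region_idx["coding-x"]),
        (hap_y, y_idx, region_idx["coding-y"]),
    ):
        mask = np.isin(idx_set, coding)
        seen = {}
        for k, v in pool.items():
            key = v[mask].tobytes()
            if key in seen:
                raise RuntimeError(f"planted haplotypes collide: {seen[key]} vs {k}")
            seen[key] = k

    # ---- sample roles and haplotype assignment
    n_per = cfg.n_samples_per_lineage
    rec_lineages: list[int] = []
    l_cycle = [1, 2, 0]  # plant recombinants in L2, then L3, then L1, round-robin
    i = 0
    while len(rec_lineages) < cfg.recombinant_count:
        cand = l_cycle[i % 3]
        if n_per[cand] - rec_lineages.count(cand) > 1:
            rec_lineages.append(cand)
        i += 1
        if i > 3 * (cfg.recombinant_count + 3):
            raise ValueError("cannot place recombinants: lineages too small")
    shared_n = cfg.shared_haplotype_count
    if shared_n and (n_per[0] == 0 or n_per[1] == 0):
        raise ValueError("shared haplotypes need samples in lineages 1 and 2")

    rows = []
    for l, lin in enumerate(LINEAGES):
        n = n_per[l]
        kx, ky = cfg.n_haplotypes_x[l], cfg.n_haplotypes_y[l]
        n_rec = rec_lineages.count(l)
        n_shared = shared_n if l == 1 else 0
        n_regular = n - n_rec - n_shared
        if n_regular < 0:
            raise ValueError(f"lineage {lin} too small for its planted roles")
        for s in range(n):
            name = f"{lin}_S{s:03d}"
            if s < n_regular:
                rows.append((name, lin, f"{lin}.x{s % kx}", f"{lin}.y{s % ky}", False, ""))
            elif s < n_regular + n_shared:
                m = s - n_regular  # shared haplotype m from lineage 1's pool
                rows.append((name, lin, f"L1.x{m % cfg.n_haplotypes_x[0]}",
                             f"L1.y{m % cfg.n_haplotypes_y[0]}", False, ""))
            else:
                donor = LINEAGES[(l + 1) % 3] if n_per[(l + 1) % 3] > 0 else LINEAGES[(l + 2) % 3]
                rows.append((name, lin, f"{lin}.x0", f"{donor}.y0", True, ""))
    # duplicated accessions: re-sequenced copies of regular samples
    sources = [r for r in rows if not r[4]]
    for d in range(cfg.duplicate_pairs):
        src = sources[(d * 7) % len(sources)]
        rows.append((f"{src[0]}_dup", src[1], src[2], src[3], False, src[0]))

    samples_df = pd.DataFrame(
        rows,
        columns=["sample", "lineage", "x_haplotype", "y_haplotype", "is_recombinant", "duplicate_of"],
    )
    sample_names = list(samples_df["sample"])
    n_samples = len(sample_names)

    # ---- true allele matrix (sites x samples)
    truth_alleles = np.zeros((n_sites, n_samples), dtype=np.int8)
    for j, r in enumerate(samples_df.itertuples()):
        truth_alleles[x_idx, j] = hap_x[r.x_haplotype]
        truth_alleles[y_idx, j] = hap_y[r.y_haplotype]

    # ---- sequencing noise: DP, DV, QUAL
    dp = rng.poisson(cfg.mean_depth, size=(n_sites, n_samples))
    dp = np.clip(dp, 2, None)
    p_alt_read = np.where(truth_alleles == 1, 1.0 - cfg.error_rate, cfg.error_rate)
    dv = rng.binomial(dp, p_alt_read)
    low_qual = rng.random(n_sites) < cfg.qual_low_fraction
    qual = np.where(low_qual, rng.uniform(5.0, 40.0, n_sites), rng.uniform(50.0, 250.0, n_sites))
    qual = np.round(qual, 1)

    # ---- metadata (collection sites: lineage centroid + Gaussian jitter)
    lats, lons = [], []
    coords: dict[str, tuple[float, float]] = {}
    for r in samples_df.itertuples():
        if r.duplicate_of:
            lat, lon = coords[r.duplicate_of]
        else:
            c_lat, c_lon = _CENTROIDS[r.lineage]
            sd = _JITTER_SD[r.lineage]
            lat = float(np.clip(c_lat + sd * rng.standard_normal(), -89.9, 89.9))
            lon = float(c_lon + sd * rng.standard_normal())
            coords[r.sample] = (lat, lon)
        lats.append(round(lat, 5))
        lons.append(round(lon, 5))
    metadata = pd.DataFrame(
        {"sample": sample_names, "lineage": samples_df["lineage"], "lat": lats, "lon": lons}
    )

    # ---- genome-wide call table (for duplicate detection)
    n_gw = cfg.n_genomewide_sites
    gw_base = rng.integers(0, 2, size=(n_gw, 3), dtype=np.int8)
    gw = np.zeros((n_gw, n_samples), dtype=np.int8)
    lineage_col = {lin: l for l, lin in enumerate(LINEAGES)}
    private_rate = 0.02
    for j, r in enumerate(samples_df.itertuples()):
        if r.duplicate_of:
            src_j = sample_names.index(r.duplicate_of)
            v = gw[:, src_j].copy()
            flip = rng.integers(0, n_gw)  # one mismatch: identity 1 - 1/n_gw
            v[flip] ^= 1
        else:
            v = gw_base[:, lineage_col[r.lineage]].copy()
            flips = rng.random(n_gw) < private_rate
            v[flips] ^= 1
        gw[:, j] = v
    genomewide = pd.DataFrame(gw, columns=sample_names)

    # ---- truth tables
    sites_df = pd.DataFrame(
        {
            "chrom": locus.chrom,
            "pos": positions,
            "region": regions,
            "ref": refs,
            "alt": alts,
            "is_coding": [r.startswith("coding") for r in regions],
            "planted_effect": effects,
        }
    )
    truth = SyntheticTruth(
        cfg, locus, gene_x, gene_y, samples_df, sites_df, {**hap_x, **hap_y}, genomewide
    )

    # ---- VCF text (VCFv4.2, one ALT per record, FORMAT DP:DV)
    out = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={locus.chrom}>",
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##FORMAT=<ID=DV,Number=1,Type=Integer,Description="Alternate allele read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names),
    ]
    for i in range(n_sites):
        cells = "\t".join(f"{dp[i, j]}:{dv[i, j]}" for j in range(n_samples))
        out.append(
            f"{locus.chrom}\t{positions[i]}\t.\t{refs[i]}\t{alts[i]}\t{qual[i]:.1f}\t.\t.\tDP:DV\t{cells}"
        )
    vcf_text = "\n".join(out) + "\n"
    return vcf_text, metadata, truth


# ---------------------------------------------------------------------------
# k-mer bin simulation


def simulate_kmer_bins(
    n_bins: int,
    bin_size: int = 100_000,
    planted: dict[int, str] | None = None,
    background_rate: float = 2.0,
    seed: int = 0,
    chrom: str = "chr1D",
    assembly: str = "synthetic_assembly",
    lineages: tuple[str, ...] = LINEAGES,
) -> pd.DataFrame:
    """Per-bin lineage-specific k-mer counts with planted lineage bins.

    Planted bins are guaranteed to exceed every other lineage's count by more
    than ``margin_for(bin_size)``; background bins stay within the margin
    (background draws are clipped at the margin), so the classification of
    every bin is determined by construction.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    planted = dict(planted or {})
    for b, lin in planted.items():
        if not (0 <= b < n_bins):
            raise ValueError(f"planted bin {b} out of range [0, {n_bins})")
        if lin not in lineages:
            raise ValueError(f"unknown lineage {lin!r}")
    rng = np.random.default_rng(seed)
    margin = margin_for(bin_size)
    counts = rng.poisson(background_rate, size=(n_bins, len(lineages)))
    counts = np.minimum(counts, int(math.floor(margin)))
    for b, lin in planted.items():
        li = lineages.index(lin)
        others = np.delete(counts[b], li)
        counts[b, li] = int(others.max()) + int(math.ceil(margin)) + 1 + rng.poisson(background_rate)
    df = pd.DataFrame(
        {
            "assembly": assembly,
            "chrom": chrom,
            "bin_start": np.arange(n_bins) * bin_size,
        }
    )
    for li, lin in enumerate(lineages):
        df[f"count_{lin}"] = counts[:, li]
    return df
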