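"""Coding-effect annotation for SNVs against a gene model.

Each coding SNV is classified per-site against the reference codon under the
standard nuclear code (synonymous / missense / nonsense / stop-loss /
start-loss), and cysteine gains/losses are audited because disulfide-bonding
cysteines drive HMW-glutenin dough functionality.  Whole-haplotype CDS and
protein sequences are also built by substituting ALT bases into the
reference CDS.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .variant_core import ALT, VariantSite

__all__ = [
    "GeneModel",
    "CodingEffect",
    "build_haplotype_cds",
    "classify_effects",
    "cysteine_audit",
    "effect_tally",
    "translate_cds",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

NONSYNONYMOUS_CLASSES = ("missense", "nonsense", "stop-loss", "start-loss")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(seq: str) -> str:
    return str(Seq(seq).translate())


@dataclass(frozen=True)
class GeneModel:
    """Single- or multi-interval CDS gene model with its reference sequence.

    Intervals are 1-based inclusive genomic coordinates in ascending order;
    ``cds_seq`` is on the coding strand (reverse-complemented relative to the
    genome for minus-strand genes).
    """

    gene_id: str
    chrom: str
    intervals: tuple[tuple[int, int], ...]
    strand: str
    cds_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        length = sum(e - s + 1 for s, e in self.intervals)
        if length != len(self.cds_seq):
            raise ValueError(
                f"{self.gene_id}: CDS sequence length {len(self.cds_seq)} != interval span {length}"
            )
        if len(self.cds_seq) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)

    def genomic_to_cds(self, pos: int) -> int | None:
        """0-based CDS index of a genomic position, or None outside the CDS."""
        offset = 0
        for s, e in self.intervals:
            if s <= pos <= e:
                fwd = offset + (pos - s)
                return fwd if self.strand == "+" else self.cds_length - 1 - fwd
            offset += e - s + 1
        return None

    def coding_allele(self, pos: int, base: str) -> str:
        """Genomic base mapped onto the coding strand."""
        return base if self.strand == "+" else base.translate(_COMPLEMENT)

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "chrom": self.chrom,
            "intervals": [list(iv) for iv in self.intervals],
            "strand": self.strand,
            "cds_seq": self.cds_seq,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        return cls(
            d["gene_id"],
            d["chrom"],
            tuple(tuple(iv) for iv in d["intervals"]),
            d["strand"],
            d["cds_seq"],
        )


@dataclass(frozen=True)
class CodingEffect:
    gene_id: str
    site: VariantSite
    codon_index: int | None
    ref_codon: str | None
    alt_codon: str | None
    ref_aa: str | None
    alt_aa: str | None
    effect_class: str  # synonymous | missense | nonsense | stop-loss | start-loss | non-coding
    cysteine_delta: int


def _check_ref(gm: GeneModel, site: VariantSite, idx: int) -> None:
    expected = gm.coding_allele(site.pos, site.ref).upper()
    actual = gm.cds_seq[idx].upper()
    if expected != actual:
        raise ValueError(
            f"{gm.gene_id}: REF allele {site.ref!r} at {site.chrom}:{site.pos} does not "
            f"match reference CDS base {actual!r} (CDS index {idx})"
        )


def build_haplotype_cds(gm: GeneModel, alleles, sites: list[VariantSite]) -> str:
    """Reference CDS with ALT bases substituted at the haplotype's ALT sites.

    ``alleles`` aligns with ``sites`` (REF/ALT/MISSING codes); only SNVs
    inside the CDS are applied.  A REF allele mismatching the reference
    sequence is an error naming the position.
    """
    seq = list(gm.cds_seq)
    for allele, site in zip(alleles, sites):
        if len(site.ref) != 1 or len(site.alt) != 1:
            raise ValueError(f"not an SNV at {site.chrom}:{site.pos}")
        idx = gm.genomic_to_cds(site.pos)
        if idx is None:
            continue
        _check_ref(gm, site, idx)
        if allele == ALT:
            seq[idx] = gm.coding_allele(site.pos, site.alt).upper()
    return "".join(seq)


def classify_effects(gm: GeneModel, sites: list[VariantSite]) -> list[CodingEffect]:
    """Per-site codon substitution effects against the reference CDS.

    Sites outside the CDS are classified ``non-coding`` and excluded from
    synonymous/non-synonymous tallies.  The cysteine delta is recorded for
    every non-synonymous substitution that gains or loses a Cys (a stop gain
    that removes a Cys counts as a loss).
    """
    effects: list[CodingEffect] = []
    for site in sites:
        if len(site.ref) != 1 or len(site.alt) != 1:
            raise ValueError(
                f"multi-nucleotide variant at {site.chrom}:{site.pos} not supported"
            )
        idx = gm.genomic_to_cds(site.pos)
        if idx is None:
            effects.append(
                CodingEffect(gm.gene_id, site, None, None, None, None, None, "non-coding", 0)
            )
            continue
        _check_ref(gm, site, idx)
        codon_index, within = divmod(idx, 3)
        ref_codon = gm.cds_seq[3 * codon_index : 3 * codon_index + 3].upper()
        alt_base = gm.coding_allele(site.pos, site.alt).upper()
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        ref_aa = translate_cds(ref_codon)
        alt_aa = translate_cds(alt_codon)
        if ref_aa == alt_aa:
            cls = "synonymous"
        elif codon_index == 0 and ref_codon == "ATG":
            cls = "start-loss"
        elif alt_aa == "*":
            cls = "nonsense"
        elif ref_aa == "*":
            cls = "stop-loss"
        else:
            cls = "missense"
        delta = 0
        if cls != "synonymous":
            delta = int(alt_aa == "C") - int(ref_aa == "C")
        effects.append(
            CodingEffect(
                gm.gene_id, site, codon_index, ref_codon, alt_codon, ref_aa, alt_aa, cls, delta
            )
        )
    return effects


def cysteine_audit(effects: list[CodingEffect], domains: dict | None = None) -> dict:
    """Per-gene counts of Cys-gaining and Cys-losing substitutions.

    ``domains`` optionally restricts the audit to codon-index windows per gene
    (e.g. the N/C terminal domains); default is the whole CDS.  A (0, 0)
    result is the negative finding that no coding variant touches the
    disulfide-bonding capacity.
    """
    out: dict[str, dict[str, int]] = defaultdict(lambda: {"gains": 0, "losses": 0})
    for eff in effects:
        out.setdefault(eff.gene_id, {"gains": 0, "losses": 0})
        if eff.cysteine_delta == 0:
            continue
        if domains and eff.gene_id in domains:
            windows = domains[eff.gene_id]
            if not any(lo <= eff.codon_index <= hi for lo, hi in windows):
                continue
        key = "gains" if eff.cysteine_delta > 0 else "losses"
        out[eff.gene_id][key] += 1
    return dict(out)


def effect_tally(effects: list[CodingEffect]) -> dict:
    """Per-gene synonymous / non-synonymous / non-coding counts."""
    out: dict[str, dict[str, int]] = {}
    for eff in effects:
        t = out.setdefault(
            eff.gene_id, {"synonymous": 0, "nonsynonymous": 0, "non_coding": 0, "coding": 0}
        )
        if eff.effect_class == "non-coding":
            t["non_coding"] += 1
        elif eff.effect_class == "synonymous":
            t["synonymous"] += 1
            t["coding"] += 1
        else:
            t["nonsynonymous"] += 1
            t["coding"] += 1
    return out


def gene_models_from_gff(gff_path, genome_fasta) -> dict[str, GeneModel]:
    """Build gene models from GFF3 CDS features plus a genome FASTA.

    CDS features are grouped by their Parent (falling back to ID); the CDS
    sequence is stitched in genomic order and reverse-complemented for
    minus-strand genes.
    """
    from pyfaidx import Fasta

    groups: dict[str, dict] = {}
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "CDS":
                continue
            chrom, _, _, start, end, _, strand, _, attrs = fields[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("Parent", attr.get("ID", "gene"))
            g = groups.setdefault(gid, {"chrom": chrom, "strand": strand, "ivs": []})
            g["ivs"].append((int(start), int(end)))
    fa = Fasta(str(genome_fasta))
    models = {}
    for gid, g in groups.items():
        ivs = tuple(sorted(g["ivs"]))
        seq = "".join(str(fa[g["chrom"]][s - 1 : e]) for s, e in ivs)
        if g["strand"] == "-":
            seq = _revcomp(seq)
        models[gid] = GeneModel(gid, g["chrom"], ivs, g["strand"], seq.upper())
    return models


def effects_to_tsv(effects: list[CodingEffect], path) -> None:
    rows = []
    for e in effects:
        rows.append(
            {
                "gene": e.gene_id,
                "chrom": e.site.chrom,
                "pos": e.site.pos,
                "ref": e.site.ref,
                "alt": e.site.alt,
                "codon_index": e.codon_index,
                "ref_codon": e.ref_codon,
                "alt_codon": e.alt_codon,
                "ref_aa": e.ref_aa,
                "alt_aa": e.alt_aa,
                "class": e.effect_class,
                "cysteine_delta": e.cysteine_delta,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
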