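#!/usr/bin/env python
"""Classify coding variants and audit cysteine residues.

Each coding SNV is classified against the reference codon (synonymous /
missense / nonsense / start- / stop-loss); cysteines matter because their
disulfide bonds set the strength of the gluten network.  Haplotype protein
sequences are emitted as FASTA for external protein phylogenetics.
"""

import json
from pathlib import Path

from gluhap.haplotyping import group_haplotypes
from gluhap.protein_effects import (
    GeneModel,
    build_haplotype_cds,
    classify_effects,
    cysteine_audit,
    effect_tally,
    effects_to_tsv,
    translate_cds,
)
from gluhap.variant_core import GenotypeMatrix

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    out = ROOT / "effects"
    out.mkdir(parents=True, exist_ok=True)
    m = GenotypeMatrix.from_tsv(ROOT / "genotypes" / "matrix_filtered.tsv")
    with open(ROOT / "panel" / "study" / "gene_models.json") as fh:
        models = {k: GeneModel.from_dict(v) for k, v in json.load(fh).items()}

    effects = []
    for region, gene in (("coding-x", "Glu-D1x"), ("coding-y", "Glu-D1y")):
        sub = m.restrict_regions((region,))
        effects.extend(classify_effects(models[gene], sub.sites))
        part = group_haplotypes(m, (region,))
        with open(out / f"proteins_{region[-1]}.fasta", "w") as fh:
            for hap_id, vec in part.haplotypes.items():
                cds = build_haplotype_cds(models[gene], vec, sub.sites)
                fh.write(f">{gene}_{hap_id}\n{translate_cds(cds)}\n")
    effects_to_tsv(effects, out / "effects.tsv")
    tally = effect_tally(effects)
    audit = cysteine_audit(effects)
    for gene, t in tally.items():
        print(
            f"{gene}: {t['nonsynonymous']} of {t['coding']} coding variants "
            f"non-synonymous ({t['synonymous']} synonymous); cysteine "
            f"gains/losses: {audit[gene]['gains']}/{audit[gene]['losses']}"
        )


if __name__ == "__main__":
    main()
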