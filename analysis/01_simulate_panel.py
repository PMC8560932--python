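#!/usr/bin/env python
"""Generate the synthetic study panels.

Writes two panels under results/panel/:

* ``study/``  — the full-scale panel (117/143/8 accessions per lineage,
  ~10x depth, 308 sites, sequencing noise), the conditions the downstream
  analyses emulate;
* ``fixture/`` — the small zero-noise panel with fully known truth
  (11 combined haplotypes, 2 recombinants, 1 duplicate pair) used for
  validation.
"""

import json
from pathlib import Path

from gluhap.synthetic_data import PanelConfig, fixture_config, simulate_panel

RESULTS = Path(__file__).resolve().parent.parent / "results" / "panel"
SEED = 11


def write_panel(cfg, out):
    out.mkdir(parents=True, exist_ok=True)
    vcf_text, metadata, truth = simulate_panel(cfg)
    (out / "panel.vcf").write_text(vcf_text)
    metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    truth.write(out)
    with open(out / "locus.json", "w") as fh:
        json.dump(truth.locus.to_dict(), fh)
    with open(out / "gene_models.json", "w") as fh:
        json.dump({g.gene_id: g.to_dict() for g in (truth.gene_x, truth.gene_y)}, fh)
    return metadata, truth


def main():
    import dataclasses

    meta, truth = write_panel(dataclasses.replace(PanelConfig(), seed=SEED), RESULTS / "study")
    print(
        f"study panel: {meta.shape[0]} samples, {truth.sites.shape[0]} sites, "
        f"{truth.n_combined_haplotypes()} planted combined haplotypes, "
        f"{len(truth.recombinant_samples())} recombinants"
    )
    meta, truth = write_panel(fixture_config(SEED), RESULTS / "fixture")
    print(
        f"fixture panel: {meta.shape[0]} samples, {truth.n_combined_haplotypes()} "
        f"planted combined haplotypes (zero noise)"
    )


if __name__ == "__main__":
    main()
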