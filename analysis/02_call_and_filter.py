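#!/usr/bin/env python
"""Call genotypes from DV/DP ratios and filter sites for the study panel.

Reports the site funnel: raw locus records -> QUAL/depth-gated calls ->
polymorphic sites passing the MAF (>=1%) and missingness (<=90%) filters.
Also finds duplicated accessions from the genome-wide call table (identity
> 99.8%).
"""

import json
from pathlib import Path

import pandas as pd

from gluhap.variant_core import (
    LocusDefinition,
    apply_site_filters,
    call_genotypes,
    find_duplicates,
    read_vcf_region,
)

PANEL = Path(__file__).resolve().parent.parent / "results" / "panel" / "study"
OUT = Path(__file__).resolve().parent.parent / "results" / "genotypes"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    locus = LocusDefinition.from_dict(json.loads((PANEL / "locus.json").read_text()))
    records = read_vcf_region(PANEL / "panel.vcf", locus)
    m = call_genotypes(records)
    mf = apply_site_filters(m)
    mf.to_tsv(OUT / "matrix_filtered.tsv")
    mf.sites_to_bed(OUT / "sites_filtered.bed")
    print(f"locus records: {len(records.sites)}; retained after filters: {mf.n_sites}")
    missing_frac = (mf.calls == -1).mean()
    print(f"missing-call fraction in the filtered matrix: {missing_frac:.4f}")

    gw = pd.read_csv(PANEL / "truth_genomewide.tsv", sep="\t")
    groups = [g for g in find_duplicates(gw) if len(g) > 1]
    pd.DataFrame({"group": range(len(groups)), "samples": [",".join(g) for g in groups]}).to_csv(
        OUT / "duplicate_groups.tsv", sep="\t", index=False
    )
    print(f"duplicated accessions: {len(groups)} group(s): {groups}")


if __name__ == "__main__":
    main()
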