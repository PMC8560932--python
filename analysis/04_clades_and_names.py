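#!/usr/bin/env python
"""Cluster accessions, cut major-clades/subclades and name the haplotypes.

Genetic distances are Euclidean distances between rows of the additive
relationship matrix; complete-linkage clustering is cut into 3 major clades
and nested subclades, haplotype clades are lifted by carrier majority, and
the subclade-letter nomenclature (Dx1a, Dy1b, x1a+y1b) is assigned.  A
neighbor-joining tree is exported as newick for external viewers.
"""

from pathlib import Path

import pandas as pd

from gluhap.haplotyping import assign_names, combine_subunits, combined_names, group_haplotypes
from gluhap.phylo import (
    additive_relationship,
    clades_for_haplotypes,
    cut_clades,
    distance_from_A,
    hierarchical_cluster,
    neighbor_joining,
    write_newick,
)
from gluhap.variant_core import GenotypeMatrix

ROOT = Path(__file__).resolve().parent.parent / "results"
K_MAJOR, K_SUB = 3, 15


def main():
    out = ROOT / "clades"
    out.mkdir(parents=True, exist_ok=True)
    m = GenotypeMatrix.from_tsv(ROOT / "genotypes" / "matrix_filtered.tsv")
    D = distance_from_A(additive_relationship(m))
    D.write(str(out / "genetic_distances.tsv"))
    dendro = hierarchical_cluster(D)
    k_sub = min(K_SUB, m.n_samples)
    sample_clades = cut_clades(dendro, K_MAJOR, k_sub)
    sample_clades.to_tsv(out / "clades_samples.tsv")

    lineages = pd.read_csv(ROOT / "panel" / "study" / "metadata.tsv", sep="\t")
    merged = lineages.assign(major=[sample_clades.major[s] for s in lineages["sample"]])
    table = merged.groupby(["major", "lineage"]).size().unstack(fill_value=0)
    print("major clade x lineage composition:")
    print(table.to_string())

    px = group_haplotypes(m, ("coding-x",))
    py = group_haplotypes(m, ("coding-y",))
    combined = combine_subunits(px, py)
    xc = clades_for_haplotypes(px, sample_clades)
    yc = clades_for_haplotypes(py, sample_clades)
    names_x = assign_names(px, xc, "x")
    names_y = assign_names(py, yc, "y")
    names_c = combined_names(combined, names_x, names_y)
    px.to_tsv(out / "haplotypes_x_named.tsv", names_x.names)
    py.to_tsv(out / "haplotypes_y_named.tsv", names_y.names)
    combined.to_tsv(out / "haplotypes_combined_named.tsv", names_c.names)
    print(f"named {len(names_x.names)} x and {len(names_y.names)} y haplotypes "
          f"across {len(set(xc.sub.values()))}/{len(set(yc.sub.values()))} subclades")

    (out / "nj_tree.nwk").write_text(write_newick(neighbor_joining(D)))
    print("wrote NJ tree to clades/nj_tree.nwk")


if __name__ == "__main__":
    main()
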