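"""Hypergeometric term enrichment and chromosomal gene-cluster detection."""

from togcn import (
    CascadeParams,
    PipelineConfig,
    detect_genomic_clusters,
    hypergeometric_enrichment,
    simulate_cascade,
)

# enrichment: 4 of a 5-gene term in a 5-gene study from a 20-gene universe
universe = [f"gene{i:02d}" for i in range(20)]
term_map = {"lipid biosynthesis": set(universe[:5])}
study = universe[:4] + [universe[10]]
enr = hypergeometric_enrichment(study, term_map, universe, PipelineConfig())
row = enr.iloc[0]
print(f"term {row['term']!r}: k={row['k']} of K={row['K']} in study n={row['n']} "
      f"(universe N={row['N']}) -> p = {row['p_value']:.6f} (exact 76/15504)")

# positional clustering of the simulated pathway genes
counts, design, catalog, sites, truth = simulate_cascade(CascadeParams(rng_seed=1))
pathway = [g for g in catalog.table["gene_id"] if catalog.roles(g)]
clusters = detect_genomic_clusters(catalog, pathway, PipelineConfig())
print(f"\n{len(clusters)} gene clusters (gap <= 2 Mb, >= 3 genes):")
print(clusters.to_string(index=False))
# the generator plants three multi-megabase enzyme clusters; single-linkage
# clustering along each chromosome should report exactly those
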