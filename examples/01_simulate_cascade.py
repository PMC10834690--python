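"""Simulate a developmental time course with a planted TF cascade.

The generator emits a count matrix (genes x samples), a sample sheet,
a gene catalog, a TF->target binding-site table and the ground truth
(planted levels, regulatory edges, binding sites, DE sets).
"""

from togcn import CascadeParams, simulate_cascade

params = CascadeParams(rng_seed=1)
counts, design, catalog, sites, truth = simulate_cascade(params)

print(f"count matrix: {counts.shape[0]} genes x {counts.shape[1]} samples "
      f"({params.n_stages} stages x {params.n_replicates} replicates)")
print(f"TFs: {len(catalog.tf_ids)}  enzyme genes: {len(catalog.structural_ids)}")
print(f"seed TF: {truth.seed_tf} (declines from stage 1)")
print(f"hub TF:  {truth.hub_tf} (level-2 master regulator)")
print(f"planted regulatory edges: {len(truth.edges)}")
print(f"binding sites: {len(sites)} "
      f"({len(truth.binding_sites)} planted + {len(truth.decoy_sites)} decoys)")
print(f"focal order-3 chain: {' -> '.join(truth.focal_chain)}")
# The focal chain is the designated regulator cascade the analysis
# should rediscover: seed TF -> hub -> level-3 TF -> enzyme gene.
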