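"""Maximum-parsimony tree of the promoter panel with bootstrap support.

Runs a TBR hill-climb over topologies on the simulated promoter alignment,
reports tree length with consistency/retention indices, and attaches
site-resampling bootstrap percentages to the internal branches.
"""

from promdiverge.phylo import bootstrap_support, tbr_search
from promdiverge.simulate import SimulationConfig, gen_promoters

aln, truth = gen_promoters(SimulationConfig(seed=1))
tree = tbr_search(aln, restarts=4, seed=1)
tree = bootstrap_support(aln, reps=50, seed=1, restarts=1, tree=tree)

print(f"most parsimonious tree length: {tree.length} site changes")
print(f"consistency index CI = {tree.ci:.4f} (informative sites: "
      f"{tree.ci_informative:.4f})")
print(f"retention index  RI = {tree.ri:.4f} (informative sites: "
      f"{tree.ri_informative:.4f})")
print("\nNewick with bootstrap support (% of 50 replicates):")
print(tree.newick_with_support())
print("\nThe three species carrying the planted AP1 site should form a")
print("well-supported clade; CI < 1 measures homoplasy accumulated under")
print("the substitution noise.")
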