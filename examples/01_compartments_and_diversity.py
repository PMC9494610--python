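"""Paired PBMC/TIL compartment analysis and clonal diversity.

Simulates one patient's paired blood/tumour repertoires with a known
25% shared-clone fraction, partitions clones into the four sharing
compartments, and compares clonal expansion between the blood clones
that are tumour-shared (cTATs) and the rest.
"""

from tatscreen import (
    RepertoireSimConfig,
    assign_compartments,
    extract_tats,
    gen_paired_repertoires,
    overlap_proportion,
    repertoire_diversity,
)
from tatscreen.compartments import PBMCS_ONLY

cfg = RepertoireSimConfig(n_clones=2000, shared_fraction=0.25, seed=1)
pbmc, til, truth = gen_paired_repertoires(cfg)

assignment = assign_compartments(pbmc, til)
ov = overlap_proportion(assignment, pbmc, til)
print(f"planted shared fraction      : {cfg.shared_fraction:.3f}")
print(f"recovered PBMC shared (seq)  : {ov.pbmc_shared_prop_seq:.3f}")
print(f"recovered PBMC shared (clone): {ov.pbmc_shared_prop_clone:.3f}")

tats = extract_tats(assignment, pbmc)
pbmc_only = pbmc.subset(assignment.keys_in(PBMCS_ONLY))
d_tat = repertoire_diversity(tats)
d_rest = repertoire_diversity(pbmc_only)
print(f"\ncTAT clones      : {d_tat.richness:5d}  clonality {d_tat.clonality:.3f}  gini {d_tat.gini:.3f}")
print(f"PBMC-only clones : {d_rest.richness:5d}  clonality {d_rest.clonality:.3f}  gini {d_rest.gini:.3f}")
print(
    "\nThe sequence-level overlap recovers the planted sharing rate; the\n"
    "clonality and Gini indices summarise clone-size inequality within each\n"
    "compartment (the simulator gives both compartments the same heavy-tailed\n"
    "count distribution, so here they are similar by construction)."
)
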