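"""Core/pan-genome rarefaction with fitted saturation curves.

Builds a 15-genome collection with a 25-family universal core and an open
accessory pool, rarefies over 10 random genome orderings, and fits the
exponential core-decay curve F_c(n) = kappa*exp(-n/tau) + omega and Heaps'
law F_p(n) = K*n**gamma to the mean curves.
"""

import pandas as pd

from pangenet.pangenome import fit_core_decay, fit_pan_growth, rarefy
from pangenet.simulate import PangenomeDesign, generate_pangenome_collection

design = PangenomeDesign(
    n_unassigned=15, core_size=25, cloud_size=60, cloud_presence_prob=0.25,
    within_family_identity=100.0, gene_length_range=(60, 90), seed=2)
collection = generate_pangenome_collection(design)

# at 100% within-family identity the planted truth is the family assignment
families = sorted(set(collection.truth.values()))
matrix = pd.DataFrame(0, index=families, columns=collection.genome_ids)
for genome in collection.genomes:
    for gene_id, _ in genome.genes:
        matrix.loc[collection.truth[gene_id], genome.genome_id] = 1

samples = rarefy(matrix, n_permutations=10, seed=3)
print("mean core sizes:", samples.mean_core().round(1).tolist())
print("mean pan  sizes:", samples.mean_pan().round(1).tolist())

core_fit = fit_core_decay(samples)
pan_fit = fit_pan_growth(samples)
print(f"core decay: omega = {core_fit.params['omega']:.1f} families "
      f"(true core = 25), tau = {core_fit.params['tau']:.2f} genomes")
print(f"pan growth: Heaps gamma = {pan_fit.params['gamma']:.3f} "
      f"(> 0 indicates an open pangenome)")
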