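"""Habitat cores, habitat-specific families, cloud content and pathways.

Plants four habitats x three genomes with an 8-family universal core and
5 private-core families per habitat, then recovers each habitat's core and
specific sets and the cloud content (families spanning <= 2 habitats).
Finishes with a pathway-completeness screen on annotated gene symbols.
"""

import pandas as pd

from pangenet.habitat import (
    ECTOINE_BIOSYNTHESIS,
    HabitatGrouping,
    cloud_content,
    habitat_core,
    habitat_specific,
    pathway_completeness,
)
from pangenet.simulate import PangenomeDesign, generate_pangenome_collection

design = PangenomeDesign(
    n_per_habitat={h: 3 for h in ("rhizosphere", "soil", "marine", "freshwater")},
    core_size=8, habitat_core_size=5, cloud_size=20, cloud_presence_prob=0.2,
    within_family_identity=100.0, gene_length_range=(60, 80), seed=4)
collection = generate_pangenome_collection(design)

families = sorted(set(collection.truth.values()))
matrix = pd.DataFrame(0, index=families, columns=collection.genome_ids)
for genome in collection.genomes:
    for gene_id, _ in genome.genes:
        matrix.loc[collection.truth[gene_id], genome.genome_id] = 1

grouping = HabitatGrouping.from_habitat_map(collection.habitat_map)
specific = habitat_specific(matrix, grouping, mode="core")
for habitat in grouping.habitats:
    core = habitat_core(matrix, grouping, habitat)
    print(f"{habitat}: core = {len(core)} families, specific = {len(specific[habitat])}")
cloud = cloud_content(matrix, grouping, max_habitats=2)
print(f"cloud (families spanning <= 2 habitats): {len(cloud)}")
# each habitat core = 8 universal + 5 private; specific sets are the private
# cores once the other habitats' cores (incl. the universal 8) are subtracted

for symbols in ({"ectA", "ectB", "ectC"}, {"ectA", "ectB"}, set()):
    status = pathway_completeness(symbols, ECTOINE_BIOSYNTHESIS)
    print(f"ectoine biosynthesis with {sorted(symbols) or 'no genes'}: {status}")
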