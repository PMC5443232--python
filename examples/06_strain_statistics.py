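"""Group statistics on the bundled 27-strain characteristics table.

Recomputes the headline descriptive statistics of the genome collection:
overall and per-habitat genome sizes, the one-way ANOVA for habitat effect
on genome size, and the GC-content range.
"""

from pangenet.datasets import load_strain_table, strain_habitat_grouping
from pangenet.genomestats import group_summary, one_way_anova

table = load_strain_table()
sizes = dict(zip(table["strain"], table["genome_size_bp"] / 1e6))
print(f"{len(table)} strains; mean genome {sum(sizes.values())/len(sizes):.2f} Mbp, "
      f"range {min(sizes.values()):.2f}-{max(sizes.values()):.2f} Mbp")

grouping = strain_habitat_grouping(table)
summary = group_summary(sizes, grouping)
for habitat, (n, mean, sd) in sorted(summary.items(), key=lambda kv: -kv[1][1]):
    print(f"  {habitat:18s} {mean:.2f} +/- {sd:.2f} Mbp (n = {n})")

anova = one_way_anova(sizes, grouping)
print(f"habitat effect on genome size: F({anova.df_between},{anova.df_within}) = "
      f"{anova.f_statistic:.2f}, p = {anova.p_value:.2g}")
# a large F with p << 0.001 says mean genome size differs between habitats

gc = table.set_index("strain")["gc_percent"]
print(f"GC content range: {gc.min():.1f}% ({gc.idxmin()}) to {gc.max():.1f}% ({gc.idxmax()})")
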