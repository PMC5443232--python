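"""Bundled reference data.

Ships the published genome characteristics of 27 *Novosphingobium* strains
(strain name, isolation habitat where at least three representatives exist,
assembly size in bp, GC %, gene count, GenBank accession).  Eight strains
carry no habitat label — their isolation site is either unknown or has too
few representatives to form a group.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_STRAIN_TABLE = "novosphingobium_strains.tsv"


def load_strain_table() -> pd.DataFrame:
    """The 27-strain characteristics table as a DataFrame.

    Columns: ``strain``, ``habitat`` (empty string when unassigned),
    ``genome_size_bp``, ``gc_percent``, ``n_genes``, ``accession``.
    """
    with resources.files("pangenet.data").joinpath(_STRAIN_TABLE).open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def strain_habitat_grouping(table: pd.DataFrame | None = None) -> dict[str, list[str]]:
    """Habitat -> strain list for the habitat-assigned strains."""
    table = load_strain_table() if table is None else table
    assigned = table[table["habitat"] != ""]
    return {
        habitat: sorted(group["strain"]) for habitat, group in assigned.groupby("habitat")
    }
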