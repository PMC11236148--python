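"""Packaged reference fixtures.

The study's published composition table (family-level rows with genus and
species counts, class/order assignments and percent-of-total) is shipped
verbatim as package data; helpers expand it into a species-level community
so that composition, C/P and taxonomy machinery can be exercised against
the printed totals. Genus and species identifiers in the expansion are
synthetic placeholders (the survey's 199 binomials are not printed), but
the per-family counts and the full class/order/family skeleton are exact.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .tables import AbundanceTable, TaxonomyTable

__all__ = ["composition_table", "composition_community"]


def composition_table() -> pd.DataFrame:
    """The published family-level composition table.

    Columns: class, order, family, genera (count), species (count),
    percent (as printed, e.g. '8.04%').
    """
    ref = importlib.resources.files("ciliatecomm.data") / "table2_composition.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def composition_community() -> tuple[AbundanceTable, TaxonomyTable]:
    """Expand the composition table into a one-sample, species-level community.

    Each family row contributes `species` placeholder morphospecies named
    ``<Family>_sp<k>``, allocated round-robin to ``<Family>_g<j>`` placeholder
    genera so every genus holds at least one species. All species are present
    once in a single pooled sample, which is the right granularity for
    richness-based summaries (composition percentages, C/P quotient).
    """
    comp = composition_table().rename(columns={"class": "class_"})
    records = []
    for row in comp.itertuples(index=False):
        for k in range(int(row.species)):
            records.append(
                {
                    "species": f"{row.family}_sp{k + 1:02d}",
                    "genus": f"{row.family}_g{k % int(row.genera) + 1}",
                    "family": row.family,
                    "order": row.order,
                    "class": row.class_,
                }
            )
    tax_df = pd.DataFrame(records).set_index("species")
    counts = pd.DataFrame(
        [[1] * len(tax_df)], index=["basin"], columns=tax_df.index
    )
    meta = pd.DataFrame(
        {"ecosystem": ["pooled"], "season": ["pooled"]}, index=["basin"]
    )
    return AbundanceTable(counts, metadata=meta), TaxonomyTable(tax_df)
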