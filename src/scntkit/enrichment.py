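"""Over-representation analysis (ORA) of gene lists against annotation sets.

For a list of n genes drawn from a universe of N, of which K belong to an
annotation set, the p-value of observing an overlap of at least k is the
upper tail of the hypergeometric distribution:

    p = sum_{i >= k} C(K, i) C(N - K, n - i) / C(N, n)

BH adjustment is applied across the sets tested.  The annotation database
itself is user-supplied (GMT); nothing here is specific to GO.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection
from .rescue import benjamini_hochberg

__all__ = ["hypergeometric_ora", "hypergeom_upper_tail"]


def hypergeom_upper_tail(k: int, universe: int, set_size: int, list_size: int) -> float:
    """P(overlap >= k) for a hypergeometric draw.

    ``universe`` = N, ``set_size`` = K (annotated genes), ``list_size`` = n
    (genes drawn).  ``k = 0`` returns 1 exactly.
    """
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe, set_size, list_size))


def hypergeometric_ora(
    gene_list,
    annotation_sets: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``gene_list`` in each set.

    Sets are intersected with the universe first; the gene list must be a
    subset of the universe.  Returns a table sorted by raw p with columns
    set_name, overlap, list_size, set_size, universe_size, p_value, fdr.
    """
    universe = set(universe)
    genes = set(gene_list)
    if not universe:
        raise ValueError("empty universe")
    if not genes:
        raise ValueError("empty gene list")
    outside = genes - universe
    if outside:
        raise ValueError(
            f"{len(outside)} listed gene(s) not in the universe, e.g. {sorted(outside)[:5]}"
        )

    rows = []
    for s in annotation_sets:
        members = set(s.genes) & universe
        overlap = len(genes & members)
        p = hypergeom_upper_tail(overlap, len(universe), len(members), len(genes))
        rows.append(
            {
                "set_name": s.name,
                "overlap": overlap,
                "list_size": len(genes),
                "set_size": len(members),
                "universe_size": len(universe),
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    table["fdr"] = benjamini_hochberg(table["p_value"].to_numpy())
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)
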