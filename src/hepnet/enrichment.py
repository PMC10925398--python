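"""Gene-ontology-style overrepresentation against GMT collections."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GeneSetCollection
from .differential import bh_adjust
from .netmap import _enrichment_rows


def go_fet(
    foreground,
    background,
    gmt: GeneSetCollection,
    min_genes: int = 5,
    z_min: float = 1.96,
    q_max: float = 0.05,
    min_size_on: str = "overlap",
) -> pd.DataFrame:
    """One-tailed FET overrepresentation of a symbol list in each gene set.

    Gene sets are intersected with the background; sets with no background
    members are skipped, and BH correction runs across all tested sets.  The
    ``passes_filter`` flag applies the pruning rule: Z > ``z_min``, BH q <
    ``q_max`` and a minimum gene count — measured on the overlap by default
    (``min_size_on='overlap'``) or on the background-intersected set size
    (``min_size_on='set'``).
    """
    if min_size_on not in ("overlap", "set"):
        raise ValueError("min_size_on must be 'overlap' or 'set'")
    fg = {s.upper() for s in foreground}
    if not fg:
        raise ValueError("foreground is empty")
    bg = {s.upper() for s in background}
    outside = fg - bg
    if outside:
        raise ValueError(f"foreground symbols missing from background: {sorted(outside)[:5]}")

    sets = {gs.set_id: set(gs.genes) for gs in gmt}
    table = _enrichment_rows(fg, sets, bg)
    if not len(table):
        table["q_bh"] = []
        table["description"] = []
        table["passes_filter"] = []
        return table
    table["q_bh"] = bh_adjust(table["p_one_tailed"].to_numpy())
    table["description"] = [gmt[s].description for s in table.index]
    size = table["overlap_k"] if min_size_on == "overlap" else table["set_size_K"]
    table["passes_filter"] = (
        (table["z_score"] > z_min) & (table["q_bh"] < q_max) & (size >= min_genes)
    )
    # stable, content-determined ordering
    table = table.sort_values(["p_one_tailed", "set_id"], kind="stable")
    return table
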