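"""Cross-reference differential results against a writer/eraser/reader table.

Writers add a histone mark, erasers remove it, readers bind it. Flagging a
differential protein as one of these connects a proteome-level change to
the histone-PTM analysis (e.g. a down-regulated methyltransferase next to
an altered methylation mark).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ptmdiff.io_tables import ModifierDB

logger = logging.getLogger(__name__)


def match_modifiers(
    results: pd.DataFrame, db: ModifierDB, organism: str
) -> pd.DataFrame:
    """Flag result rows whose protein is a known chromatin modifier.

    Matching is symbol-first (the catalogue is symbol-centric): a feature
    matches when its ``gene_id`` equals a ``protein_id`` case-insensitively
    for the stated organism, falling back to exact ``uniprot_id`` match.
    Adds ``modifier_match`` (bool), ``modifier_role`` and ``modifier_mark``
    columns; a protein matching several catalogue rows gets all roles/marks
    joined with ';' and is never arbitrarily resolved to one.
    """
    orgs = {o.lower() for o in db.organisms}
    if organism.lower() not in orgs:
        raise KeyError(
            f"organism {organism!r} not in modifier table; available: {db.organisms}"
        )
    sub = db.for_organism(organism)
    by_symbol: dict[str, list[tuple[str, str]]] = {}
    for _, row in sub.iterrows():
        by_symbol.setdefault(str(row["protein_id"]).lower(), []).append(
            (str(row["role"]).lower(), str(row["mark"]).lower())
        )

    out = results.copy()
    n = len(out)
    match = np.zeros(n, dtype=bool)
    roles = np.full(n, "", dtype=object)
    marks = np.full(n, "", dtype=object)
    genes = out["gene_id"] if "gene_id" in out.columns else pd.Series([None] * n)
    accs = out["uniprot_id"] if "uniprot_id" in out.columns else pd.Series([None] * n)
    for i, (gene, acc) in enumerate(zip(genes, accs)):
        hits = None
        if pd.notna(gene) and str(gene).lower() in by_symbol:
            hits = by_symbol[str(gene).lower()]
        elif pd.notna(acc) and str(acc).lower() in by_symbol:
            hits = by_symbol[str(acc).lower()]
        if hits:
            match[i] = True
            roles[i] = ";".join(sorted({r for r, _ in hits}))
            marks[i] = ";".join(sorted({m for _, m in hits}))
            if len(hits) > 1:
                logger.info("feature %s matches %d modifier entries", gene, len(hits))
    out["modifier_match"] = match
    out["modifier_role"] = roles
    out["modifier_mark"] = marks
    return out
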