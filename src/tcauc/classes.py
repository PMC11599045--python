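"""Seven-class response categorization and threshold gene sets.

Given two per-gene log2 AUC-ratio contrasts — a chronic one (e.g. CHyp vs
Norm) and an acute one (AHyp vs Norm) — every gene is assigned exactly one
of seven labels:

    ChH  up in the chronic contrast only
    AcH  up in the acute contrast only
    HH   up in both
    ChL  down in the chronic contrast only
    AcL  down in the acute contrast only
    LL   down in both
    NC   not changed

"Up" means log2 ratio strictly above ``up_thr`` and "down" strictly below
``-down_thr`` (defaults 1.0 log2 unit, i.e. twofold; configurable — the
cut is a conventional fold threshold, recorded in the output metadata).
Genes up in one contrast and down in the other are not covered by the
quadrant picture; they are assigned the direction-specific label of the
axis with the larger |log2 ratio| (ties go to NC) and flagged
``discordant`` so they remain auditable.

Directional gene sets (e.g. ConA_up / ConA_down) collect the genes whose
log2 ratio exceeds a fold threshold strictly — "more than fourfold" means
|log2 ratio| > 2.0.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .auc import AUCContrast
from .io import GeneSet, GeneSetCollection

__all__ = ["CLASS_LABELS", "ClassAssignment", "classify_genes", "build_direction_gene_sets"]

CLASS_LABELS = ("ChH", "AcH", "HH", "ChL", "AcL", "LL", "NC")


@dataclass
class ClassAssignment:
    """Per-gene class labels with the ratios and thresholds that produced them.

    ``table``: indexed by gene_id, columns ``log2_ratio_chronic``,
    ``log2_ratio_acute``, ``class``, ``discordant``.
    """

    table: pd.DataFrame
    up_thr: float
    down_thr: float

    def counts(self) -> pd.Series:
        return self.table["class"].value_counts().reindex(CLASS_LABELS, fill_value=0)

    def genes_in(self, label: str) -> list[str]:
        if label not in CLASS_LABELS:
            raise KeyError(f"unknown class {label!r}")
        return list(self.table.index[self.table["class"] == label])

    def to_tsv(self, path) -> None:
        from .io import FLOAT_FORMAT

        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# up_thr={self.up_thr:g} down_thr={self.down_thr:g} (log2 units)\n")
            self.table.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT, index_label="gene_id")


def classify_genes(
    chronic: AUCContrast,
    acute: AUCContrast,
    up_thr: float = 1.0,
    down_thr: float = 1.0,
) -> ClassAssignment:
    """Partition the gene universe into the seven response classes."""
    if up_thr <= 0 or down_thr <= 0:
        raise ValueError("thresholds must be > 0 log2 units")
    if set(chronic.genes) != set(acute.genes):
        only_c = sorted(set(chronic.genes) - set(acute.genes))[:5]
        only_a = sorted(set(acute.genes) - set(chronic.genes))[:5]
        raise ValueError(
            f"gene universes differ: only-chronic {only_c}..., only-acute {only_a}..."
        )
    u_c = chronic.log2_ratio
    u_a = acute.log2_ratio.reindex(u_c.index)

    cu = u_c.to_numpy() > up_thr
    cd = u_c.to_numpy() < -down_thr
    au = u_a.to_numpy() > up_thr
    ad = u_a.to_numpy() < -down_thr

    labels = np.full(len(u_c), "NC", dtype=object)
    discordant = np.zeros(len(u_c), dtype=bool)

    labels[cu & au] = "HH"
    labels[cd & ad] = "LL"
    labels[cu & ~au & ~ad] = "ChH"
    labels[au & ~cu & ~cd] = "AcH"
    labels[cd & ~au & ~ad] = "ChL"
    labels[ad & ~cu & ~cd] = "AcL"

    # opposite directions: the dominant axis decides, exact ties stay NC
    disc = (cu & ad) | (cd & au)
    if disc.any():
        abs_c = np.abs(u_c.to_numpy())
        abs_a = np.abs(u_a.to_numpy())
        chronic_wins = disc & (abs_c > abs_a)
        acute_wins = disc & (abs_a > abs_c)
        labels[chronic_wins & cu] = "ChH"
        labels[chronic_wins & cd] = "ChL"
        labels[acute_wins & au] = "AcH"
        labels[acute_wins & ad] = "AcL"
        labels[disc & (abs_c == abs_a)] = "NC"
        discordant[disc] = True

    table = pd.DataFrame(
        {
            "log2_ratio_chronic": u_c,
            "log2_ratio_acute": u_a,
            "class": labels,
            "discordant": discordant,
        },
        index=u_c.index,
    )
    return ClassAssignment(table=table, up_thr=up_thr, down_thr=down_thr)


def build_direction_gene_sets(
    contrast: AUCContrast,
    threshold: float = 2.0,
    name_prefix: str = "set",
    allow_empty: bool = False,
) -> GeneSetCollection:
    """Directional gene sets from one contrast at a strict fold threshold.

    ``<prefix>_up`` holds genes with log2 ratio > threshold, and
    ``<prefix>_down`` those with log2 ratio < -threshold. The default
    threshold 2.0 log2 units corresponds to "more than fourfold". An
    empty resulting set is an error unless ``allow_empty`` is set, in
    which case a warning is recorded and the set is emitted empty.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0 log2 units")
    r = contrast.log2_ratio
    up = list(r.index[r > threshold])
    down = list(r.index[r < -threshold])
    sets = []
    for suffix, members in (("up", up), ("down", down)):
        name = f"{name_prefix}_{suffix}"
        if not members:
            msg = f"gene set {name!r} is empty at threshold {threshold:g}"
            if not allow_empty:
                raise ValueError(msg)
            warnings.warn(msg)
            gs = GeneSet.__new__(GeneSet)  # bypass non-empty invariant deliberately
            gs.name, gs.description, gs.members = name, f"|log2 ratio| > {threshold:g} ({contrast.name})", []
            sets.append(gs)
        else:
            sets.append(
                GeneSet(name, f"|log2 ratio| > {threshold:g} ({contrast.name})", members)
            )
    return GeneSetCollection(sets)
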