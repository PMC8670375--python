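"""Protein qualification and ON/OFF presence calling.

A protein qualifies for quantification in a given (strain, fraction,
condition) when it (i) was identified with at least ``min_unique_peptides``
unique peptides, (ii) was detected in at least ``min_replicates`` of the
biological replicates of that condition, and (iii) its predicted subcellular
localization is compatible with the fraction.  Cell-wall proteins are
excluded from every fraction (no cell-wall enrichment is performed), as are
proteins of unknown localization; the compatibility table is overridable.

Presence calls compare the two conditions within a (strain, fraction):
a protein qualified only under induction is ON, only in the control is OFF,
in both conditions is "both" (and proceeds to the fold-change test), and
otherwise "neither".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io import AnnotationMaps
from .simulate import CONTROL, INDUCED

#: localization class -> set of compatible fractions (default reading of the
#: PSORTb classes; Cellwall and Unknown are excluded everywhere)
DEFAULT_COMPATIBILITY: Mapping[str, frozenset] = {
    "Cytoplasmic": frozenset({"cytosolic"}),
    "CytoplasmicMembrane": frozenset({"membrane"}),
    "Extracellular": frozenset({"extracellular"}),
    "Cellwall": frozenset(),
    "Unknown": frozenset(),
}

CALL_ON = "ON"
CALL_OFF = "OFF"
CALL_BOTH = "both"
CALL_NEITHER = "neither"


@dataclass
class QualifiedSet:
    """Per (strain, fraction, condition, protein): replicate detection counts
    and the qualification verdict."""

    counts: pd.DataFrame  # strain, fraction, condition, protein,
    #                       n_detected, unique_peptides, loc_ok, qualified
    min_unique_peptides: int = 2
    min_replicates: int = 2

    def qualified(self, strain: str, fraction: str, condition: str) -> set[str]:
        c = self.counts
        m = (
            (c["strain"] == strain)
            & (c["fraction"] == fraction)
            & (c["condition"] == condition)
            & c["qualified"]
        )
        return set(c.loc[m, "protein"])

    def observed(self, strain: str, fraction: str) -> set[str]:
        c = self.counts
        m = (c["strain"] == strain) & (c["fraction"] == fraction)
        return set(c.loc[m, "protein"])

    def qualified_union(self, strain: str, condition: str) -> set[str]:
        """Union over fractions of the qualified proteins of one condition."""
        c = self.counts
        m = (c["strain"] == strain) & (c["condition"] == condition) & c["qualified"]
        return set(c.loc[m, "protein"])


def qualify_proteins(
    table: pd.DataFrame,
    maps: AnnotationMaps,
    min_unique_peptides: int = 2,
    min_replicates: int = 2,
    compatibility: Mapping[str, frozenset] | None = None,
) -> QualifiedSet:
    """Apply the qualification filters to a validated quantification table."""
    compat = dict(DEFAULT_COMPATIBILITY)
    if compatibility:
        compat.update({k: frozenset(v) for k, v in compatibility.items()})

    grouped = (
        table.groupby(
            ["strain", "fraction", "condition", "protein"], sort=True, observed=True
        )
        .agg(
            n_detected=("replicate", "nunique"),
            unique_peptides=("unique_peptides", "max"),
        )
        .reset_index()
    )
    loc = grouped["protein"].map(maps.localization).fillna("Unknown")
    grouped["loc_ok"] = [
        frac in compat.get(cls, frozenset())
        for frac, cls in zip(grouped["fraction"], loc)
    ]
    grouped["qualified"] = (
        (grouped["unique_peptides"] >= min_unique_peptides)
        & (grouped["n_detected"] >= min_replicates)
        & grouped["loc_ok"]
    )
    return QualifiedSet(
        counts=grouped,
        min_unique_peptides=min_unique_peptides,
        min_replicates=min_replicates,
    )


def call_presence(qs: QualifiedSet, strict_absence: bool = False) -> pd.DataFrame:
    """Assign ON / OFF / both / neither per (strain, fraction, protein).

    By default "absent from a condition" means failing qualification there
    (the quantification-centric reading).  With ``strict_absence`` the protein
    must additionally have zero detected replicates in the other condition.
    """
    c = qs.counts
    wide = c.pivot_table(
        index=["strain", "fraction", "protein"],
        columns="condition",
        values=["qualified", "n_detected"],
        aggfunc="first",
    )
    q_ind = wide.get(("qualified", INDUCED), pd.Series(False, index=wide.index)).eq(True)
    q_ctl = wide.get(("qualified", CONTROL), pd.Series(False, index=wide.index)).eq(True)
    n_ind = wide.get(("n_detected", INDUCED), pd.Series(0, index=wide.index)).fillna(0)
    n_ctl = wide.get(("n_detected", CONTROL), pd.Series(0, index=wide.index)).fillna(0)

    on = q_ind & ~q_ctl
    off = q_ctl & ~q_ind
    if strict_absence:
        on &= n_ctl == 0
        off &= n_ind == 0
    both = q_ind & q_ctl

    call = pd.Series(CALL_NEITHER, index=wide.index, name="call")
    call[on] = CALL_ON
    call[off] = CALL_OFF
    call[both] = CALL_BOTH
    out = call.reset_index()
    return out
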