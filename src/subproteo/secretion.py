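"""Sec-pathway secretome statistics.

The headline quantity is the Sec proportion: the percentage of the summed
extracellular LFQ intensity attributable to proteins with a predicted
Sec-type signal peptide, among the proteins qualified in the extracellular
fraction under induction.  It is computed per biological replicate and then
averaged (so a standard deviation across replicates exists); a
pooled-intensity variant is available.  Intensities are linear - a summed
intensity is only meaningful on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationMaps
from .qualify import QualifiedSet
from .simulate import INDUCED


@dataclass
class SecProportion:
    """Sec-secretion proportion for one strain (percent of summed intensity)."""

    strain: str
    per_replicate: pd.Series  # replicate -> percent
    mean: float
    sd: float
    n_sec_quantified: int
    pooled: float


def sec_proportion(
    table: pd.DataFrame,
    qs: QualifiedSet,
    maps: AnnotationMaps,
    strain: str,
    condition: str = INDUCED,
    fraction: str = "extracellular",
) -> SecProportion:
    """Percent of summed extracellular intensity from Sec-signal-peptide
    proteins, per replicate and averaged.
    """
    if table.attrs.get("is_log2", False):
        raise ValueError("sec_proportion needs linear intensities")
    qualified = qs.qualified(strain, fraction, condition)
    sub = table[
        (table["strain"] == strain)
        & (table["condition"] == condition)
        & (table["fraction"] == fraction)
        & table["protein"].isin(qualified)
    ]
    if sub.empty or sub["intensity"].sum() <= 0:
        raise ValueError(
            f"no qualified intensity in {strain}/{condition}/{fraction}"
        )
    sp = sub["protein"].map(maps.sec_sp).fillna(False).astype(bool)
    per_rep = (
        sub.assign(sp=sp)
        .groupby("replicate")
        .apply(
            lambda g: 100.0 * g.loc[g["sp"], "intensity"].sum() / g["intensity"].sum(),
            include_groups=False,
        )
    )
    pooled = 100.0 * sub.loc[sp.to_numpy(), "intensity"].sum() / sub["intensity"].sum()
    n_sec = int(sub.loc[sp.to_numpy(), "protein"].nunique())
    return SecProportion(
        strain=strain,
        per_replicate=per_rep,
        mean=float(per_rep.mean()),
        sd=float(per_rep.std(ddof=1)) if len(per_rep) > 1 else 0.0,
        n_sec_quantified=n_sec,
        pooled=float(pooled),
    )


def compare_sec_proportions(a: SecProportion, b: SecProportion):
    """Two-sided t test on the per-replicate proportions of two strains."""
    t, p = stats.ttest_ind(
        a.per_replicate.to_numpy(), b.per_replicate.to_numpy(), equal_var=True
    )
    return float(t), float(p)


def secreted_regulation_ratio(
    classed_by_strain: dict[str, pd.DataFrame],
    maps: AnnotationMaps,
    category: str = "Secreted proteins",
):
    """Count ON + significantly-upregulated proteins in the secreted-protein
    functional category per strain, and the ratio between the two strains.

    Returns ``(counts, ratio)`` where ratio is first strain / second strain
    (None when the denominator is zero).
    """
    members = {
        p
        for p, paths in maps.categories.items()
        if any(category in path for path in paths)
    }
    if not members:
        raise ValueError(f"category {category!r} absent from the annotation map")
    counts = {}
    for strain, classed in classed_by_strain.items():
        hits = classed[
            classed["protein"].isin(members) & classed["class"].isin(["ON", "up"])
        ]
        counts[strain] = int(hits["protein"].nunique())
    strains = list(counts)
    ratio = None
    if len(strains) == 2 and counts[strains[1]] > 0:
        ratio = counts[strains[0]] / counts[strains[1]]
    return counts, ratio


def mislocalization_check(
    qs: QualifiedSet,
    maps: AnnotationMaps,
    strain: str,
    condition: str = INDUCED,
    cell_fractions: tuple[str, ...] = ("cytosolic", "membrane"),
    secreted_fraction: str = "extracellular",
) -> list[str]:
    """Sec-signal-peptide proteins stuck inside the cell: qualified in a
    cytosolic or membrane fraction under induction but not extracellularly."""
    sp = maps.sec_positive
    in_cell = set()
    for fraction in cell_fractions:
        in_cell |= qs.qualified(strain, fraction, condition)
    outside = qs.qualified(strain, secreted_fraction, condition)
    return sorted(str(p) for p in (in_cell & sp) - outside)
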