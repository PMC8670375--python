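"""Category / regulon aggregation, core-proteome intersections, PCA QC and
treemap weight/color export.

Functional category paths (up to 4 levels, SubtiWiki-export style) are first
completed to exactly 4 levels by repeating the deepest available label, so a
protein annotated only to "Metabolism / Carbon" is counted at levels 3 and 4
under "Carbon" as well.  Tallies count (protein, group) incidences: a protein
assigned to several categories or regulons increments each of them.

The treemap layout itself is not computed here; the export is the weighted
hierarchy plus a per-protein color value (the log2 difference on a symmetric
orange/turquoise scale, with sentinel colors for ON, OFF, gene-deleted and
unidentified proteins) that any Voronoi-treemap renderer can consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.decomposition import PCA

from .io import AnnotationMaps, MAX_CATEGORY_LEVELS
from .simulate import CONTROL, INDUCED

ALTERED_CLASSES = ("up", "down", "ON", "OFF")
CLASS_ORDER = ("up", "down", "unchanged", "ON", "OFF")

ON_COLOR = "#cc5500"  # dark orange sentinel
OFF_COLOR = "#00868b"  # dark turquoise sentinel
MISSING_COLOR = "#d3d3d3"  # unidentified / gene-deleted


def backfill_category_levels(
    categories: Mapping[str, list[tuple[str, ...]]],
) -> dict[str, list[tuple[str, ...]]]:
    """Extend every category path to 4 levels by repeating its deepest label.

    Proteins with only empty paths are dropped (treated as unannotated).
    """
    out: dict[str, list[tuple[str, ...]]] = {}
    for protein, paths in categories.items():
        filled = []
        for path in paths:
            path = tuple(p for p in path if p)
            if not path:
                continue
            if len(path) > MAX_CATEGORY_LEVELS:
                raise ValueError(f"category path deeper than 4 levels: {path}")
            filled.append(path + (path[-1],) * (MAX_CATEGORY_LEVELS - len(path)))
        if filled:
            out[protein] = filled
    return out


def _protein_groups(maps: AnnotationMaps, grouping: str, level: int):
    """protein -> list of group labels under the requested grouping."""
    if grouping == "regulon":
        return {p: [r for r, _ in regs] for p, regs in maps.regulons.items()}
    if grouping == "category":
        if not 1 <= level <= MAX_CATEGORY_LEVELS:
            raise ValueError("category level must be 1..4")
        filled = backfill_category_levels(maps.categories)
        return {
            p: sorted({path[level - 1] for path in paths})
            for p, paths in filled.items()
        }
    raise ValueError(f"unknown grouping {grouping!r}")


def tally_by_group(
    classed: pd.DataFrame,
    maps: AnnotationMaps,
    grouping: str = "category",
    level: int = 2,
    deleted_genes: set[str] | None = None,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Count regulation classes per functional group and strain.

    Proteins without annotation fall into an "unannotated" group.  A protein
    appearing in several fractions is counted once per (strain, group) with
    its most extreme class (ON/OFF > up/down > unchanged).  ``deleted_genes``
    adds a per-group deleted count; ``universe`` (all annotated proteins)
    adds an unidentified count.
    """
    groups = _protein_groups(maps, grouping, level)
    rank = {c: i for i, c in enumerate(("unchanged", "up", "down", "OFF", "ON"))}
    dedup = (
        classed.assign(_rank=classed["class"].map(rank))
        .sort_values("_rank")
        .drop_duplicates(["strain", "protein"], keep="last")
    )
    rows = []
    for _, r in dedup.iterrows():
        for g in groups.get(r["protein"], ["unannotated"]):
            rows.append((r["strain"], g, r["protein"], r["class"]))
    inc = pd.DataFrame(rows, columns=["strain", "group", "protein", "class"])
    if inc.empty:
        return pd.DataFrame(
            columns=["strain", "group", *CLASS_ORDER, "n", "frac_significant"]
        )
    tally = (
        inc.pivot_table(
            index=["strain", "group"],
            columns="class",
            values="protein",
            aggfunc="count",
            fill_value=0,
        )
        .reindex(columns=CLASS_ORDER, fill_value=0)
        .reset_index()
    )
    tally["n"] = tally[list(CLASS_ORDER)].sum(axis=1)
    tally["frac_significant"] = (tally["up"] + tally["down"]) / tally["n"]
    if deleted_genes is not None:
        del_counts = {}
        for p in deleted_genes:
            for g in groups.get(p, ["unannotated"]):
                del_counts[g] = del_counts.get(g, 0) + 1
        tally["deleted"] = tally["group"].map(del_counts).fillna(0).astype(int)
    if universe is not None:
        seen = inc.groupby("strain")["protein"].apply(set)
        unid = []
        for _, r in tally.iterrows():
            members = {p for p, gs in groups.items() if r["group"] in gs}
            unid.append(len(members - seen.get(r["strain"], set())))
        tally["unidentified"] = unid
    return tally


@dataclass
class VennCounts:
    """All region counts of a 4-set Venn diagram over qualified sets."""

    regions: dict[str, int]  # exact-membership regions, keyed by sorted labels
    core: int
    union: int


def core_proteome(sets: Mapping[str, set]) -> VennCounts:
    """Region counts for the four qualified sets (2 strains x 2 conditions).

    Region keys name the sets a protein belongs to (joined with "&"); the 15
    non-empty membership patterns partition the union, and ``core`` counts
    proteins present in all four sets.
    """
    labels = list(sets)
    if len(labels) != 4:
        raise ValueError("core_proteome expects exactly 4 sets")
    union = set().union(*sets.values())
    regions: dict[str, int] = {}
    for k in range(1, 5):
        for combo in combinations(labels, k):
            exact = set.intersection(*(sets[l] for l in combo))
            for other in labels:
                if other not in combo:
                    exact = exact - sets[other]
            regions["&".join(combo)] = len(exact)
    core = len(set.intersection(*sets.values()))
    return VennCounts(regions=regions, core=core, union=len(union))


def total_altered(classed: pd.DataFrame, per_fraction: bool = False):
    """Number of proteins altered upon induction (up, down, ON or OFF).

    By default a protein altered in any fraction counts once per strain;
    ``per_fraction`` returns counts per (strain, fraction) instead.
    """
    altered = classed[classed["class"].isin(ALTERED_CLASSES)]
    if per_fraction:
        return (
            altered.groupby(["strain", "fraction"])["protein"].nunique().to_dict()
        )
    return altered.groupby("strain")["protein"].nunique().to_dict()


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # condition, replicate, PC1, PC2
    explained_variance_ratio: tuple[float, float]
    ellipses: dict[str, dict]
    separated: bool
    degenerate: bool


def pca_qc(
    log2_table: pd.DataFrame,
    strain: str,
    fraction: str | None = None,
    n_replicates: int = 3,
) -> PCAResult:
    """Replicate-level PCA on the complete-case protein matrix of one strain.

    Samples are the condition/replicate columns; features are the proteins
    observed in every sample.  Reports the first two components, 95%
    confidence ellipses per condition, and whether the condition centroids
    separate beyond the within-condition spread.
    """
    sub = log2_table[log2_table["strain"] == strain]
    if fraction is not None:
        sub = sub[sub["fraction"] == fraction]
    wide = sub.pivot_table(
        index="protein",
        columns=["condition", "replicate"],
        values="intensity",
        aggfunc="mean",
    ).dropna(axis=0)
    if wide.shape[1] < 3:
        raise ValueError("PCA QC needs at least 3 replicate samples")
    X = wide.to_numpy().T  # samples x proteins
    degenerate = bool(np.allclose(X.std(axis=0), 0))
    n_comp = min(2, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)
    if n_comp < 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    evr = tuple(pca.explained_variance_ratio_[:2]) + (0.0, 0.0)
    frame = pd.DataFrame(
        {
            "condition": [c for c, _ in wide.columns],
            "replicate": [r for _, r in wide.columns],
            "PC1": coords[:, 0],
            "PC2": coords[:, 1],
        }
    )
    ellipses = {}
    scale = chi2.ppf(0.95, df=2)
    for cond, grp in frame.groupby("condition"):
        xy = grp[["PC1", "PC2"]].to_numpy()
        center = xy.mean(axis=0)
        if len(xy) < 2 or np.allclose(xy.std(axis=0), 0):
            ellipses[cond] = {
                "center": center.tolist(),
                "width": 0.0,
                "height": 0.0,
                "angle_deg": 0.0,
                "degenerate": True,
            }
            continue
        cov = np.cov(xy.T)
        vals, vecs = np.linalg.eigh(np.atleast_2d(cov))
        vals = np.clip(vals, 0, None)
        angle = float(np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1])))
        ellipses[cond] = {
            "center": center.tolist(),
            "width": float(2 * np.sqrt(scale * vals[-1])),
            "height": float(2 * np.sqrt(scale * vals[0])),
            "angle_deg": angle,
            "degenerate": False,
        }
    centroids = frame.groupby("condition")[["PC1", "PC2"]].mean()
    separated = False
    if len(centroids) == 2:
        between = np.linalg.norm(centroids.iloc[0] - centroids.iloc[1])
        within = frame.groupby("condition")[["PC1", "PC2"]].std().fillna(0).mean().mean()
        separated = bool(between > 2 * max(within, 1e-12))
    return PCAResult(
        coordinates=frame,
        explained_variance_ratio=(float(evr[0]), float(evr[1])),
        ellipses=ellipses,
        separated=separated,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# treemap export
# ---------------------------------------------------------------------------


def _diff_color(difference: float, max_abs: float) -> str:
    """Symmetric orange (positive) / turquoise (negative) scale around 0."""
    if max_abs <= 0:
        frac = 0.0
    else:
        frac = float(np.clip(difference / max_abs, -1.0, 1.0))
    if frac >= 0:
        target = (204, 85, 0)  # orange
    else:
        target = (0, 134, 139)  # turquoise
    white = np.array([255, 255, 255], dtype=float)
    rgb = (white + (np.array(target) - white) * abs(frac)).round().astype(int)
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def treemap_export(
    classed: pd.DataFrame,
    maps: AnnotationMaps,
    strain: str,
    grouping: str = "category",
    deleted_genes: set[str] | None = None,
    universe: set[str] | None = None,
) -> dict:
    """Build the weighted, colored hierarchy for one strain.

    Leaf nodes are proteins (weight 1, color from the log2 difference or a
    sentinel); internal weights are the sums of their children.  ``universe``
    adds unidentified proteins (sentinel color) so both strains can share a
    layout.
    """
    deleted_genes = deleted_genes or set()
    sub = classed[classed["strain"] == strain]
    rank = {c: i for i, c in enumerate(("unchanged", "up", "down", "OFF", "ON"))}
    dedup = (
        sub.assign(_rank=sub["class"].map(rank))
        .sort_values("_rank")
        .drop_duplicates("protein", keep="last")
        .set_index("protein")
    )
    finite = dedup["difference"].dropna()
    max_abs = float(finite.abs().max()) if len(finite) else 0.0

    if grouping == "category":
        paths_by_protein = backfill_category_levels(maps.categories)
    elif grouping == "regulon":
        paths_by_protein = {
            p: [(r,) for r, _ in regs] for p, regs in maps.regulons.items()
        }
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    proteins = set(dedup.index)
    if universe is not None:
        proteins |= set(universe) & set(paths_by_protein)

    root = {"name": strain, "weight": 0, "children": {}}
    for protein in sorted(proteins):
        for path in paths_by_protein.get(protein, [("unannotated",)]):
            if protein in dedup.index:
                cls = dedup.loc[protein, "class"]
                diff = dedup.loc[protein, "difference"]
                if protein in deleted_genes:
                    color, status = MISSING_COLOR, "deleted"
                elif cls == "ON":
                    color, status = ON_COLOR, "ON"
                elif cls == "OFF":
                    color, status = OFF_COLOR, "OFF"
                else:
                    color, status = _diff_color(diff, max_abs), cls
                diff_val = None if pd.isna(diff) else float(diff)
            else:
                color, status, diff_val = (
                    MISSING_COLOR,
                    "deleted" if protein in deleted_genes else "unidentified",
                    None,
                )
            node = root
            for label in path:
                node = node["children"].setdefault(
                    label, {"name": label, "weight": 0, "children": {}}
                )
            node["children"][protein] = {
                "name": protein,
                "weight": 1,
                "color": color,
                "status": status,
                "difference": diff_val,
                "children": {},
            }

    def _finalize(node):
        children = [_finalize(c) for c in node["children"].values()]
        out = {"name": node["name"], "weight": node.get("weight", 0)}
        if children:
            out["children"] = children
            out["weight"] = sum(c["weight"] for c in children)
        else:
            out.update(
                {
                    k: node[k]
                    for k in ("color", "status", "difference")
                    if k in node
                }
            )
        return out

    return _finalize(root)


def write_treemap(tree: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(tree, fh, indent=1, sort_keys=True)


def read_treemap(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
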