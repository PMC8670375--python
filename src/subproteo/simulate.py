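"""Synthetic LFQ proteomics and plate-reader data with known ground truth.

The generator emulates a two-strain, two-condition (control vs induced),
three-fraction (cytosolic / membrane / extracellular) label-free quantification
experiment with three biological replicates per condition.  Protein-level
log2 intensities are drawn from a normal baseline distribution; regulated
proteins receive a +/- ``effect_log2`` shift in the induced condition; and
each individual measurement is detected with a logistic probability in its
expected log2 intensity, so missingness is missing-not-at-random and low
abundance proteins drop out first.  Presence-regulated proteins (ON / OFF)
have their detection probability forced to zero in the condition where they
must be absent.  Undetected measurements are absent rows, never zeros.

A separate generator produces 96-well plate-reader growth/fluorescence time
series (logistic OD600, GFP accumulating proportionally to a configurable
promoter activity, shared background fluorescence, dedicated reporter-free
control wells) for the live-cell-array stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

# Canonical condition / fraction / localization vocabulary used pipeline-wide.
CONTROL = "control"
INDUCED = "induced"
CONDITIONS = (CONTROL, INDUCED)

FRACTIONS = ("cytosolic", "membrane", "extracellular")

LOC_CYTOPLASMIC = "Cytoplasmic"
LOC_MEMBRANE = "CytoplasmicMembrane"
LOC_EXTRACELLULAR = "Extracellular"
LOC_CELLWALL = "Cellwall"
LOC_UNKNOWN = "Unknown"

#: localization class -> fraction in which such proteins are actually measured
_LOC_TO_FRACTION = {
    LOC_CYTOPLASMIC: "cytosolic",
    LOC_MEMBRANE: "membrane",
    LOC_EXTRACELLULAR: "extracellular",
}

CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_UNCHANGED = "unchanged"
CLASS_ON = "ON"
CLASS_OFF = "OFF"
TRUE_CLASSES = (CLASS_UP, CLASS_DOWN, CLASS_UNCHANGED, CLASS_ON, CLASS_OFF)

SECRETED_CATEGORY = ("Cellular processes", "Secreted proteins")

_REGULON_POOL = (
    ("SigB", "activation"),
    ("SigW", "activation"),
    ("Spx", "activation"),
    ("PurR", "repression"),
    ("PyrR", "repression"),
    ("TnrA", "repression"),
    ("CssR", "activation"),
    ("Stringent response", "other"),
)

_CATEGORY_ROOTS = (
    "Metabolism",
    "Information processing",
    "Cellular processes",
    "Lifestyle adaptations",
    "Groups of genes",
)


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimConfig:
    """Parameters of the synthetic LFQ experiment.

    Intensity parameters are on the log2 scale of MaxQuant-style LFQ
    intensities (typical real data spans roughly log2 22-34).  ``noise_log2_sd``
    is the replicate-to-replicate measurement noise.  Detection follows
    ``p = expit(detect_slope * (log2_intensity - detect_midpoint))``; with the
    defaults a protein at the baseline mean is observed in essentially every
    replicate while proteins two baseline SDs down start dropping out.
    """

    n_proteins: int = 1000
    strains: Sequence[str] = ("168", "midi")
    fractions: Sequence[str] = FRACTIONS
    n_replicates: int = 3
    baseline_log2_mean: float = 27.0
    baseline_log2_sd: float = 2.0
    noise_log2_sd: float = 0.5
    effect_log2: float = 2.0
    frac_up: float = 0.05
    frac_down: float = 0.05
    frac_on: float = 0.05
    frac_off: float = 0.05
    detect_midpoint: float = 22.0
    detect_slope: float = 1.0
    unique_peptide_range: tuple[int, int] = (1, 30)
    localization_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            LOC_CYTOPLASMIC: 0.60,
            LOC_MEMBRANE: 0.20,
            LOC_EXTRACELLULAR: 0.12,
            LOC_CELLWALL: 0.04,
            LOC_UNKNOWN: 0.04,
        }
    )
    sec_sp_prob_extracellular: float = 0.8
    sec_sp_prob_other: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ConfigurationError("n_proteins must be positive")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.detect_slope <= 0:
            raise ConfigurationError("detect_slope must be > 0")
        fracs = (self.frac_up, self.frac_down, self.frac_on, self.frac_off)
        if any(f < 0 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ConfigurationError(
                "regulated-class fractions must be non-negative and sum to <= 1"
            )
        total = sum(self.localization_probs.values())
        if not np.isclose(total, 1.0):
            raise ConfigurationError("localization_probs must sum to 1")


@dataclass
class GroundTruth:
    """Per-protein truth behind a synthetic dataset."""

    table: pd.DataFrame  # protein, true_class, localization, sec_sp, fraction

    @property
    def classes(self) -> pd.Series:
        return self.table.set_index("protein")["true_class"]

    def proteins_of_class(self, cls: str) -> set[str]:
        t = self.table
        return set(t.loc[t["true_class"] == cls, "protein"])


def _simulate_categories(rng, proteins, sec_sp) -> dict[str, list[tuple[str, ...]]]:
    """Random 1-4 level category paths; SP+ proteins also get the secreted category."""
    categories: dict[str, list[tuple[str, ...]]] = {}
    for prot, sp in zip(proteins, sec_sp):
        root = _CATEGORY_ROOTS[rng.integers(len(_CATEGORY_ROOTS))]
        depth = int(rng.integers(1, 5))
        path = [root]
        for lvl in range(2, depth + 1):
            path.append(f"{root} L{lvl}.{int(rng.integers(1, 4))}")
        paths = [tuple(path)]
        if sp:
            paths.append(SECRETED_CATEGORY)
        # ~8% of proteins carry a second, unrelated category
        if rng.random() < 0.08:
            other = _CATEGORY_ROOTS[rng.integers(len(_CATEGORY_ROOTS))]
            paths.append((other, f"{other} L2.{int(rng.integers(1, 4))}"))
        categories[prot] = paths
    return categories


def _simulate_regulons(rng, proteins) -> dict[str, list[tuple[str, str]]]:
    regulons: dict[str, list[tuple[str, str]]] = {}
    for prot in proteins:
        k = int(rng.choice([0, 1, 1, 2], p=[0.35, 0.3, 0.2, 0.15]))
        if k == 0:
            continue
        idx = rng.choice(len(_REGULON_POOL), size=k, replace=False)
        regulons[prot] = [_REGULON_POOL[i] for i in idx]
    return regulons


def generate_quant_dataset(config: SimConfig):
    """Simulate a full quantification dataset.

    Returns
    -------
    (QuantTable, AnnotationMaps, GroundTruth)
        The quantification table is long-format with one row per *detected*
        measurement; the annotation maps carry localization, Sec-signal-peptide
        flags, functional categories and regulons consistent with the truth.
    """
    from .io import AnnotationMaps  # local import to avoid a cycle

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    proteins = np.array([f"P{i:05d}" for i in range(n)])

    p_unchanged = 1.0 - (cfg.frac_up + cfg.frac_down + cfg.frac_on + cfg.frac_off)
    true_class = rng.choice(
        TRUE_CLASSES,
        size=n,
        p=[cfg.frac_up, cfg.frac_down, p_unchanged, cfg.frac_on, cfg.frac_off],
    )

    loc_classes = list(cfg.localization_probs)
    loc_probs = np.array([cfg.localization_probs[c] for c in loc_classes])
    localization = rng.choice(loc_classes, size=n, p=loc_probs)

    # each protein is physically measured in one fraction; mislocalized classes
    # (cell wall / unknown) land in a random fraction and get filtered downstream
    measured_fraction = np.array(
        [
            _LOC_TO_FRACTION.get(loc, cfg.fractions[rng.integers(len(cfg.fractions))])
            for loc in localization
        ]
    )

    sec_sp = np.where(
        localization == LOC_EXTRACELLULAR,
        rng.random(n) < cfg.sec_sp_prob_extracellular,
        rng.random(n) < cfg.sec_sp_prob_other,
    )

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)
    unique_peptides = rng.integers(
        cfg.unique_peptide_range[0], cfg.unique_peptide_range[1] + 1, size=n
    )

    rows = []
    for strain in cfg.strains:
        for condition in CONDITIONS:
            shift = np.zeros(n)
            if condition == INDUCED:
                shift = np.where(
                    true_class == CLASS_UP,
                    cfg.effect_log2,
                    np.where(true_class == CLASS_DOWN, -cfg.effect_log2, 0.0),
                )
            expected = baseline + shift
            p_detect = expit(cfg.detect_slope * (expected - cfg.detect_midpoint))
            if condition == CONTROL:
                p_detect = np.where(true_class == CLASS_ON, 0.0, p_detect)
            else:
                p_detect = np.where(true_class == CLASS_OFF, 0.0, p_detect)
            for replicate in range(1, cfg.n_replicates + 1):
                detected = rng.random(n) < p_detect
                obs_log2 = expected + rng.normal(0.0, cfg.noise_log2_sd, size=n)
                idx = np.nonzero(detected)[0]
                rows.append(
                    pd.DataFrame(
                        {
                            "protein": proteins[idx],
                            "strain": strain,
                            "condition": condition,
                            "fraction": measured_fraction[idx],
                            "replicate": replicate,
                            "intensity": np.exp2(obs_log2[idx]),
                            "unique_peptides": unique_peptides[idx],
                        }
                    )
                )
    table = pd.concat(rows, ignore_index=True)
    table = table.sort_values(
        ["strain", "condition", "fraction", "protein", "replicate"]
    ).reset_index(drop=True)
    table.attrs["is_log2"] = False

    maps = AnnotationMaps(
        localization=dict(zip(proteins, localization)),
        sec_sp={p: bool(s) for p, s in zip(proteins, sec_sp)},
        categories=_simulate_categories(rng, proteins, sec_sp),
        regulons=_simulate_regulons(rng, proteins),
    )
    truth = GroundTruth(
        pd.DataFrame(
            {
                "protein": proteins,
                "true_class": true_class,
                "localization": localization,
                "sec_sp": sec_sp,
                "fraction": measured_fraction,
            }
        )
    )
    return table, maps, truth


# ---------------------------------------------------------------------------
# plate-reader simulation
# ---------------------------------------------------------------------------


@dataclass
class PlateConfig:
    """Parameters of the synthetic live-cell-array plate run.

    ``activities`` maps strain name -> constant promoter activity (arbitrary
    units): at each time step a reporter well accumulates
    ``activity * OD600_t`` fluorescence, so with zero noise the promoter
    activity statistic computed downstream recovers the injected constant
    exactly from the second time point on.  The defaults mirror a 12 h run
    read every 10 min (73 time points including t=0).
    """

    n_timepoints: int = 73
    interval_min: float = 10.0
    activities: Mapping[str, float] = field(
        default_factory=lambda: {"168": 100.0, "midi": 10.0}
    )
    wells_per_strain: int = 3
    n_control_wells: int = 3
    od_start: float = 0.05
    od_max: float = 1.5
    growth_rate: float = 0.012  # per minute, logistic
    background_per_od: float = 50.0
    background_const: float = 20.0
    gfp_noise_sd: float = 0.0
    od_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ConfigurationError("need at least 2 time points")
        if self.interval_min <= 0:
            raise ConfigurationError("interval_min must be positive")
        if self.n_control_wells < 1:
            raise ConfigurationError("need at least one control well")


def generate_plate_series(config: PlateConfig) -> pd.DataFrame:
    """Simulate OD600/GFP time series for reporter and control wells.

    Returns a long-format frame with columns
    ``well, strain, role, time_min, od600, gfp``; control wells carry only
    the background fluorescence.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.n_timepoints) * cfg.interval_min
    a0 = (cfg.od_max - cfg.od_start) / cfg.od_start
    od = cfg.od_max / (1.0 + a0 * np.exp(-cfg.growth_rate * t))
    background = cfg.background_const + cfg.background_per_od * od

    frames = []

    def _well(name, strain, role, activity):
        od_w = od + rng.normal(0.0, cfg.od_noise_sd, size=t.size)
        gfp_sig = np.zeros_like(t, dtype=float)
        if activity:
            # GFP accumulates by activity * OD at each step after t0
            incr = activity * od_w
            incr[0] = 0.0
            gfp_sig = np.cumsum(incr)
        gfp = gfp_sig + background + rng.normal(0.0, cfg.gfp_noise_sd, size=t.size)
        frames.append(
            pd.DataFrame(
                {
                    "well": name,
                    "strain": strain,
                    "role": role,
                    "time_min": t,
                    "od600": od_w,
                    "gfp": gfp,
                }
            )
        )

    for strain, activity in cfg.activities.items():
        for w in range(1, cfg.wells_per_strain + 1):
            _well(f"{strain}_R{w}", strain, "reporter", activity)
    for w in range(1, cfg.n_control_wells + 1):
        _well(f"ctrl_{w}", "control", "control", 0.0)

    return pd.concat(frames, ignore_index=True)
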