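"""Differential abundance: S0-moderated statistic, permutation FDR and
regulation classes.

For a protein quantified in both conditions the effect is the difference of
mean log2 LFQ intensities (induced - control) over its detected replicates.
Significance uses the S0-moderated two-sample statistic

    t_s0 = (mean_a - mean_b) / (se + s0)

where ``se`` is the pooled-variance standard error of the mean difference
(Welch available by flag) and ``s0`` (default 0.1) damps tiny-variance,
tiny-effect proteins.  The false-discovery rate is estimated SAM-style:
condition labels of the replicate columns are permuted within each
(strain, fraction) block, |t_s0| is recomputed for all proteins, and
FDR(c) = mean permuted exceedance count / observed exceedance count; the
significance threshold is the smallest c with FDR(c) <= the target.  When
the number of distinct label assignments is within the randomization budget
the assignments are enumerated exhaustively.  The observed labelling and its
mirror image reproduce the observed statistics exactly and carry no
information about the null, so they are excluded from the null ensemble;
with 3-vs-3 replicates this leaves 18 of the C(6,3) = 20 assignments.

Nominal p-values are empirical, pooled across the permutation null of all
proteins in the block, with add-one smoothing.  A plain Benjamini-Hochberg
mode on Student-t p-values is available as ``method="bh"``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qualify import CALL_BOTH, CALL_OFF, CALL_ON, QualifiedSet
from .simulate import CONTROL, INDUCED

logger = logging.getLogger(__name__)

CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_UNCHANGED = "unchanged"

CLASS_SYMBOLS = {
    CLASS_UP: "↑",
    CLASS_DOWN: "↓",
    CLASS_UNCHANGED: "=",
    "ON": "ON",
    "OFF": "OFF",
}


class UndefinedDifferenceError(ValueError):
    """Difference requested for a protein not quantified in both conditions."""


@dataclass
class TestConfig:
    """Parameters of the differential test (defaults follow the processing
    parameters of the study: 250 randomizations, FDR 0.05, S0 0.1)."""

    s0: float = 0.1
    n_randomizations: int = 250
    fdr: float = 0.05
    seed: int = 0
    two_sided: bool = True
    method: str = "permutation"  # "permutation" | "bh"
    welch: bool = False

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.method not in ("permutation", "bh"):
            raise ValueError(f"unknown method {self.method!r}")


def log_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Apply log2 to the intensity column exactly once.

    A table already flagged as log2 is returned as a copy with a note logged;
    non-positive intensities on the linear scale are an error.
    """
    out = table.copy()
    if table.attrs.get("is_log2", False):
        logger.info("intensities already log2-transformed; skipping")
        out.attrs["is_log2"] = True
        return out
    if (out["intensity"] <= 0).any():
        raise ValueError("cannot log-transform non-positive intensities")
    out["intensity"] = np.log2(out["intensity"])
    out.attrs["is_log2"] = True
    return out


def s0_tstat(group_a, group_b, s0: float = 0.1, welch: bool = False) -> float:
    """S0-moderated two-sample statistic for two 1-D value arrays.

    Antisymmetric under group swap; equals the classical pooled two-sample t
    when ``s0 == 0``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    return float(
        _tstat_matrix(a[None, :], b[None, :], s0=s0, welch=welch)[0]
    )


def _tstat_matrix(A, B, s0: float, welch: bool = False):
    """Row-wise t_s0 for matrices of shape (n, na) and (n, nb); NaN-aware.

    Rows with fewer than two finite values in either group yield NaN.
    """
    na = np.sum(np.isfinite(A), axis=1)
    nb = np.sum(np.isfinite(B), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(A, axis=1)
        mb = np.nanmean(B, axis=1)
        va = np.nanvar(A, axis=1, ddof=1)
        vb = np.nanvar(B, axis=1, ddof=1)
        if welch:
            se = np.sqrt(va / na + vb / nb)
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        t = (ma - mb) / (se + s0)
    t = np.where((na >= 2) & (nb >= 2), t, np.nan)
    return t


def mean_difference(induced_values, control_values) -> float:
    """Mean log2 difference (induced - control) over detected replicates."""
    a = np.asarray(induced_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise UndefinedDifferenceError(
            "difference requires values in both conditions"
        )
    return float(np.mean(a) - np.mean(b))


@dataclass
class PermutationResult:
    """Per-protein outcome of the permutation-FDR procedure on one block."""

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    threshold: float | None
    n_permutations: int
    exhaustive: bool


def _iter_assignments(n_a: int, n_b: int, cfg: TestConfig):
    """Yield label assignments (tuples of induced column indices) for the null.

    Exhaustive when C(n_a+n_b, n_a) <= n_randomizations, else uniform samples
    with replacement.  The observed assignment and its complement are never
    yielded (they replicate the observed statistics, not the null).
    """
    n = n_a + n_b
    identity = frozenset(range(n_a))
    mirror = frozenset(range(n_a, n))
    total = math.comb(n, n_a)
    if total <= cfg.n_randomizations:
        assignments = [
            c
            for c in combinations(range(n), n_a)
            if frozenset(c) not in (identity, mirror)
        ]
        return assignments, True
    rng = np.random.default_rng(cfg.seed)
    assignments = []
    while len(assignments) < cfg.n_randomizations:
        c = tuple(sorted(rng.choice(n, size=n_a, replace=False)))
        if frozenset(c) in (identity, mirror):
            continue
        assignments.append(c)
    return assignments, False


def permutation_fdr(A, B, cfg: TestConfig) -> PermutationResult:
    """SAM-style permutation FDR on one (strain, fraction) block.

    Parameters
    ----------
    A, B
        Matrices (n_proteins x n_replicates) of log2 intensities for the
        induced and control condition; NaN marks undetected replicates.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    n, n_a = A.shape
    n_b = B.shape[1]
    if n < 2:
        raise ValueError("permutation FDR needs at least 2 proteins")

    t_obs = _tstat_matrix(A, B, cfg.s0, cfg.welch)
    score_obs = np.abs(t_obs) if cfg.two_sided else t_obs
    finite = np.isfinite(score_obs)
    n_obs = int(finite.sum())
    if n_obs == 0 or np.nanstd(np.hstack([A, B])) == 0:
        logger.warning("degenerate block: no testable variation")
        return PermutationResult(
            t=t_obs,
            p=np.full(n, 1.0),
            q=np.full(n, 1.0),
            significant=np.zeros(n, dtype=bool),
            threshold=None,
            n_permutations=0,
            exhaustive=False,
        )

    M = np.hstack([A, B])
    assignments, exhaustive = _iter_assignments(n_a, n_b, cfg)
    B_n = len(assignments)

    null_vals = []
    null_weights = []  # per-value weight = scale_b / B_n
    for assign in assignments:
        cols_a = list(assign)
        cols_b = [j for j in range(n_a + n_b) if j not in set(assign)]
        t_b = _tstat_matrix(M[:, cols_a], M[:, cols_b], cfg.s0, cfg.welch)
        s_b = np.abs(t_b) if cfg.two_sided else t_b
        valid = np.isfinite(s_b)
        n_valid = int(valid.sum())
        if n_valid == 0:
            continue
        vals = s_b[valid]
        null_vals.append(vals)
        # rescale so each permutation contributes as if all proteins were valid
        null_weights.append(np.full(vals.size, (n_obs / n_valid) / B_n))
    if null_vals:
        null_vals = np.concatenate(null_vals)
        null_weights = np.concatenate(null_weights)
    else:  # pragma: no cover - pathological all-missing permutations
        null_vals = np.array([])
        null_weights = np.array([])

    order = np.argsort(null_vals)
    null_sorted = null_vals[order]
    # suffix sums give the mean scaled permuted count >= c
    w_sorted = null_weights[order]
    suffix_w = np.concatenate([np.cumsum(w_sorted[::-1])[::-1], [0.0]])

    obs_sorted = np.sort(score_obs[finite])

    def mean_null_count(c):
        i = np.searchsorted(null_sorted, c, side="left")
        return suffix_w[i]

    def obs_count(c):
        return n_obs - np.searchsorted(obs_sorted, c, side="left")

    # FDR at every observed candidate threshold (ascending), then the q-value
    # is the running minimum of FDR over thresholds at or below the protein's
    # own score
    cs = obs_sorted
    fdr_at = np.minimum(
        np.array([mean_null_count(c) for c in cs])
        / np.maximum(np.array([obs_count(c) for c in cs]), 1),
        1.0,
    )
    q_at = np.minimum.accumulate(fdr_at)

    q = np.full(n, np.nan)
    idx = np.searchsorted(cs, score_obs[finite], side="right") - 1
    q[finite] = q_at[np.clip(idx, 0, len(cs) - 1)]

    significant = np.zeros(n, dtype=bool)
    significant[finite] = q[finite] <= cfg.fdr
    passing = cs[fdr_at <= cfg.fdr]
    threshold = float(passing[0]) if passing.size else None

    # pooled empirical p with add-one smoothing
    p = np.full(n, np.nan)
    m_total = null_sorted.size
    counts = m_total - np.searchsorted(null_sorted, score_obs[finite], side="left")
    p[finite] = (1.0 + counts) / (1.0 + m_total)

    return PermutationResult(
        t=t_obs,
        p=p,
        q=q,
        significant=significant,
        threshold=threshold,
        n_permutations=B_n,
        exhaustive=exhaustive,
    )


def _bh_block(A, B, cfg: TestConfig):
    """Student-t p-values with Benjamini-Hochberg correction on one block."""
    t_obs = _tstat_matrix(A, B, cfg.s0, cfg.welch)
    tt = stats.ttest_ind(
        A, B, axis=1, equal_var=not cfg.welch, nan_policy="omit"
    )
    p = np.asarray(tt.pvalue, dtype=float)
    finite = np.isfinite(p)
    q = np.full(p.shape, np.nan)
    significant = np.zeros(p.shape, dtype=bool)
    if finite.any():
        rej, qv, *_ = multipletests(p[finite], alpha=cfg.fdr, method="fdr_bh")
        q[finite] = qv
        significant[finite] = rej
    return t_obs, p, q, significant


def _block_matrices(block: pd.DataFrame, proteins, n_replicates: int):
    """Pivot a (strain, fraction) slice of the log2 table into matrices
    (proteins x replicates) per condition, NaN for undetected."""
    mats = {}
    for condition in (INDUCED, CONTROL):
        sub = block[block["condition"] == condition]
        pivot = sub.pivot_table(
            index="protein", columns="replicate", values="intensity", aggfunc="first"
        )
        pivot = pivot.reindex(index=proteins, columns=range(1, n_replicates + 1))
        mats[condition] = pivot.to_numpy(dtype=float)
    return mats[INDUCED], mats[CONTROL]


def differential_analysis(
    log2_table: pd.DataFrame,
    qs: QualifiedSet,
    presence: pd.DataFrame,
    cfg: TestConfig,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Run the per-(strain, fraction) differential test and classify.

    Returns one row per (strain, fraction, protein) whose presence call is
    ``both``, ``ON`` or ``OFF``: columns difference, t_s0, p, neglog10_p, q,
    significant, class.  ON/OFF rows have undefined difference/statistics.
    """
    if not log2_table.attrs.get("is_log2", False):
        raise ValueError("differential_analysis expects a log2-transformed table")

    results = []
    for (strain, fraction), pres_block in presence.groupby(
        ["strain", "fraction"], sort=True
    ):
        both = pres_block.loc[pres_block["call"] == CALL_BOTH, "protein"].tolist()
        block = log2_table[
            (log2_table["strain"] == strain) & (log2_table["fraction"] == fraction)
        ]
        if both:
            A, Bm = _block_matrices(block, both, n_replicates)
            diff = np.nanmean(A, axis=1) - np.nanmean(Bm, axis=1)
            if len(both) >= 2:
                if cfg.method == "permutation":
                    res = permutation_fdr(A, Bm, cfg)
                    t, p, q, sig = res.t, res.p, res.q, res.significant
                else:
                    t, p, q, sig = _bh_block(A, Bm, cfg)
            else:
                t = _tstat_matrix(A, Bm, cfg.s0, cfg.welch)
                p = np.full(len(both), np.nan)
                q = np.full(len(both), np.nan)
                sig = np.zeros(len(both), dtype=bool)
            results.append(
                pd.DataFrame(
                    {
                        "strain": strain,
                        "fraction": fraction,
                        "protein": both,
                        "difference": diff,
                        "t_s0": t,
                        "p": p,
                        "neglog10_p": -np.log10(p),
                        "q": q,
                        "significant": sig,
                    }
                )
            )
        onoff = pres_block[pres_block["call"].isin([CALL_ON, CALL_OFF])]
        if len(onoff):
            results.append(
                pd.DataFrame(
                    {
                        "strain": strain,
                        "fraction": fraction,
                        "protein": onoff["protein"].to_numpy(),
                        "difference": np.nan,
                        "t_s0": np.nan,
                        "p": np.nan,
                        "neglog10_p": np.nan,
                        "q": np.nan,
                        "significant": False,
                    }
                )
            )
    if not results:
        return pd.DataFrame(
            columns=[
                "strain",
                "fraction",
                "protein",
                "difference",
                "t_s0",
                "p",
                "neglog10_p",
                "q",
                "significant",
                "class",
            ]
        )
    diff = pd.concat(results, ignore_index=True)
    return classify_regulation(diff, presence)


def classify_regulation(diff: pd.DataFrame, presence: pd.DataFrame) -> pd.DataFrame:
    """Attach the regulation class: ON/OFF from the presence call; for
    both-condition proteins, up/down when significant (by sign of the
    difference), unchanged otherwise."""
    key = ["strain", "fraction", "protein"]
    if diff.duplicated(key).any() or presence.duplicated(key).any():
        raise ValueError("conflicting (strain, fraction, protein) keys")
    merged = diff.merge(presence[key + ["call"]], on=key, how="left", validate="1:1")
    cls = np.where(
        merged["call"] == CALL_ON,
        "ON",
        np.where(
            merged["call"] == CALL_OFF,
            "OFF",
            np.where(
                merged["significant"].eq(True),
                np.where(merged["difference"] > 0, CLASS_UP, CLASS_DOWN),
                CLASS_UNCHANGED,
            ),
        ),
    )
    out = merged.drop(columns=["call"])
    out["class"] = cls
    return out
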