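"""Behavioral pipeline for the two-day visuomotor rotation task.

Trial-level angular errors (signed, degrees) are quality-controlled, averaged
into 8-trial bins, and summarized per subject by:

* initial error: median angular error over the first 16 learning trials,
* savings: Day 1 initial error minus Day 2 initial error,
* adaptation proxy ``A = 45 - |error|`` (45 degrees is the imposed rotation),
* Recall Ratio ``RR = A(Day-2 early) / A(Day-1 late)``, undefined when the
  denominator is below a 5-degree stability threshold,
* Learning Score: each subject's loading on the first functional principal
  component of their penalized-B-spline-smoothed two-day learning curve,
  sign-fixed so that higher scores mean lower error,
* fast/slow learner groups from a median split of the Learning Score.

Smoothing uses a cubic B-spline basis (17 basis functions) with a
second-derivative roughness penalty whose weight is chosen by generalized
cross-validation over a log-spaced grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

RT_MIN_MS = 100.0
RT_MAX_MS = 2000.0
ROTATION_DEG = 45.0
BIN_SIZE = 8
N_BASIS = 17
SPLINE_ORDER = 4                      # cubic
STABILITY_THRESHOLD_DEG = 5.0
BLOCK_ORDER = ("Baseline", "Learning", "Washout")

TRIAL_COLUMNS = ("subject", "day", "block", "trial", "error_deg", "rt_ms")


class BehaviorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# trial-level operations
# ---------------------------------------------------------------------------

def trial_qc(trials: pd.DataFrame) -> pd.DataFrame:
    """Flag invalid trials without deleting them.

    A trial is excluded when the reaction time is strictly below 100 ms,
    strictly above 2000 ms, or missing (no movement initiated).  Returns a
    copy with an ``excluded`` boolean column.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise BehaviorError(f"trial table missing columns {missing}")
    out = trials.copy()
    rt = out["rt_ms"].to_numpy(dtype=float)
    out["excluded"] = np.isnan(rt) | (rt < RT_MIN_MS) | (rt > RT_MAX_MS)
    return out


def bin_curve(errors: np.ndarray, bin_size: int = BIN_SIZE) -> np.ndarray:
    """Average trial errors into consecutive bins, ignoring excluded (NaN) trials.

    A trailing partial bin is averaged over the trials it contains.  Bins in
    which every trial was excluded are linearly interpolated from their
    neighbours (the smoothing step requires a complete grid).
    """
    errors = np.asarray(errors, dtype=float)
    if errors.ndim != 1 or errors.size == 0:
        raise BehaviorError("errors must be a non-empty 1-D array")
    edges = np.arange(0, errors.size, bin_size)
    with np.errstate(invalid="ignore"):
        sums = np.add.reduceat(np.nan_to_num(errors), edges)
        counts = np.add.reduceat((~np.isnan(errors)).astype(float), edges)
        binned = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if np.isnan(binned).any():
        if np.isnan(binned).all():
            raise BehaviorError("all bins empty after exclusions")
        ix = np.arange(binned.size)
        ok = ~np.isnan(binned)
        binned = np.interp(ix, ix[ok], binned[ok])
    return binned


def initial_error(learning_errors: np.ndarray) -> float:
    """Median angular error over the first 16 learning trials (two target cycles).

    Excluded trials (NaN) within the window are ignored.
    """
    e = np.asarray(learning_errors, dtype=float)
    if e.size < 16:
        raise BehaviorError("need >= 16 learning trials")
    window = e[:16]
    valid = window[~np.isnan(window)]
    if valid.size == 0:
        raise BehaviorError("no valid trials in the initial window")
    return float(np.median(valid))


def savings(d1_initial: float, d2_initial: float) -> float:
    """Day 1 initial error minus Day 2 initial error; negative when relearning is worse."""
    return float(d1_initial) - float(d2_initial)


def adaptation_proxy(error_deg: float | np.ndarray) -> float | np.ndarray:
    """Adaptation-performance proxy ``A = 45 - |error|`` (even in the error)."""
    return ROTATION_DEG - np.abs(error_deg)


def recall_ratio(
    a_d1_late: float,
    a_d2_early: float,
    stability_threshold: float = STABILITY_THRESHOLD_DEG,
    mode: str = "exclude",
) -> float | None:
    """``RR = A(D2 early) / A(D1 late)``; RR near 1 indicates near-complete recall.

    With ``mode='exclude'`` (default) the ratio is undefined (``None``) when
    the Day-1 late adaptation falls below the stability threshold; with
    ``mode='floor'`` the denominator is floored at the threshold instead.
    """
    if mode not in ("exclude", "floor"):
        raise BehaviorError(f"unknown stability mode {mode!r}")
    if a_d1_late < stability_threshold:
        if mode == "exclude":
            return None
        a_d1_late = stability_threshold
    return float(a_d2_early) / float(a_d1_late)


def median_split(scores: np.ndarray) -> np.ndarray:
    """Strictly-above-median scores are 'fast' learners, the rest 'slow'."""
    scores = np.asarray(scores, dtype=float)
    return np.where(scores > np.median(scores), "fast", "slow")


# ---------------------------------------------------------------------------
# penalized B-spline smoothing and functional PCA
# ---------------------------------------------------------------------------

def _bspline_knots(t0: float, t1: float, n_basis: int = N_BASIS, order: int = SPLINE_ORDER):
    n_interior = n_basis - order
    interior = np.linspace(t0, t1, n_interior + 2)[1:-1]
    return np.concatenate([np.full(order, t0), interior, np.full(order, t1)])


def _design_matrix(x: np.ndarray, knots: np.ndarray, order: int = SPLINE_ORDER) -> np.ndarray:
    return BSpline.design_matrix(x, knots, order - 1).toarray()


def _penalty_matrix(knots: np.ndarray, order: int = SPLINE_ORDER) -> np.ndarray:
    """Gram matrix of second derivatives, integrated exactly by Gauss-Legendre.

    For cubic splines the second derivatives are piecewise linear, so 2-point
    quadrature per knot span is exact.
    """
    n_basis = knots.size - order
    spans = np.unique(knots)
    gl_x, gl_w = np.polynomial.legendre.leggauss(2)
    P = np.zeros((n_basis, n_basis))
    for a, b in zip(spans[:-1], spans[1:]):
        x = 0.5 * (b - a) * gl_x + 0.5 * (a + b)
        w = 0.5 * (b - a) * gl_w
        coeffs = np.eye(n_basis)
        D2 = np.column_stack([
            BSpline(knots, coeffs[j], order - 1).derivative(2)(x) for j in range(n_basis)
        ])
        P += (D2 * w[:, None]).T @ D2
    return P


@dataclass
class FPCAResult:
    """Learning-curve fPCA: subject scores, mean function and components."""

    scores: np.ndarray               # (n_subjects,) sign-fixed fPC1 loadings
    all_scores: np.ndarray           # (n_subjects, n_components)
    variance_explained: np.ndarray   # per component, non-increasing, sums <= 1
    mean_curve: np.ndarray           # smoothed group mean on the bin grid
    components: np.ndarray           # (n_components, n_bins) eigenfunctions
    smoothed: np.ndarray             # (n_subjects, n_bins) smoothed curves
    penalty_weight: float            # GCV-selected roughness penalty


def fpca_learning_score(
    curves: np.ndarray,
    n_components: int = 3,
    penalty_grid: np.ndarray | None = None,
) -> FPCAResult:
    """Functional PCA of binned learning curves; fPC1 loading = Learning Score.

    Each subject's curve is smoothed with a 17-function cubic B-spline basis
    under a second-derivative penalty (single weight for all subjects, chosen
    by minimizing the mean GCV criterion over a log grid).  PCA across the
    smoothed curves (trapezoid-weighted over the bin grid) yields the
    functional components; fPC1 scores are flipped, if necessary, so that a
    higher Learning Score corresponds to lower overall angular error.
    """
    Y = np.asarray(curves, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 3:
        raise BehaviorError("need >= 3 subjects of binned curves")
    if np.isnan(Y).any():
        raise BehaviorError("curves contain NaN; interpolate empty bins first")
    n_subj, n_bins = Y.shape
    if n_bins < N_BASIS:
        raise BehaviorError(
            f"{n_bins} bins cannot support {N_BASIS} basis functions; reduce the basis"
        )
    t = np.arange(n_bins, dtype=float)
    knots = _bspline_knots(t[0], t[-1])
    B = _design_matrix(t, knots)
    P = _penalty_matrix(knots)

    if penalty_grid is None:
        penalty_grid = np.logspace(-4, 4, 17)
    BtB = B.T @ B
    BtY = B.T @ Y.T
    best = (np.inf, penalty_grid[0], None)
    for lam in penalty_grid:
        M = np.linalg.inv(BtB + lam * P)
        H_trace = float(np.trace(B @ M @ B.T))
        C = M @ BtY                              # (n_basis, n_subj)
        fitted = B @ C
        rss = ((Y.T - fitted) ** 2).sum(axis=0)
        gcv = (n_bins * rss / (n_bins - H_trace) ** 2).mean()
        if gcv < best[0]:
            best = (gcv, float(lam), C)
    _, lam, C = best
    smoothed = (B @ C).T                          # (n_subj, n_bins)

    w = np.full(n_bins, 1.0)
    w[0] = w[-1] = 0.5                            # trapezoid quadrature weights
    mean_curve = smoothed.mean(axis=0)
    Xc = (smoothed - mean_curve) * np.sqrt(w)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_components = min(n_components, s.size)
    var = s**2 / (s**2).sum() if s.sum() > 0 else np.zeros_like(s)
    scores = U[:, :n_components] * s[:n_components]
    components = Vt[:n_components] / np.sqrt(w)

    if s[0] == 0:                                 # identical curves: no variation
        pc1 = np.zeros(n_subj)
    else:
        pc1 = scores[:, 0]
        mean_err = Y.mean(axis=1)
        if np.corrcoef(pc1, mean_err)[0, 1] > 0:
            pc1 = -pc1
            scores[:, 0] = pc1
            components[0] = -components[0]
    return FPCAResult(
        scores=pc1,
        all_scores=scores,
        variance_explained=var[:n_components],
        mean_curve=mean_curve,
        components=components,
        smoothed=smoothed,
        penalty_weight=lam,
    )


# ---------------------------------------------------------------------------
# per-subject score table
# ---------------------------------------------------------------------------

def _block_errors(trials: pd.DataFrame, subject, day: int, block: str) -> np.ndarray:
    sel = trials[(trials["subject"] == subject) & (trials["day"] == day)
                 & (trials["block"] == block)].sort_values("trial")
    e = sel["error_deg"].to_numpy(dtype=float)
    e[sel["excluded"].to_numpy(dtype=bool)] = np.nan
    return e


def _window_adaptation(errors: np.ndarray, first: bool, n_trials: int = 48) -> float:
    window = errors[:n_trials] if first else errors[-n_trials:]
    valid = window[~np.isnan(window)]
    if valid.size == 0:
        raise BehaviorError("no valid trials in adaptation window")
    return float(adaptation_proxy(np.median(np.abs(valid))))


def subject_scores(
    trials: pd.DataFrame,
    stability_mode: str = "exclude",
) -> tuple[pd.DataFrame, FPCAResult]:
    """Full behavioral score table: one row per subject.

    Columns: initial error per day, savings, late-Day-1 / early-Day-2
    adaptation, Recall Ratio (NaN when undefined), Learning Score, fast/slow
    learner group.
    """
    trials = trial_qc(trials) if "excluded" not in trials.columns else trials
    subjects = sorted(trials["subject"].unique())
    curves = []
    rows = []
    for subj in subjects:
        seq = np.concatenate([
            _block_errors(trials, subj, day, block)
            for day in (1, 2) for block in BLOCK_ORDER
        ])
        curves.append(bin_curve(seq))
        learn1 = _block_errors(trials, subj, 1, "Learning")
        learn2 = _block_errors(trials, subj, 2, "Learning")
        e1, e2 = initial_error(learn1), initial_error(learn2)
        a_late1 = _window_adaptation(learn1, first=False)
        a_early2 = _window_adaptation(learn2, first=True)
        rr = recall_ratio(a_late1, a_early2, mode=stability_mode)
        rows.append({
            "subject": subj,
            "initial_error_d1": e1,
            "initial_error_d2": e2,
            "savings": savings(e1, e2),
            "adaptation_d1_late": a_late1,
            "adaptation_d2_early": a_early2,
            "recall_ratio": np.nan if rr is None else rr,
        })
    curve_lengths = {c.size for c in curves}
    if len(curve_lengths) != 1:
        raise BehaviorError("subjects have unequal binned-curve lengths")
    fpca = fpca_learning_score(np.vstack(curves))
    table = pd.DataFrame(rows)
    table["learning_score"] = fpca.scores
    table["learner_group"] = median_split(fpca.scores)
    return table, fpca
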