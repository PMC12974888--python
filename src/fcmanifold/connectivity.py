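"""Parcellated BOLD time series -> per-epoch covariance matrices and seed contrasts.

A scan is a regions x volumes matrix.  The analysis standardizes each region's
time series, splices the scan into equal-length task epochs (96 volumes / 48
trials each, after discarding initial volumes), and estimates one shrinkage
covariance matrix per epoch with the Ledoit-Wolf estimator, which stays
positive definite even when regions outnumber volumes.  Seed-contrast maps
(paired t-tests between epoch-averaged seed connectivity rows) and the
network-level spider-plot summaries live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.covariance import ledoit_wolf as _sk_ledoit_wolf

EPOCH_LENGTH = 96           # volumes per task epoch (48 trials at 2 volumes/trial)
VOLUMES_PER_TRIAL = 2       # 4 s trials, 2 s sampling
EPOCH_NAMES = ("Baseline", "EarlyLearning", "LateLearning", "EarlyWashout", "LateWashout")


class TimeSeriesError(ValueError):
    """Malformed or degenerate region time series."""


@dataclass
class RegionTimeSeries:
    """Standardizable regions x volumes matrix for one subject/day/scan."""

    values: np.ndarray
    subject: str
    day: int
    scan: str                       # "task" or "washout"
    region_ids: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TimeSeriesError("values must be a 2-D regions x volumes matrix")
        if np.isnan(self.values).any():
            raise TimeSeriesError("time series contains missing values")
        self.region_ids = tuple(self.region_ids)
        if len(self.region_ids) != self.values.shape[0]:
            raise TimeSeriesError(
                f"{len(self.region_ids)} region ids for {self.values.shape[0]} rows"
            )
        if len(set(self.region_ids)) != len(self.region_ids):
            raise TimeSeriesError("region ids are not unique")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EpochDefinition:
    """A 96-volume window within a scan.

    ``start`` is 0-based and counted after the discarded initial volumes.
    """

    name: str
    scan: str
    start: int
    length: int = EPOCH_LENGTH

    def __post_init__(self):
        if self.length != EPOCH_LENGTH:
            raise ValueError(f"epoch length must be {EPOCH_LENGTH} volumes, got {self.length}")
        if self.start < 0:
            raise ValueError("epoch start must be non-negative")


def default_epoch_definitions(
    baseline_volumes: int = EPOCH_LENGTH,
    learning_volumes: int = 2 * EPOCH_LENGTH,
    washout_volumes: int = 2 * EPOCH_LENGTH,
) -> list[EpochDefinition]:
    """Epoch windows for a task scan (Baseline + Learning) and a washout scan.

    Baseline is the first post-discard window of the task scan; Early/Late
    Learning are the first/last windows of the learning portion; Early/Late
    Washout the first/last windows of the washout scan.
    """
    return [
        EpochDefinition("Baseline", "task", 0),
        EpochDefinition("EarlyLearning", "task", baseline_volumes),
        EpochDefinition("LateLearning", "task", baseline_volumes + learning_volumes - EPOCH_LENGTH),
        EpochDefinition("EarlyWashout", "washout", 0),
        EpochDefinition("LateWashout", "washout", washout_volumes - EPOCH_LENGTH),
    ]


def zscore_timeseries(ts: RegionTimeSeries) -> RegionTimeSeries:
    """Standardize each region to mean 0, population (ddof=0) SD 1."""
    sd = ts.values.std(axis=1, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise TimeSeriesError(f"zero-variance region(s): {[ts.region_ids[i] for i in bad]}")
    z = (ts.values - ts.values.mean(axis=1, keepdims=True)) / sd[:, None]
    return replace(ts, values=z)


def splice_epochs(
    ts: RegionTimeSeries,
    defs: Sequence[EpochDefinition],
    discard_initial: int = 6,
) -> dict[str, np.ndarray]:
    """Cut the scan into named epoch blocks of exactly 96 volumes.

    Only definitions whose ``scan`` matches ``ts.scan`` are applied.  Windows
    are indexed after discarding the first ``discard_initial`` volumes.
    """
    blocks: dict[str, np.ndarray] = {}
    for d in defs:
        if d.scan != ts.scan:
            continue
        lo = discard_initial + d.start
        hi = lo + d.length
        if hi > ts.n_volumes:
            raise TimeSeriesError(
                f"epoch {d.name}: window [{lo}, {hi}) exceeds scan length {ts.n_volumes}"
            )
        blocks[d.name] = ts.values[:, lo:hi].copy()
    return blocks


def trial_window_to_volumes(first_trial: int, n_trials: int) -> slice:
    """Map a 1-based trial window within an epoch block to volume indices."""
    start = (first_trial - 1) * VOLUMES_PER_TRIAL
    return slice(start, start + n_trials * VOLUMES_PER_TRIAL)


def ledoit_wolf_covariance(block: np.ndarray) -> tuple[np.ndarray, float]:
    """Ledoit-Wolf shrinkage covariance of a regions x volumes block.

    Returns ``(cov, shrinkage)``; shrinkage intensity is the analytic estimate
    in [0, 1].  The result is SPD even when regions > volumes.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[1] < 2:
        raise TimeSeriesError("covariance estimation needs a 2-D block with >= 2 volumes")
    cov, shrinkage = _sk_ledoit_wolf(block.T, assume_centered=False)
    return 0.5 * (cov + cov.T), float(shrinkage)


def epoch_mean_activation(block: np.ndarray) -> np.ndarray:
    """Per-region mean of an epoch block (mean activation control measure)."""
    block = np.asarray(block, dtype=float)
    if block.ndim != 2:
        raise TimeSeriesError("block must be 2-D")
    return block.mean(axis=1)


def nuisance_regress_components(
    targets: np.ndarray,
    nuisance: np.ndarray,
    n_components: int = 3,
) -> np.ndarray:
    """Remove the top PCA components of a nuisance region set from target rows.

    PCA is run across the nuisance regions (observations = volumes); the top
    ``n_components`` component time courses are z-scored and regressed, with an
    intercept, out of every target region's time series.  Residuals are
    orthogonal to the retained components.
    """
    targets = np.asarray(targets, dtype=float)
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim != 2 or nuisance.shape[0] == 0:
        raise TimeSeriesError("nuisance set is empty")
    if targets.shape[1] != nuisance.shape[1]:
        raise TimeSeriesError("targets and nuisance must share the volume axis")
    if n_components > nuisance.shape[0]:
        raise TimeSeriesError("more components requested than nuisance regions")
    X = nuisance.T - nuisance.T.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if np.sum(s > max(X.shape) * np.finfo(float).eps * s[0]) < n_components:
        raise TimeSeriesError(f"nuisance set has rank < {n_components}")
    comps = U[:, :n_components] * s[:n_components]          # volumes x k scores
    comps = (comps - comps.mean(axis=0)) / comps.std(axis=0, ddof=0)
    design = np.column_stack([np.ones(comps.shape[0]), comps])
    beta, *_ = np.linalg.lstsq(design, targets.T, rcond=None)
    return (targets.T - design @ beta).T


@dataclass
class SeedContrastMap:
    """Per-region and per-network paired-t summary of a seed's connectivity change."""

    seed: str
    contrast: str
    region_ids: tuple[str, ...]
    t: np.ndarray                   # per-region paired t (seed self-entry is NaN)
    p: np.ndarray
    network_names: tuple[str, ...]
    network_t: np.ndarray           # paired t of subject-mean seed<->network change
    network_p: np.ndarray


def seed_contrast(
    centered_covs: Mapping[tuple, np.ndarray],
    seed: str,
    region_ids: Sequence[str],
    epochs_a: Iterable[tuple[int, str]],
    epochs_b: Iterable[tuple[int, str]],
    networks: Mapping[str, str],
    contrast_label: str | None = None,
) -> SeedContrastMap:
    """Paired t-test of seed-row connectivity between two epoch sets.

    ``centered_covs`` maps ``(subject, day, epoch)`` to centered covariance
    matrices.  For each subject the seed row is averaged within each epoch set
    (sets may span days, implementing day-averaged contrasts), then a paired t
    across subjects is computed per region.  The network summary is the paired
    t of the subject-level mean seed-to-network connectivity change, excluding
    the seed's self-entry.
    """
    region_ids = tuple(region_ids)
    if seed not in region_ids:
        raise KeyError(f"unknown seed region {seed!r}")
    seed_ix = region_ids.index(seed)
    epochs_a, epochs_b = tuple(epochs_a), tuple(epochs_b)
    subjects = sorted({k[0] for k in centered_covs})

    def subject_mean_row(subj, epoch_set):
        rows = []
        for day, epoch in epoch_set:
            key = (subj, day, epoch)
            if key not in centered_covs:
                raise KeyError(f"missing covariance for {key!r}")
            rows.append(centered_covs[key][seed_ix])
        return np.mean(rows, axis=0)

    A = np.array([subject_mean_row(s, epochs_a) for s in subjects])
    B = np.array([subject_mean_row(s, epochs_b) for s in subjects])
    diff = A - B

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(A, B, axis=0)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # identical epoch sets give an exact zero contrast; report t = 0, p = 1
    zero = np.isnan(t) & np.isclose(diff, 0).all(axis=0)
    t[zero], p[zero] = 0.0, 1.0
    t[seed_ix], p[seed_ix] = np.nan, np.nan

    net_names = tuple(sorted(set(networks.values())))
    net_t = np.zeros(len(net_names))
    net_p = np.zeros(len(net_names))
    for k, net in enumerate(net_names):
        members = [i for i, r in enumerate(region_ids) if networks[r] == net and i != seed_ix]
        subj_change = diff[:, members].mean(axis=1)
        if np.allclose(subj_change, 0):
            net_t[k], net_p[k] = 0.0, 1.0
        else:
            net_t[k], net_p[k] = stats.ttest_rel(A[:, members].mean(axis=1),
                                                 B[:, members].mean(axis=1))
    label = contrast_label or f"{sorted(epochs_a)} > {sorted(epochs_b)}"
    return SeedContrastMap(
        seed=seed, contrast=label, region_ids=region_ids, t=t, p=p,
        network_names=net_names, network_t=net_t, network_p=net_p,
    )
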