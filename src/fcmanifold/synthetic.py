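"""Synthetic multi-subject, multi-epoch datasets with known ground truth.

The generator emulates the statistical structure of a two-day visuomotor
rotation study: 2 days x 5 task epochs (Baseline, Early/Late Learning,
Early/Late Washout) of 96-volume parcellated BOLD blocks per subject, plus
trial-level behavior.

Connectivity model.  Every region is given a latent 3-D "functional
geometry" position; regions of the same network cluster around a shared
centroid, and the base covariance ``Sigma0`` is a Gaussian kernel of
latent distance (plus a floor and edge-wise jitter), so within-network
couplings are elevated and the affinity spectrum has three dominant axes -
the low-dimensional manifold the analysis pipeline is designed to recover.
Subject-epoch covariances are composed additively in the tangent space at
``Sigma0`` and retracted with the exponential map (which guarantees SPD
covariances at any effect scale): a stable random subject signature ``D_i``,
a shared epoch effect ``E_j``, and a small subject-by-epoch fluctuation.
Shared epoch effects are generated geometrically, as covariance changes
induced by epoch-specific displacements of the latent positions; the planted
"contraction" additionally mixes the target regions' coupling profiles toward
the brain-average profile during Early Learning, which raises their
between-network covariance, lowers their within-network covariance and pulls
them toward the manifold centroid (lower eccentricity).  "Expansion" sharpens
their profiles away from the average instead.  When the
reinstatement flag is set, the Day-2 Early Learning effect is exactly the
Day-1 Early Learning effect; all other epochs get independent displacement
fields.  Time series are drawn as zero-mean Gaussians (optionally AR(1))
with the resulting covariance.

Behavioral model.  Learning-block error decays exponentially,
``error_t = 45 exp(-rho_i t) + noise`` with subject-specific rates ``rho_i``;
washout shows a mirrored, faster-decaying aftereffect; baseline error is pure
noise; Day-2 rates are scaled by a savings factor > 1.  Reaction times fall
inside the QC bounds except for a configurable contamination fraction.

All output is deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .connectivity import (
    EPOCH_LENGTH,
    EPOCH_NAMES,
    EpochDefinition,
    RegionTimeSeries,
    default_epoch_definitions,
)

DISCARD_VOLUMES = 6


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the desk-scale study conditions."""

    n_subjects: int = 24
    n_regions: int = 100
    n_networks: int = 7
    volumes_per_epoch: int = EPOCH_LENGTH
    # latent functional geometry
    centroid_radius_min: float = 1.2
    centroid_radius_max: float = 2.0
    latent_scatter: float = 0.80      # region scatter around its network centroid
    target_network_scatter: float = 0.35    # tighter scatter for the Net1 module
    kernel_amplitude: float = 0.35    # covariance at zero latent distance
    kernel_length: float = 1.0        # kernel length scale
    base_cov: float = 0.03            # covariance floor between distant regions
    edge_jitter: float = 0.02         # edge-wise SD added to the base couplings
    # effect scales
    subject_scale: float = 0.10       # entry SD of the stable subject tangent effect
    epoch_scale: float = 0.5          # latent displacement SD of shared epoch effects
    noise_scale: float = 0.01         # entry SD of subject-by-epoch tangent noise
    contraction_scale: float = 0.6    # fraction of target profile mixed toward average
    n_targets: int = 10
    plant_contraction: bool = True
    planted_effect: str = "contraction"     # or "expansion"
    reinstatement: bool = True
    ar_coef: float = 0.0              # AR(1) coefficient for the time series
    # behavior
    learning_rate_mean: float = 0.045       # per-trial exponential decay rate (median)
    learning_rate_log_sd: float = 0.5
    savings_factor: float = 1.8
    error_noise_sd: float = 4.0             # degrees, per trial
    aftereffect_fraction: float = 0.6
    rt_contamination: float = 0.01
    n_baseline_trials: int = 120
    n_learning_trials: int = 320
    n_washout_trials: int = 120
    seed: int = 0

    def __post_init__(self):
        for name in ("subject_scale", "epoch_scale", "noise_scale", "contraction_scale",
                     "latent_scatter", "error_noise_sd", "rt_contamination"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.planted_effect not in ("contraction", "expansion"):
            raise ValueError("planted_effect must be 'contraction' or 'expansion'")
        if self.n_networks > self.n_regions:
            raise ValueError("more networks than regions")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SyntheticGroundTruth:
    """Everything needed to verify pipeline recovery on generated data."""

    sigma0: np.ndarray
    latent_positions: np.ndarray     # (n_regions, 3) baseline functional geometry
    subject_effects: dict            # subject id -> tangent matrix D_i
    epoch_effects: dict              # (day, epoch) -> tangent matrix E_j
    learning_rates: dict             # subject id -> rho_i
    target_regions: list
    planted_effect: str
    reinstatement: bool

    def to_json(self) -> dict:
        return {
            "target_regions": list(self.target_regions),
            "planted_effect": self.planted_effect,
            "reinstatement": self.reinstatement,
            "learning_rates": {str(k): float(v) for k, v in self.learning_rates.items()},
            "epoch_effect_norms": {
                f"day{d}_{e}": float(np.linalg.norm(E)) for (d, e), E in self.epoch_effects.items()
            },
        }


def subject_ids(n: int) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(n)]


def gen_parcellation(n_regions: int, n_networks: int = 7, seed: int = 0) -> pd.DataFrame:
    """Region table with balanced network labels and unit-sphere centroids.

    Networks are contiguous blocks of near-equal size, named ``Net1..NetK``
    with ``Net1`` playing the association/DMN-analogue role; anatomical
    centroids (used only by the spin test) are uniform on the sphere, with
    hemisphere assigned by the sign of x.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    sizes = np.full(n_networks, n_regions // n_networks)
    sizes[: n_regions % n_networks] += 1
    networks = np.repeat([f"Net{k + 1}" for k in range(n_networks)], sizes)
    pts = rng.standard_normal((n_regions, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    hemi = np.where(pts[:, 0] < 0, "L", "R")
    return pd.DataFrame({
        "region": [f"R{i:03d}" for i in range(n_regions)],
        "network": networks,
        "hemisphere": hemi,
        "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
    })


def _latent_positions(cfg: GeneratorConfig, networks: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Latent 3-D positions: network centroids at staggered radii plus scatter.

    Net1, the association/DMN-analogue network that hosts planted effects, is
    placed at the largest radius: functionally segregated, with the highest
    baseline eccentricity, mirroring transmodal cortex at the apex of the
    connectivity gradient.
    """
    names = list(dict.fromkeys(networks))
    radii = np.linspace(cfg.centroid_radius_max, cfg.centroid_radius_min, len(names))
    centroids = {}
    for name, radius in zip(names, radii):
        v = rng.standard_normal(3)
        centroids[name] = radius * v / np.linalg.norm(v)
    tau = np.where(networks == names[0], cfg.target_network_scatter, cfg.latent_scatter)
    scatter = tau[:, None] * rng.standard_normal((networks.size, 3))
    return np.array([centroids[k] for k in networks]) + scatter


def _kernel_covariance(cfg: GeneratorConfig, positions: np.ndarray) -> np.ndarray:
    """Gaussian kernel of latent distance, with covariance floor and unit diagonal."""
    d2 = ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(axis=2)
    sigma = cfg.base_cov + cfg.kernel_amplitude * np.exp(-d2 / (2 * cfg.kernel_length**2))
    np.fill_diagonal(sigma, 1.0)
    return sigma


def _base_covariance(cfg: GeneratorConfig, positions: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Base covariance: latent kernel plus edge jitter, kept safely SPD."""
    n = positions.shape[0]
    sigma0 = _kernel_covariance(cfg, positions)
    A = rng.standard_normal((n, n))
    sigma0 = sigma0 + cfg.edge_jitter * (A + A.T) / np.sqrt(2.0)
    np.fill_diagonal(sigma0, 1.0)
    w_min = linalg.eigvalsh(sigma0)[0]
    if w_min < 0.05:
        sigma0 = sigma0 + (0.05 - w_min) * np.eye(n)
    return sigma0


def _sym_noise(rng: np.random.Generator, n: int, entry_sd: float) -> np.ndarray:
    A = rng.standard_normal((n, n))
    S = entry_sd * (A + A.T) / np.sqrt(2.0)
    np.fill_diagonal(S, 0.0)
    return S


def _epoch_displacement(cfg: GeneratorConfig, n_regions: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Random latent displacement field shared by all subjects in one epoch."""
    return cfg.epoch_scale * rng.standard_normal((n_regions, 3))


def _planted_profile_effect(sigma0: np.ndarray, targets: np.ndarray,
                            gamma: float) -> np.ndarray:
    """Symmetric tangent effect that flattens (or sharpens) target profiles.

    Contraction (``gamma > 0``) mixes each target region's coupling row a
    fraction ``gamma`` of the way toward the brain-average coupling row: its
    strong within-network couplings weaken, its weak between-network couplings
    strengthen, and its connectivity profile loses its network signature -
    integration, hence lower manifold eccentricity.  A negative ``gamma``
    sharpens the profile away from the average instead (segregation,
    expansion).
    """
    n = sigma0.shape[0]
    mean_row = (sigma0.sum(axis=0) - np.diag(sigma0)) / (n - 1)
    E = np.zeros_like(sigma0)
    # graded magnitudes (mean 1) give the planted effect a spatial pattern
    # across targets, the signature the reinstatement analysis looks for
    weights = np.linspace(0.4, 1.6, len(targets))
    for t, w in zip(targets, weights):
        delta = w * gamma * (mean_row - sigma0[t])
        delta[t] = 0.0
        E[t] += delta
        E[:, t] += delta
    # edges between two targets received two (different) updates; average them
    E[np.ix_(targets, targets)] /= 2.0
    np.fill_diagonal(E, 0.0)
    return E


def _epoch_effect(cfg: GeneratorConfig, positions: np.ndarray, sigma0: np.ndarray,
                  sigma_kernel: np.ndarray, displacement: np.ndarray,
                  targets: np.ndarray | None) -> np.ndarray:
    """Tangent-space epoch effect: latent displacement field plus planted effect.

    The shared random part is ``Sigma(positions + displacement) -
    Sigma(positions)``; on Early Learning epochs the planted profile
    flattening/sharpening of the target regions is added.
    """
    E = _kernel_covariance(cfg, positions + displacement) - sigma_kernel
    if targets is not None and cfg.plant_contraction:
        gamma = (cfg.contraction_scale if cfg.planted_effect == "contraction"
                 else -cfg.contraction_scale)
        E = E + _planted_profile_effect(sigma0, targets, gamma)
    return E


def gen_connectivity_dataset(
    cfg: GeneratorConfig,
) -> tuple[list[RegionTimeSeries], list[EpochDefinition], pd.DataFrame, SyntheticGroundTruth]:
    """Generate scans for every subject/day plus the matching ground truth.

    Returns ``(scans, epoch_definitions, parcellation, ground_truth)``; each
    subject/day contributes a task scan (Baseline + Early/Late Learning) and a
    washout scan (Early/Late Washout), with 6 discardable initial volumes.
    """
    rng = np.random.default_rng(cfg.seed)
    parc = gen_parcellation(cfg.n_regions, cfg.n_networks, seed=cfg.seed)
    networks = parc["network"].to_numpy()
    region_ids = tuple(parc["region"])
    positions = _latent_positions(cfg, networks, rng)
    sigma0 = _base_covariance(cfg, positions, rng)
    sigma_kernel = _kernel_covariance(cfg, positions)

    n_targets = min(cfg.n_targets, cfg.n_regions)
    targets = np.flatnonzero(networks == "Net1")[:n_targets]
    if targets.size < n_targets:       # spill over into subsequent regions
        extra = np.setdiff1d(np.arange(cfg.n_regions), targets)[: n_targets - targets.size]
        targets = np.sort(np.concatenate([targets, extra]))

    w, V = linalg.eigh(sigma0)
    sq = (V * np.sqrt(w)) @ V.T
    isq = (V / np.sqrt(w)) @ V.T

    epoch_effects: dict[tuple[int, str], np.ndarray] = {}
    for day in (1, 2):
        for epoch in EPOCH_NAMES:
            if epoch == "Baseline":
                E = np.zeros((cfg.n_regions, cfg.n_regions))
            elif (day, epoch) == (2, "EarlyLearning") and cfg.reinstatement:
                E = epoch_effects[(1, "EarlyLearning")].copy()
            else:
                disp = _epoch_displacement(cfg, cfg.n_regions, rng)
                E = _epoch_effect(
                    cfg, positions, sigma0, sigma_kernel, disp,
                    targets if epoch == "EarlyLearning" else None,
                )
            epoch_effects[(day, epoch)] = E

    subjects = subject_ids(cfg.n_subjects)
    subject_effects = {s: _sym_noise(rng, cfg.n_regions, cfg.subject_scale) for s in subjects}

    def retract(T: np.ndarray) -> np.ndarray:
        Tw = isq @ T @ isq
        Tw = 0.5 * (Tw + Tw.T)
        ew, eV = linalg.eigh(Tw)
        S = sq @ ((eV * np.exp(ew)) @ eV.T) @ sq
        return 0.5 * (S + S.T)

    def draw_block(cov: np.ndarray, n_vol: int) -> np.ndarray:
        L = linalg.cholesky(cov, lower=True)
        z = rng.standard_normal((cov.shape[0], n_vol))
        if cfg.ar_coef > 0:
            for t in range(1, n_vol):
                z[:, t] = cfg.ar_coef * z[:, t - 1] + np.sqrt(1 - cfg.ar_coef**2) * z[:, t]
        return L @ z

    epoch_defs = default_epoch_definitions(
        baseline_volumes=cfg.volumes_per_epoch,
        learning_volumes=2 * cfg.volumes_per_epoch,
        washout_volumes=2 * cfg.volumes_per_epoch,
    )
    scan_layout = {
        "task": ("Baseline", "EarlyLearning", "LateLearning"),
        "washout": ("EarlyWashout", "LateWashout"),
    }

    scans: list[RegionTimeSeries] = []
    for subj in subjects:
        D = subject_effects[subj]
        for day in (1, 2):
            for scan, epochs in scan_layout.items():
                blocks = []
                for k, epoch in enumerate(epochs):
                    W = _sym_noise(rng, cfg.n_regions, cfg.noise_scale)
                    cov = retract(D + epoch_effects[(day, epoch)] + W)
                    n_vol = cfg.volumes_per_epoch + (DISCARD_VOLUMES if k == 0 else 0)
                    blocks.append(draw_block(cov, n_vol))
                scans.append(RegionTimeSeries(
                    values=np.concatenate(blocks, axis=1),
                    subject=subj, day=day, scan=scan, region_ids=region_ids,
                ))

    truth = SyntheticGroundTruth(
        sigma0=sigma0,
        latent_positions=positions,
        subject_effects=subject_effects,
        epoch_effects=epoch_effects,
        learning_rates={},
        target_regions=[region_ids[t] for t in targets],
        planted_effect=cfg.planted_effect,
        reinstatement=cfg.reinstatement,
    )
    return scans, epoch_defs, parc, truth


def gen_learning_curves(cfg: GeneratorConfig) -> tuple[pd.DataFrame, dict[str, float]]:
    """Trial tables for the two-day task plus the true per-subject learning rates."""
    # independent stream so behavior does not perturb the imaging draw
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))
    subjects = subject_ids(cfg.n_subjects)
    rates = {
        s: float(cfg.learning_rate_mean *
                 np.exp(cfg.learning_rate_log_sd * rng.standard_normal()))
        for s in subjects
    }
    rows = []
    for subj in subjects:
        for day in (1, 2):
            rho = rates[subj] * (cfg.savings_factor if day == 2 else 1.0)
            for block, n_trials in (("Baseline", cfg.n_baseline_trials),
                                    ("Learning", cfg.n_learning_trials),
                                    ("Washout", cfg.n_washout_trials)):
                t = np.arange(n_trials)
                if block == "Baseline":
                    signal = np.zeros(n_trials)
                elif block == "Learning":
                    signal = 45.0 * np.exp(-rho * t)
                else:
                    signal = -45.0 * cfg.aftereffect_fraction * np.exp(-2.0 * rho * t)
                err = np.clip(signal + cfg.error_noise_sd * rng.standard_normal(n_trials),
                              -180.0, 180.0)
                rt = rng.uniform(300.0, 900.0, size=n_trials)
                bad = rng.random(n_trials) < cfg.rt_contamination
                rt[bad] = rng.choice([50.0, 2500.0], size=bad.sum())
                for i in range(n_trials):
                    rows.append((subj, day, block, i + 1, err[i], rt[i]))
    trials = pd.DataFrame(rows, columns=["subject", "day", "block", "trial",
                                         "error_deg", "rt_ms"])
    return trials, rates


def make_fixture(out_dir: str | Path, seed: int = 1234,
                 n_subjects: int = 6, n_regions: int = 21) -> GeneratorConfig:
    """Write a deterministic miniature dataset (time series, parcellation,
    trials, ground truth) for fast end-to-end tests."""
    from . import io as fio

    cfg = GeneratorConfig(n_subjects=n_subjects, n_regions=n_regions,
                          n_targets=min(4, n_regions), seed=seed)
    scans, epoch_defs, parc, truth = gen_connectivity_dataset(cfg)
    trials, rates = gen_learning_curves(cfg)
    truth.learning_rates = rates

    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    for ts in scans:
        fio.write_timeseries(out / "timeseries" / fio.timeseries_filename(ts), ts)
    fio.write_parcellation(out / "parcellation.tsv", parc)
    fio.write_trials(out / "trials.tsv", trials)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({"seed": seed, **truth.to_json()}, fh, indent=2, sort_keys=True)
    return cfg
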