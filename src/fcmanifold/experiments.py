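"""Simulation experiments that characterize the pipeline on generated data.

Each function runs the full analysis on synthetic datasets with known ground
truth and returns summary numbers: how completely centering removes subject
structure, how reliably a planted manifold contraction is detected, whether
the reinstatement similarity analysis peaks at Day-2 Early Learning and is
calibrated under the null, how well the behavioral Learning Score recovers the
true learning rates, and whether spin-test p-values are calibrated.  The
acceptance script and the heavier end of the test-suite are thin wrappers
around these functions.

Replicate problem sizes (subjects/regions) are scaled to desk-top runtimes;
effect scales are the generator defaults.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import silhouette_score

from . import inference as inf
from . import spd
from .behavior import subject_scores
from .pipeline import EPOCHS, eccentricity_from_covs, scans_to_covariances
from .synthetic import GeneratorConfig, gen_connectivity_dataset, gen_learning_curves

E_IX = {name: i for i, name in enumerate(EPOCHS)}


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit seeds derived from a master seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) >> 1]


def _dataset_eccentricity(cfg: GeneratorConfig):
    """Generate scans, run covariance + centering + manifold stages."""
    scans, epoch_defs, parc, truth = gen_connectivity_dataset(cfg)
    covs, _ = scans_to_covariances(scans, epoch_defs)
    subjects = sorted({k[0] for k in covs})
    centering = spd.center_dataset(covs)
    template, ecc = eccentricity_from_covs(centering.centered, subjects)
    networks = parc["network"].to_numpy()
    target_ix = np.array([list(parc["region"]).index(r) for r in truth.target_regions])
    return ecc, template, networks, target_ix, covs, centering, subjects, parc


def subject_separation(seed: int, n_subjects: int = 24, n_regions: int = 100,
                       subject_scale: float = 0.25, epoch_scale: float = 0.05) -> dict:
    """Silhouette of affine distances by subject label, before vs after centering.

    Strong positive silhouette before centering reflects stable subject
    covariance signatures; values near zero afterwards show that centering
    removed them.  The subject-effect scale is set well above the epoch-effect
    scale (sigma_D >> sigma_E), the regime in which subject identity dominates
    raw covariance similarity.
    """
    cfg = GeneratorConfig(n_subjects=n_subjects, n_regions=n_regions, seed=seed,
                          subject_scale=subject_scale, epoch_scale=epoch_scale)
    scans, epoch_defs, _, _ = gen_connectivity_dataset(cfg)
    covs, _ = scans_to_covariances(scans, epoch_defs)
    keys = sorted(covs)
    labels = [k[0] for k in keys]
    centering = spd.center_dataset(covs)
    d_before = spd.pairwise_affine_distance([covs[k] for k in keys])
    d_after = spd.pairwise_affine_distance([centering.centered[k] for k in keys])
    return {
        "silhouette_before": float(silhouette_score(d_before, labels, metric="precomputed")),
        "silhouette_after": float(silhouette_score(d_after, labels, metric="precomputed")),
        "n": len(keys),
    }


def contraction_detection(
    seed: int,
    n_replicates: int = 50,
    n_subjects: int = 16,
    n_regions: int = 70,
) -> dict:
    """Recovery of a planted manifold contraction in target regions.

    Per replicate: the mean Early-Learning-minus-Baseline eccentricity change
    of the target regions (expected negative), and sensitivity / realized
    false-discovery proportion of the region-wise Day x Epoch rmANOVA with
    BH-FDR at q = 0.05, scored against the generator's planted targets.  The
    shared random epoch effect is switched off so that non-target regions are
    genuinely null.
    """
    delta, sens, fdp = [], [], []
    for s in _child_seeds(seed, n_replicates):
        cfg = GeneratorConfig(
            n_subjects=n_subjects, n_regions=n_regions, seed=s,
            epoch_scale=0.0, reinstatement=False, plant_contraction=True,
        )
        ecc, _, _, targets, *_ = _dataset_eccentricity(cfg)
        d = (ecc[:, :, E_IX["EarlyLearning"]] - ecc[:, :, E_IX["Baseline"]]).mean(axis=(0, 1))
        delta.append(d[targets].mean())
        anova = inf.rm_anova_2way(ecc)
        sig, _ = inf.fdr_bh(anova.p_epoch, q=0.05)
        is_target = np.zeros(n_regions, dtype=bool)
        is_target[targets] = True
        sens.append(sig[is_target].mean())
        n_sig = sig.sum()
        fdp.append(sig[~is_target].sum() / n_sig if n_sig else 0.0)
    delta = np.asarray(delta)
    return {
        "fraction_negative_delta": float((delta < 0).mean()),
        "mean_target_delta": float(delta.mean()),
        "sensitivity": float(np.mean(sens)),
        "realized_fdr": float(np.mean(fdp)),
        "n": n_replicates,
    }


def _dmn_ensemble_regions(ecc, template, networks, q: float = 0.05, seed: int = 0) -> np.ndarray:
    """Regions of the functional ensemble whose modal network is Net1.

    Significant epoch-effect regions are clustered in template space (k = 4);
    if no cluster is Net1-dominated (or too few regions are significant) the
    Net1 regions themselves are used.
    """
    anova = inf.rm_anova_2way(ecc)
    sig, _ = inf.fdr_bh(anova.p_epoch, q=q)
    sig_ix = np.flatnonzero(sig)
    if sig_ix.size >= 12:
        ens = inf.kmeans_ensembles(template.coordinates[sig_ix], sig_ix,
                                   networks[sig_ix], k=4, seed=seed)
        for c in range(ens.k):
            members = ens.region_index[ens.labels == c]
            if ens.modal_network[c] == "Net1" and members.size >= 3:
                return members
    return np.flatnonzero(networks == "Net1")


def reinstatement_analysis(
    seed: int,
    n_replicates: int = 50,
    n_subjects: int = 20,
    n_regions: int = 70,
    metric: str = "pearson",
) -> dict:
    """Planted reinstatement plus a shuffled-epoch null from the same replicates.

    Power side: with the Day-2 Early Learning epoch effect planted equal to
    the Day-1 one, does the DMN-analogue ensemble's mean similarity profile
    peak at Day-2 Early Learning, and are the six planned one-tailed
    contrasts significant in aggregate (subjects pooled across replicates)?

    Calibration side: epoch effects are shared across subjects, so epochs
    genuinely differ within any one dataset; the null therefore shuffles the
    epoch assignment of every subject's similarity profile independently,
    which destroys the epoch alignment while preserving the values (the
    sigma_E-shuffled null).  The omnibus rejection rate on shuffled profiles
    estimates the test's type-I error at alpha = 0.05.
    """
    peaks = []
    pooled = []
    null_rejections = []
    for s in _child_seeds(seed, n_replicates):
        cfg = GeneratorConfig(n_subjects=n_subjects, n_regions=n_regions, seed=s,
                              reinstatement=True, plant_contraction=True)
        ecc, template, networks, *_ = _dataset_eccentricity(cfg)
        members = _dmn_ensemble_regions(ecc, template, networks, seed=s)
        profiles = inf.rsa_profile(ecc, EPOCHS, members, metric=metric)
        pooled.append(profiles)
        peaks.append(int(np.argmax(profiles.mean(axis=0)) == inf.RSA_REINSTATEMENT_INDEX))
        rng = np.random.default_rng(s + 1)
        shuffled = np.array([row[rng.permutation(row.size)] for row in profiles])
        null_rejections.append(int(inf.reinstatement_test(shuffled).p_omnibus < 0.05))
    pooled = np.vstack(pooled)
    agg = inf.reinstatement_test(pooled)
    return {
        "peak_rate": float(np.mean(peaks)),
        "aggregate_contrast_p_max": float(agg.contrast_p.max()),
        "aggregate_omnibus_p": float(agg.p_omnibus),
        "null_omnibus_type1": float(np.mean(null_rejections)),
        "n": n_replicates,
    }


def spin_calibration(
    seed: int,
    n_maps: int = 200,
    n_subjects: int = 20,
    n_regions: int = 70,
    n_perm: int = 1000,
) -> dict:
    """Spin-test calibration on spatially unstructured null maps.

    Returns the per-network rejection rate at alpha = 0.05 (uncorrected spin
    p-values) over ``n_maps`` independent subject-map/score draws, using one
    fixed set of spins (the null is conditional on the parcellation).
    """
    from .synthetic import gen_parcellation

    parc = gen_parcellation(n_regions, seed=seed)
    coords = parc[["x", "y", "z"]].to_numpy()
    hemi = parc["hemisphere"].tolist()
    networks = parc["network"].to_numpy()
    spins = inf.generate_spins(coords, hemi, n_perm=n_perm, seed=seed)
    rng = np.random.default_rng(seed + 1)
    rejected = []
    for _ in range(n_maps):
        delta = rng.standard_normal((n_subjects, n_regions))
        scores = rng.standard_normal(n_subjects)
        res = inf.spin_test(delta, scores, networks, spins=spins, seed=seed)
        rejected.append(res.p < 0.05)
    rates = np.mean(rejected, axis=0)
    return {
        "type1_mean": float(rates.mean()),
        "type1_max": float(rates.max()),
        "type1_min": float(rates.min()),
        "n": n_maps,
    }


def behavior_recovery(seed: int, n_subjects: int = 32) -> dict:
    """Spearman correlation between fPCA Learning Scores and the generator's
    true per-subject learning rates, plus group-level savings."""
    cfg = GeneratorConfig(n_subjects=n_subjects, seed=seed)
    trials, rates = gen_learning_curves(cfg)
    table, fpca = subject_scores(trials)
    rho_true = np.array([rates[s] for s in table["subject"]])
    rho = stats.spearmanr(table["learning_score"], rho_true).statistic
    rr_valid = table["recall_ratio"].dropna()
    return {
        "score_rate_spearman": float(rho),
        "fpc1_variance_explained": float(fpca.variance_explained[0]),
        "mean_savings_deg": float(table["savings"].mean()),
        "mean_recall_ratio": float(rr_valid.mean()) if len(rr_valid) else float("nan"),
        "n": n_subjects,
    }


def determinism_check(seed: int, work_dir) -> dict:
    """Run the file-driven pipeline twice on a fixture dataset and compare the
    checksums of every output table."""
    from pathlib import Path

    from .pipeline import RunConfig, run_pipeline
    from .synthetic import make_fixture

    work = Path(work_dir)
    data = work / "data"
    make_fixture(data, seed=seed % 2**31)
    manifests = []
    for run in ("run1", "run2"):
        cfg = RunConfig(
            timeseries_dir=str(data / "timeseries"),
            parcellation=str(data / "parcellation.tsv"),
            trials=str(data / "trials.tsv"),
            out_dir=str(work / run),
            n_perm=200,
            seed=7,
        )
        manifests.append(run_pipeline(cfg))
    sums = [{k: v["sha256"] for k, v in m["outputs"].items()} for m in manifests]
    return {
        "identical": float(sums[0] == sums[1]),
        "n": len(sums[0]),
    }


def template_variance(seed: int, n_subjects: int = 16, n_regions: int = 70) -> dict:
    """Cumulative variance explained by the top three template components."""
    cfg = GeneratorConfig(n_subjects=n_subjects, n_regions=n_regions, seed=seed)
    _, template, *_ = _dataset_eccentricity(cfg)
    return {
        "top3_variance_fraction": float(template.variance_explained.sum()),
        "n": n_regions,
    }


def geometry_roundtrip(seed: int, dim: int = 32, n_cases: int = 20) -> dict:
    """Worst-case error of the geometric round trips on random SPD matrices."""
    rng = np.random.default_rng(seed)

    def rand_spd():
        A = rng.standard_normal((dim, dim))
        return A @ A.T / dim + np.eye(dim)

    errs = []
    for _ in range(n_cases):
        S, base = rand_spd(), rand_spd()
        errs.append(np.abs(spd.matrix_power(spd.matrix_power(S, 0.5), 2.0) - S).max())
        T = spd.matrix_log(S)
        errs.append(np.abs(spd.matrix_exp(T) - S).max())
        errs.append(np.abs(spd.tangent_retract(spd.tangent_project(S, base), base) - S).max())
        A, B = rand_spd(), rand_spd()
        closed = spd.matrix_power(A, 0.5) @ spd.matrix_power(
            spd.matrix_power(A, -0.5) @ B @ spd.matrix_power(A, -0.5), 0.5
        ) @ spd.matrix_power(A, 0.5)
        errs.append(np.abs(spd.geometric_mean([A, B]) - closed).max())
        Tn = spd.tangent_project(S, base)
        transported = spd.parallel_transport(Tn, base, A)
        errs.append(abs(spd.whitened_norm(Tn, base) - spd.whitened_norm(transported, A)))
    return {"max_roundtrip_error": float(np.max(errs)), "n": n_cases}
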