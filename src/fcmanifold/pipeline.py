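"""End-to-end runner: time series -> covariances -> centering -> manifold ->
eccentricity -> statistics -> behavior -> report.

The pipeline can be driven from files through :class:`RunConfig` /
:func:`run_pipeline` (TOML config, TSV inputs, TSV/JSON outputs plus an
atomically-written manifest with checksums) or entirely in memory through
:func:`analyze_scans`, which the test-suite and the simulation experiments
use.  Given identical inputs, config and seeds, every numeric output is
reproducible bit-identically.
"""

from __future__ import annotations

import logging
import time
import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import behavior as beh
from . import connectivity as conn
from . import inference as inf
from . import io as fio
from . import manifold as man
from . import spd

logger = logging.getLogger(__name__)

EPOCHS = conn.EPOCH_NAMES
DAYS = (1, 2)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run (mirrors the TOML config file)."""

    timeseries_dir: str
    parcellation: str
    out_dir: str
    trials: str | None = None
    discard_initial: int = 6
    density: float = 0.10
    n_components: int = 3
    n_perm: int = 1000
    k_ensembles: int = 4
    fdr_q: float = 0.05
    rsa_metric: str = "pearson"
    seed: int = 0
    kmeans_restarts: int = 50

    def __post_init__(self):
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")
        if self.rsa_metric not in ("pearson", "spearman"):
            raise ValueError("rsa_metric must be 'pearson' or 'spearman'")
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must be in (0, 1)")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls(**raw)


@dataclass
class AnalysisResult:
    """In-memory outputs of :func:`analyze_scans`."""

    subjects: list
    region_ids: tuple
    networks: np.ndarray
    template: man.Embedding
    eccentricity: np.ndarray                   # (n_subj, 2, 5, n_regions)
    anova: inf.AnovaResult
    significant: np.ndarray                    # FDR mask on the Epoch effect
    ensembles: inf.EnsembleAssignment | None
    rsa_profiles: dict                         # ensemble id -> (n_subj, 7) array
    reinstatement: dict                        # ensemble id -> ReinstatementResult
    shrinkages: dict
    centering: spd.CenteringResult


def scans_to_covariances(
    scans: Sequence[conn.RegionTimeSeries],
    epoch_defs: Sequence[conn.EpochDefinition],
    discard_initial: int = 6,
) -> tuple[dict, dict]:
    """z-score, splice and estimate one Ledoit-Wolf covariance per epoch.

    Returns ``(covs, shrinkages)`` keyed by ``(subject, day, epoch)``.
    """
    covs, shrinkages = {}, {}
    for ts in scans:
        z = conn.zscore_timeseries(ts)
        blocks = conn.splice_epochs(z, epoch_defs, discard_initial=discard_initial)
        for epoch, block in blocks.items():
            cov, alpha = conn.ledoit_wolf_covariance(block)
            covs[(ts.subject, ts.day, epoch)] = cov
            shrinkages[(ts.subject, ts.day, epoch)] = alpha
    return covs, shrinkages


def eccentricity_from_covs(
    centered: dict,
    subjects: Sequence,
    density: float = 0.10,
    n_components: int = 3,
) -> tuple[man.Embedding, np.ndarray]:
    """Template construction, alignment and eccentricity for all epochs.

    Returns the template embedding and an ``(n_subj, 2, 5, n_regions)``
    eccentricity array ordered by ``subjects`` / day / :data:`EPOCHS`.
    """
    baselines = {s: [centered[(s, d, "Baseline")] for d in DAYS] for s in subjects}
    template = man.build_template(baselines, density=density, n_components=n_components)
    n_regions = template.coordinates.shape[0]
    ecc = np.zeros((len(subjects), len(DAYS), len(EPOCHS), n_regions))
    for i, subj in enumerate(subjects):
        for d, day in enumerate(DAYS):
            for e, epoch in enumerate(EPOCHS):
                emb = man.embed_covariance(centered[(subj, day, epoch)],
                                           density=density, n_components=n_components)
                aligned = man.procrustes_align(emb, template)
                ecc[i, d, e] = man.eccentricity(aligned)
    return template, ecc


def analyze_scans(
    scans: Sequence[conn.RegionTimeSeries],
    epoch_defs: Sequence[conn.EpochDefinition],
    parcellation: pd.DataFrame,
    cfg: RunConfig | None = None,
) -> AnalysisResult:
    """Full imaging analysis on in-memory scans."""
    if cfg is None:
        cfg = RunConfig(timeseries_dir="", parcellation="", out_dir="")
    region_ids = scans[0].region_ids
    fio.check_region_consistency(region_ids, parcellation)
    networks = parcellation.set_index("region").loc[list(region_ids), "network"].to_numpy()

    covs, shrinkages = scans_to_covariances(scans, epoch_defs, cfg.discard_initial)
    subjects = sorted({k[0] for k in covs})
    centering = spd.center_dataset({k: v for k, v in covs.items()})
    template, ecc = eccentricity_from_covs(
        centering.centered, subjects, density=cfg.density, n_components=cfg.n_components
    )

    anova = inf.rm_anova_2way(ecc)
    significant, _ = inf.fdr_bh(anova.p_epoch, q=cfg.fdr_q)

    ensembles = None
    rsa_profiles: dict = {}
    reinstatement: dict = {}
    sig_ix = np.flatnonzero(significant)
    if sig_ix.size >= cfg.k_ensembles:
        ensembles = inf.kmeans_ensembles(
            template.coordinates[sig_ix], sig_ix, networks[sig_ix],
            k=cfg.k_ensembles, seed=cfg.seed, n_restarts=cfg.kmeans_restarts,
        )
        for c in range(ensembles.k):
            members = ensembles.region_index[ensembles.labels == c]
            if members.size < 3:
                continue
            profiles = inf.rsa_profile(ecc, EPOCHS, members, metric=cfg.rsa_metric)
            rsa_profiles[c] = profiles
            reinstatement[c] = inf.reinstatement_test(profiles)

    return AnalysisResult(
        subjects=subjects, region_ids=region_ids, networks=networks,
        template=template, eccentricity=ecc, anova=anova, significant=significant,
        ensembles=ensembles, rsa_profiles=rsa_profiles, reinstatement=reinstatement,
        shrinkages=shrinkages, centering=centering,
    )


# ---------------------------------------------------------------------------
# file-driven run
# ---------------------------------------------------------------------------

def _ecc_long_table(res: AnalysisResult) -> pd.DataFrame:
    rows = []
    for i, subj in enumerate(res.subjects):
        for d, day in enumerate(DAYS):
            for e, epoch in enumerate(EPOCHS):
                rows.append(pd.DataFrame({
                    "subject": subj, "day": day, "epoch": epoch,
                    "region": list(res.region_ids),
                    "eccentricity": res.eccentricity[i, d, e],
                }))
    return pd.concat(rows, ignore_index=True)


def _anova_table(res: AnalysisResult) -> pd.DataFrame:
    a = res.anova
    return pd.DataFrame({
        "region": list(res.region_ids),
        "F_day": a.f_day, "p_day": a.p_day,
        "F_epoch": a.f_epoch, "p_epoch": a.p_epoch,
        "F_interaction": a.f_inter, "p_interaction": a.p_inter,
        "epoch_significant": res.significant.astype(int),
    })


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages from files and write result tables plus a manifest."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.time() - t0
        logger.info("stage %s at %.1fs", name, timings[name])

    parc = fio.read_parcellation(cfg.parcellation)
    ts_files = sorted(Path(cfg.timeseries_dir).glob("sub-*_day-*_scan-*.tsv"))
    if not ts_files:
        raise fio.FormatError(f"no time-series files in {cfg.timeseries_dir}")
    scans = [fio.read_timeseries(f) for f in ts_files]
    stage("read")

    epoch_defs = conn.default_epoch_definitions()
    res = analyze_scans(scans, epoch_defs, parc, cfg)
    stage("imaging")

    outputs = {}
    _ecc_long_table(res).to_csv(out / "eccentricity.tsv", sep="\t", index=False,
                                float_format="%.8g")
    outputs["eccentricity"] = out / "eccentricity.tsv"
    _anova_table(res).to_csv(out / "anova.tsv", sep="\t", index=False, float_format="%.8g")
    outputs["anova"] = out / "anova.tsv"

    tmpl = pd.DataFrame(res.template.coordinates,
                        columns=[f"PC{i+1}" for i in range(res.template.n_components)])
    tmpl.insert(0, "region", list(res.region_ids))
    tmpl.to_csv(out / "template.tsv", sep="\t", index=False, float_format="%.8g")
    outputs["template"] = out / "template.tsv"
    with open(out / "template_variance.json", "w") as fh:
        fh.write(pd.Series(res.template.variance_explained,
                           index=[f"PC{i+1}" for i in range(res.template.n_components)])
                 .to_json(indent=2))
    outputs["template_variance"] = out / "template_variance.json"

    if res.ensembles is not None:
        ens = pd.DataFrame({
            "region": [res.region_ids[i] for i in res.ensembles.region_index],
            "cluster": res.ensembles.labels,
            "modal_network": [res.ensembles.modal_network[c] for c in res.ensembles.labels],
        })
        ens.to_csv(out / "ensembles.tsv", sep="\t", index=False)
        outputs["ensembles"] = out / "ensembles.tsv"
        rsa_rows = []
        for c, profiles in res.rsa_profiles.items():
            for s_ix, subj in enumerate(res.subjects):
                for j, (day, epoch) in enumerate(inf.RSA_EPOCH_ORDER):
                    rsa_rows.append((c, subj, day, epoch, profiles[s_ix, j]))
        pd.DataFrame(rsa_rows, columns=["cluster", "subject", "day", "epoch", "r"]).to_csv(
            out / "rsa_profiles.tsv", sep="\t", index=False, float_format="%.8g")
        outputs["rsa_profiles"] = out / "rsa_profiles.tsv"
    stage("statistics")

    scores_table = None
    if cfg.trials:
        trials = fio.read_trials(cfg.trials)
        scores_table, fpca = beh.subject_scores(trials)
        scores_table.to_csv(out / "behavior_scores.tsv", sep="\t", index=False,
                            float_format="%.8g")
        outputs["behavior_scores"] = out / "behavior_scores.tsv"

        imaged = [s for s in res.subjects if s in set(scores_table["subject"])]
        if len(imaged) >= 4 and len(imaged) == len(res.subjects):
            e_ix = {name: i for i, name in enumerate(EPOCHS)}
            delta = (res.eccentricity[:, 0, e_ix["EarlyLearning"]]
                     - res.eccentricity[:, 0, e_ix["Baseline"]])
            scores = scores_table.set_index("subject").loc[res.subjects,
                                                           "learning_score"].to_numpy()
            spin = inf.spin_test(
                delta, scores, res.networks,
                coords=parc.set_index("region").loc[list(res.region_ids),
                                                    ["x", "y", "z"]].to_numpy()
                if {"x", "y", "z"} <= set(parc.columns) else None,
                hemisphere=parc.set_index("region").loc[list(res.region_ids),
                                                        "hemisphere"].tolist(),
                n_perm=cfg.n_perm, seed=cfg.seed, q=cfg.fdr_q,
            )
            pd.DataFrame({
                "network": spin.network_names,
                "r": spin.observed_r,
                "p_spin": spin.p,
                "significant": spin.significant.astype(int),
                "null_q025": np.quantile(spin.null_r, 0.025, axis=0),
                "null_q975": np.quantile(spin.null_r, 0.975, axis=0),
            }).to_csv(out / "network_correlations.tsv", sep="\t", index=False,
                      float_format="%.8g")
            outputs["network_correlations"] = out / "network_correlations.tsv"
    else:
        logger.info("no behavior table supplied; skipping behavioral stages")
    stage("behavior")

    manifest = {
        "config": asdict(cfg),
        "version": _package_version(),
        "n_subjects": len(res.subjects),
        "n_regions": len(res.region_ids),
        "timings_s": timings,
        "outputs": {k: {"path": str(v), "sha256": fio.file_checksum(v)}
                    for k, v in outputs.items()},
    }
    fio.write_manifest(out / "manifest.json", manifest)
    return manifest


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version
    try:
        return version("fcmanifold")
    except PackageNotFoundError:
        return "unknown"


def report(out_dir: str | Path) -> str:
    """Human-readable summary regenerated from stored outputs alone."""
    out = Path(out_dir)
    lines = ["fcmanifold run summary", "======================"]
    anova_path = out / "anova.tsv"
    if anova_path.exists():
        anova = pd.read_csv(anova_path, sep="\t")
        n_sig = int(anova["epoch_significant"].sum())
        lines.append(f"significant epoch-effect regions: {n_sig} / {len(anova)}")
        ens_path = out / "ensembles.tsv"
        if n_sig and ens_path.exists():
            ens = pd.read_csv(ens_path, sep="\t")
            pct = (ens.groupby("modal_network")["region"].count() / len(ens) * 100)
            for net, val in pct.sort_values(ascending=False).items():
                lines.append(f"  {net}: {val:.1f}% of significant regions")
        elif n_sig == 0:
            lines.append("  zero significant regions; ensemble and RSA stages skipped")
    rsa_path = out / "rsa_profiles.tsv"
    if rsa_path.exists():
        rsa = pd.read_csv(rsa_path, sep="\t")
        for c, grp in rsa.groupby("cluster"):
            prof = grp.groupby(["day", "epoch"], sort=False)["r"].mean()
            peak = prof.idxmax()
            lines.append(f"ensemble {c}: mean similarity peaks at day {peak[0]} {peak[1]} "
                         f"(r = {prof.max():.3f})")
    net_path = out / "network_correlations.tsv"
    if net_path.exists():
        net = pd.read_csv(net_path, sep="\t")
        for _, row in net.iterrows():
            flag = "*" if row["significant"] else " "
            lines.append(f"network {row['network']}: r = {row['r']:+.3f} "
                         f"(spin p = {row['p_spin']:.3f}){flag}")
    return "\n".join(lines)
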