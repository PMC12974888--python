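"""Region- and network-level statistics for eccentricity analyses.

Contents: vectorized within-subject ANOVAs (2 x 5 Day-by-Epoch per region and
the one-way omnibus used for similarity profiles), Benjamini-Hochberg FDR,
paired epoch contrasts, k-means functional ensembles in template manifold
space, reinstatement representational-similarity profiles, network-level
correlations with behavioral scores, and the spatial ("spin") permutation test
that builds nulls by rotating region centroids on the sphere.

No sphericity correction is applied to the repeated-measures ANOVAs: F ratios
are reported with their uncorrected degrees of freedom, e.g. Epoch df
``(b-1, (b-1)(n-1))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

# order of the 7 comparison epochs in a similarity profile (the Day-1 Early
# Learning reference pattern is compared to each of these)
RSA_EPOCH_ORDER = (
    (1, "LateLearning"),
    (1, "EarlyWashout"),
    (1, "LateWashout"),
    (2, "EarlyLearning"),
    (2, "LateLearning"),
    (2, "EarlyWashout"),
    (2, "LateWashout"),
)
RSA_REINSTATEMENT_INDEX = RSA_EPOCH_ORDER.index((2, "EarlyLearning"))


class InferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Per-outcome F and p for Day, Epoch and Day x Epoch effects."""

    f_day: np.ndarray
    p_day: np.ndarray
    f_epoch: np.ndarray
    p_epoch: np.ndarray
    f_inter: np.ndarray
    p_inter: np.ndarray
    df_day: tuple[int, int]
    df_epoch: tuple[int, int]
    df_inter: tuple[int, int]


def rm_anova_2way(y: np.ndarray) -> AnovaResult:
    """Two-way fully within-subject ANOVA, vectorized over trailing axes.

    Parameters
    ----------
    y : array of shape ``(n_subjects, n_day, n_epoch, ...)`` with a complete,
        balanced design.  Trailing axes (e.g. regions) are analyzed
        independently.

    Each main effect is tested against its effect-by-subject interaction; the
    Day x Epoch interaction against the three-way residual.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim < 3:
        raise InferenceError("need (subjects, day, epoch, ...) data")
    if np.isnan(y).any():
        raise InferenceError("missing cells in repeated-measures design")
    n, a, b = y.shape[:3]
    if n < 2 or a < 2 or b < 2:
        raise InferenceError("need >= 2 subjects and >= 2 levels per factor")

    grand = y.mean(axis=(0, 1, 2))
    m_s = y.mean(axis=(1, 2))            # (n, ...)
    m_d = y.mean(axis=(0, 2))            # (a, ...)
    m_e = y.mean(axis=(0, 1))            # (b, ...)
    m_sd = y.mean(axis=2)                # (n, a, ...)
    m_se = y.mean(axis=1)                # (n, b, ...)
    m_de = y.mean(axis=0)                # (a, b, ...)

    ss_day = b * n * ((m_d - grand) ** 2).sum(axis=0)
    ss_epoch = a * n * ((m_e - grand) ** 2).sum(axis=0)
    ss_inter = n * ((m_de - m_d[:, None] - m_e[None, :] + grand) ** 2).sum(axis=(0, 1))
    ss_ds = b * ((m_sd - m_s[:, None] - m_d[None, :] + grand) ** 2).sum(axis=(0, 1))
    ss_es = a * ((m_se - m_s[:, None] - m_e[None, :] + grand) ** 2).sum(axis=(0, 1))
    resid = (
        y
        - m_sd[:, :, None] - m_se[:, None, :] - m_de[None]
        + m_s[:, None, None] + m_d[None, :, None] + m_e[None, None, :]
        - grand
    )
    ss_res = (resid**2).sum(axis=(0, 1, 2))

    df_day = (a - 1, (a - 1) * (n - 1))
    df_epoch = (b - 1, (b - 1) * (n - 1))
    df_inter = ((a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1))

    def f_and_p(ss_eff, df_eff, ss_err, df_err):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_eff / df_eff) / (ss_err / df_err)
        f = np.where(np.asarray(ss_err) <= 0, np.inf, f)
        p = stats.f.sf(f, df_eff, df_err)
        return np.asarray(f, dtype=float), np.asarray(p, dtype=float)

    f_d, p_d = f_and_p(ss_day, df_day[0], ss_ds, df_day[1])
    f_e, p_e = f_and_p(ss_epoch, df_epoch[0], ss_es, df_epoch[1])
    f_i, p_i = f_and_p(ss_inter, df_inter[0], ss_res, df_inter[1])
    return AnovaResult(f_d, p_d, f_e, p_e, f_i, p_i, df_day, df_epoch, df_inter)


def rm_anova_1way(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """One-way within-subject ANOVA over ``(n_subjects, n_levels, ...)`` data.

    Returns ``(F, p, (df1, df2))`` with ``df = (k-1, (k-1)(n-1))``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim < 2:
        raise InferenceError("need (subjects, levels, ...) data")
    if np.isnan(y).any():
        raise InferenceError("missing cells in repeated-measures design")
    n, k = y.shape[:2]
    if n < 2 or k < 2:
        raise InferenceError("need >= 2 subjects and >= 2 levels")
    grand = y.mean(axis=(0, 1))
    m_s = y.mean(axis=1)
    m_l = y.mean(axis=0)
    ss_level = n * ((m_l - grand) ** 2).sum(axis=0)
    resid = y - m_s[:, None] - m_l[None] + grand
    ss_err = (resid**2).sum(axis=(0, 1))
    df = (k - 1, (k - 1) * (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_level / df[0]) / (ss_err / df[1])
    f = np.where(np.asarray(ss_err) <= 0, np.inf, f)
    p = stats.f.sf(f, df[0], df[1])
    return np.asarray(f, dtype=float), np.asarray(p, dtype=float), df


# ---------------------------------------------------------------------------
# multiple comparisons and contrasts
# ---------------------------------------------------------------------------

def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR. Returns ``(reject mask, adjusted p)``."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise InferenceError("empty p-value list")
    if np.any((pvals < 0) | (pvals > 1)):
        raise InferenceError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvals.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(pvals.shape), p_adj.reshape(pvals.shape)


def paired_contrast(
    a: np.ndarray,
    b: np.ndarray,
    alternative: str = "two-sided",
) -> tuple[np.ndarray, np.ndarray]:
    """Paired t-test between matched subject-level arrays (subjects on axis 0).

    Inputs are typically day-averaged epoch values.  An exactly-zero contrast
    is reported as ``t = 0, p = 1`` (two-sided).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InferenceError("paired arrays must have identical shapes")
    if a.shape[0] < 3:
        raise InferenceError("paired contrast needs >= 3 subjects")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(a, b, axis=0, alternative=alternative)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    zero = np.isnan(t) & np.atleast_1d(np.isclose(a - b, 0).all(axis=0))
    t[zero] = 0.0
    p[zero] = 1.0 if alternative == "two-sided" else 0.5
    if a.ndim == 1:
        return float(t[0]), float(p[0])
    return t, p


def day_average(ecc: np.ndarray, epochs: Sequence[str], members: Sequence[str]) -> np.ndarray:
    """Average eccentricity over days and a named epoch subset.

    ``ecc`` has shape ``(n_subjects, n_days, n_epochs, n_regions)`` with the
    epoch axis ordered as ``epochs``.
    """
    ix = [list(epochs).index(e) for e in members]
    return ecc[:, :, ix].mean(axis=(1, 2))


# ---------------------------------------------------------------------------
# functional ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleAssignment:
    region_index: np.ndarray          # indices of the clustered (significant) regions
    labels: np.ndarray                # cluster id in {0..k-1} per clustered region
    k: int
    modal_network: tuple[str, ...]    # modal network label per cluster


def kmeans_ensembles(
    coords: np.ndarray,
    region_index: np.ndarray,
    networks: Sequence[str],
    k: int = 4,
    seed: int = 0,
    n_restarts: int = 50,
) -> EnsembleAssignment:
    """k-means clustering of significant regions in template manifold space.

    Cluster ids are relabeled deterministically by descending cluster size
    (ties broken by the lowest member region index), and each cluster is
    annotated with the modal network label of its members.
    """
    coords = np.asarray(coords, dtype=float)
    region_index = np.asarray(region_index, dtype=int)
    if coords.shape[0] != region_index.shape[0]:
        raise InferenceError("coords/region_index length mismatch")
    if coords.shape[0] < k:
        raise InferenceError(f"cannot form {k} clusters from {coords.shape[0]} regions")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(coords)
    order = sorted(
        range(k),
        key=lambda c: (-(raw == c).sum(), int(region_index[raw == c].min())),
    )
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[c] for c in raw])
    modal = []
    nets = np.asarray(list(networks))
    for c in range(k):
        members = nets[labels == c]
        vals, counts = np.unique(members, return_counts=True)
        modal.append(str(vals[np.argmax(counts)]))
    return EnsembleAssignment(region_index=region_index, labels=labels, k=k,
                              modal_network=tuple(modal))


# ---------------------------------------------------------------------------
# reinstatement RSA
# ---------------------------------------------------------------------------

def rsa_profile(
    ecc: np.ndarray,
    epochs: Sequence[str],
    ensemble_regions: Sequence[int],
    metric: str = "pearson",
) -> np.ndarray:
    """Similarity of each later epoch's eccentricity pattern to Day-1 Early Learning.

    ``ecc`` has shape ``(n_subjects, 2, n_epochs, n_regions)``.  Returns an
    ``(n_subjects, 7)`` array ordered as :data:`RSA_EPOCH_ORDER`, restricted to
    the ensemble's regions.
    """
    ecc = np.asarray(ecc, dtype=float)
    regions = np.asarray(ensemble_regions, dtype=int)
    if regions.size < 3:
        raise InferenceError("ensemble needs >= 3 regions for spatial correlation")
    if metric not in ("pearson", "spearman"):
        raise InferenceError(f"unknown similarity metric {metric!r}")
    epochs = list(epochs)
    e_early = epochs.index("EarlyLearning")
    ref = ecc[:, 0, e_early][:, regions]          # day 1 early learning
    profiles = np.zeros((ecc.shape[0], len(RSA_EPOCH_ORDER)))
    for j, (day, epoch) in enumerate(RSA_EPOCH_ORDER):
        pat = ecc[:, day - 1, epochs.index(epoch)][:, regions]
        for s in range(ecc.shape[0]):
            x, y = ref[s], pat[s]
            if np.std(x) == 0 or np.std(y) == 0:
                raise InferenceError(f"constant eccentricity pattern for subject {s}")
            if metric == "pearson":
                profiles[s, j] = stats.pearsonr(x, y).statistic
            else:
                profiles[s, j] = stats.spearmanr(x, y).statistic
    return profiles


@dataclass
class ReinstatementResult:
    f_omnibus: float
    p_omnibus: float
    df_omnibus: tuple[int, int]
    contrast_t: np.ndarray       # one-tailed t, reinstatement epoch vs each other epoch
    contrast_p: np.ndarray
    contrast_epochs: tuple


def reinstatement_test(profiles: np.ndarray) -> ReinstatementResult:
    """Omnibus rmANOVA over the 7-epoch similarity profile plus planned contrasts.

    The planned one-tailed paired t-tests ask whether similarity to the Day-1
    Early Learning pattern is higher during Day-2 Early (re)Learning than
    during each of the six other epochs.  Following common reporting practice
    the six contrasts are not multiplicity-corrected.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[1] != len(RSA_EPOCH_ORDER):
        raise InferenceError(f"profiles must be (n_subjects, {len(RSA_EPOCH_ORDER)})")
    if profiles.shape[0] < 3:
        raise InferenceError("need >= 3 subjects")
    f, p, df = rm_anova_1way(profiles)
    others = [j for j in range(profiles.shape[1]) if j != RSA_REINSTATEMENT_INDEX]
    t = np.zeros(len(others))
    pv = np.zeros(len(others))
    for i, j in enumerate(others):
        t[i], pv[i] = paired_contrast(
            profiles[:, RSA_REINSTATEMENT_INDEX], profiles[:, j], alternative="greater"
        )
    return ReinstatementResult(
        f_omnibus=float(f), p_omnibus=float(p), df_omnibus=df,
        contrast_t=t, contrast_p=pv,
        contrast_epochs=tuple(RSA_EPOCH_ORDER[j] for j in others),
    )


# ---------------------------------------------------------------------------
# network correlations and spin test
# ---------------------------------------------------------------------------

def network_means(values: np.ndarray, networks: Sequence[str]) -> tuple[np.ndarray, tuple[str, ...]]:
    """Average the trailing region axis within each network label."""
    values = np.asarray(values, dtype=float)
    nets = np.asarray(list(networks))
    names = tuple(sorted(set(nets)))
    out = np.stack([values[..., nets == n].mean(axis=-1) for n in names], axis=-1)
    return out, names


def network_correlation(
    delta_ecc: np.ndarray,
    scores: np.ndarray,
    networks: Sequence[str],
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Pearson r between subjects' network-mean eccentricity change and scores."""
    delta_ecc = np.asarray(delta_ecc, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if delta_ecc.shape[0] != scores.shape[0]:
        raise InferenceError("subject count mismatch")
    if delta_ecc.shape[0] < 4:
        raise InferenceError("need >= 4 subjects for network correlations")
    if np.std(scores) == 0:
        raise InferenceError("scores are constant")
    means, names = network_means(delta_ecc, networks)
    r = _columnwise_pearson(means, scores)
    return r, names


def _columnwise_pearson(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, Xc.T @ yc / denom, np.nan)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation via QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _greedy_assignment(orig: np.ndarray, rotated: np.ndarray) -> np.ndarray:
    """One-to-one nearest-neighbour matching, greedy by distance.

    ``perm[i] = j`` means region ``i`` takes the value of region ``j`` after
    the rotation.
    """
    d = np.linalg.norm(orig[:, None, :] - rotated[None, :, :], axis=2)
    n = d.shape[0]
    perm = np.full(n, -1)
    d = d.copy()
    for _ in range(n):
        i, j = np.unravel_index(np.argmin(d), d.shape)
        perm[i] = j
        d[i, :] = np.inf
        d[:, j] = np.inf
    return perm


def generate_spins(
    coords: np.ndarray,
    hemisphere: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Spin permutations of regions on the sphere (one rotation per permutation).

    The same random rotation is applied to the left hemisphere and its mirror
    image (reflection of the x axis) to the right, then regions are reassigned
    one-to-one to their nearest rotated neighbour within each hemisphere.
    Returns an ``(n_perm, n_regions)`` integer array of source indices.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise InferenceError("unit-sphere centroids of shape (n, 3) are required")
    if np.isnan(coords).any():
        raise InferenceError("missing centroid coordinates")
    hemi = np.asarray(list(hemisphere))
    rng = np.random.default_rng(seed)
    mirror = np.diag([-1.0, 1.0, 1.0])
    sides = [np.flatnonzero(hemi == h) for h in ("L", "R")]
    if sum(ix.size for ix in sides) != coords.shape[0]:
        raise InferenceError("hemisphere labels must be 'L' or 'R'")
    perms = np.zeros((n_perm, coords.shape[0]), dtype=int)
    for p in range(n_perm):
        rot = _random_rotation(rng)
        for h, ix in enumerate(sides):
            if ix.size == 0:
                continue
            R = rot if h == 0 else mirror @ rot @ mirror
            local = _greedy_assignment(coords[ix], coords[ix] @ R.T)
            perms[p, ix] = ix[local]
    return perms


@dataclass
class SpinTestResult:
    network_names: tuple[str, ...]
    observed_r: np.ndarray
    null_r: np.ndarray             # (n_perm, n_networks)
    p: np.ndarray
    significant: np.ndarray        # BH-FDR mask at q
    q: float
    fallback_label_permutation: bool = False


def spin_test(
    delta_ecc: np.ndarray,
    scores: np.ndarray,
    networks: Sequence[str],
    coords: np.ndarray | None = None,
    hemisphere: Sequence[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    q: float = 0.05,
    spins: np.ndarray | None = None,
) -> SpinTestResult:
    """Spatial permutation test of network-level eccentricity/score correlations.

    The observed statistic per network is the Pearson correlation across
    subjects between network-mean eccentricity change and the behavioral
    score.  The null rotates the region-to-coordinate assignment (Vasa-style
    spins, identical across subjects), recomputes the network means and
    correlations, and uses the add-one two-sided p-value
    ``(1 + #{|null| >= |obs|}) / (1 + n_perm)``, BH-FDR corrected across
    networks.  When no spherical coordinates are available a plain label
    permutation of regions is used and flagged in the result.
    """
    delta_ecc = np.asarray(delta_ecc, dtype=float)
    scores = np.asarray(scores, dtype=float)
    nets = np.asarray(list(networks))
    names = tuple(sorted(set(nets)))
    obs, _ = network_correlation(delta_ecc, scores, nets)

    rng = np.random.default_rng(seed)
    fallback = False
    if spins is None:
        if coords is None or hemisphere is None:
            fallback = True
            spins = np.array([rng.permutation(delta_ecc.shape[1]) for _ in range(n_perm)])
        else:
            spins = generate_spins(coords, hemisphere, n_perm=n_perm, seed=seed)
    n_perm = spins.shape[0]

    masks = [nets == n for n in names]
    null = np.zeros((n_perm, len(names)))
    for p_ix in range(n_perm):
        spun = delta_ecc[:, spins[p_ix]]
        means = np.stack([spun[:, m].mean(axis=1) for m in masks], axis=1)
        null[p_ix] = _columnwise_pearson(means, scores)
    pvals = (1.0 + np.sum(np.abs(null) >= np.abs(obs)[None, :], axis=0)) / (1.0 + n_perm)
    reject, _ = fdr_bh(pvals, q=q)
    return SpinTestResult(
        network_names=names, observed_r=obs, null_r=null, p=pvals,
        significant=reject, q=q, fallback_label_permutation=fallback,
    )
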