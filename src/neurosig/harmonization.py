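"""Multi-site harmonization: ComBat location/scale correction plus CovBat
covariance correction, fitted with the training site as reference batch.

ComBat models each voxel value for map *i* at site *s* as

    y_isv = alpha_v + gamma_sv + delta_sv * eps_isv

and removes the per-site location ``gamma_sv`` and scale ``delta_sv`` using
parametric empirical-Bayes shrinkage (normal prior on gamma, inverse-gamma
prior on delta^2), pooling information across voxels within a site.  With a
reference batch, the grand mean ``alpha_v`` and pooled sd are taken from the
reference site and reference-site data passes through unchanged: holdout
maps are transformed into the training distribution, never the reverse,
because classifiers are frozen after fitting on training data.

CovBat then corrects residual site differences in feature *covariance*:
residuals after ComBat are projected onto their principal axes, the per-site
mean and variance of the top-q scores (q chosen by a cumulative
explained-variance cutoff) are aligned to the reference site, and the
adjusted scores are back-projected.

Because condition (class) structure shifts voxel means and covariances, the
full pipeline is fitted separately on the beta maps of each of the three
task conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import CLASS_LABELS, BetaMapSet


class HarmonizationError(ValueError):
    """Harmonization is not applicable to the given data."""


class SiteError(KeyError):
    """Data contains a site unknown to the fitted model."""


@dataclass
class CombatModel:
    """Fitted reference-batch ComBat parameters (no covariate design)."""

    reference_site: str
    site_ids: list[str]
    alpha: np.ndarray          # (n_voxels,) reference-site voxel means
    pooled_sd: np.ndarray      # (n_voxels,) reference-site voxel sds
    gamma_star: dict[str, np.ndarray]   # per-site EB location, standardized units
    delta_star: dict[str, np.ndarray]   # per-site EB scale, standardized units
    zero_variance: np.ndarray  # (n_voxels,) bool: passed through unadjusted

    def gamma_star_destandardized(self, site_id: str) -> np.ndarray:
        """Site location effect on the original beta scale."""
        return self.gamma_star[site_id] * self.pooled_sd


@dataclass
class CovbatModel:
    """ComBat plus principal-component-score harmonization parameters."""

    combat: CombatModel
    score_loadings: np.ndarray     # (n_voxels, q)
    q: int
    variance_fraction: float
    score_center: dict[str, np.ndarray]  # per-site score means, (q,)
    score_scale: dict[str, np.ndarray]   # per-site score sds, (q,)


@dataclass
class HarmonizationByClass:
    """One fitted CovBat model per task condition."""

    models: dict[str, CovbatModel]

    def __post_init__(self) -> None:
        if set(self.models) != set(CLASS_LABELS):
            raise HarmonizationError(
                f"expected one model per class {CLASS_LABELS}, "
                f"got {sorted(self.models)}"
            )


def _pool(train: BetaMapSet, holdout: BetaMapSet) -> tuple[np.ndarray, np.ndarray]:
    y = np.vstack([train.values_matrix(), holdout.values_matrix()])
    sites = np.concatenate([train.site_ids(), holdout.site_ids()])
    return y, sites


def combat_fit(train: BetaMapSet, holdout: BetaMapSet) -> CombatModel:
    """Fit reference-batch ComBat on the pooled train + holdout maps.

    The (single) training site is the reference batch.  Requires at least two
    sites in the pooled data and at least two maps per site.
    """
    y, sites = _pool(train, holdout)
    site_list = list(dict.fromkeys(sites))
    if len(site_list) < 2:
        raise HarmonizationError(
            "harmonization requires >= 2 sites; found only "
            f"{site_list}"
        )
    for s in site_list:
        if (sites == s).sum() < 2:
            raise HarmonizationError(f"site {s!r} has < 2 maps")
    train_sites = set(train.site_ids())
    if len(train_sites) != 1:
        raise HarmonizationError(
            "reference-batch ComBat expects a single training site, got "
            f"{sorted(train_sites)}"
        )
    reference_site = next(iter(train_sites))

    ref = y[sites == reference_site]
    alpha = ref.mean(axis=0)
    pooled_sd = ref.std(axis=0, ddof=1)
    zero_var = pooled_sd <= 1e-12
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance voxel(s) in the reference "
            "site pass through unadjusted",
            stacklevel=2,
        )
    safe_sd = np.where(zero_var, 1.0, pooled_sd)
    z = (y - alpha) / safe_sd

    gamma_star: dict[str, np.ndarray] = {}
    delta_star: dict[str, np.ndarray] = {}
    for s in site_list:
        zs = z[sites == s]
        n_s = zs.shape[0]
        if s == reference_site:
            gamma_star[s] = np.zeros(y.shape[1])
            delta_star[s] = np.ones(y.shape[1])
            continue
        gamma_hat = zs.mean(axis=0)
        delta2_hat = zs.var(axis=0, ddof=1)
        # moment-matched hyperpriors across voxels
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        m = delta2_hat.mean()
        s2 = delta2_hat.var(ddof=1)
        if s2 <= 1e-12:
            a_prior, b_prior = 2.0, m  # flat-ish fallback for degenerate spread
        else:
            a_prior = (2.0 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
        # single-pass conditional posterior (non-iterative EB)
        g_star = (n_s * tau2 * gamma_hat + delta2_hat * gamma_bar) / (
            n_s * tau2 + delta2_hat
        )
        resid2 = ((zs - g_star) ** 2).sum(axis=0)
        d2_star = (b_prior + 0.5 * resid2) / (n_s / 2.0 + a_prior - 1.0)
        d_star = np.sqrt(np.maximum(d2_star, 1e-12))
        g_star = np.where(zero_var, 0.0, g_star)
        d_star = np.where(zero_var, 1.0, d_star)
        gamma_star[s] = g_star
        delta_star[s] = d_star

    return CombatModel(
        reference_site=reference_site,
        site_ids=site_list,
        alpha=alpha,
        pooled_sd=safe_sd,
        gamma_star=gamma_star,
        delta_star=delta_star,
        zero_variance=zero_var,
    )


def combat_apply(model: CombatModel, data: BetaMapSet) -> BetaMapSet:
    """Apply fitted ComBat adjustments; reference-site maps are unchanged."""
    if len(data) == 0:
        return data
    y = data.values_matrix()
    sites = data.site_ids()
    unknown = set(sites) - set(model.site_ids)
    if unknown:
        raise SiteError(f"sites not seen at fit time: {sorted(unknown)}")
    out = y.copy()
    for s in np.unique(sites):
        if s == model.reference_site:
            continue
        idx = sites == s
        z = (y[idx] - model.alpha) / model.pooled_sd
        z_adj = (z - model.gamma_star[s]) / model.delta_star[s]
        adj = z_adj * model.pooled_sd + model.alpha
        adj[:, model.zero_variance] = y[idx][:, model.zero_variance]
        out[idx] = adj
    return data.with_values(out)


def _combat_residuals(model: CombatModel, data: BetaMapSet) -> np.ndarray:
    return data.values_matrix() - model.alpha


def covbat_fit_apply(
    train: BetaMapSet,
    holdout: BetaMapSet,
    variance_fraction: float = 0.95,
) -> tuple[CovbatModel, BetaMapSet]:
    """Fit ComBat + CovBat on pooled data and return the harmonized holdout.

    After ComBat, pooled residuals are decomposed by SVD; the smallest q
    principal scores reaching ``variance_fraction`` cumulative explained
    variance have their per-site mean and variance aligned to the reference
    (training) site, then the residuals are reassembled.
    """
    if not 0.0 < variance_fraction <= 1.0:
        raise HarmonizationError(
            f"variance_fraction must be in (0, 1], got {variance_fraction}"
        )
    combat = combat_fit(train, holdout)
    train_adj = combat_apply(combat, train)
    holdout_adj = combat_apply(combat, holdout)

    resid = np.vstack(
        [_combat_residuals(combat, train_adj), _combat_residuals(combat, holdout_adj)]
    )
    sites = np.concatenate([train_adj.site_ids(), holdout_adj.site_ids()])
    center = resid.mean(axis=0)
    u, svals, vt = np.linalg.svd(resid - center, full_matrices=False)
    evr = svals**2 / (svals**2).sum()
    rank = int((svals > svals[0] * 1e-10).sum()) if svals.size else 0
    q = int(np.searchsorted(np.cumsum(evr), variance_fraction - 1e-12) + 1)
    q = max(1, min(q, rank))
    loadings = vt[:q].T  # (n_voxels, q), orthonormal columns

    scores = (resid - center) @ loadings
    score_center: dict[str, np.ndarray] = {}
    score_scale: dict[str, np.ndarray] = {}
    for s in combat.site_ids:
        sc = scores[sites == s]
        score_center[s] = sc.mean(axis=0)
        sd = sc.std(axis=0, ddof=1)
        score_scale[s] = np.where(sd <= 1e-12, 1.0, sd)

    model = CovbatModel(
        combat=combat,
        score_loadings=loadings,
        q=q,
        variance_fraction=variance_fraction,
        score_center=score_center,
        score_scale=score_scale,
    )
    return model, covbat_apply(model, holdout, _pre_combat=False, _adjusted=holdout_adj)


def covbat_apply(
    model: CovbatModel,
    data: BetaMapSet,
    _pre_combat: bool = True,
    _adjusted: BetaMapSet | None = None,
) -> BetaMapSet:
    """Apply the fitted CovBat transform; reference-site data is unchanged."""
    if len(data) == 0:
        return data
    combat = model.combat
    adj = combat_apply(combat, data) if _pre_combat else _adjusted
    assert adj is not None
    y = adj.values_matrix()
    sites = adj.site_ids()
    ref = combat.reference_site
    out = y.copy()
    mu_ref = model.score_center[ref]
    sd_ref = model.score_scale[ref]
    for s in np.unique(sites):
        if s == ref:
            continue
        idx = sites == s
        resid = y[idx] - combat.alpha
        scores = resid @ model.score_loadings
        scores_adj = (scores - model.score_center[s]) / model.score_scale[
            s
        ] * sd_ref + mu_ref
        out[idx] = y[idx] + (scores_adj - scores) @ model.score_loadings.T
    return adj.with_values(out)


def harmonize_by_class(
    train: BetaMapSet,
    holdout: BetaMapSet,
    variance_fraction: float = 0.95,
) -> tuple[HarmonizationByClass, BetaMapSet]:
    """Fit one CovBat model per condition and return the harmonized holdout
    with annotations (subject, class, site, map order) preserved."""
    for label in CLASS_LABELS:
        if len(train.select_class(label)) == 0:
            raise HarmonizationError(f"training set has no {label!r} maps")
        if len(holdout.select_class(label)) == 0:
            raise HarmonizationError(f"holdout set has no {label!r} maps")

    models: dict[str, CovbatModel] = {}
    harmonized = holdout.values_matrix().copy()
    holdout_labels = np.array(holdout.label_names())
    for label in CLASS_LABELS:
        tr = train.select_class(label)
        hd = holdout.select_class(label)
        model, hd_harm = covbat_fit_apply(tr, hd, variance_fraction)
        models[label] = model
        harmonized[holdout_labels == label] = hd_harm.values_matrix()
    return HarmonizationByClass(models=models), holdout.with_values(harmonized)
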