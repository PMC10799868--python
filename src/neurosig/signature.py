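"""Bootstrap voxel-signature maps with sign-consistency thresholding.

For each bootstrap resample of training *subjects* (a subject's three
condition maps always enter together), the chosen model family is refitted
and per-class voxel contribution weights ``W_k = V beta_k`` are recorded,
where ``V`` is the training loading matrix (principal-component loadings for
LASSO-PCR, restricted to components kept by the penalty; the two
discriminant loadings for LDA) and ``beta_k`` the fitted multinomial
coefficients for class k.  Across replicates each voxel gets:

* ``prop_pos`` / ``prop_neg`` — share of replicates with strictly positive /
  negative weight (exact zeros, e.g. fully penalized components, count
  toward neither sign — conservatively reducing consistency),
* sign-consistency ``p = 1 - max(prop_pos, prop_neg)`` — significant at
  p < 0.005 means the voxel contributed with a consistent sign in at least
  99.5% of replicates,
* ``z`` — bootstrap mean weight divided by bootstrap sd.

Significant voxels are grouped into signed connected-component clusters with
volumes in mm^3 and peak world coordinates.

The identical bootstrap index lists are reused across model families so the
two signatures are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .classifiers import (
    LdaModel,
    PcrModel,
    fit_lasso_pcr,
    fit_lda,
    voxel_weights,
)
from .data_model import CLASS_LABELS, BetaMap, BetaMapSet, BrainMask, unmask

logger = logging.getLogger(__name__)

N_CLASSES = len(CLASS_LABELS)


@dataclass
class SignatureConfig:
    n_bootstrap: int = 1000
    p_threshold: float = 0.005
    seed: int = 0
    two_sided: bool = False      # alternative p = 2 * min(prop_pos, prop_neg)
    connectivity: int = 26       # 6, 18 or 26-neighborhood
    min_cluster_voxels: int = 10

    def __post_init__(self) -> None:
        if self.n_bootstrap < 100:
            raise ValueError("n_bootstrap must be >= 100")
        if not 0.0 < self.p_threshold < 0.5:
            raise ValueError("p_threshold must be in (0, 0.5)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class BootstrapWeights:
    """Per-class (n_bootstrap, n_voxels) matrices of contribution weights."""

    weights: dict[str, np.ndarray]
    n_bootstrap: int
    model_family: str


@dataclass
class SignatureMap:
    """Per-voxel bootstrap summary for one class."""

    class_label: str
    mean: np.ndarray
    sd: np.ndarray
    z: np.ndarray
    prop_pos: np.ndarray
    prop_neg: np.ndarray
    p: np.ndarray
    significant: np.ndarray   # bool
    p_threshold: float


@dataclass
class ClusterRecord:
    class_label: str
    sign: int                 # +1 or -1
    n_voxels: int
    volume_mm3: float
    peak_xyz_mm: tuple[float, float, float]
    max_z: float


def draw_bootstrap_samples(
    train: BetaMapSet, config: SignatureConfig
) -> list[np.ndarray]:
    """Draw subject-level bootstrap samples.

    Each sample is an array of ``n_subjects`` subject indices drawn with
    replacement (a sample over 82 subjects lists 82 draws and expands to
    their 246 maps).  Samples in which some class would be absent are
    redrawn (and logged); the returned list is reused verbatim for every
    model family.
    """
    subjects = train.subjects
    if len(subjects) < 2:
        raise ValueError("bootstrap needs at least 2 subjects")
    subj_labels = {
        s: set(train.labels()[train.subject_ids() == s]) for s in subjects
    }
    rng = np.random.default_rng(config.seed)
    samples: list[np.ndarray] = []
    while len(samples) < config.n_bootstrap:
        drawn = rng.choice(len(subjects), size=len(subjects), replace=True)
        covered = set().union(*(subj_labels[subjects[i]] for i in drawn))
        if len(covered) < N_CLASSES:
            logger.info("bootstrap sample missing a class; redrawing")
            continue
        samples.append(drawn)
    return samples


def expand_sample(train: BetaMapSet, subject_draws: np.ndarray) -> BetaMapSet:
    """Materialize one bootstrap sample as a BetaMapSet.

    A subject drawn multiple times enters once per draw as a distinct
    pseudo-subject (id suffixed ``#2``, ``#3``, ...), so repeated draws count
    as independent resampling units while the one-map-per-(subject, class)
    bookkeeping stays intact.
    """
    subjects = train.subjects
    by_subject = {
        s: [m for m in train if m.subject_id == s] for s in subjects
    }
    maps = []
    counts: dict[str, int] = {}
    for i in subject_draws:
        sid = subjects[int(i)]
        counts[sid] = counts.get(sid, 0) + 1
        suffix = "" if counts[sid] == 1 else f"#{counts[sid]}"
        for m in by_subject[sid]:
            maps.append(
                BetaMap(m.subject_id + suffix, m.class_label, m.site_id, m.values)
            )
    return BetaMapSet(train.mask, maps, train.class_encoding)


def _align_pca_signs(model: PcrModel, reference_v: np.ndarray) -> PcrModel:
    """Align bootstrap principal-axis signs to the full-data loadings by the
    inner-product rule, flipping matching coefficient rows.  ``W_k = V beta_k``
    is invariant to the joint flip; alignment makes the stored loadings and
    coefficients individually comparable across replicates."""
    k = min(model.V_pca.shape[1], reference_v.shape[1])
    signs = np.sign(np.einsum("vj,vj->j", model.V_pca[:, :k], reference_v[:, :k]))
    signs[signs == 0] = 1.0
    model.V_pca[:, :k] *= signs
    model.B_coef[:k] *= signs[:, None]
    return model


def compute_weights(
    samples: list[np.ndarray],
    train: BetaMapSet,
    model_family: str,
    variance_threshold: float = 0.90,
    lambda_: float | None = None,
    n_folds: int = 10,
    seed: int = 0,
    reference_model: PcrModel | None = None,
) -> BootstrapWeights:
    """Refit the model family on every bootstrap sample and collect
    per-class voxel weight vectors ``W_k = V beta_k``.

    For LASSO-PCR, the penalty is held fixed across replicates at
    ``lambda_`` (by default the cross-validated penalty of a full-data fit),
    so replicates differ only through resampling.  A replicate whose penalty
    removes every component yields an all-zero weight row (logged, not an
    error).
    """
    if model_family not in ("pcr", "lda"):
        raise ValueError(f"unknown model family {model_family!r}")
    n_vox = train.mask.n_voxels
    out = {c: np.zeros((len(samples), n_vox)) for c in CLASS_LABELS}

    ref_v: np.ndarray | None = None
    if model_family == "pcr":
        if lambda_ is None:
            if reference_model is None:
                reference_model = fit_lasso_pcr(
                    train,
                    variance_threshold=variance_threshold,
                    n_folds=n_folds,
                    seed=seed,
                )
            lambda_ = reference_model.lambda_
        if reference_model is not None:
            ref_v = reference_model.V_pca

    for b, idx in enumerate(samples):
        sample = expand_sample(train, idx)
        if model_family == "pcr":
            model: PcrModel | LdaModel = fit_lasso_pcr(
                sample, variance_threshold=variance_threshold, lambda_=lambda_
            )
            if ref_v is not None:
                model = _align_pca_signs(model, ref_v)
            if model.n_nonzero == 0:
                logger.info("bootstrap %d: all coefficients penalized to zero", b)
        else:
            model = fit_lda(sample)
        w = voxel_weights(model)  # (n_vox, 3)
        for k, c in enumerate(CLASS_LABELS):
            out[c][b] = w[:, k]
    return BootstrapWeights(
        weights=out, n_bootstrap=len(samples), model_family=model_family
    )


def sign_consistency(
    weights: BootstrapWeights, config: SignatureConfig
) -> dict[str, SignatureMap]:
    """Summarize bootstrap weight matrices into per-class signature maps."""
    maps: dict[str, SignatureMap] = {}
    for label, w in weights.weights.items():
        b = w.shape[0]
        prop_pos = (w > 0).sum(axis=0) / b
        prop_neg = (w < 0).sum(axis=0) / b
        if config.two_sided:
            p = 2.0 * np.minimum(prop_pos, prop_neg)
            # voxels never assigned a sign carry no evidence either way
            p = np.where((prop_pos + prop_neg) == 0, 1.0, p)
        else:
            p = 1.0 - np.maximum(prop_pos, prop_neg)
        mean = w.mean(axis=0)
        sd = w.std(axis=0, ddof=1)
        z = np.divide(mean, sd, out=np.zeros_like(mean), where=sd > 0)
        maps[label] = SignatureMap(
            class_label=label,
            mean=mean,
            sd=sd,
            z=z,
            prop_pos=prop_pos,
            prop_neg=prop_neg,
            p=p,
            significant=p < config.p_threshold,
            p_threshold=config.p_threshold,
        )
    return maps


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_clusters(
    sig_map: SignatureMap, mask: BrainMask, config: SignatureConfig
) -> list[ClusterRecord]:
    """Signed connected-component clusters of significant voxels.

    Components are found separately for positive-mean and negative-mean
    significant voxels (so touching opposite-sign voxels form distinct
    clusters), filtered by ``min_cluster_voxels``, and sorted by volume
    descending within each sign (positive first)."""
    structure = _STRUCTURES[config.connectivity]
    vv = mask.voxel_volume_mm3
    world = mask.world_coords()
    records: list[ClusterRecord] = []
    for sign in (+1, -1):
        sel = sig_map.significant & (
            sig_map.mean > 0 if sign > 0 else sig_map.mean < 0
        )
        grid = unmask(sel.astype(float), mask) > 0
        labeled, n_comp = ndimage.label(grid, structure=structure)
        comp_of_voxel = labeled[mask.inside]  # scan-order component id
        sign_records = []
        for comp in range(1, n_comp + 1):
            members = np.nonzero(comp_of_voxel == comp)[0]
            if len(members) < config.min_cluster_voxels:
                continue
            zvals = sig_map.z[members]
            peak_local = members[int(np.argmax(np.abs(zvals)))]
            sign_records.append(
                ClusterRecord(
                    class_label=sig_map.class_label,
                    sign=sign,
                    n_voxels=len(members),
                    volume_mm3=len(members) * vv,
                    peak_xyz_mm=tuple(np.round(world[peak_local], 6)),
                    max_z=float(sig_map.z[peak_local]),
                )
            )
        sign_records.sort(key=lambda r: -r.volume_mm3)
        records.extend(sign_records)
    return records


@dataclass
class SignatureResult:
    """Full bootstrap signature output for one model family."""

    family: str
    maps: dict[str, SignatureMap]
    clusters: dict[str, list[ClusterRecord]] = field(default_factory=dict)


def run_signature(
    train: BetaMapSet,
    config: SignatureConfig,
    families: tuple[str, ...] = ("pcr", "lda"),
    variance_threshold: float = 0.90,
    n_folds: int = 10,
    samples: list[np.ndarray] | None = None,
) -> dict[str, SignatureResult]:
    """End-to-end signature derivation: shared bootstrap samples, per-family
    weights, sign-consistency maps, and signed cluster tables."""
    if samples is None:
        samples = draw_bootstrap_samples(train, config)
    results: dict[str, SignatureResult] = {}
    for family in families:
        weights = compute_weights(
            samples,
            train,
            family,
            variance_threshold=variance_threshold,
            n_folds=n_folds,
            seed=config.seed,
        )
        maps = sign_consistency(weights, config)
        clusters = {
            label: extract_clusters(maps[label], train.mask, config)
            for label in maps
        }
        results[family] = SignatureResult(
            family=family, maps=maps, clusters=clusters
        )
    return results
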