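"""Spatial ICA decomposition and z-map-weighted AIF extraction.

The dynamic series is arranged as a time-by-voxel matrix X (p × v) and
decomposed by spatial ICA: after PCA dimension reduction to q components,
FastICA maximizes the non-Gaussianity of the *voxel-domain* maps, yielding
q spatial component maps N (q × v) with paired mixing time courses, so that
the centered data is approximated by the sum of time-course ⊗ map outer
products.

A component map of interest is standardized into a z-map
(z_i = (x_i - mean) / std over the map, population convention), the k
voxels of largest z form the AIF region, and the AIF is the z-weighted
average of their time courses with weights normalized to mean one — so a
uniform map reduces exactly to the plain region average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.decomposition import PCA, FastICA

from .concentration import (
    ConversionParams,
    GammaFit,
    GammaFitError,
    aif_features,
    fit_gamma_variate,
)
from .series import DynamicSeries

__all__ = [
    "ICResult",
    "ZMap",
    "AIFCurve",
    "ComponentScore",
    "RegionSelection",
    "decompose",
    "decompose_ensemble",
    "compactness",
    "zscore_map",
    "rank_components",
    "top_k_voxels",
    "weighted_aif",
    "component_zmap",
    "pole_response",
    "select_artery_surround",
]

log = logging.getLogger(__name__)


@dataclass
class ICResult:
    """Spatial ICA decomposition of a dynamic series.

    ``component_maps`` has shape (q, v) over the masked voxel domain,
    ``time_courses`` shape (q, p).  ``voxel_ids`` maps the v columns back to
    flat indices of the original image grid.
    """

    component_maps: np.ndarray
    time_courses: np.ndarray
    explained_variance: np.ndarray
    voxel_ids: np.ndarray
    spatial_shape: Tuple[int, ...]
    feature_means: np.ndarray  # per-time-point means removed before ICA
    data: Optional[np.ndarray] = None  # the masked (p, v) matrix decomposed
    seed: Optional[int] = None

    def positions_of(self, flat_ids: np.ndarray) -> np.ndarray:
        """Columns of the masked domain corresponding to flat voxel ids."""
        pos = np.searchsorted(self.voxel_ids, flat_ids)
        if not np.array_equal(self.voxel_ids[pos], np.asarray(flat_ids)):
            raise KeyError("voxel ids outside the decomposition domain")
        return pos

    @property
    def n_components(self) -> int:
        return self.component_maps.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Approximate the data (p × v) from the retained components."""
        return self.time_courses.T @ self.component_maps + self.feature_means[:, None]


@dataclass
class ZMap:
    """A component map standardized by its own moments (population std)."""

    values: np.ndarray
    mean_ic: float
    std_ic: float
    voxel_ids: np.ndarray
    component: Optional[int] = None

    def value_at(self, flat_ids: np.ndarray) -> np.ndarray:
        lookup = {int(v): i for i, v in enumerate(self.voxel_ids)}
        try:
            pos = np.array([lookup[int(v)] for v in np.atleast_1d(flat_ids)])
        except KeyError as e:  # pragma: no cover - guarded by callers
            raise KeyError(f"voxel {e} not in z-map domain") from e
        return self.values[pos]


@dataclass
class AIFCurve:
    """A (weighted) arterial input function with its provenance."""

    curve: np.ndarray
    voxel_ids: np.ndarray
    weights: np.ndarray
    source_label: str = "artery"
    component: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.voxel_ids) != len(self.weights):
            raise ValueError("voxel_ids and weights must have equal length")


@dataclass(frozen=True)
class ComponentScore:
    """Bolus-likeness of one pole (map orientation) of one component.

    An IC map is a spatial contrast: both its positive and negative poles
    can mark coherent regions, so each orientation is ranked as a separate
    candidate.  ``sign`` is +1/-1 for the pole; ``flipped`` is True for the
    negative pole.
    """

    component: int
    score: float
    fit: Optional[GammaFit]
    sign: int = 1
    error: Optional[str] = None

    @property
    def flipped(self) -> bool:
        return self.sign < 0


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def choose_n_components(eigen_fractions: Sequence[float], variance_fraction: float) -> int:
    """Smallest q whose cumulative eigenvalue fraction reaches the target."""
    cum = np.cumsum(np.asarray(eigen_fractions, dtype=float))
    hit = np.nonzero(cum >= variance_fraction - 1e-12)[0]
    if hit.size == 0:
        return len(cum)
    return int(hit[0]) + 1


def decompose(
    series: Union[DynamicSeries, np.ndarray],
    brain_mask: Optional[np.ndarray] = None,
    n_components: Optional[int] = None,
    variance_fraction: Optional[float] = None,
    seed: int = 0,
    max_iter: int = 2000,
    fun: str = "exp",
) -> ICResult:
    """Spatial ICA of a dynamic series.

    Exactly one of ``n_components`` / ``variance_fraction`` selects the PCA
    reduction: a fixed q, or the smallest q covering that fraction of the
    eigenvalue spectrum.  Deterministic for a given ``seed``.
    """
    if isinstance(series, DynamicSeries):
        X = series.as_matrix()
        spatial_shape = series.spatial_shape
    else:
        X = np.asarray(series, dtype=float)
        spatial_shape = (X.shape[1],)
    p, v_full = X.shape

    if brain_mask is None:
        voxel_ids = np.arange(v_full)
    else:
        brain_mask = np.asarray(brain_mask)
        voxel_ids = (np.nonzero(brain_mask.ravel())[0]
                     if brain_mask.dtype == bool else brain_mask.astype(int))
    Xm = X[:, voxel_ids]
    v = Xm.shape[1]

    if (n_components is None) == (variance_fraction is None):
        raise ValueError("specify exactly one of n_components / variance_fraction")
    if not np.isfinite(Xm).all():
        raise ValueError("non-finite values in masked data")
    if np.ptp(Xm) == 0:
        raise ValueError("degenerate (zero-variance) data")

    # voxels are the samples, time points the features: spatial ICA
    D = Xm.T
    pca = PCA(n_components=min(p, v), random_state=seed)
    pca.fit(D)
    evr = pca.explained_variance_ratio_

    if variance_fraction is not None:
        if not (0 < variance_fraction <= 1):
            raise ValueError("variance_fraction must be in (0, 1]")
        q = choose_n_components(evr, variance_fraction)
    else:
        q = int(n_components)
    if q > p:
        raise ValueError(f"n_components={q} exceeds the {p} time points")
    if q > v:
        raise ValueError(f"n_components={q} exceeds the {v} masked voxels")

    ica = FastICA(
        n_components=q,
        random_state=seed,
        whiten="unit-variance",
        fun=fun,
        max_iter=max_iter,
        tol=1e-5,
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # partial convergence is expected on noisy data; restart pooling
        # (decompose_ensemble) is the stabilization mechanism
        warnings.simplefilter("ignore", ConvergenceWarning)
        maps = ica.fit_transform(D)      # (v, q) spatial maps
    time_courses = ica.mixing_           # (p, q)
    return ICResult(
        component_maps=maps.T,
        time_courses=time_courses.T,
        explained_variance=evr[:q],
        voxel_ids=voxel_ids,
        spatial_shape=spatial_shape,
        feature_means=ica.mean_,
        data=Xm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# z-maps and voxel selection
# ---------------------------------------------------------------------------

def zscore_map(
    component_map: np.ndarray,
    voxel_ids: Optional[np.ndarray] = None,
    component: Optional[int] = None,
) -> ZMap:
    """Standardize an IC map: z_i = (x_i - mean) / std, population std."""
    x = np.asarray(component_map, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("constant map: z-scores undefined")
    mean = float(x.mean())
    std = float(x.std(ddof=0))
    if std == 0:
        raise ValueError("zero-variance map: z-scores undefined")
    if voxel_ids is None:
        voxel_ids = np.arange(x.size)
    return ZMap(values=(x - mean) / std, mean_ic=mean, std_ic=std,
                voxel_ids=np.asarray(voxel_ids), component=component)


def top_k_voxels(z: ZMap, k: int = 50) -> np.ndarray:
    """Flat ids of the k voxels of largest z; ties by ascending voxel index."""
    if k > z.values.size:
        raise ValueError(f"k={k} exceeds map size {z.values.size}")
    order = np.lexsort((z.voxel_ids, -z.values))
    return z.voxel_ids[order[:k]].copy()


def weighted_aif(
    series_or_matrix: Union[DynamicSeries, np.ndarray],
    voxels: np.ndarray,
    z: ZMap,
    source_label: str = "artery",
) -> AIFCurve:
    """z-weighted average AIF over the selected voxels.

    Weights are the z-values of the selected voxels normalized to mean 1,
    so the weighted average reduces to the plain mean under uniform z.
    Selected voxels with non-positive z are excluded (with a log message).
    """
    X = (series_or_matrix.as_matrix()
         if isinstance(series_or_matrix, DynamicSeries)
         else np.asarray(series_or_matrix, dtype=float))
    voxels = np.asarray(voxels, dtype=int)
    if voxels.size < 1:
        raise ValueError("need at least one voxel")
    zvals = z.value_at(voxels)
    keep = zvals > 0
    if not keep.all():
        log.warning("weighted_aif: excluding %d voxels with non-positive z",
                    int((~keep).sum()))
        voxels, zvals = voxels[keep], zvals[keep]
        if voxels.size == 0:
            raise ValueError("no voxels with positive z remain")
    weights = zvals / zvals.mean()
    curve = (X[:, voxels] * weights[None, :]).sum(axis=1) / voxels.size
    return AIFCurve(curve=curve, voxel_ids=voxels, weights=weights,
                    source_label=source_label, component=z.component)


# ---------------------------------------------------------------------------
# component ranking and selection
# ---------------------------------------------------------------------------

def align_sign(time_course: np.ndarray, baseline_slice: slice) -> Tuple[np.ndarray, bool]:
    """Flip a component time course so its bolus deflection is positive.

    The deflection is measured against the pre-injection baseline mean; the
    baseline-subtracted course is returned.
    """
    tc = np.asarray(time_course, dtype=float)
    dev = tc - tc[baseline_slice].mean()
    k = int(np.argmax(np.abs(dev)))
    flipped = dev[k] < 0
    return (-dev if flipped else dev), flipped


def pole_response(
    ic: ICResult,
    component: int,
    sign: int,
    baseline_slice: slice,
    k: int = 50,
) -> np.ndarray:
    """Bolus response of one pole: mean signal of its top-k voxels,
    expressed as the positive-going drop (baseline mean minus signal)."""
    if ic.data is None:
        raise ValueError("ICResult carries no data matrix")
    z = component_zmap(ic, component, sign)
    k = min(k, z.values.size)
    vox = top_k_voxels(z, k)
    curve = ic.data[:, ic.positions_of(vox)].mean(axis=1)
    return curve[baseline_slice].mean() - curve


def rank_components(
    ic: ICResult,
    conv: ConversionParams,
    dt: float,
    fit_window: Tuple[int, int] = (7, 25),
    k: int = 50,
) -> List[ComponentScore]:
    """Rank component poles by the bolus-likeness of their regions.

    Every component map is a spatial contrast, so both poles are candidate
    regions.  For each pole, the mean raw signal of its top-k z voxels is
    turned into a positive-going bolus (baseline minus signal) and
    gamma-fitted; the score is peak_height / (FWHM * max(TTP, dt)) — early,
    narrow, high-peaked responses (arteries) rank first.  Poles whose fit
    fails score 0 and sink to the bottom; ties keep ascending component
    order with the positive pole first.
    """
    window = conv.baseline_window or (1, max(1, fit_window[0] - 1))
    bsl = slice(window[0] - 1, window[1])
    scores: List[ComponentScore] = []
    for i in range(ic.n_components):
        for sign in (1, -1):
            try:
                curve = pole_response(ic, i, sign, bsl, k)
                # reduced start grid: ranking needs robust, not exhaustive, fits
                fit = fit_gamma_variate(curve, dt, fit_window,
                                        starts=[(0, 3.0), (2, 2.0)], maxfev=4000)
                feats = aif_features(curve, fit, dt)
                score = feats.peak_height / (feats.fwhm * max(feats.ttp, dt))
                scores.append(ComponentScore(i, float(score), fit, sign))
            except (GammaFitError, ValueError) as e:
                log.info("component %d pole %+d not bolus-like (%s)", i, sign, e)
                scores.append(ComponentScore(i, 0.0, None, sign, error=str(e)))
    return sorted(scores, key=lambda s: (-s.score, s.component, -s.sign))


def component_zmap(ic: ICResult, component: int, sign: int = 1) -> ZMap:
    """z-map of one pole of a component.

    ICA leaves a sign ambiguity on each (map, time course) pair, and a map
    is in general a contrast whose two poles mark different regions;
    ``sign`` selects which pole carries the high z-values.
    """
    m = ic.component_maps[component]
    return zscore_map(m if sign >= 0 else -m, ic.voxel_ids, component)


def _face_adjacent(ids_a: np.ndarray, ids_b: np.ndarray,
                   spatial_shape: Tuple[int, ...]) -> bool:
    """True if any voxel of set A is a face neighbor of a voxel of set B."""
    coords_b = {tuple(c) for c in np.array(np.unravel_index(ids_b, spatial_shape)).T}
    ndim = len(spatial_shape)
    for ca in np.array(np.unravel_index(ids_a, spatial_shape)).T:
        for axis in range(ndim):
            for step in (-1, 1):
                nb = list(ca)
                nb[axis] += step
                if tuple(nb) in coords_b:
                    return True
    return False


def compactness(flat_ids: np.ndarray, spatial_shape: Tuple[int, ...]) -> int:
    """Number of face-adjacent voxel pairs inside a set.

    Contiguous anatomical regions score high; noise-scattered voxel sets
    score low.
    """
    coords = {tuple(c) for c in np.array(np.unravel_index(flat_ids, spatial_shape)).T}
    ndim = len(spatial_shape)
    n = 0
    for c in coords:
        for axis in range(ndim):
            nb = list(c)
            nb[axis] += 1
            if tuple(nb) in coords:
                n += 1
    return n


@dataclass
class RegionSelection:
    """One selected AIF region: the decomposition run, pole, and voxels."""

    ic: ICResult
    candidate: ComponentScore
    zmap: ZMap
    voxels: np.ndarray

    @property
    def component(self) -> int:
        return self.candidate.component


def decompose_ensemble(
    series: Union[DynamicSeries, np.ndarray],
    brain_mask: Optional[np.ndarray] = None,
    n_components: Optional[int] = None,
    variance_fraction: Optional[float] = None,
    seed: int = 0,
    n_restarts: int = 8,
    conv: Optional[ConversionParams] = None,
    dt: float = 1.5,
    k: int = 50,
    **kwargs,
) -> List[Tuple[ICResult, List[ComponentScore]]]:
    """Run spatial ICA from several random starts and rank each run's poles.

    FastICA is a stochastic optimization; pooling candidates over restarts
    stabilizes region selection.  Restart r uses seed ``(seed*1009 + r)``.
    Returns ``(ICResult, ranking)`` pairs.
    """
    conv = conv or ConversionParams()
    runs = []
    for r in range(n_restarts):
        sub = (int(seed) * 1009 + r) % (2**31)
        ic = decompose(series, brain_mask=brain_mask, n_components=n_components,
                       variance_fraction=variance_fraction, seed=sub, **kwargs)
        runs.append((ic, rank_components(ic, conv, dt, k=k)))
    return runs


def select_artery_surround(
    runs,
    ranking=None,
    k: int = 50,
    max_shared: int = 13,
    conv: Optional[ConversionParams] = None,
    dt: float = 1.5,
):
    """Automatic pick of the artery and artery-surrounding AIF regions.

    ``runs`` is either a single :class:`ICResult` (with its ``ranking``) or
    a list of ``(ICResult, ranking)`` pairs from restarts.  The artery is
    the globally top-scoring pole.  Surrounding-tissue candidates are the
    pooled poles that (i) share at most ``max_shared`` of their top-k
    voxels with the artery set — about half the partial-volume strip that
    both regions legitimately claim — and (ii) are face-adjacent to it;
    among those, the winner maximizes (restart stability) x (spatial
    compactness), where stability is the mean Jaccard overlap of the
    candidate's voxel set with the other eligible candidates and
    compactness counts face-adjacent pairs inside the set.  Returns a pair
    of :class:`RegionSelection` (surround may be None).
    """
    if isinstance(runs, ICResult):
        if ranking is None:
            raise ValueError("a single ICResult needs its ranking")
        pairs = [(runs, ranking)]
    else:
        pairs = list(runs)

    best = max(pairs, key=lambda pr: pr[1][0].score)
    ic_a, rank_a = best
    art_cand = rank_a[0]
    z_art = component_zmap(ic_a, art_cand.component, art_cand.sign)
    art_vox = top_k_voxels(z_art, k)
    art_set = set(art_vox.tolist())
    artery = RegionSelection(ic_a, art_cand, z_art, art_vox)

    eligible = []
    for ic, rank in pairs:
        for cand in rank:
            if cand.score <= 0:
                continue
            if ic is ic_a and cand.component == art_cand.component:
                continue
            z = component_zmap(ic, cand.component, cand.sign)
            vox = top_k_voxels(z, k)
            vset = set(vox.tolist())
            if len(art_set & vset) > max_shared:
                continue
            if not _face_adjacent(vox, art_vox, ic.spatial_shape):
                continue
            eligible.append((vset, compactness(vox, ic.spatial_shape),
                             RegionSelection(ic, cand, z, vox)))
    if not eligible:
        log.warning("no adjacent, artery-disjoint surrounding-tissue candidate")
        return artery, None

    def stability(i):
        others = [e for j, e in enumerate(eligible) if j != i]
        if not others:
            return 1.0
        return float(np.mean([
            len(eligible[i][0] & o[0]) / len(eligible[i][0] | o[0])
            for o in others
        ]))

    quality = [stability(i) * e[1] for i, e in enumerate(eligible)]
    return artery, eligible[int(np.argmax(quality))][2]
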