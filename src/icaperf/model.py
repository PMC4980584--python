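"""Model/Results facade over the AIF-determination pipeline.

:class:`PerfusionICA` is constructed from a :class:`~icaperf.series.DynamicSeries`
(or a NIfTI file) and its :meth:`~PerfusionICA.fit` runs the full chain —
spatial ICA, component ranking, z-map voxel selection, z-weighted AIF,
gamma-variate characterization, concentration conversion and SVD
deconvolution — returning a :class:`PerfusionICAResults` that carries the
AIF, its bolus features, the CBF map, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from . import deconvolution as deconv
from . import ica as _ica
from .concentration import (
    ConversionParams,
    aif_features,
    fit_gamma_variate,
    signal_to_concentration,
)
from .series import DynamicSeries

__all__ = ["PerfusionICA", "PerfusionICAResults"]


class PerfusionICA:
    """ICA-based AIF determination and perfusion quantification model.

    Parameters
    ----------
    series
        The dynamic signal series.
    n_components, variance_fraction
        PCA/ICA dimensionality: a fixed component count (phantom default
        10) or the smallest count covering the given eigenvalue fraction
        (clinical convention 0.99).  Exactly one must be given.
    k_voxels
        Number of top-z voxels forming each AIF region (default 50).
    conversion, deconv_spec
        Concentration-conversion and deconvolution settings.
    aif_on
        Whether the weighted AIF is averaged on ``"signal"`` and then
        converted to concentration (default), or averaged on already
        converted ``"concentration"`` curves.
    n_restarts
        FastICA restarts pooled for region selection (stochastic
        optimization; restarts stabilize the component estimates).
    """

    def __init__(
        self,
        series: DynamicSeries,
        n_components: Optional[int] = 10,
        variance_fraction: Optional[float] = None,
        k_voxels: int = 50,
        conversion: Optional[ConversionParams] = None,
        deconv_spec: Optional[deconv.DeconvSpec] = None,
        brain_mask: Optional[np.ndarray] = None,
        aif_on: str = "signal",
        n_restarts: int = 8,
    ):
        if variance_fraction is not None:
            n_components = None
        if aif_on not in ("signal", "concentration"):
            raise ValueError("aif_on must be 'signal' or 'concentration'")
        self.series = series
        self.n_components = n_components
        self.variance_fraction = variance_fraction
        self.k_voxels = k_voxels
        self.conversion = conversion or ConversionParams(
            te=series.te, baseline_window=series.baseline_window)
        self.deconv_spec = deconv_spec or deconv.DeconvSpec(dt=series.dt)
        self.brain_mask = brain_mask
        self.aif_on = aif_on
        self.n_restarts = n_restarts

    @classmethod
    def from_nifti(cls, path, te: Optional[float] = None, **kwargs):
        from .io import read_dynamic_series

        series = read_dynamic_series(path, te=te)
        return cls(series, **kwargs)

    def fit(
        self,
        seed: int = 0,
        artery_component: Optional[int] = None,
        surround_component: Optional[int] = None,
    ) -> "PerfusionICAResults":
        """Run the pipeline; component overrides allow manual confirmation."""
        series = self.series
        runs = _ica.decompose_ensemble(
            series, brain_mask=self.brain_mask,
            n_components=self.n_components,
            variance_fraction=self.variance_fraction, seed=seed,
            n_restarts=self.n_restarts, conv=self.conversion,
            dt=series.dt, k=self.k_voxels,
        )
        auto_art, auto_sur = _ica.select_artery_surround(runs, k=self.k_voxels)
        ic = auto_art.ic
        ranking = next(rk for r_ic, rk in runs if r_ic is ic)

        def _override(idx):
            # user confirms a component index from the selected run's ranking
            cand = next(r for r in ranking if r.component == idx)
            z = _ica.component_zmap(ic, cand.component, cand.sign)
            return _ica.RegionSelection(ic, cand, z, _ica.top_k_voxels(z, self.k_voxels))

        artery = auto_art if artery_component is None else _override(artery_component)
        surround = auto_sur if surround_component is None else _override(surround_component)

        conc = signal_to_concentration(series, self.conversion)
        aifs: Dict[str, _ica.AIFCurve] = {}
        features = {}
        for label, sel in (("artery", artery), ("surround", surround)):
            if sel is None:
                continue
            comp = sel.component
            z = sel.zmap
            vox = sel.voxels
            if self.aif_on == "signal":
                aif_sig = _ica.weighted_aif(series, vox, z, label)
                sub = DynamicSeries(
                    data=aif_sig.curve[:, None], dt=series.dt, te=series.te,
                    injection_tp=series.injection_tp,
                    baseline_window=series.baseline_window)
                aif_conc = signal_to_concentration(sub, self.conversion).data[:, 0]
                aif = _ica.AIFCurve(curve=aif_conc, voxel_ids=aif_sig.voxel_ids,
                                    weights=aif_sig.weights, source_label=label,
                                    component=comp)
            else:
                aif = _ica.weighted_aif(conc, vox, z, label)
                aif.source_label = label
            aifs[label] = aif
            try:
                gfit = fit_gamma_variate(aif.curve, series.dt)
                features[label] = aif_features(aif.curve, gfit, series.dt)
            except Exception:  # noqa: BLE001 - features are advisory
                features[label] = None
        return PerfusionICAResults(
            model=self, ic=ic, ranking=ranking,
            artery_component=artery.component if artery else None,
            surround_component=surround.component if surround else None,
            aifs=aifs, features=features, concentration=conc, seed=seed,
        )


@dataclass
class PerfusionICAResults:
    """Fitted AIF(s), bolus features, and on-demand perfusion maps."""

    model: PerfusionICA
    ic: _ica.ICResult
    ranking: list
    artery_component: Optional[int]
    surround_component: Optional[int]
    aifs: Dict[str, _ica.AIFCurve]
    features: Dict[str, object]
    concentration: object
    seed: int
    _maps: Dict[str, deconv.PerfusionMaps] = field(default_factory=dict)

    @property
    def aif_(self) -> _ica.AIFCurve:
        """The primary (surrounding-tissue, else arterial) AIF."""
        return self.aifs.get("surround") or self.aifs["artery"]

    def perfusion(self, source: Optional[str] = None,
                  mask: Optional[np.ndarray] = None) -> deconv.PerfusionMaps:
        """CBF map deconvolved with the chosen AIF (cached per source)."""
        source = source or ("surround" if "surround" in self.aifs else "artery")
        key = source if mask is None else None
        if key and key in self._maps:
            return self._maps[key]
        maps = deconv.cbf_map(self.concentration, self.aifs[source],
                              self.model.deconv_spec, mask=mask)
        if key:
            self._maps[key] = maps
        return maps

    def ranking_table(self) -> pd.DataFrame:
        rows = []
        for r in self.ranking:
            rows.append({
                "component": r.component, "pole": r.sign, "score": r.score,
                "ttp_s": r.fit.ttp if r.fit else np.nan,
                "error": r.error or "",
            })
        return pd.DataFrame(rows)

    def summary(self) -> SimpleTable:
        """Human-readable summary of the fit."""
        rows = [
            ("time points", str(self.model.series.n_timepoints)),
            ("voxels", str(self.model.series.n_voxels)),
            ("ICA components", str(self.ic.n_components)),
            ("seed", str(self.seed)),
            ("artery component", str(self.artery_component)),
            ("surround component", str(self.surround_component)),
        ]
        for label, feats in self.features.items():
            if feats is None:
                rows.append((f"{label} AIF", "gamma fit failed"))
                continue
            rows.append((f"{label} TTP (s)", f"{feats.ttp:.2f}"))
            rows.append((f"{label} onset (s)", f"{feats.onset_time:.2f}"))
            rows.append((f"{label} FWHM (s)", f"{feats.fwhm:.2f}"))
            rows.append((f"{label} peak height", f"{feats.peak_height:.4g}"))
        return SimpleTable(
            [[k, v] for k, v in rows],
            headers=["quantity", "value"],
            title="PerfusionICA results",
        )
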