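"""End-to-end run: simulate/load -> ICA -> AIF -> features -> CBF -> report."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict

import numpy as np

from . import io as _io
from .concentration import aif_features, fit_gamma_variate, signal_to_concentration
from .config import RunConfig
from .deconvolution import cbf_map
from .ica import AIFCurve
from .model import PerfusionICA
from .phantom import build_phantom

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _manual_aif(series, mask_path: str) -> AIFCurve:
    """Plain average AIF over a user-supplied mask (NIfTI label or .txt ids)."""
    p = Path(mask_path)
    if p.suffix == ".txt":
        ids = np.loadtxt(p, dtype=int).ravel()
    else:
        import nibabel as nib

        arr = np.asarray(nib.load(str(p)).get_fdata())
        ids = np.nonzero(arr.ravel() > 0)[0]
    X = series.as_matrix()
    if ids.size == 0:
        raise ValueError("manual mask selects no voxels")
    curve = X[:, ids].mean(axis=1)
    return AIFCurve(curve=curve, voxel_ids=ids, weights=np.ones(ids.size),
                    source_label="manual")


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the full pipeline described by ``config``.

    Writes AIF CSV/JSON, a bolus-feature CSV, a CBF NIfTI per AIF source and
    a JSON report (with the config hash) into ``config.out_dir``; returns
    the artifact paths and in-memory results.  A stage failure raises
    :class:`PipelineError` after persisting whatever was produced.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict[str, object] = {"config_hash": config.hash(), "stages": []}
    artifacts: Dict[str, object] = {"out_dir": str(out)}

    # --- acquire ---------------------------------------------------------
    try:
        if config.simulate is not None:
            import dataclasses

            spec = dataclasses.replace(config.simulate, seed=config.seed)
            series, truth = build_phantom(spec)
            _io.write_dynamic_series(series, out / "series.nii.gz")
            _io.write_truth(truth, spec, out / "truth.json")
            artifacts["truth"] = truth
        else:
            inp = config.input
            series = _io.read_dynamic_series(
                inp.path, te=inp.te, dt=inp.dt, injection_tp=inp.injection_tp,
                discard_first=inp.discard_first)
        artifacts["series"] = series
        report["stages"].append("acquire")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("acquire", e) from e

    # --- ICA + AIF -------------------------------------------------------
    try:
        model = PerfusionICA(
            series,
            n_components=config.ica.n_components,
            variance_fraction=config.ica.variance_fraction,
            k_voxels=config.ica.k_voxels,
            conversion=config.conversion,
            deconv_spec=config.deconv,
            aif_on=config.ica.aif_on,
        )
        results = model.fit(
            seed=config.seed,
            artery_component=config.ica.artery_component,
            surround_component=config.ica.surround_component,
        )
        artifacts["results"] = results
        report["artery_component"] = results.artery_component
        report["surround_component"] = results.surround_component
        report["ranking"] = results.ranking_table().to_dict("records")
        report["stages"].append("ica_aif")
    except Exception as e:  # noqa: BLE001
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise PipelineError("ica_aif", e) from e

    # --- manual-mask AIF (optional side-by-side) -------------------------
    aifs = dict(results.aifs)
    if config.input is not None and config.input.manual_mask:
        try:
            sig_aif = _manual_aif(series, config.input.manual_mask)
            from .series import DynamicSeries

            sub = DynamicSeries(data=sig_aif.curve[:, None], dt=series.dt,
                                te=series.te, injection_tp=series.injection_tp,
                                baseline_window=series.baseline_window)
            conc_curve = signal_to_concentration(sub, model.conversion).data[:, 0]
            aifs["manual"] = AIFCurve(curve=conc_curve, voxel_ids=sig_aif.voxel_ids,
                                      weights=sig_aif.weights, source_label="manual")
            report["stages"].append("manual_aif")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("manual_aif", e) from e

    # --- features + deconvolution ---------------------------------------
    try:
        features = dict(results.features)
        for label, aif in aifs.items():
            if label not in features:
                try:
                    gfit = fit_gamma_variate(aif.curve, series.dt)
                    features[label] = aif_features(aif.curve, gfit, series.dt)
                except Exception:  # noqa: BLE001
                    features[label] = None
            _io.write_aif_csv(aif, series.dt, out / f"aif_{label}.csv")
        _io.write_features_csv(features, out / "features.csv")

        report["cbf"] = {}
        for label, aif in aifs.items():
            maps = cbf_map(results.concentration, aif, config.deconv)
            img = maps.cbf_image()
            import nibabel as nib

            vol = img[..., None] if img.ndim == 2 else img
            nib.save(nib.Nifti1Image(np.asarray(vol, float), np.eye(4)),
                     str(out / f"cbf_{label}.nii.gz"))
            finite = img[np.isfinite(img)]
            report["cbf"][label] = {
                "mean": float(finite.mean()) if finite.size else None,
                "median_threshold": float(np.nanmedian(maps.threshold_used)),
            }
            artifacts[f"cbf_{label}"] = maps
        report["stages"].append("quantify")
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise PipelineError("quantify", e) from e

    report["seed"] = config.seed
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    artifacts["report"] = report
    artifacts["features"] = features
    return artifacts
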