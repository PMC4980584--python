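"""NIfTI / CSV / JSON input-output for series, truth, AIFs and maps.

Dynamic series are stored as 4D NIfTI with the time axis last
(x, y, z, t); the in-memory convention is time first.  Acquisition
metadata that NIfTI cannot carry (TE, injection time point, baseline
window) travels in a JSON sidecar next to the image, and can be
overridden at read time.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import PhantomSpec, PhantomTruth
from .series import DynamicSeries

__all__ = [
    "read_dynamic_series",
    "write_dynamic_series",
    "write_truth",
    "read_truth",
    "truth_label_image",
    "write_aif_csv",
    "write_features_csv",
]

log = logging.getLogger(__name__)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_dynamic_series(series: DynamicSeries, path) -> Path:
    """Write a series as 4D NIfTI (+ JSON sidecar with TE etc.)."""
    path = Path(path)
    data = series.data
    if data.ndim == 3:  # (t, y, x) -> add a singleton z axis
        spatial = np.moveaxis(data, 0, -1)[:, :, None, :]
    elif data.ndim == 4:
        spatial = np.moveaxis(data, 0, -1)
    else:
        raise ValueError("can only write 2D+t or 3D+t series")
    img = nib.Nifti1Image(np.asarray(spatial, dtype=np.float64), affine=np.eye(4))
    img.header["pixdim"][4] = series.dt
    nib.save(img, str(path))
    sidecar = {
        "dt": series.dt,
        "te": series.te,
        "injection_tp": series.injection_tp,
        "baseline_window": list(series.baseline_window),
        "orig_ndim": data.ndim,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_dynamic_series(
    path,
    te: Optional[float] = None,
    dt: Optional[float] = None,
    injection_tp: Optional[int] = None,
    baseline_window: Optional[Tuple[int, int]] = None,
    discard_first: int = 0,
) -> DynamicSeries:
    """Read a 4D NIfTI series, with metadata overrides.

    ``discard_first`` drops leading dummy frames (clinical series
    conventionally discard the first 3).  Raises ``FileNotFoundError`` for
    a missing file, ``ValueError`` for a non-4D volume, and a dedicated
    ``ValueError`` if TE is neither in the sidecar nor overridden.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    arr = np.asarray(img.get_fdata())
    if arr.ndim != 4:
        raise ValueError(f"expected a 4D volume, got {arr.ndim}D")
    data = np.moveaxis(arr, -1, 0)

    meta = {}
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    if meta.get("orig_ndim") == 3 and data.shape[1:][-1] == 1:
        data = data[:, :, :, 0]

    dt_val = dt if dt is not None else meta.get("dt") or float(img.header["pixdim"][4])
    if not dt_val or dt_val <= 0:
        raise ValueError("no sampling interval (TR) available; pass dt=")
    te_val = te if te is not None else meta.get("te")
    if te_val is None:
        raise ValueError("no echo time available; pass te=")
    inj = injection_tp if injection_tp is not None else meta.get("injection_tp", 7)
    bw = baseline_window or (tuple(meta["baseline_window"]) if "baseline_window" in meta else None)

    series = DynamicSeries(data=data, dt=float(dt_val), te=float(te_val),
                           injection_tp=int(inj), baseline_window=bw)
    if discard_first:
        series = series.discard_leading(discard_first)
    return series


# ---------------------------------------------------------------------------
# phantom truth
# ---------------------------------------------------------------------------

def write_truth(truth: PhantomTruth, spec: PhantomSpec, path) -> Path:
    """Serialize the phantom ground truth (and a spec echo) as JSON."""
    payload = {
        "spec": {
            "block_edge": spec.block_edge, "overlap_cols": spec.overlap_cols,
            "pv_fraction": spec.pv_fraction, "n_timepoints": spec.n_timepoints,
            "dt": spec.dt, "mtt": spec.mtt, "cnr": spec.cnr,
            "injection_tp": spec.injection_tp, "s0": spec.s0, "seed": spec.seed,
            "bolus": {"c_max": spec.bolus.c_max, "t0": spec.bolus.t0},
        },
        "spatial_shape": list(truth.spatial_shape),
        "masks": {
            "artery": truth.mask_artery.tolist(),
            "surround": truth.mask_surround.tolist(),
            "tissue": truth.mask_tissue.tolist(),
            "overlap_12": truth.mask_overlap_12.tolist(),
            "overlap_23": truth.mask_overlap_23.tolist(),
        },
        "pure_signals": {k: v.tolist() for k, v in truth.pure_signals.items()},
    }
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def read_truth(path) -> PhantomTruth:
    d = json.loads(Path(path).read_text())
    m = d["masks"]
    return PhantomTruth(
        mask_artery=np.array(m["artery"]),
        mask_surround=np.array(m["surround"]),
        mask_tissue=np.array(m["tissue"]),
        mask_overlap_12=np.array(m["overlap_12"]),
        mask_overlap_23=np.array(m["overlap_23"]),
        pure_signals={k: np.array(v) for k, v in d["pure_signals"].items()},
        spatial_shape=tuple(d["spatial_shape"]),
    )


def truth_label_image(truth: PhantomTruth) -> np.ndarray:
    """Integer label image: 1 artery, 2 surround, 3 tissue, 4/5 overlaps."""
    img = np.zeros(int(np.prod(truth.spatial_shape)), dtype=np.int16)
    for label, mask in enumerate(
        (truth.mask_artery, truth.mask_surround, truth.mask_tissue,
         truth.mask_overlap_12, truth.mask_overlap_23), start=1):
        img[mask] = label
    return img.reshape(truth.spatial_shape)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_aif_csv(aif, dt: float, path) -> Path:
    """AIF curve as (time_s, value) CSV plus a JSON provenance sidecar."""
    path = Path(path)
    pd.DataFrame({
        "time_s": np.arange(len(aif.curve)) * dt,
        "value": aif.curve,
    }).to_csv(path, index=False)
    prov = {
        "source_label": aif.source_label,
        "component": aif.component,
        "voxel_ids": np.asarray(aif.voxel_ids).tolist(),
        "weights": np.asarray(aif.weights).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(prov, indent=2))
    return path


def write_features_csv(features: dict, path) -> Path:
    """Bolus feature table (one row per AIF source).

    peak_height is in fitted-curve (relaxivity-scaled concentration) units.
    """
    rows = []
    for label, f in features.items():
        if f is None:
            continue
        rows.append({"source": label, "ttp_s": f.ttp, "onset_s": f.onset_time,
                     "fwhm_s": f.fwhm, "peak_height": f.peak_height})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
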