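"""Reading and writing gated series, ROI masks and mixture models.

A gated equilibrium radionuclide angiography (ERNA) study is a short cine of
``K`` frames of ``M x M`` counts covering one average cardiac cycle. Series
and masks travel as NIfTI-1 volumes with time (or the label plane) on the
third axis, or as an ``.npz`` container with a ``counts`` (respectively
``labels``) array; mixture models travel as JSON.

The bidimensional time-activity-curve (TAC) array stacks the temporal
sequence of every selected pixel as one row. Pixel (i, j) of an ``M x M``
frame (1-based, row-major) maps to row index ``p = (i - 1) * M + j``; rows
are ordered by ascending ``p`` and columns by frame number ``k = 1..K``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np

from .mixture import FitInfo, GaussianMixture, MixtureError

__all__ = [
    "GatedSeries",
    "RoiMask",
    "TacMatrix",
    "FormatError",
    "BACKGROUND",
    "LV",
    "RV",
    "read_gated_series",
    "write_gated_series",
    "read_roi_mask",
    "write_roi_mask",
    "build_tac_matrix",
    "pixel_linear_index",
    "save_model",
    "load_model",
    "load_reference_model",
]

#: canonical ROI label codes
BACKGROUND, LV, RV = 0, 1, 2

_DEFAULT_REGIONS = {BACKGROUND: "background", LV: "LV", RV: "RV"}


class FormatError(ValueError):
    """A file or array violates the gated-series / mask / model contracts."""


@dataclass
class GatedSeries:
    """K-frame stack of ``M x M`` count images, frames first: ``(K, M, M)``."""

    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise FormatError("counts must be a (K, M, M) stack")
        k, rows, cols = self.counts.shape
        if rows != cols:
            raise FormatError(f"non-square frame 0: {rows}x{cols}")
        if k < 2:
            raise FormatError(f"need at least 2 frames, got {k}")
        if not np.isfinite(self.counts).all():
            kk, ii, jj = np.unravel_index(
                int(np.flatnonzero(~np.isfinite(self.counts))[0]),
                self.counts.shape)
            raise FormatError(f"non-finite count at frame {kk}, pixel "
                              f"({ii + 1}, {jj + 1})")
        if (self.counts < 0).any():
            kk, ii, jj = np.unravel_index(
                int(np.flatnonzero(self.counts < 0)[0]), self.counts.shape)
            raise FormatError(f"negative count at frame {kk}, pixel "
                              f"({ii + 1}, {jj + 1})")

    @property
    def frames(self) -> int:
        return self.counts.shape[0]

    @property
    def grid(self) -> int:
        return self.counts.shape[1]


@dataclass
class RoiMask:
    """``M x M`` integer label map (0 background, 1 LV, 2 RV by default)."""

    labels: np.ndarray
    region_names: dict = field(default_factory=lambda: dict(_DEFAULT_REGIONS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 and self.labels.ndim != 2:
            raise FormatError("labels must be an M x M map")
        if self.labels.ndim == 3:
            if self.labels.shape[2] != 1:
                raise FormatError("labels must be an M x M map")
            self.labels = self.labels[:, :, 0]
        if self.labels.shape[0] != self.labels.shape[1]:
            raise FormatError(
                f"non-square mask: {self.labels.shape[0]}x{self.labels.shape[1]}")
        self.labels = self.labels.astype(int)

    @property
    def grid(self) -> int:
        return self.labels.shape[0]

    def label_for(self, region) -> int:
        """Resolve a region given as label code or name."""
        if isinstance(region, str):
            for code, name in self.region_names.items():
                if name == region:
                    return code
            raise FormatError(f"unknown region {region!r}")
        return int(region)

    def region_pixels(self, regions) -> np.ndarray:
        """Boolean M x M selection of the union of the given regions."""
        codes = [self.label_for(r) for r in regions]
        return np.isin(self.labels, codes)


@dataclass
class TacMatrix:
    """``P x K`` matrix of pixel time-activity curves plus the pixel map.

    ``pixel_index[p]`` is the 1-based ``(i, j)`` source pixel of row ``p``;
    linearized indices follow ``p = (i - 1) * M + j``.
    """

    values: np.ndarray
    pixel_index: list
    grid: int

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.pixel_index) != self.values.shape[0]:
            raise FormatError("pixel_index length must match row count")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def frames(self) -> int:
        return self.values.shape[1]

    def linear_indices(self) -> np.ndarray:
        """1-based linearized pixel indices p for every row."""
        return np.array([pixel_linear_index(i, j, self.grid)
                         for i, j in self.pixel_index])


def pixel_linear_index(i: int, j: int, m: int) -> int:
    """Row-major 1-based linearization ``p = (i - 1) * M + j``."""
    if not (1 <= i <= m and 1 <= j <= m):
        raise FormatError(f"pixel ({i}, {j}) outside {m}x{m} grid")
    return (i - 1) * m + j


# ---------------------------------------------------------------------------
# series / mask containers


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("nifti", "npz"):
            raise FormatError(f"unknown format {format!r}")
        return format
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".npz"):
        return "npz"
    raise FormatError(f"cannot infer container format of {path}")


def _read_volume(path: Path, format: str | None, key: str) -> tuple[np.ndarray, dict]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        meta = {}
        descrip = img.header.get("descrip", b"")
        try:
            text = bytes(descrip).decode("utf-8", "ignore").strip("\x00")
            if text:
                meta = json.loads(text)
        except (ValueError, TypeError):
            meta = {}
        return data, meta
    with np.load(path, allow_pickle=False) as npz:
        if key not in npz:
            raise FormatError(f"{path} has no {key!r} array")
        data = npz[key]
        meta = json.loads(str(npz["meta"])) if "meta" in npz else {}
    return data, meta


def read_gated_series(path, format: str | None = None) -> GatedSeries:
    """Read a gated series (NIfTI with time 3rd axis, or npz ``counts``)."""
    data, meta = _read_volume(Path(path), format, "counts")
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got {data.ndim}-D")
    fmt = _infer_format(Path(path), format)
    if fmt == "nifti":
        data = np.moveaxis(data, 2, 0)  # (M, M, K) on disk -> (K, M, M)
    return GatedSeries(np.asarray(data, dtype=float), meta=meta)


def write_gated_series(series: GatedSeries, path, format: str | None = None) -> Path:
    """Write a gated series; format inferred from the suffix by default."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "nifti":
        img = nib.Nifti1Image(np.moveaxis(series.counts, 0, 2), np.eye(4))
        meta_text = json.dumps(series.meta, default=str)
        if len(meta_text) <= 79:  # NIfTI descrip field is 80 bytes
            img.header["descrip"] = meta_text.encode()
        nib.save(img, str(path))
    else:
        np.savez(path, counts=series.counts,
                 meta=json.dumps(series.meta, default=str))
    return path


def read_roi_mask(path, format: str | None = None,
                  region_names: dict | None = None) -> RoiMask:
    data, _ = _read_volume(Path(path), format, "labels")
    return RoiMask(np.asarray(data),
                   region_names=dict(region_names or _DEFAULT_REGIONS))


def write_roi_mask(mask: RoiMask, path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "nifti":
        img = nib.Nifti1Image(mask.labels.astype(np.int16)[:, :, None], np.eye(4))
        nib.save(img, str(path))
    else:
        np.savez(path, labels=mask.labels)
    return path


def build_tac_matrix(series: GatedSeries, mask: RoiMask,
                     regions=("LV", "RV")) -> TacMatrix:
    """Stack the TACs of the pixels in the selected regions, rows by ``p``.

    Row order is ascending linearized pixel index ``p = (i - 1) * M + j``
    (row-major scan of the frame); columns follow acquisition order.
    """
    if mask.grid != series.grid:
        raise FormatError(
            f"mask grid {mask.grid} does not match series grid {series.grid}")
    selected = mask.region_pixels(regions)
    flat = np.flatnonzero(selected.ravel(order="C"))
    if flat.size == 0:
        raise FormatError(f"no pixels selected for regions {tuple(regions)!r}")
    m = series.grid
    rows, cols = np.divmod(flat, m)
    values = series.counts[:, rows, cols].T  # (P, K)
    pixel_index = [(int(i) + 1, int(j) + 1) for i, j in zip(rows, cols)]
    return TacMatrix(values=values, pixel_index=pixel_index, grid=m)


# ---------------------------------------------------------------------------
# mixture model JSON

_MODEL_FORMAT = "fadsync-mixture"


def save_model(model: GaussianMixture, path) -> Path:
    """Serialize a mixture to JSON (lossless at double precision)."""
    model.validate(weight_tol=1e-6)
    doc = {
        "format": _MODEL_FORMAT,
        "version": 1,
        "family": model.family,
        "R": model.n_components,
        "weights": model.weights.tolist(),
        "means": model.means.tolist(),
        "covariances": model.covariances.tolist(),
        "fit": model.fit.to_dict() if model.fit is not None else None,
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    return path


def _model_from_document(doc: dict, source: str) -> GaussianMixture:
    for key in ("weights", "means", "covariances"):
        if key not in doc:
            raise FormatError(f"{source}: missing {key!r}")
    weights = np.asarray(doc["weights"], dtype=float)
    total = weights.sum()
    if abs(total - 1.0) > 1e-3 + 1e-12:  # printed 0.999 must pass exactly
        raise FormatError(
            f"{source}: weights sum to {total:.6g}, outside the 1e-3 tolerance")
    weights = weights / total  # renormalize printed rounding
    covs = np.asarray(doc["covariances"], dtype=float)
    for r, cov in enumerate(covs, start=1):
        sym_ok = np.allclose(cov, cov.T, atol=1e-8)
        if not sym_ok or np.linalg.eigvalsh(0.5 * (cov + cov.T)).min() <= 0:
            raise FormatError(f"{source}: covariance {r} not SPD")
    fit = None
    if doc.get("fit"):
        f = doc["fit"]
        fit = FitInfo(n=f.get("n", 0), d=f.get("d", 3),
                      log_likelihood=f.get("log_likelihood", float("nan")),
                      bic=f.get("bic", float("nan")),
                      converged=f.get("converged", False),
                      n_iter=f.get("n_iter", 0), seed=f.get("seed"))
    try:
        return GaussianMixture(weights, np.asarray(doc["means"], dtype=float),
                               covs, family=doc.get("family", "VVV"), fit=fit)
    except MixtureError as exc:
        raise FormatError(f"{source}: {exc}") from exc


def load_model(path) -> GaussianMixture:
    """Load and validate a mixture-model JSON file."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    return _model_from_document(doc, str(path))


def load_reference_model() -> GaussianMixture:
    """The shipped published reference model of the normal contraction pattern.

    A five-component ``VVV`` mixture of the three most significant factor
    coordinates fitted to a 23-subject control population (weights as
    printed sum to 0.999 and are renormalized on load; one covariance was
    symmetrized from its printed form).
    """
    text = resources.files("fadsync.data").joinpath(
        "control_3msf_gmm.json").read_text()
    return _model_from_document(json.loads(text), "control_3msf_gmm.json")
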