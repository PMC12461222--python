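"""Volume and sinogram readers/writers, run configuration and metrics.

Volumes travel as NIfTI (``.nii``/``.nii.gz``, via nibabel) or as a raw
little-endian array beside a JSON header (``.raw`` + ``.json``); both
round-trip float64 and integer-label volumes losslessly.  Sinograms,
which have no established interchange format, are stored as a flat raw
float64 array plus a versioned JSON geometry header mirroring
:class:`~cbctlab.geometry.ProjectionGeometry`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import nibabel as nib
import numpy as np
import yaml

from .forward import Sinogram
from .geometry import ProjectionGeometry

__all__ = [
    "write_volume",
    "read_volume",
    "write_sinogram",
    "read_sinogram",
    "compute_metrics",
    "RunConfig",
]

SINOGRAM_HEADER_VERSION = 1


def write_volume(image: np.ndarray, path) -> None:
    """Write a 2D/3D volume; format chosen by extension."""
    path = Path(path)
    image = np.asarray(image)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        if image.dtype.kind == "f":
            img = nib.Nifti1Image(np.asarray(image, dtype=np.float64), np.eye(4))
        else:  # label volumes: NIfTI has no int64, int32 is lossless here
            img = nib.Nifti1Image(np.asarray(image, dtype=np.int32), np.eye(4))
        nib.save(img, path)
        return
    if path.suffix == ".raw":
        header = {
            "shape": list(image.shape),
            "dtype": str(image.dtype),
            "order": "C",
        }
        path.with_suffix(".json").write_text(json.dumps(header))
        image.astype(image.dtype).tofile(path)
        return
    raise ValueError(f"unsupported volume extension {path.suffix!r}")


def read_volume(path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        return np.asarray(nib.load(path).dataobj)
    if path.suffix == ".raw":
        hpath = path.with_suffix(".json")
        try:
            header = json.loads(hpath.read_text())
            shape = tuple(header["shape"])
            dtype = np.dtype(header["dtype"])
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise ValueError(f"malformed volume header {hpath}: {exc}") from exc
        data = np.fromfile(path, dtype=dtype)
        if data.size != int(np.prod(shape)):
            raise ValueError(
                f"truncated volume file {path}: expected {int(np.prod(shape))} "
                f"elements, found {data.size}")
        return data.reshape(shape)
    raise ValueError(f"unsupported volume extension {path.suffix!r}")


def write_sinogram(sinogram: Sinogram, path) -> None:
    """Flat float64 binary array plus JSON geometry header."""
    path = Path(path)
    g = sinogram.geometry
    header = {
        "version": SINOGRAM_HEADER_VERSION,
        "shape": list(sinogram.values.shape),
        "provenance": sinogram.provenance,
        "geometry": {
            "kind": g.kind,
            "n_views": g.n_views,
            "n_det_u": g.n_det_u,
            "det_spacing": g.det_spacing,
            "angular_range": g.angular_range,
            "source_radius": g.source_radius,
            "detector_radius": g.detector_radius,
            "n_det_v": g.n_det_v,
            "det_spacing_v": g.det_spacing_v,
            "det_offset": g.det_offset,
            "truncation": list(g.truncation) if g.truncation else None,
            "explicit_angles": (g.explicit_angles.tolist()
                                if g.explicit_angles is not None else None),
        },
    }
    path.with_suffix(".json").write_text(json.dumps(header))
    sinogram.values.astype(np.float64).tofile(path)


def read_sinogram(path) -> Sinogram:
    path = Path(path)
    try:
        header = json.loads(path.with_suffix(".json").read_text())
        gd = header["geometry"]
        geom = ProjectionGeometry(
            kind=gd["kind"], n_views=gd["n_views"], n_det_u=gd["n_det_u"],
            det_spacing=gd["det_spacing"], angular_range=gd["angular_range"],
            source_radius=gd["source_radius"], detector_radius=gd["detector_radius"],
            n_det_v=gd["n_det_v"], det_spacing_v=gd["det_spacing_v"],
            det_offset=gd["det_offset"],
            truncation=tuple(gd["truncation"]) if gd["truncation"] else None,
            explicit_angles=(np.asarray(gd["explicit_angles"])
                             if gd["explicit_angles"] is not None else None),
        )
        shape = tuple(header["shape"])
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"malformed sinogram header for {path}: {exc}") from exc
    data = np.fromfile(path, dtype=np.float64)
    if data.size != int(np.prod(shape)):
        raise ValueError(f"truncated sinogram file {path}")
    return Sinogram(data.reshape(shape), geom, header.get("provenance", ""))


def compute_metrics(image: np.ndarray, reference: np.ndarray,
                    mask: Optional[np.ndarray] = None) -> Dict[str, float]:
    """RMSE, PSNR (reference dynamic range) and max abs error over a
    mask (defaults to the full grid)."""
    image = np.asarray(image, float)
    reference = np.asarray(reference, float)
    if image.shape != reference.shape:
        raise ValueError("shape mismatch")
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    diff = image[mask] - reference[mask]
    rmse = float(np.sqrt(np.mean(diff**2)))
    rng = float(reference[mask].max() - reference[mask].min())
    psnr = float(np.inf) if rmse == 0 else 20 * np.log10(rng / rmse) if rng > 0 else float("nan")
    return {"rmse": rmse, "psnr": psnr, "max_abs": float(np.max(np.abs(diff)))}


@dataclass
class RunConfig:
    """Resolved configuration of a simulation/reconstruction run.

    Serialises to YAML losslessly; every CLI run writes its resolved
    config beside the outputs so results are reproducible from the file
    plus the seed alone.
    """

    phantom: Dict = field(default_factory=lambda: {"preset": "dental", "size": 64,
                                                   "n_teeth": 8})
    spectrum: Dict = field(default_factory=lambda: {"preset": "dental_bichromatic"})
    geometry: Dict = field(default_factory=lambda: {"kind": "parallel2d",
                                                    "n_views": 90, "n_det_u": 95,
                                                    "det_spacing": 1.0,
                                                    "det_offset": 0.0})
    degradation: Dict = field(default_factory=dict)
    method: Dict = field(default_factory=lambda: {"name": "fbp", "filter": "ramlak"})
    seed: int = 0
    output_dir: str = "."

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
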