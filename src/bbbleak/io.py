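"""NIfTI / CSV / JSON input-output with sidecar metadata.

Volumes travel as NIfTI-1 (optionally gzipped) with the time axis as the
fourth dimension; acquisition metadata that NIfTI cannot carry (time
stamps, sequence role, pre-contrast count, provenance) lives in a JSON
sidecar next to the image.  Grids are index-addressed: the affine is
carried through unchanged and never resampled, so masks and series must
share an affine to within a small tolerance.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .conversion import ConcentrationSeries, DynamicSeries

__all__ = [
    "save_volume", "load_volume", "save_series", "load_series",
    "save_concentration", "load_concentration", "assert_affines_match",
    "sidecar_path",
]

AFFINE_TOL = 1e-4


def sidecar_path(path: str | Path) -> Path:
    """The JSON sidecar path of a NIfTI file (strips .nii / .nii.gz)."""
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            name = name[: -len(suf)]
            break
    return p.with_name(name + ".json")


def assert_affines_match(a: np.ndarray, b: np.ndarray,
                         tol: float = AFFINE_TOL) -> None:
    """Reject affines that differ beyond ``tol`` (no resampling is done)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.max(np.abs(a - b)) > tol:
        raise ValueError(
            "affine mismatch beyond tolerance "
            f"{tol}:\n{np.array_repr(a)}\nvs\n{np.array_repr(b)}")


def save_volume(path: str | Path, data: np.ndarray,
                affine: np.ndarray | None = None,
                meta: dict | None = None) -> None:
    """Write a 3D/4D volume as NIfTI with an optional JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, float))
    nib.save(img, str(path))
    if meta is not None:
        sidecar_path(path).write_text(json.dumps(meta, indent=2,
                                                 sort_keys=True))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict | None]:
    """Read a NIfTI volume; returns (data, affine, sidecar-or-None)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    meta = None
    sp = sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())
    return data, np.asarray(img.affine, float), meta


def save_series(path: str | Path, series: DynamicSeries,
                affine: np.ndarray | None = None) -> None:
    """Write a dynamic series with its sidecar (times, role, baseline count)."""
    save_volume(path, series.data, affine, meta={
        "times_s": series.times_s.tolist(),
        "role": series.role,
        "n_precontrast": int(series.n_precontrast),
    })


def load_series(path: str | Path,
                expect_affine: np.ndarray | None = None) -> DynamicSeries:
    """Read a dynamic series; the JSON sidecar is mandatory."""
    data, affine, meta = load_volume(path)
    if meta is None:
        raise ValueError(
            f"4D series {path} has no JSON sidecar "
            f"({sidecar_path(path).name}); write one with times_s, role "
            "and n_precontrast, e.g. via bbbleak.io.save_series")
    if expect_affine is not None:
        assert_affines_match(affine, expect_affine)
    return DynamicSeries(data, np.asarray(meta["times_s"], float),
                         meta["role"], int(meta["n_precontrast"]))


def save_concentration(path: str | Path, conc: ConcentrationSeries,
                       affine: np.ndarray | None = None) -> None:
    save_volume(path, conc.data, affine, meta={
        "times_s": conc.times_s.tolist(),
        "provenance": [str(x) for x in conc.provenance],
        "n_clamped": int(conc.n_clamped),
    })


def load_concentration(path: str | Path) -> ConcentrationSeries:
    data, _, meta = load_volume(path)
    if meta is None:
        raise ValueError(f"concentration series {path} has no JSON sidecar")
    return ConcentrationSeries(data, np.asarray(meta["times_s"], float),
                               np.asarray(meta["provenance"]),
                               n_clamped=int(meta.get("n_clamped", 0)))
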