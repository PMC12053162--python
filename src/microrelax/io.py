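"""NIfTI / JSON / CSV input-output for volumes, schedules and maps."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .models import EchoSchedule
from .preprocessing import MultiEchoVolume

__all__ = [
    "save_multiecho",
    "load_multiecho",
    "load_mask",
    "save_maps",
    "save_sidecar",
]


def save_sidecar(path: Path | str, sched: EchoSchedule, extra: dict | None = None) -> None:
    """Write the JSON sidecar carrying echo times (s) and repetition layout."""
    payload = {
        "EchoTimes": sched.echo_times.tolist(),
        "NRepetitions": sched.n_repetitions,
    }
    if not np.all(sched.f_macro == 1.0):
        payload["FMacro"] = sched.f_macro.tolist()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def save_multiecho(vol: MultiEchoVolume, nifti_path: Path | str,
                   sidecar_path: Path | str | None = None,
                   extra: dict | None = None) -> None:
    """Write a 4-D multi-echo volume as NIfTI-1 plus its JSON sidecar."""
    nifti_path = Path(nifti_path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine=np.eye(4))
    nib.save(img, str(nifti_path))
    if sidecar_path is None:
        name = nifti_path.name
        for suf in (".nii.gz", ".nii"):
            if name.endswith(suf):
                name = name[: -len(suf)]
                break
        sidecar_path = nifti_path.with_name(name + ".json")
    save_sidecar(sidecar_path, vol.sched, extra)


def load_multiecho(nifti_path: Path | str,
                   sidecar_path: Path | str | None = None) -> MultiEchoVolume:
    """Load a 4-D volume and its echo-time sidecar."""
    nifti_path = Path(nifti_path)
    if sidecar_path is None:
        name = nifti_path.name
        for suf in (".nii.gz", ".nii"):
            if name.endswith(suf):
                name = name[: -len(suf)]
                break
        sidecar_path = nifti_path.with_name(name + ".json")
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"echo-time sidecar not found: {sidecar_path} "
            f"(expected next to {nifti_path.name})"
        )
    meta = json.loads(sidecar_path.read_text())
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata(), float)
    sched = EchoSchedule(
        echo_times=np.asarray(meta["EchoTimes"], float),
        f_macro=np.asarray(meta["FMacro"], float) if "FMacro" in meta else None,
        n_repetitions=int(meta.get("NRepetitions", 1)),
    )
    return MultiEchoVolume(data=data, sched=sched)


def load_mask(path: Path | str, grid_shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Load an integer-label or boolean mask volume."""
    img = nib.load(str(path))
    mask = np.asarray(img.get_fdata())
    if grid_shape is not None and mask.shape != tuple(grid_shape):
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid_shape}")
    return mask


def save_maps(maps: dict[str, np.ndarray], out_dir: Path | str,
              prefix: str = "") -> list[Path]:
    """Write each 3-D parameter map as its own NIfTI file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in maps.items():
        p = out_dir / f"{prefix}{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, np.float32), np.eye(4)), str(p))
        written.append(p)
    return written
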