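"""File-format adapters: Z-spectrum CSV, YAML (de)serialization of spin
systems / schemes / configs, relaxometry CSV, and NIfTI voxel stacks with
an offsets sidecar."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .pipeline import RunConfig
from .relaxometry import RelaxSeries
from .saturation import SaturationScheme
from .spinsystem import ExchangePool, InvalidInputError, SpinSystem
from .zspectrum import ZSpectrum

__all__ = [
    "read_zspectrum", "write_zspectrum", "read_relax_series",
    "write_relax_series", "system_to_yaml", "system_from_yaml",
    "scheme_to_yaml", "scheme_from_yaml", "config_from_yaml",
    "read_nifti_stack", "write_nifti_stack",
]


def write_zspectrum(spec: ZSpectrum, path) -> None:
    """Two-column CSV (offset_ppm, z) with z0/b0 in header comments."""
    with open(path, "w") as fh:
        fh.write(f"# z0 = {float(spec.z0)!r}\n")
        fh.write(f"# b0_shift = {float(spec.b0_shift)!r}\n")
        fh.write("offset_ppm,z\n")
        for o, z in zip(spec.offsets, spec.signals):
            fh.write(f"{float(o)!r},{float(z)!r}\n")


def read_zspectrum(path) -> ZSpectrum:
    z0, b0 = 1.0, 0.0
    offsets, signals = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                key = key.strip()
                if key == "z0":
                    z0 = float(value)
                elif key == "b0_shift":
                    b0 = float(value)
                continue
            if line.startswith("offset_ppm"):
                continue
            a, _, b = line.partition(",")
            offsets.append(float(a))
            signals.append(float(b))
    return ZSpectrum(np.asarray(offsets), np.asarray(signals), z0=z0,
                     b0_shift=b0)


def write_relax_series(series: RelaxSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind = {series.kind}\n")
        fh.write("time_s,signal\n")
        for t, s in zip(series.times, series.signals):
            fh.write(f"{float(t)!r},{float(s)!r}\n")


def read_relax_series(path, kind: str | None = None) -> RelaxSeries:
    times, signals = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                if key.strip() == "kind" and kind is None:
                    kind = value.strip()
                continue
            if not line or line.startswith("time_s"):
                continue
            a, _, b = line.partition(",")
            times.append(float(a))
            signals.append(float(b))
    if kind is None:
        raise InvalidInputError("series kind not given and not in header")
    return RelaxSeries(kind, np.asarray(times), np.asarray(signals))


def system_to_yaml(system: SpinSystem, path=None) -> str:
    doc = {"larmor_frequency": system.larmor_frequency,
           "pools": [asdict(p) for p in system.pools]}
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def system_from_yaml(source) -> SpinSystem:
    doc = _load_yaml(source)
    pools = tuple(ExchangePool(**p) for p in doc["pools"])
    return SpinSystem(pools, doc.get("larmor_frequency", 400.0))


def scheme_to_yaml(scheme: SaturationScheme, path=None) -> str:
    doc = asdict(scheme)
    doc["offsets"] = [float(o) for o in scheme.offsets]
    doc["reference_offsets"] = [float(o) for o in scheme.reference_offsets]
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def scheme_from_yaml(source) -> SaturationScheme:
    doc = _load_yaml(source)
    doc["offsets"] = tuple(doc.get("offsets", ()))
    doc["reference_offsets"] = tuple(doc.get("reference_offsets", (-100.0, 100.0)))
    return SaturationScheme(**doc)


def config_from_yaml(source) -> RunConfig:
    doc = _load_yaml(source) or {}
    try:
        return RunConfig(**doc)
    except TypeError as exc:
        raise InvalidInputError(f"bad run configuration: {exc}") from exc


def _load_yaml(source):
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        with open(source) as fh:
            return yaml.safe_load(fh)
    return yaml.safe_load(source)


def write_nifti_stack(stack: np.ndarray, offsets, path, *,
                      n_reference: int = 2) -> None:
    """Write a (frames, x, y) stack as NIfTI plus a JSON offsets sidecar.

    The last ``n_reference`` frames are the far-off-resonance reference
    acquisitions.
    """
    import nibabel as nib

    stack = np.asarray(stack)
    img = nib.Nifti1Image(np.moveaxis(stack, 0, -1).astype(np.float64),
                          affine=np.eye(4))
    nib.save(img, str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"offsets_ppm": [float(o) for o in offsets],
         "n_reference": n_reference}, indent=2))


def read_nifti_stack(path, sidecar=None):
    """Read a NIfTI Z-spectrum stack into per-voxel spectra.

    Returns (offsets, spectra, shape): ``spectra`` is a list of ZSpectrum,
    one per voxel (flattened in C order), each normalized by that voxel's
    mean reference signal (so signals are Z/Z0 and z0 is stored as 1).
    Voxels with nonpositive reference signal yield None.
    """
    import nibabel as nib

    if sidecar is None:
        sidecar = Path(str(path)).with_suffix("").with_suffix(".json")
    try:
        meta = json.loads(Path(sidecar).read_text())
        offsets = np.asarray(meta["offsets_ppm"], dtype=float)
        n_ref = int(meta.get("n_reference", 2))
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise InvalidInputError(f"malformed offsets sidecar {sidecar}: {exc}")
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    frames = np.moveaxis(data, -1, 0)
    if frames.shape[0] != offsets.size + n_ref:
        raise InvalidInputError(
            f"volume has {frames.shape[0]} frames but sidecar describes "
            f"{offsets.size} offsets + {n_ref} references")
    shape = frames.shape[1:]
    flat = frames.reshape(frames.shape[0], -1)
    order = np.argsort(offsets)
    spectra = []
    for v in range(flat.shape[1]):
        z0 = float(flat[offsets.size:, v].mean())
        if z0 <= 0:
            spectra.append(None)
            continue
        spectra.append(ZSpectrum(offsets[order],
                                 np.clip(flat[:offsets.size, v][order] / z0,
                                         -0.05, 1.05),
                                 z0=1.0))
    return offsets[order], spectra, shape
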