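"""Reading and writing studies as NIfTI volumes with a JSON sidecar.

One ``.nii.gz`` file per channel plus ``study.json`` listing the
b-values, echo times, dynamic timestamps and contrast-arrival time, so a
directory round-trips to an identical :class:`MultiSequenceStudy`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from . import phantom as ph
from .volume import ImageVolume, as_bool_mask


def _write_volume(vol: ImageVolume, path: Path, as_mask: bool = False) -> None:
    img = vol.to_sitk()
    if as_mask:
        img = sitk.Cast(img, sitk.sitkUInt8)
    sitk.WriteImage(img, str(path), useCompression=True)


def _read_volume(path: Path, **channel) -> ImageVolume:
    return ImageVolume.from_sitk(sitk.ReadImage(str(path)), **channel)


def write_study(study: ph.MultiSequenceStudy, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_volume(study.t2w, outdir / "t2w.nii.gz")
    for i, v in enumerate(study.t2sw):
        _write_volume(v, outdir / f"t2sw_e{i}.nii.gz")
    for i, v in enumerate(study.dw):
        _write_volume(v, outdir / f"dw_b{i}.nii.gz")
    for ti, frame in enumerate(study.dme):
        for ei, v in enumerate(frame):
            _write_volume(v, outdir / f"dme_t{ti:03d}_e{ei}.nii.gz")
    for name, attr in (
        ("observer_a", study.observer_a),
        ("observer_b", study.observer_b),
        ("truth", study.truth),
    ):
        _write_volume(attr, outdir / f"{name}.nii.gz", as_mask=True)
    sidecar = {
        "patient_id": study.patient_id,
        "b_values": [v.channel.get("b") for v in study.dw],
        "echo_times_t2sw_ms": [v.channel.get("te_ms") for v in study.t2sw],
        "echo_times_dme_ms": list(study.dme_echo_times_ms),
        "timestamps_s": list(map(float, study.timestamps_s)),
        "arrival_s": study.arrival_s,
        "seed": study.seed,
        "n_dme_timepoints": len(study.dme),
    }
    with open(outdir / "study.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return outdir


def read_study(indir) -> ph.MultiSequenceStudy:
    indir = Path(indir)
    with open(indir / "study.json") as fh:
        meta = json.load(fh)
    t2w = _read_volume(indir / "t2w.nii.gz", sequence=ph.T2W)
    t2sw = [
        _read_volume(indir / f"t2sw_e{i}.nii.gz", sequence=ph.T2SW, te_ms=te)
        for i, te in enumerate(meta["echo_times_t2sw_ms"])
    ]
    dw = [
        _read_volume(indir / f"dw_b{i}.nii.gz", sequence=ph.DW, b=b)
        for i, b in enumerate(meta["b_values"])
    ]
    dme = []
    for ti, t in enumerate(meta["timestamps_s"][: meta["n_dme_timepoints"]]):
        frame = [
            _read_volume(
                indir / f"dme_t{ti:03d}_e{ei}.nii.gz",
                sequence=ph.DME, t_s=t, te_ms=te,
            )
            for ei, te in enumerate(meta["echo_times_dme_ms"])
        ]
        dme.append(frame)
    masks = {
        name: as_bool_mask(_read_volume(indir / f"{name}.nii.gz"))
        for name in ("observer_a", "observer_b", "truth")
    }
    return ph.MultiSequenceStudy(
        patient_id=meta["patient_id"],
        t2w=t2w, t2sw=t2sw, dw=dw, dme=dme,
        timestamps_s=tuple(meta["timestamps_s"]),
        dme_echo_times_ms=tuple(meta["echo_times_dme_ms"]),
        arrival_s=meta["arrival_s"],
        observer_a=masks["observer_a"],
        observer_b=masks["observer_b"],
        truth=masks["truth"],
        seed=meta.get("seed"),
    )


def write_mask(mask: ImageVolume, path) -> None:
    _write_volume(mask, Path(path), as_mask=True)


def read_mask(path) -> ImageVolume:
    return as_bool_mask(_read_volume(Path(path)))
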