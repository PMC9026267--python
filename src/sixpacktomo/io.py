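"""File I/O: TIFF hologram frames, YAML sidecars, JSON reports.

Holograms are written as single-channel 8- or 16-bit TIFF, one file per
camera per frame (``frame{idx:04d}_cam{1|2}.tif``), with a sidecar YAML
that records everything needed to reconstruct without the original
config: optics, carrier layout, illumination set, coherence model, seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .forward import (CarrierLayout, CoherenceModel, IlluminationAngle,
                      IlluminationSet, MultiplexedHologram, OpticalConfig)

__all__ = [
    "write_frame_pair", "read_frame_pair", "write_sidecar", "read_sidecar",
    "write_report", "write_phase_stack",
]

SIDECAR_NAME = "sidecar.yaml"


def _holo_dtype(bit_depth):
    if bit_depth is None or bit_depth > 16:
        return np.float32
    return np.uint8 if bit_depth <= 8 else np.uint16


def write_frame_pair(outdir, frames: dict, config: OpticalConfig,
                     layout: CarrierLayout, illum: IlluminationSet,
                     coherence: CoherenceModel, seed: int,
                     frame_index: int = 0) -> dict:
    """Write sample + background frame pairs and the sidecar.

    ``frames`` is the dict from
    :func:`sixpacktomo.forward.simulate_frame_pair`.  Returns the mapping
    of written file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for tag, pair in (("sample", frames["sample"]),
                      ("background", frames["background"])):
        for holo in pair:
            prefix = "" if tag == "sample" else "bg_"
            name = f"{prefix}frame{frame_index:04d}_cam{holo.camera_id}.tif"
            path = outdir / name
            tifffile.imwrite(path, holo.data.astype(_holo_dtype(holo.bit_depth)))
            written[f"{tag}_cam{holo.camera_id}"] = name
    write_sidecar(outdir / SIDECAR_NAME, config, layout, illum, coherence,
                  seed, files=written)
    written["sidecar"] = SIDECAR_NAME
    return written


def write_sidecar(path, config, layout, illum, coherence, seed, files=None):
    doc = {
        "optics": {
            "wavelength_um": config.wavelength_um,
            "na": config.na,
            "magnification": config.magnification,
            "camera_pixel_um": config.camera_pixel_um,
            "bit_depth": config.bit_depth,
            "n_medium": config.n_medium,
        },
        "carriers": {
            "k_na": float(layout.k_na),
            "vectors": [[float(v) for v in c] for c in layout.carriers],
        },
        "illumination": [
            {"theta_deg": a.theta_deg, "phi_deg": a.phi_deg,
             "channel": a.channel, "group": a.group}
            for a in illum
        ],
        "coherence": {"l_c_um": coherence.l_c_um, "step_um": coherence.step_um},
        "seed": int(seed),
        "files": files or {},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_sidecar(path):
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    config = OpticalConfig(**doc["optics"])
    layout = CarrierLayout(np.array(doc["carriers"]["vectors"]),
                           doc["carriers"]["k_na"])
    illum = IlluminationSet([IlluminationAngle(**a) for a in doc["illumination"]])
    coherence = CoherenceModel(**doc["coherence"])
    return {"config": config, "layout": layout, "illum": illum,
            "coherence": coherence, "seed": doc.get("seed", 0),
            "files": doc.get("files", {})}


def read_frame_pair(indir, sidecar=None):
    """Read sample/background frame pairs using the sidecar's file map."""
    indir = Path(indir)
    side = read_sidecar(indir / SIDECAR_NAME if sidecar is None else sidecar)
    config = side["config"]
    layout = side["layout"]

    def load(tag, cam):
        name = side["files"].get(f"{tag}_cam{cam}")
        if name is None:
            raise FileNotFoundError(f"sidecar lists no {tag} frame for camera {cam}")
        data = tifffile.imread(indir / name).astype(np.float64)
        bits = config.bit_depth if np.issubdtype(
            tifffile.imread(indir / name).dtype, np.integer) else None
        return MultiplexedHologram(data, config.pixel_pitch_um, bits, cam, layout)

    side["sample"] = (load("sample", 1), load("sample", 2))
    side["background"] = (load("background", 1), load("background", 2))
    return side


def write_phase_stack(path, fields) -> None:
    """Optional inspection output: 12-page float TIFF of unwrapped phases."""
    stack = np.stack([f.phase.astype(np.float32) for f in fields])
    tifffile.imwrite(path, stack)


def write_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
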