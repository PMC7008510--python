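"""File formats: SMV detector images and experiment metadata JSON.

SMV is the simple ADSC-style format: a 512-byte ASCII header followed by
little-endian unsigned 16-bit pixel values (values above 65535 are clipped
to 65535 on write).  Integer counts round-trip bit-exactly below the
overflow guard.  Experiment metadata (panel, cell, orientation, seeds,
pixel-origin convention) travels as JSON next to the images.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .crystal import Orientation, UnitCell, reciprocal_B
from .detector import PIXEL_ORIGIN_CONVENTION, DetectorPanel

__all__ = ["write_smv", "read_smv", "write_experiment_json", "read_experiment_json"]

SMV_HEADER_BYTES = 512


def write_smv(path, counts: np.ndarray, panel: DetectorPanel,
              wavelength_A: float = 1.7409) -> None:
    counts = np.asarray(counts)
    ny, nx = counts.shape
    data = np.clip(np.rint(counts), 0, 65535).astype("<u2")
    fields = {
        "HEADER_BYTES": SMV_HEADER_BYTES,
        "DIM": 2,
        "BYTE_ORDER": "little_endian",
        "TYPE": "unsigned_short",
        "SIZE1": nx,
        "SIZE2": ny,
        "PIXEL_SIZE": panel.pixel_size,
        "DISTANCE": panel.distance,
        "WAVELENGTH": wavelength_A,
        "BEAM_CENTER_X": panel.beam_center[0] * panel.pixel_size,
        "BEAM_CENTER_Y": panel.beam_center[1] * panel.pixel_size,
    }
    head = "{\n" + "".join(f"{k}={v};\n" for k, v in fields.items()) + "}\n"
    head = head.encode().ljust(SMV_HEADER_BYTES, b" ")
    if len(head) > SMV_HEADER_BYTES:
        raise ValueError("SMV header overflow")
    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(data.tobytes())


def read_smv(path) -> tuple[np.ndarray, dict]:
    with open(path, "rb") as fh:
        head = fh.read(SMV_HEADER_BYTES).decode(errors="replace")
        meta = {}
        for line in head.splitlines():
            line = line.strip().rstrip(";")
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k.strip()] = v.strip()
        nx, ny = int(meta["SIZE1"]), int(meta["SIZE2"])
        data = np.frombuffer(fh.read(2 * nx * ny), dtype="<u2").reshape(ny, nx)
    return data.astype(np.int64), meta


def write_experiment_json(path, panel: DetectorPanel, cell: UnitCell,
                          orientation: Orientation | None = None,
                          seeds: dict | None = None,
                          extra: dict | None = None) -> None:
    doc = {
        "pixel_origin": PIXEL_ORIGIN_CONVENTION,
        "beam": {"direction": [0, 0, 1], "polarization": "horizontal-x"},
        "panel": {
            "n_fast": panel.n_fast, "n_slow": panel.n_slow,
            "pixel_size_mm": panel.pixel_size, "distance_mm": panel.distance,
            "beam_center_px": list(panel.beam_center), "gain": panel.gain,
            "calibration_noise_sd": panel.calibration_noise_sd,
        },
        "cell": {"a": cell.a, "b": cell.b, "c": cell.c, "alpha": cell.alpha,
                 "beta": cell.beta, "gamma": cell.gamma,
                 "space_group": cell.space_group},
        "seeds": seeds or {},
    }
    if orientation is not None:
        doc["orientation_U"] = np.asarray(orientation.U).tolist()
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1))


def read_experiment_json(path) -> tuple[DetectorPanel, UnitCell, Orientation | None, dict]:
    doc = json.loads(Path(path).read_text())
    p = doc["panel"]
    panel = DetectorPanel(p["n_fast"], p["n_slow"], p["pixel_size_mm"],
                          p["distance_mm"], tuple(p["beam_center_px"]),
                          p.get("gain", 1.0), p.get("calibration_noise_sd", 0.01))
    c = doc["cell"]
    cell = UnitCell(c["a"], c["b"], c["c"], c["alpha"], c["beta"], c["gamma"],
                    space_group=c.get("space_group", "P1"))
    orientation = None
    if "orientation_U" in doc:
        orientation = Orientation(np.array(doc["orientation_U"]),
                                  reciprocal_B(cell), cell)
    return panel, cell, orientation, doc
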