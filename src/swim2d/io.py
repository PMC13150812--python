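"""Containers, formats, and run manifests.

The cube container is a single HDF5 file holding the intensity matrix and
product axis as datasets, with the instrument/simulation configurations
and the run manifest embedded as JSON-string attributes, so a cube (or a
decoded 2D spectrum) is always self-describing and reproducible.  Small
cubes can round-trip through CSV (header row = product m/z bin centres,
one row per SWIM index, JSON sidecar for the configs), and per-index
spectra can be exported as mzML for interoperability with general
mass-spectrometry tooling.

The mzML writer emits minimal, standard-conformant mzML 1.1.0 directly
(m/z as 64-bit and intensity as 32-bit zlib-compressed base64 arrays)
and reads it back with the standard-library XML parser; the test suite
additionally validates exported files with an independent mzML reader.
"""

from __future__ import annotations

import base64
import hashlib
import json
import struct
import sys
import zlib
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from xml.sax.saxutils import escape

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .config import InstrumentConfig
from .decode import Peak2D, Spectrum2D
from .forward_sim import DataCube, SimulationConfig
from .secular import CalibrationFit

__all__ = [
    "RunManifest",
    "write_cube",
    "read_cube",
    "write_cube_csv",
    "read_cube_csv",
    "export_mzml",
    "import_mzml",
    "write_spectrum",
    "read_spectrum",
    "peaks_to_dataframe",
    "write_peaks_csv",
]


@dataclass
class RunManifest:
    """Provenance record embedded in every output container."""

    seed: int | None = None
    command: str = ""
    version: str = __version__
    timestamp: str = ""
    config_hashes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        if not self.command:
            self.command = " ".join(sys.argv)

    @staticmethod
    def hash_of(obj) -> str:
        blob = json.dumps(obj, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "RunManifest":
        return cls(**json.loads(s))


# ---------------------------------------------------------------------------
# HDF5 cube container
# ---------------------------------------------------------------------------

def write_cube(cube: DataCube, path, manifest: RunManifest | None = None) -> None:
    manifest = manifest or RunManifest(
        seed=cube.sim.seed if cube.sim else None,
        config_hashes={"instrument": RunManifest.hash_of(cube.instrument.to_dict())},
    )
    with h5py.File(path, "w") as f:
        f.create_dataset("intensities", data=cube.intensities)
        f.create_dataset("product_axis", data=cube.product_axis)
        f.attrs["instrument"] = cube.instrument.to_json()
        if cube.sim is not None:
            f.attrs["sim"] = json.dumps(cube.sim.to_dict())
        f.attrs["meta"] = json.dumps(cube.meta, default=str)
        f.attrs["manifest"] = manifest.to_json()
        f.attrs["container"] = "swim2d.cube"


def read_cube(path) -> DataCube:
    with h5py.File(path, "r") as f:
        for name in ("intensities", "product_axis"):
            if name not in f:
                raise ValueError(f"malformed cube container: missing dataset {name!r}")
        if "instrument" not in f.attrs:
            raise ValueError("malformed cube container: missing 'instrument' attribute")
        sim = None
        if "sim" in f.attrs:
            sim = SimulationConfig.from_dict(json.loads(f.attrs["sim"]))
        meta = json.loads(f.attrs.get("meta", "{}"))
        if "manifest" in f.attrs:
            meta["manifest"] = json.loads(f.attrs["manifest"])
        return DataCube(
            intensities=f["intensities"][...],
            product_axis=f["product_axis"][...],
            instrument=InstrumentConfig.from_json(f.attrs["instrument"]),
            sim=sim,
            meta=meta,
        )


# ---------------------------------------------------------------------------
# CSV cube
# ---------------------------------------------------------------------------

def write_cube_csv(cube: DataCube, path) -> None:
    """Small-cube CSV export: header = product m/z, one row per index.

    Configs go in a JSON sidecar ``<path>.json`` so the CSV round-trips.
    """
    path = Path(path)
    df = pd.DataFrame(cube.intensities,
                      columns=[repr(float(v)) for v in cube.product_axis])
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {"instrument": cube.instrument.to_dict(),
               "sim": cube.sim.to_dict() if cube.sim else None,
               "meta": cube.meta}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str))


def read_cube_csv(path, instrument: InstrumentConfig | None = None) -> DataCube:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sim = None
    meta = {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        instrument = instrument or InstrumentConfig.from_dict(sidecar["instrument"])
        if sidecar.get("sim"):
            sim = SimulationConfig.from_dict(sidecar["sim"])
        meta = sidecar.get("meta", {})
    if instrument is None:
        raise ValueError(
            "cube CSV has no JSON sidecar; pass an InstrumentConfig explicitly"
        )
    try:
        axis = np.array([float(c) for c in df.columns])
    except ValueError as err:
        raise ValueError(f"cube CSV header is not a product m/z axis: {err}") from None
    return DataCube(intensities=df.to_numpy(dtype=float), product_axis=axis,
                    instrument=instrument, sim=sim, meta=meta)


# ---------------------------------------------------------------------------
# mzML export / import
# ---------------------------------------------------------------------------

def _b64(data: np.ndarray, dtype: str) -> str:
    raw = np.asarray(data).astype(dtype).tobytes()
    return base64.b64encode(zlib.compress(raw)).decode()


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="swim2d" version="{version}"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="swim2d">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="{run_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{count}" defaultDataProcessingRef="DP1">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{npts}">
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <userParam name="swim_index" value="{swim_index}" type="xsd:integer"/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def export_mzml(cube: DataCube, path, run_id: str = "swim2d-cube") -> None:
    """Write one MS1 spectrum per SWIM index; the index is recorded as a
    ``swim_index`` userParam.  Intensities are stored as 32-bit floats."""
    mz_b64 = _b64(cube.product_axis, "<f8")
    parts = [_MZML_HEADER.format(version=__version__, run_id=escape(run_id),
                                 count=cube.n_indices)]
    for n in range(cube.n_indices):
        int_b64 = _b64(cube.intensities[n], "<f4")
        parts.append(_MZML_SPECTRUM.format(
            index=n, scan=n + 1, npts=len(cube.product_axis),
            swim_index=n, mz_b64=mz_b64, mz_len=len(mz_b64),
            int_b64=int_b64, int_len=len(int_b64),
        ))
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts))


_NS = "{http://psi.hupo.org/ms/mzml}"
_ACC_MZ = "MS:1000514"
_ACC_INT = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _decode_binary_array(bda) -> np.ndarray:
    accs = {cv.get("accession") for cv in bda.iter(f"{_NS}cvParam")}
    blob = base64.b64decode((bda.find(f"{_NS}binary").text or "").encode())
    if _ACC_ZLIB in accs:
        blob = zlib.decompress(blob)
    dtype = "<f8" if _ACC_F64 in accs else "<f4"
    return np.frombuffer(blob, dtype=dtype).astype(float)


def import_mzml(path, instrument: InstrumentConfig,
                sim: SimulationConfig | None = None) -> DataCube:
    """Re-import an exported per-index mzML file (stdlib XML parser)."""
    import xml.etree.ElementTree as ET

    spectra = []
    axis = None
    root = ET.parse(str(path)).getroot()
    for spectrum in root.iter(f"{_NS}spectrum"):
        arrays = {}
        for bda in spectrum.iter(f"{_NS}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter(f"{_NS}cvParam")}
            if _ACC_MZ in accs:
                arrays["mz"] = _decode_binary_array(bda)
            elif _ACC_INT in accs:
                arrays["intensity"] = _decode_binary_array(bda)
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(
                f"spectrum {spectrum.get('id')!r} lacks m/z or intensity array")
        if axis is None:
            axis = arrays["mz"]
        spectra.append(arrays["intensity"])
    if axis is None:
        raise ValueError(f"no spectra found in {path}")
    return DataCube(intensities=np.vstack(spectra), product_axis=axis,
                    instrument=instrument, sim=sim,
                    meta={"source": str(path)})


# ---------------------------------------------------------------------------
# 2D spectrum container and peak lists
# ---------------------------------------------------------------------------

def write_spectrum(spec: Spectrum2D, path,
                   manifest: RunManifest | None = None) -> None:
    manifest = manifest or RunManifest()
    with h5py.File(path, "w") as f:
        f.create_dataset("magnitude", data=spec.magnitude)
        f.create_dataset("fe_axis", data=spec.fe_axis)
        f.create_dataset("product_axis", data=spec.product_axis)
        if spec.precursor_axis is not None:
            f.create_dataset("precursor_axis", data=spec.precursor_axis)
        if spec.first_pass is not None:
            f.create_dataset("first_pass", data=spec.first_pass)
        f.attrs["instrument"] = spec.instrument.to_json()
        if spec.axis_method:
            f.attrs["axis_method"] = spec.axis_method
        if spec.calibration is not None:
            f.attrs["calibration"] = spec.calibration.to_json()
        f.attrs["meta"] = json.dumps(spec.meta, default=str)
        f.attrs["manifest"] = manifest.to_json()
        f.attrs["container"] = "swim2d.spectrum2d"


def read_spectrum(path) -> Spectrum2D:
    with h5py.File(path, "r") as f:
        for name in ("magnitude", "fe_axis", "product_axis"):
            if name not in f:
                raise ValueError(
                    f"malformed spectrum container: missing dataset {name!r}")
        if "instrument" not in f.attrs:
            raise ValueError(
                "malformed spectrum container: missing 'instrument' attribute")
        calib = None
        if "calibration" in f.attrs:
            calib = CalibrationFit.from_json(f.attrs["calibration"])
        meta = json.loads(f.attrs.get("meta", "{}"))
        if "manifest" in f.attrs:
            meta["manifest"] = json.loads(f.attrs["manifest"])
        return Spectrum2D(
            magnitude=f["magnitude"][...],
            fe_axis=f["fe_axis"][...],
            product_axis=f["product_axis"][...],
            instrument=InstrumentConfig.from_json(f.attrs["instrument"]),
            precursor_axis=(f["precursor_axis"][...]
                            if "precursor_axis" in f else None),
            first_pass=f["first_pass"][...] if "first_pass" in f else None,
            axis_method=f.attrs.get("axis_method"),
            calibration=calib,
            meta=meta,
        )


def peaks_to_dataframe(peaks: list[Peak2D]) -> pd.DataFrame:
    return pd.DataFrame([{
        "precursor_mz": p.precursor_mz,
        "product_mz": p.product_mz,
        "fe": p.fe,
        "height": p.height,
        "snr": p.snr,
        "harmonic_order": p.harmonic_order,
        "on_autocorrelation": p.on_autocorrelation,
    } for p in peaks])


def write_peaks_csv(peaks: list[Peak2D], path) -> None:
    peaks_to_dataframe(peaks).to_csv(path, index=False)
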