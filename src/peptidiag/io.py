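"""File formats: spectra (two-column CSV and mzML), feature matrices,
labels, differential tables, importances, core sets and net-benefit curves.

Every artifact written here is re-loadable by the function next to its
writer; spectrum round-trips are bit-exact (mzML arrays are stored as
uncompressed little-endian float64).
"""

from __future__ import annotations

import base64
import hashlib
import json
import warnings
import zlib
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .peaks import FeatureMatrix
from .spectra import Spectrum

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_mzml",
    "write_mzml",
    "load_spectra",
    "save_feature_matrix",
    "load_feature_matrix",
    "config_hash",
]


def write_spectrum_csv(s: Spectrum, path) -> None:
    pd.DataFrame({"mz": s.mz, "intensity": s.intensity}).to_csv(path, index=False)


def read_spectrum_csv(path, sample_id: str | None = None) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (mz, intensity)")
    mz = df.iloc[:, 0].to_numpy(dtype=float)
    inten = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(np.diff(mz) <= 0):
        warnings.warn(f"{path}: unsorted m/z axis repaired by sorting")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
    return Spectrum(mz=mz, intensity=inten,
                    sample_id=sample_id if sample_id is not None else path.stem)


def _encode_array(a: np.ndarray) -> str:
    return base64.b64encode(a.astype("<f8").tobytes()).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="run">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="{sid}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(spectra: list[Spectrum], path) -> None:
    """Minimal profile-mode mzML writer (uncompressed 64-bit float arrays)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MZML_HEADER.format(count=len(spectra)))
        for i, s in enumerate(spectra):
            mz_b64 = _encode_array(s.mz)
            int_b64 = _encode_array(s.intensity)
            fh.write(
                _MZML_SPECTRUM.format(
                    index=i, sid=escape(s.sample_id or f"spectrum{i}"),
                    n=len(s), mz_len=len(mz_b64), int_len=len(int_b64),
                    mz_b64=mz_b64, int_b64=int_b64,
                )
            )
        fh.write(_MZML_FOOTER)


_ACC_MZ = "MS:1000514"
_ACC_INTENSITY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def read_mzml(path) -> list[Spectrum]:
    """Stream-parse an mzML file (uncompressed or zlib, 32/64-bit floats)."""
    import xml.etree.ElementTree as ET

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    out: list[Spectrum] = []
    for _, elem in ET.iterparse(str(path), events=("end",)):
        if local(elem.tag) != "spectrum":
            continue
        arrays: dict[str, np.ndarray] = {}
        for bda in elem.iter():
            if local(bda.tag) != "binaryDataArray":
                continue
            accs = {
                child.get("accession")
                for child in bda
                if local(child.tag) == "cvParam"
            }
            binary = next(
                (c for c in bda if local(c.tag) == "binary"), None
            )
            raw = base64.b64decode(binary.text or "") if binary is not None else b""
            if _ACC_ZLIB in accs:
                raw = zlib.decompress(raw)
            dtype = "<f4" if _ACC_F32 in accs else "<f8"
            data = np.frombuffer(raw, dtype=dtype).astype(float)
            if _ACC_MZ in accs:
                arrays["mz"] = data
            elif _ACC_INTENSITY in accs:
                arrays["intensity"] = data
        if "mz" in arrays and "intensity" in arrays:
            out.append(
                Spectrum(
                    mz=arrays["mz"], intensity=arrays["intensity"],
                    sample_id=str(elem.get("id", f"spectrum{len(out)}")),
                )
            )
        elem.clear()
    if not out:
        raise ValueError(f"{path}: no spectra found")
    return out


def load_spectra(path, format: str | None = None) -> list[Spectrum]:
    """Load spectra from an mzML file, a single two-column CSV, or a
    directory of per-sample CSVs.  ``format`` is inferred from the suffix
    when omitted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise ValueError(f"{path}: no .csv spectra found")
        return [read_spectrum_csv(f) for f in files]
    fmt = format or ("mzml" if path.suffix.lower() == ".mzml" else "csv")
    if fmt == "mzml":
        return read_mzml(path)
    if fmt == "csv":
        return [read_spectrum_csv(path)]
    raise ValueError(f"unknown spectrum format {fmt!r}")


def save_feature_matrix(m: FeatureMatrix, matrix_path, labels_path=None) -> None:
    """CSV with sample_id as first column and consensus m/z (2 decimals) as
    headers; labels go to a companion CSV."""
    df = m.values.copy()
    df.columns = [f"{float(c):.2f}" for c in df.columns]
    df.insert(0, "sample_id", df.index)
    df.to_csv(matrix_path, index=False)
    if labels_path is not None and not m.labels.empty:
        pd.DataFrame({"sample_id": m.labels.index, "label": m.labels.values}).to_csv(
            labels_path, index=False
        )


def load_feature_matrix(matrix_path, labels_path=None) -> FeatureMatrix:
    df = pd.read_csv(matrix_path)
    df = df.set_index("sample_id")
    df.columns = [float(c) for c in df.columns]
    labels = pd.Series([], dtype=object)
    if labels_path is not None:
        lab = pd.read_csv(labels_path).set_index("sample_id")["label"]
        labels = lab.reindex(df.index)
    return FeatureMatrix(
        values=df, labels=labels,
        fill_mask=pd.DataFrame(False, index=df.index, columns=df.columns),
    )


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
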