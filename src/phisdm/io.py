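"""Readers and writers: TSV tables, JSON calibrations/reports, centroid mzML.

TSV is the plain-text interchange for spectra, sticks, centroids, pair tables
and DIA schemes; mzML (centroid spectra only, 64-bit float arrays, no
compression) is the open dialect for centroided mass spectra, emitted and
parsed with a small lxml-based layer carrying the proper PSI-MS CV terms.
"""

from __future__ import annotations

import base64
import json
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .calibration import MzCalibration, NoiseModel, PhaseModel
from .deconvolution import StickSpectrum
from .peaks import CentroidList, PeakPair

MZML_NS = "http://psi.hupo.org/ms/mzml"


# ---------------------------------------------------------------------------
# TSV


def write_spectrum_tsv(path, freqs, values, calib: MzCalibration | None = None) -> None:
    """Two-column spectrum TSV (frequency, intensity); m/z added when calibrated."""
    df = pd.DataFrame({"freq_hz": np.asarray(freqs), "intensity": np.asarray(values)})
    if calib is not None:
        df.insert(1, "mz", calib.frequency_to_mz(df["freq_hz"].to_numpy()))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_sticks_tsv(path, st: StickSpectrum, calib: MzCalibration | None = None) -> None:
    df = pd.DataFrame({
        "freq_hz": st.freqs,
        "mz": calib.frequency_to_mz(st.freqs) if (calib and len(st)) else np.full(len(st), np.nan),
        "amplitude": st.amplitudes,
        "phase_residual": st.phase_residuals,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_centroids_tsv(path, c: CentroidList) -> None:
    pd.DataFrame({"mz": c.mz, "intensity": c.intensity}).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_centroids_tsv(path) -> CentroidList:
    df = pd.read_csv(path, sep="\t")
    return CentroidList(mz=df["mz"].to_numpy(), intensity=df["intensity"].to_numpy())


def write_pairs_tsv(path, pairs) -> None:
    df = pd.DataFrame([{
        "mz_low": p.mz_low, "mz_high": p.mz_high, "delta_mz": p.delta_mz,
        "int_low": p.intensity_low, "int_high": p.intensity_high,
        "required_R": p.required_R, "required_R_at_200": p.required_R_at_200,
    } for p in pairs])
    if df.empty:
        df = pd.DataFrame(columns=["mz_low", "mz_high", "delta_mz", "int_low",
                                   "int_high", "required_R", "required_R_at_200"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_scheme_tsv(path, scheme) -> None:
    edges = scheme.window_edges
    pd.DataFrame({
        "window": np.arange(scheme.n_windows),
        "lower_mz": edges[:, 0],
        "center_mz": edges.mean(axis=1),
        "upper_mz": edges[:, 1],
    }).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_xics_tsv(path):
    """Long-format XIC table (time, fragment_id, intensity) -> (times, traces)."""
    df = pd.read_csv(path, sep="\t")
    wide = df.pivot_table(index="time", columns="fragment_id", values="intensity",
                          aggfunc="first").sort_index()
    return wide.index.to_numpy(dtype=float), wide.to_numpy(dtype=float).T


# ---------------------------------------------------------------------------
# JSON calibration


def write_calibration_json(path, phase: PhaseModel, calib: MzCalibration,
                           noise: NoiseModel | None = None,
                           source: str | None = None) -> None:
    doc = {"phi0": phase.phi0, "t0": phase.t0,
           "valid_band": [float(phase.valid_band[0]),
                          None if np.isinf(phase.valid_band[1]) else float(phase.valid_band[1])],
           "C": calib.C}
    if noise is not None:
        doc["sigma_spec"] = noise.sigma_spec
        doc["noise_method"] = noise.method
    if source is not None:
        doc["source"] = source
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_calibration_json(path):
    with open(path) as fh:
        doc = json.load(fh)
    band = doc.get("valid_band", [0.0, None])
    phase = PhaseModel(phi0=doc["phi0"], t0=doc["t0"],
                       valid_band=(band[0], np.inf if band[1] is None else band[1]))
    calib = MzCalibration(C=doc["C"])
    noise = (NoiseModel(sigma_spec=doc["sigma_spec"],
                        method=doc.get("noise_method", "mad"))
             if "sigma_spec" in doc else None)
    return phase, calib, noise


# ---------------------------------------------------------------------------
# mzML (centroid spectra)


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def _cv(parent, accession, name, value="", **extra):
    el = etree.SubElement(parent, "cvParam", cvRef="MS", accession=accession,
                          name=name, value=str(value))
    for k, v in extra.items():
        el.set(k, v)
    return el


def write_centroids_mzml(path, c: CentroidList, spectrum_id: str = "scan=1",
                         ms_level: int = 2) -> None:
    """Write a single centroid-mode spectrum to mzML 1.1.0."""
    nsmap = {None: MZML_NS}
    root = etree.Element("mzML", nsmap=nsmap, version="1.1.0")
    cvlist = etree.SubElement(root, "cvList", count="1")
    etree.SubElement(cvlist, "cv", id="MS", fullName="Proteomics Standards "
                     "Initiative Mass Spectrometry Ontology",
                     URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    _cv(fcontent, "MS:1000127", "centroid spectrum")
    slist = etree.SubElement(root, "softwareList", count="1")
    sw = etree.SubElement(slist, "software", id="phisdm", version="0.1.0")
    _cv(sw, "MS:1000799", "custom unreleased software tool", value="phisdm")
    ilist = etree.SubElement(root, "instrumentConfigurationList", count="1")
    etree.SubElement(ilist, "instrumentConfiguration", id="IC1")
    dplist = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dplist, "dataProcessing", id="DP1")
    pm = etree.SubElement(dp, "processingMethod", order="0", softwareRef="phisdm")
    _cv(pm, "MS:1000035", "peak picking")
    run = etree.SubElement(root, "run", id="run1",
                           defaultInstrumentConfigurationRef="IC1")
    speclist = etree.SubElement(run, "spectrumList", count="1",
                                defaultDataProcessingRef="DP1")
    spec = etree.SubElement(speclist, "spectrum", index="0", id=spectrum_id,
                            defaultArrayLength=str(len(c)))
    _cv(spec, "MS:1000580", "MSn spectrum")
    _cv(spec, "MS:1000127", "centroid spectrum")
    _cv(spec, "MS:1000511", "ms level", value=str(ms_level))
    bal = etree.SubElement(spec, "binaryDataArrayList", count="2")
    for accession, name, unit_acc, unit_name, data in (
        ("MS:1000514", "m/z array", "MS:1000040", "m/z", c.mz),
        ("MS:1000515", "intensity array", "MS:1000131",
         "number of detector counts", c.intensity),
    ):
        enc = _b64(data)
        bda = etree.SubElement(bal, "binaryDataArray", encodedLength=str(len(enc)))
        _cv(bda, "MS:1000523", "64-bit float")
        _cv(bda, "MS:1000576", "no compression")
        _cv(bda, accession, name, unitCvRef="MS", unitAccession=unit_acc,
            unitName=unit_name)
        etree.SubElement(bda, "binary").text = enc
    etree.ElementTree(root).write(str(path), xml_declaration=True,
                                  encoding="utf-8", pretty_print=True)


def read_centroids_mzml(path) -> CentroidList:
    """Read the first centroid spectrum of an mzML file.

    Supports the subset this package writes: 64-bit float arrays without
    compression. Parse problems are reported with the offending element's
    line number.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed mzML file {path}: {exc}") from exc
    ns = {"m": MZML_NS}
    spec = tree.find(".//m:spectrum", ns)
    if spec is None:
        raise ValueError(f"malformed mzML file {path}: no spectrum element")
    arrays = {}
    for bda in spec.findall(".//m:binaryDataArray", ns):
        accs = {cv.get("accession") for cv in bda.findall("m:cvParam", ns)}
        if "MS:1000523" not in accs or "MS:1000576" not in accs:
            raise ValueError(
                f"malformed mzML file {path}: unsupported encoding at line "
                f"{bda.sourceline} (need 64-bit float, no compression)")
        binary = bda.find("m:binary", ns)
        data = np.frombuffer(
            base64.b64decode(binary.text or ""), dtype="<f8")
        if "MS:1000514" in accs:
            arrays["mz"] = data
        elif "MS:1000515" in accs:
            arrays["intensity"] = data
    if set(arrays) != {"mz", "intensity"}:
        raise ValueError(
            f"malformed mzML file {path}: missing m/z or intensity array "
            f"at line {spec.sourceline}")
    return CentroidList(mz=arrays["mz"], intensity=arrays["intensity"])
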