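"""Readers and writers for pipeline artifacts.

Raw segments come in as EDF (header sampling rate, read via mne), CSV
(one column per segment, sampling rate supplied by the caller) or
MAT-style numeric matrices.  All tabular stage outputs (IMF sets, feature
matrices, embeddings, labels) round-trip through plain CSV.  A minimal
16-bit EDF writer is included for exporting synthetic datasets; mne
serves as the independent read-back path.
"""
from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .decompose import IMFSet
from .embed import Embedding
from .features import FeatureMatrix
from .segment import LabeledDataset, SignalSegment

__all__ = [
    "read_signals",
    "write_dataset_csv",
    "read_dataset_csv",
    "write_dataset_edf",
    "imfset_to_csv",
    "imfset_from_csv",
    "feature_matrix_to_csv",
    "feature_matrix_from_csv",
    "embedding_to_csv",
    "embedding_from_csv",
    "labels_to_csv",
    "labels_from_csv",
]


def read_signals(
    path: str | Path, format: str | None = None, fs: float | None = None
) -> list[SignalSegment]:
    """Read one SignalSegment per channel/column/record of a file.

    ``format`` defaults to the file extension (edf, csv or mat).  EDF files
    carry their own sampling rate; CSV and MAT need ``fs``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"{path}: no such file")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "tsv" or path.name == "manifest.tsv":
        return read_dataset_csv(path).segments
    if fmt == "csv":
        if fs is None:
            raise IOError(f"{path}: sampling rate required for CSV input")
        frame = pd.read_csv(path)
        return [
            SignalSegment(samples=frame[col].to_numpy(dtype=float), fs=fs,
                          id=str(col))
            for col in frame.columns
        ]
    if fmt == "mat":
        if fs is None:
            raise IOError(f"{path}: sampling rate required for MAT input")
        from scipy.io import loadmat

        try:
            contents = loadmat(path)
        except Exception as exc:  # malformed file
            raise IOError(f"{path}: cannot parse MAT file ({exc})") from exc
        arrays = {
            k: np.asarray(v)
            for k, v in contents.items()
            if not k.startswith("__") and np.asarray(v).ndim == 2
            and np.issubdtype(np.asarray(v).dtype, np.number)
        }
        if not arrays:
            raise IOError(f"{path}: no numeric matrix found")
        name, mat = max(arrays.items(), key=lambda kv: kv[1].size)
        mat = mat.astype(float)
        if mat.shape[0] > mat.shape[1]:  # orient records along rows
            mat = mat.T
        return [
            SignalSegment(samples=row, fs=fs, id=f"{name}_{i:03d}")
            for i, row in enumerate(mat)
        ]
    if fmt == "edf":
        import mne

        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as exc:
            raise IOError(f"{path}: cannot parse EDF file ({exc})") from exc
        try:
            data = raw.get_data(units="uV")  # mne stores EEG in volts
        except (TypeError, ValueError):
            data = raw.get_data()
        return [
            SignalSegment(samples=data[i], fs=float(raw.info["sfreq"]),
                          id=str(ch))
            for i, ch in enumerate(raw.ch_names)
        ]
    raise IOError(f"{path}: unsupported format {fmt!r}")


# ---------------------------------------------------------------- datasets

def write_dataset_csv(dataset: LabeledDataset, out_dir: str | Path) -> Path:
    """One CSV per segment plus a manifest (id, class, file per row)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for seg, label in zip(dataset.segments, dataset.labels):
        fname = f"{seg.id}.csv"
        pd.DataFrame({seg.id: seg.samples}).to_csv(out_dir / fname, index=False)
        rows.append({"id": seg.id, "class": int(label), "file": fname,
                     "fs": seg.fs})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_dataset_csv(manifest: str | Path) -> LabeledDataset:
    manifest = Path(manifest)
    table = pd.read_csv(manifest, sep="\t")
    segments, labels = [], []
    for _, row in table.iterrows():
        frame = pd.read_csv(manifest.parent / row["file"])
        segments.append(
            SignalSegment(
                samples=frame.iloc[:, 0].to_numpy(dtype=float),
                fs=float(row["fs"]), id=str(row["id"]),
                stage_label=int(row["class"]),
            )
        )
        labels.append(int(row["class"]))
    return LabeledDataset(segments=segments, labels=np.asarray(labels))


def write_dataset_edf(dataset: LabeledDataset, path: str | Path) -> Path:
    """Write all segments to one EDF file, one signal per segment.

    Minimal EDF: one data record spanning the whole segment, 16-bit
    samples, physical range from the data.  Channel labels encode the
    class, e.g. ``c1_interictal_007``.
    """
    path = Path(path)
    segs = dataset.segments
    if not segs:
        raise ValueError("empty dataset")
    n_samples = len(segs[0])
    fs = segs[0].fs
    if any(len(s) != n_samples or s.fs != fs for s in segs):
        raise ValueError("EDF export requires equal-length, equal-rate segments")
    ns = len(segs)
    record_duration = n_samples / fs

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8),                       # version
        pad("X X X X", 80),                # patient id
        pad("Startdate X X X X", 80),      # recording id
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 + ns * 256), 8),       # header bytes
        pad("", 44),
        pad("1", 8),                       # number of records
        pad(f"{record_duration:.6g}", 8),
        pad(str(ns), 4),
    ])
    # EDF label field is 16 chars; keep labels short, unique, class-tagged
    labels = [f"c{lab}_{i:04d}" for i, lab in enumerate(dataset.labels)]
    phys_min, phys_max, dig = [], [], []
    for s in segs:
        lo, hi = float(np.min(s.samples)), float(np.max(s.samples))
        if hi == lo:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        scaled = (s.samples - lo) / (hi - lo) * 65535.0 - 32768.0
        dig.append(np.round(scaled).astype("<i2"))
    fields = [
        [pad(lab, 16) for lab in labels],
        [pad("", 80)] * ns,                       # transducer
        [pad("uV", 8)] * ns,
        [pad(f"{v:.8g}"[:8], 8) for v in phys_min],
        [pad(f"{v:.8g}"[:8], 8) for v in phys_max],
        [pad("-32768", 8)] * ns,
        [pad("32767", 8)] * ns,
        [pad("", 80)] * ns,                       # prefiltering
        [pad(str(n_samples), 8)] * ns,
        [pad("", 32)] * ns,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        for d in dig:
            fh.write(struct.pack(f"<{n_samples}h", *d.tolist()))
    return path


# ----------------------------------------------------------- stage tables

def imfset_to_csv(imfset: IMFSet, path: str | Path) -> Path:
    cols = {f"IMF{k + 1}": imfset.imfs[k] for k in range(imfset.n_imfs)}
    cols["residue"] = imfset.residue
    pd.DataFrame(cols).to_csv(path, index=False)
    return Path(path)


def imfset_from_csv(path: str | Path) -> IMFSet:
    frame = pd.read_csv(path)
    imf_cols = [c for c in frame.columns if c.startswith("IMF")]
    return IMFSet(
        imfs=frame[imf_cols].to_numpy(dtype=float).T,
        residue=frame["residue"].to_numpy(dtype=float),
        source_length=len(frame),
    )


def feature_matrix_to_csv(fm: FeatureMatrix, path: str | Path) -> Path:
    fm.to_dataframe().to_csv(path)
    return Path(path)


def feature_matrix_from_csv(path: str | Path, standardized: bool = True) -> FeatureMatrix:
    frame = pd.read_csv(path, index_col="id")
    return FeatureMatrix(
        values=frame.to_numpy(dtype=float),
        feature_names=list(frame.columns),
        segment_ids=[str(i) for i in frame.index],
        standardized=standardized,
    )


def embedding_to_csv(emb: Embedding, ids: list[str], path: str | Path) -> Path:
    axes = ["x", "y", "z"][: emb.coords.shape[1]]
    frame = pd.DataFrame(emb.coords, columns=axes)
    frame.insert(0, "id", ids)
    frame.to_csv(path, index=False)
    return Path(path)


def embedding_from_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path)
    ids = [str(v) for v in frame["id"]]
    coords = frame.drop(columns="id").to_numpy(dtype=float)
    return coords, ids


def labels_to_csv(ids: list[str], labels: np.ndarray, path: str | Path) -> Path:
    pd.DataFrame({"id": ids, "label": np.asarray(labels, dtype=int)}).to_csv(
        path, index=False
    )
    return Path(path)


def labels_from_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    frame = pd.read_csv(path)
    return [str(v) for v in frame["id"]], frame["label"].to_numpy(dtype=int)
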