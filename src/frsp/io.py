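"""File I/O: BrainVision recordings, fixation tables, FRSP arrays, run config.

BrainVision triplets (.vhdr/.vmrk/.eeg) are written natively (multiplexed
IEEE float32 or int16-with-resolution, dialect recorded in the header) and
read back through MNE, which also accepts recordings from actual amplifiers.
Fixation events travel as tab-separated tables in the scanpath schema
(subject, trial, condition, word_index, onset_ms, duration_ms, pass_label) —
the conversion target for EyeLink-ASC-derived event tables. FRSP arrays
persist in HDF5 with full axis metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .eeg import EVENT_COLUMNS, SyntheticRecording
from .em import SCANPATH_COLUMNS
from .reading import OFF_WORD, StimulusQuadruple
from .tfr import FRSPResult

# ---------------------------------------------------------------------------
# BrainVision
# ---------------------------------------------------------------------------

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by frsp

[Common Infos]
Codepage=UTF-8
DataFile={data_file}
MarkerFile={marker_file}
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval}

[Binary Infos]
BinaryFormat={binary_format}

[Channel Infos]
; Ch<number>=<name>,<reference>,<resolution in microvolts>,<unit>
{channel_lines}
"""


def write_brainvision(
    basepath: str | Path,
    rec: SyntheticRecording,
    fmt: str = "float32",
    int16_resolution_uv: float = 0.1,
) -> Path:
    """Write a BrainVision triplet; returns the .vhdr path.

    ``fmt`` selects the binary dialect: multiplexed IEEE float32 (lossless
    for our float32 data) or int16 with a fixed resolution in microvolts.
    Events are mirrored as .vmrk markers with the class, trial and condition
    encoded in the marker description.
    """
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    vhdr, vmrk, eeg = (basepath.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    if fmt == "float32":
        binary_format = "IEEE_FLOAT_32"
        resolution = 1.0
        payload = rec.data.T.astype("<f4").tobytes()
    elif fmt == "int16":
        binary_format = "INT_16"
        resolution = int16_resolution_uv
        scaled = np.clip(np.round(rec.data / resolution), -32768, 32767)
        payload = scaled.T.astype("<i2").tobytes()
    else:
        raise ValueError("fmt must be 'float32' or 'int16'")

    channel_lines = "\n".join(
        f"Ch{i + 1}={name},,{resolution:g},µV" for i, name in enumerate(rec.ch_names)
    )
    vhdr.write_text(
        _VHDR_TEMPLATE.format(
            data_file=eeg.name,
            marker_file=vmrk.name,
            n_channels=len(rec.ch_names),
            sampling_interval=int(round(1e6 / rec.fs)),
            binary_format=binary_format,
            channel_lines=channel_lines,
        ),
        encoding="utf-8",
    )
    with open(eeg, "wb") as fh:
        fh.write(payload)

    lines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "; Mk<number>=<type>,<description>,<position>,<size>,<channel>",
        "Mk1=New Segment,,1,1,0",
    ]
    for k, row in enumerate(rec.events.itertuples(index=False), start=2):
        desc = f"{row.event_class}/trial={row.trial}/cond={row.condition}/quad={row.quad_id}"
        # BrainVision marker positions are 1-based
        lines.append(f"Mk{k}=Stimulus,{desc},{int(row.sample) + 1},1,0")
    vmrk.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return vhdr


def read_brainvision(vhdr_path: str | Path) -> SyntheticRecording:
    """Read a BrainVision triplet into a SyntheticRecording (microvolts).

    Supports the int16-with-resolution and IEEE float32 dialects. Raises with
    the offending filename when the companion files are missing or the binary
    payload size does not match the header.
    """
    import mne

    vhdr_path = Path(vhdr_path)
    if not vhdr_path.exists():
        raise FileNotFoundError(f"missing header file: {vhdr_path}")
    header = vhdr_path.read_text(encoding="utf-8", errors="replace")
    kv = dict(
        line.split("=", 1)
        for line in header.splitlines()
        if "=" in line and not line.startswith(";")
    )
    for key in ("DataFile", "MarkerFile"):
        companion = vhdr_path.parent / kv[key]
        if not companion.exists():
            raise FileNotFoundError(f"missing companion file: {companion}")
    n_ch = int(kv["NumberOfChannels"])
    itemsize = 4 if kv.get("BinaryFormat", "IEEE_FLOAT_32") == "IEEE_FLOAT_32" else 2
    size = os.path.getsize(vhdr_path.parent / kv["DataFile"])
    if size % (n_ch * itemsize) != 0:
        raise ValueError(
            f"data file size {size} is not a multiple of frame size in "
            f"{vhdr_path.parent / kv['DataFile']}"
        )

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    rows = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if "/" not in desc:
            continue
        name = desc.split("/", 1)[1] if desc.startswith("Stimulus/") else desc
        parts = name.split("/")
        fields = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
        rows.append(
            {
                "sample": int(round(onset * raw.info["sfreq"])),
                "event_class": parts[0],
                "subject": -1,
                "trial": int(fields.get("trial", -1)),
                "condition": fields.get("cond", ""),
                "quad_id": int(fields.get("quad", -1)),
            }
        )
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return SyntheticRecording(
        data=data_uv.astype(np.float32),
        fs=float(raw.info["sfreq"]),
        ch_names=tuple(raw.ch_names),
        events=events,
    )


# ---------------------------------------------------------------------------
# fixation tables / corpus / events
# ---------------------------------------------------------------------------

def write_fixation_table(path: str | Path, fixations: pd.DataFrame) -> None:
    fixations.to_csv(path, sep="\t", index=False, columns=SCANPATH_COLUMNS)


def read_fixation_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a scanpath TSV.

    Unknown / negative word indices are mapped to the off-word sentinel.
    Non-monotone onsets within a trial, or malformed durations, raise with
    the offending data row number (1-based, excluding the header).
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(SCANPATH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fixation table missing columns: {sorted(missing)}")
    if df.empty:
        return df[SCANPATH_COLUMNS]
    for col in ("onset_ms", "duration_ms"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna() & df[col].notna() | vals.isna())
        if len(bad):
            raise ValueError(f"malformed {col} in data row {bad[0] + 1}")
        df[col] = vals
    if (df["duration_ms"] <= 0).any():
        row = int(np.flatnonzero(df["duration_ms"] <= 0)[0]) + 1
        raise ValueError(f"non-positive duration in data row {row}")
    df["word_index"] = (
        pd.to_numeric(df["word_index"], errors="coerce").fillna(OFF_WORD).astype(int)
    )
    df.loc[df["word_index"] < 0, "word_index"] = OFF_WORD
    for (_, _), grp in df.groupby(["subject", "trial"], sort=False):
        onsets = grp["onset_ms"].to_numpy()
        if (np.diff(onsets) < 0).any():
            row = int(grp.index[np.flatnonzero(np.diff(onsets) < 0)[0] + 1]) + 1
            raise ValueError(f"non-monotone onset within a trial at data row {row}")
    return df[SCANPATH_COLUMNS]


def write_corpus_json(path: str | Path, corpus: list[StimulusQuadruple]) -> None:
    payload = [
        {
            "quad_id": q.quad_id,
            "words_ord": list(map(int, q.words_ord)),
            "words_rdm": list(map(int, q.words_rdm)),
            "target_index": q.target_index,
        }
        for q in corpus
    ]
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_corpus_json(path: str | Path) -> list[StimulusQuadruple]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        StimulusQuadruple(
            quad_id=q["quad_id"],
            words_ord=tuple(q["words_ord"]),
            words_rdm=tuple(q["words_rdm"]),
            target_index=q["target_index"],
        )
        for q in payload
    ]


# ---------------------------------------------------------------------------
# FRSP persistence
# ---------------------------------------------------------------------------

def save_frsp(path: str | Path, results: list[FRSPResult]) -> None:
    """Persist FRSP maps in HDF5 with axis metadata."""
    with h5py.File(path, "w") as fh:
        for k, res in enumerate(results):
            grp = fh.create_group(f"frsp_{k:04d}")
            grp.create_dataset("db", data=res.db, compression="gzip")
            grp.create_dataset("freqs_hz", data=res.freqs)
            grp.create_dataset("times_ms", data=res.times)
            grp.create_dataset("valid_mask", data=res.mask)
            grp.attrs["baseline_ms"] = res.baseline_ms
            grp.attrs["scheme"] = res.scheme
            grp.attrs["condition"] = res.condition or ""
            grp.attrs["subject"] = -1 if res.subject is None else res.subject
            grp.attrs["ch_names"] = list(res.ch_names or ())


def load_frsp(path: str | Path) -> list[FRSPResult]:
    out = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys()):
            grp = fh[key]
            subject = int(grp.attrs["subject"])
            out.append(
                FRSPResult(
                    db=grp["db"][()],
                    freqs=grp["freqs_hz"][()],
                    times=grp["times_ms"][()],
                    mask=grp["valid_mask"][()],
                    baseline_ms=tuple(grp.attrs["baseline_ms"]),
                    scheme=str(grp.attrs["scheme"]),
                    condition=str(grp.attrs["condition"]) or None,
                    subject=None if subject == -1 else subject,
                    ch_names=tuple(str(c) for c in grp.attrs["ch_names"]),
                )
            )
    return out


def export_band_slice(
    path: str | Path, res: FRSPResult, f_lo: float, f_hi: float
) -> None:
    """Per-channel mean dB in a band over time, as TSV (simple map export)."""
    fsel = (res.freqs >= f_lo) & (res.freqs <= f_hi)
    sl = res.db[:, fsel, :].mean(axis=1)
    df = pd.DataFrame(sl.T, columns=list(res.ch_names or range(sl.shape[0])))
    df.insert(0, "time_ms", res.times)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Every knob of the generate-and-analyze pipeline, serializable to YAML."""

    # corpus / design
    n_quads: int = 120
    subjects: int = 32
    length_mean: float = 9.56
    length_sd: float = 1.61
    pos_mean: float = 7.1
    pos_sd: float = 1.37
    # scanpath model (per-condition: ffd mean, p refix, refix mean, p regression,
    # second-pass mean)
    condition_params: dict = field(
        default_factory=lambda: {
            "ORD_COR": [198.0, 0.20, 145.0, 0.08, 150.0],
            "ORD_SEM": [203.0, 0.20, 170.0, 0.22, 150.0],
            "RDM_COR": [211.0, 0.20, 185.0, 1.0 / 6.0, 150.0],
            "RDM_SEM": [217.0, 0.20, 215.0, 0.20, 150.0],
        }
    )
    duration_shape: float = 25.0
    skip_prob_target: float = 0.05
    skip_prob_other: float = 0.10
    saccade_gap_ms: float = 30.0
    # EEG
    fs: float = 500.0
    noise_exponent: float = 1.0
    session_quads: int = 24  # reduced recording length for the EEG session
    # analysis
    f_min: float = 3.0
    f_max: float = 70.0
    n_cycles: float = 3.0
    decim: int = 10
    baseline_scheme: str = "trial_mean"
    target_epoch_ms: tuple = (-1000.0, 1500.0)
    sentence_epoch_ms: tuple = (-1000.0, 2500.0)
    baseline_ms: tuple = (-1000.0, 0.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for name in ("target_epoch_ms", "sentence_epoch_ms", "baseline_ms"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def save(self, path: str | Path) -> None:
        d = self.to_dict()
        for name in ("target_epoch_ms", "sentence_epoch_ms", "baseline_ms"):
            d[name] = list(d[name])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    json.dump(payload, buf, indent=1, sort_keys=True, default=float)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
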