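"""Record I/O: a minimal WFDB reader for CTU-UHB-style records, last-30-minute
segment selection, and the package's own delimited-text fixture format.

The WFDB reader supports the header conventions and signal formats (16 and
212) the CTU-UHB database uses; it is read-only and never touches the
network.  The fixture format is one CSV per record (``t_sec,fhr,uc``) plus a
JSON sidecar (record id, metadata, label, sample rate) and a dataset manifest
listing record files and split assignments.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import CTGRecord, MaternalMetadata

__all__ = [
    "RawRecording", "FormatError", "EligibilityError", "read_wfdb_record",
    "select_segment", "write_fixture", "read_fixture", "write_manifest",
    "read_manifest",
]


class FormatError(ValueError):
    pass


class EligibilityError(ValueError):
    pass


#: case-insensitive header-comment aliases for the maternal variables;
#: extendable at call time for other database conventions
DEFAULT_ALIASES = {
    "age": ("age", "maternal_age"),
    "gravidity": ("gravidity", "grav", "gravida"),
    "parity": ("parity", "para"),
    "diabetes": ("diabetes", "gest_diabetes", "gdm", "dm"),
}

STAGE_MARKER_KEYS = ("pos_iist", "pos._ii.st.", "ii_stage_pos", "second_stage_pos")


@dataclass
class RawRecording:
    record_id: str
    fhr: np.ndarray
    uc: np.ndarray
    sample_rate: float
    header_metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fhr = np.asarray(self.fhr, dtype=float)
        self.uc = np.asarray(self.uc, dtype=float)
        if self.fhr.shape != self.uc.shape:
            raise FormatError("channels must have equal length")


def _parse_signal_line(line: str) -> dict:
    # <file> <fmt> [gain[(baseline)][/units]] [adcres] [adczero] [init] [cks] [bs] [description...]
    toks = line.split()
    if len(toks) < 2:
        raise FormatError(f"malformed signal line: {line!r}")
    spec: dict = {"file": toks[0], "fmt": toks[1].split("x")[0],
                  "gain": 200.0, "baseline": None, "units": "", "adczero": 0}
    if len(toks) >= 3:
        m = re.match(r"^(-?[\d.]+)(\((-?\d+)\))?(/(\S+))?$", toks[2])
        if not m:
            raise FormatError(f"bad gain field: {toks[2]!r}")
        spec["gain"] = float(m.group(1)) or 200.0
        if m.group(3) is not None:
            spec["baseline"] = int(m.group(3))
        if m.group(5):
            spec["units"] = m.group(5)
    if len(toks) >= 5:
        try:
            spec["adczero"] = int(toks[4])
        except ValueError:
            pass
    if len(toks) >= 10:
        spec["description"] = " ".join(toks[9:])
    if spec["baseline"] is None:
        spec["baseline"] = spec["adczero"]
    return spec


def _read_dat(path: Path, fmt: str, nsig: int, nsamp: int) -> np.ndarray:
    """Return (nsamp, nsig) raw ADC values for the signals stored in `path`."""
    if not path.exists():
        raise FormatError(f"missing signal file {path}")
    raw = path.read_bytes()
    if fmt == "16":
        data = np.frombuffer(raw, dtype="<i2")
        if data.size < nsig * nsamp:
            raise FormatError("signal file shorter than header declares")
        return data[:nsig * nsamp].reshape(nsamp, nsig).astype(np.int64)
    if fmt == "212":
        b = np.frombuffer(raw, dtype=np.uint8)
        n_pairs = (nsig * nsamp + 1) // 2
        if b.size < 3 * n_pairs:
            raise FormatError("signal file shorter than header declares")
        b = b[:3 * n_pairs].reshape(-1, 3).astype(np.int64)
        first = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
        second = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
        first -= (first & 0x800) << 1     # sign-extend 12 bits
        second -= (second & 0x800) << 1
        flat = np.empty(2 * len(b), dtype=np.int64)
        flat[0::2], flat[1::2] = first, second
        return flat[:nsig * nsamp].reshape(nsamp, nsig)
    raise FormatError(f"unsupported WFDB signal format {fmt!r}")


def _normalize_key(key: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", key.strip().lower()).strip("_")


def read_wfdb_record(path: str | Path, aliases: dict | None = None) -> RawRecording:
    """Parse a WFDB header/signal pair into a RawRecording.

    The FHR channel is identified by bpm units (falling back to a description
    containing 'fhr'); the remaining channel is UC.  Header comment lines
    (``#key value``) populate header_metadata; absent fields stay missing.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"missing header file {hea}")
    lines = [ln.rstrip() for ln in hea.read_text().splitlines() if ln.strip()]
    comments = [ln for ln in lines if ln.startswith("#")]
    content = [ln for ln in lines if not ln.startswith("#")]
    if not content:
        raise FormatError("empty header")
    head = content[0].split()
    if len(head) < 4:
        raise FormatError(f"malformed record line: {content[0]!r}")
    record_id = head[0]
    try:
        nsig, fs, nsamp = int(head[1]), float(head[2]), int(head[3])
    except ValueError as exc:
        raise FormatError(f"malformed record line: {content[0]!r}") from exc
    if nsig != 2:
        raise FormatError(f"expected 2 signals (FHR, UC), header declares {nsig}")
    specs = [_parse_signal_line(ln) for ln in content[1:1 + nsig]]
    if len(specs) != nsig:
        raise FormatError("header declares more signals than it describes")

    # read each distinct .dat once (signals may share a file, interleaved)
    physical: list[np.ndarray] = []
    by_file: dict[str, list[int]] = {}
    for i, s in enumerate(specs):
        by_file.setdefault(s["file"], []).append(i)
    columns: dict[int, np.ndarray] = {}
    for fname, sig_idx in by_file.items():
        adc = _read_dat(hea.parent / fname, specs[sig_idx[0]]["fmt"],
                        len(sig_idx), nsamp)
        for col, i in enumerate(sig_idx):
            columns[i] = adc[:, col]
    for i, s in enumerate(specs):
        physical.append((columns[i] - s["baseline"]) / s["gain"])

    units = [s.get("units", "").lower() for s in specs]
    desc = [s.get("description", "").lower() for s in specs]
    if "bpm" in units:
        fhr_i = units.index("bpm")
    elif any("fhr" in d for d in desc):
        fhr_i = next(i for i, d in enumerate(desc) if "fhr" in d)
    else:
        fhr_i = 0
    uc_i = 1 - fhr_i

    header_metadata: dict = {}
    for ln in comments:
        body = ln.lstrip("#").strip()
        if not body:
            continue
        parts = body.split(None, 1)
        key = _normalize_key(parts[0])
        header_metadata[key] = parts[1].strip() if len(parts) > 1 else ""
    return RawRecording(record_id=record_id, fhr=physical[fhr_i],
                        uc=physical[uc_i], sample_rate=fs,
                        header_metadata=header_metadata)


def _maybe_float(val) -> float | None:
    try:
        f = float(val)
    except (TypeError, ValueError):
        return None
    return f if np.isfinite(f) and f >= 0 else None


def metadata_from_header(header: dict, aliases: dict | None = None) -> MaternalMetadata:
    aliases = {**DEFAULT_ALIASES, **(aliases or {})}
    found: dict = {}
    norm = {_normalize_key(k): v for k, v in header.items()}
    for fieldname, keys in aliases.items():
        for k in keys:
            if _normalize_key(k) in norm:
                found[fieldname] = _maybe_float(norm[_normalize_key(k)])
                break
    if found.get("diabetes") is not None:
        found["diabetes"] = int(found["diabetes"] > 0)
    return MaternalMetadata(**found)


def stage1_end_from_header(header: dict) -> int | None:
    """Second-stage position marker (samples) if the header carries one."""
    norm = {_normalize_key(k): v for k, v in header.items()}
    for key in STAGE_MARKER_KEYS:
        if _normalize_key(key) in norm:
            val = _maybe_float(norm[_normalize_key(key)])
            if val is not None:
                return int(val)
    return None


def select_segment(rec: RawRecording, stage1_end: int | None = None,
                   window_minutes: float = 30.0, label: int = 0,
                   aliases: dict | None = None) -> CTGRecord:
    """The ``window_minutes`` of signal ending at ``stage1_end`` (or at the
    recording end when no marker is given or stored).  30 min at 4 Hz is
    exactly 7200 samples."""
    if stage1_end is None:
        stage1_end = stage1_end_from_header(rec.header_metadata)
    end = rec.fhr.size if stage1_end is None else int(stage1_end)
    if not 0 < end <= rec.fhr.size:
        raise EligibilityError(f"stage marker {end} outside the recording")
    n = int(round(window_minutes * 60.0 * rec.sample_rate))
    if end < n:
        raise EligibilityError(
            f"insufficient signal length: need {n} samples before the "
            f"first-stage end, have {end}")
    sl = slice(end - n, end)
    return CTGRecord(
        record_id=rec.record_id,
        fhr=rec.fhr[sl], uc=rec.uc[sl],
        metadata=metadata_from_header(rec.header_metadata, aliases),
        label=label, sample_rate=rec.sample_rate,
        provenance={"source": "wfdb", "segment": [sl.start, sl.stop],
                    "header": dict(rec.header_metadata)},
    )


# --------------------------------------------------------------------------- #
# fixture format
# --------------------------------------------------------------------------- #

def write_fixture(record: CTGRecord, out_dir: str | Path) -> tuple[Path, Path]:
    """One CSV (t_sec,fhr,uc) plus one JSON sidecar per record."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{record.record_id}.csv"
    json_path = out_dir / f"{record.record_id}.json"
    t = np.arange(len(record)) / record.sample_rate
    pd.DataFrame({"t_sec": t, "fhr": record.fhr, "uc": record.uc}).to_csv(
        csv_path, index=False, float_format="%.6f")
    sidecar = {
        "record_id": record.record_id,
        "metadata": record.metadata.to_dict(),
        "label": int(record.label),
        "sample_rate": record.sample_rate,
    }
    sidecar.update(record.provenance.get("extras", {}))
    json_path.write_text(json.dumps(sidecar, indent=2))
    return csv_path, json_path


_SIDE_KEYS = {"record_id", "metadata", "label", "sample_rate"}


def read_fixture(csv_path: str | Path) -> CTGRecord:
    """Read a record back; unknown sidecar keys are preserved untouched in
    ``provenance['extras']`` (forward compatibility)."""
    csv_path = Path(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    missing = _SIDE_KEYS - sidecar.keys()
    if missing:
        raise FormatError(f"sidecar missing keys: {sorted(missing)}")
    df = pd.read_csv(csv_path)
    if not {"t_sec", "fhr", "uc"} <= set(df.columns):
        raise FormatError(f"fixture CSV missing columns in {csv_path}")
    extras = {k: v for k, v in sidecar.items() if k not in _SIDE_KEYS}
    return CTGRecord(
        record_id=sidecar["record_id"],
        fhr=df["fhr"].to_numpy(), uc=df["uc"].to_numpy(),
        metadata=MaternalMetadata.from_dict(sidecar["metadata"]),
        label=int(sidecar["label"]),
        sample_rate=float(sidecar["sample_rate"]),
        provenance={"source": "fixture", "extras": extras},
    )


def write_manifest(out_dir: str | Path, records: list[CTGRecord],
                   splits: dict[str, list[str]] | None = None) -> Path:
    """Write all records plus a manifest listing files and split assignment."""
    out_dir = Path(out_dir)
    entries = []
    for rec in records:
        csv_path, _ = write_fixture(rec, out_dir)
        entries.append({"record_id": rec.record_id, "file": csv_path.name,
                        "label": int(rec.label)})
    manifest = {"records": entries, "splits": splits or {}}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_manifest(path: str | Path) -> tuple[list[CTGRecord], dict]:
    path = Path(path)
    manifest = json.loads(path.read_text())
    records = [read_fixture(path.parent / e["file"]) for e in manifest["records"]]
    return records, manifest.get("splits", {})
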