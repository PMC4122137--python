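"""Readers and writers: EDF recordings, CSV event/area tables, epoch archives.

Recordings are exchanged in European Data Format (EDF): reading goes through
MNE's native EDF reader; writing uses a minimal EDF writer implemented here
(16-bit integer records with per-channel physical scaling), which round-trips
against MNE's reader to within quantization error. Events and channel-area
maps are plain CSV; epoched data is archived as NumPy ``.npz``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import EpochSet, EventOnsets, Recording

_EDF_DIG_MAX = 32767


def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording to EDF with 1-s data records and 'uV' physical units.

    Each channel is scaled independently to the 16-bit digital range using a
    symmetric physical range, so the quantization step is
    ``max|signal| / 32767`` per channel. Header dates are fixed for
    byte-reproducible output.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((n_ch, n_rec * spr))
    data[:, : rec.n_samples] = rec.signal

    phys_max = np.maximum(np.max(np.abs(data), axis=1), 1e-6)
    scale = _EDF_DIG_MAX / phys_max
    digital = np.round(data * scale[:, None]).astype("<i2")

    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field("X X X X", 80),
            _ascii_field(f"Startdate 01-JAN-2001 {rec.session_id}", 80),
            _ascii_field("01.01.01", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (1 + n_ch), 8),
            _ascii_field("", 44),
            _ascii_field(n_rec, 8),
            _ascii_field(1, 8),
            _ascii_field(n_ch, 4),
        ]
    )
    fields = [
        (rec.channel_labels, 16),
        ([""] * n_ch, 80),          # transducer
        (["uV"] * n_ch, 8),         # physical dimension
        ([f"{-pm:.6g}"[:8] for pm in phys_max], 8),
        ([f"{pm:.6g}"[:8] for pm in phys_max], 8),
        ([-_EDF_DIG_MAX] * n_ch, 8),
        ([_EDF_DIG_MAX] * n_ch, 8),
        ([""] * n_ch, 80),          # prefiltering
        ([spr] * n_ch, 8),
        ([""] * n_ch, 32),
    ]
    sig_header = b"".join(
        b"".join(_ascii_field(v, w) for v in values) for values, w in fields
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        # record-major layout: all of channel 0's samples for record r, then channel 1, ...
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(
    path: str | Path,
    area_of_channel: dict[str, str] | None = None,
    session_id: str | None = None,
) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # MNE returns volts for 'uV'-dimensioned channels
    return Recording(
        signal=signal,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        area_of_channel=area_of_channel or {},
        session_id=session_id or Path(path).stem,
    )


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def write_events_csv(events_by_session: Sequence[Sequence[tuple[float, str]]],
                     path: str | Path,
                     session_ids: Sequence[str] | None = None) -> None:
    """Events to CSV with columns (session, onset_time_s, class)."""
    rows = []
    for s_idx, events in enumerate(events_by_session):
        sid = session_ids[s_idx] if session_ids else f"session{s_idx + 1}"
        rows.extend({"session": sid, "onset_time_s": t, "class": c} for t, c in events)
    pd.DataFrame(rows, columns=["session", "onset_time_s", "class"]).to_csv(path, index=False)


def read_events_csv(path: str | Path, session: str | None = None) -> EventOnsets:
    """Read one session's events from a (session, onset_time_s, class) CSV."""
    df = pd.read_csv(path)
    required = {"session", "onset_time_s", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"events CSV must have columns {sorted(required)}")
    if session is not None:
        df = df[df["session"].astype(str) == str(session)]
    if df.empty:
        raise ValueError(f"no events found for session {session!r}")
    df = df.sort_values("onset_time_s")
    onsets = [(float(t), str(c)) for t, c in zip(df["onset_time_s"], df["class"])]
    return EventOnsets(onsets=onsets, source="provided")


def write_area_map_csv(area_of_channel: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        [{"label": k, "area": v} for k, v in area_of_channel.items()]
    ).to_csv(path, index=False)


def read_area_map_csv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    if not {"label", "area"}.issubset(df.columns):
        raise ValueError("area map CSV must have columns (label, area)")
    return dict(zip(df["label"].astype(str), df["area"].astype(str)))


def write_selections_csv(bands, path: str | Path) -> None:
    """Selected bands to CSV (channel, area, f_lo_hz, f_hi_hz, peak_diff_db, favored_class)."""
    pd.DataFrame(
        [
            {
                "channel": b.channel,
                "area": b.area,
                "f_lo_hz": b.f_lo,
                "f_hi_hz": b.f_hi,
                "peak_diff_db": b.peak_diff_db,
                "favored_class": b.favored_class,
            }
            for b in bands
        ],
        columns=["channel", "area", "f_lo_hz", "f_hi_hz", "peak_diff_db", "favored_class"],
    ).to_csv(path, index=False)


def read_selections_csv(path: str | Path):
    from .spectral import SelectedBand

    df = pd.read_csv(path)
    return [
        SelectedBand(
            channel=str(r.channel),
            area=str(r.area) if pd.notna(r.area) else "",
            f_lo=float(r.f_lo_hz),
            f_hi=float(r.f_hi_hz),
            peak_diff_db=float(r.peak_diff_db),
            favored_class=str(r.favored_class),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Epoch archives and dataset export
# ---------------------------------------------------------------------------

def save_epochs(es: EpochSet, path: str | Path) -> None:
    """Archive an epoch set as a NumPy ``.npz`` file."""
    labels = np.array(["" if l is None else str(l) for l in es.labels])
    areas = np.array([es.area_of_channel.get(c, "") for c in es.channel_labels])
    np.savez(
        path,
        epochs=es.epochs,
        labels=labels,
        kept_mask=es.kept_mask,
        channel_labels=np.array(es.channel_labels),
        areas=areas,
        session_id=np.array(es.session_id),
        onset_times=es.onset_times if es.onset_times is not None else np.array([]),
        fs=np.array(es.fs),
    )


def load_epochs(path: str | Path) -> EpochSet:
    with np.load(path, allow_pickle=False) as z:
        channels = [str(c) for c in z["channel_labels"]]
        areas = dict(zip(channels, (str(a) for a in z["areas"])))
        onsets = z["onset_times"]
        return EpochSet(
            epochs=z["epochs"],
            labels=np.array([l if l else None for l in z["labels"]], dtype=object),
            kept_mask=z["kept_mask"],
            channel_labels=channels,
            area_of_channel=areas,
            session_id=str(z["session_id"]),
            onset_times=onsets if onsets.size else None,
            fs=float(z["fs"]),
        )


def write_dataset(dataset, out_dir: str | Path) -> dict[str, Path]:
    """Export a synthetic dataset: one EDF per session, events.csv, channels.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    session_ids = []
    for rec in dataset.recordings:
        p = out / f"{rec.session_id}.edf"
        write_edf(rec, p)
        paths[rec.session_id] = p
        session_ids.append(rec.session_id)
    write_events_csv(dataset.events, out / "events.csv", session_ids)
    paths["events"] = out / "events.csv"
    write_area_map_csv(dataset.recordings[0].area_of_channel, out / "channels.csv")
    paths["channels"] = out / "channels.csv"
    return paths
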