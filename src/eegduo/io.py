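"""Session fixture format and EDF import.

A session is a directory containing:

``signal.npy``
    ``(n_channels, n_samples)`` float32 array in microvolts (portable
    NumPy binary).  ``save_session(..., csv=True)`` additionally writes
    ``signal.csv`` (channels as columns) for tools that cannot read npy.
``channels.txt``
    one channel label per line, in signal row order.
``events.tsv``
    tab-separated ``sample_index<TAB>label`` rows.
``meta.json``
    sampling rate, reference scheme and free-form metadata.

EDF recordings (e.g. exports from acquisition software) are imported with
MNE; writing EDF is out of scope, the fixture format is the write path.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .containers import Recording


def save_session(rec: Recording, directory: str | Path, *, csv: bool = False) -> Path:
    """Write a recording to a session fixture directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.save(d / "signal.npy", rec.signal.astype(np.float32))
    (d / "channels.txt").write_text("\n".join(rec.channels) + "\n")
    with open(d / "events.tsv", "w") as fh:
        fh.write("sample_index\tlabel\n")
        for idx, label in rec.events:
            fh.write(f"{idx}\t{label}\n")
    meta = {"fs_hz": rec.fs, "reference": rec.reference, **rec.meta}
    (d / "meta.json").write_text(json.dumps(meta, indent=2, default=str) + "\n")
    if csv:
        np.savetxt(d / "signal.csv", rec.signal.T, delimiter=",",
                   header=",".join(rec.channels), comments="", fmt="%.6g")
    return d


def load_session(directory: str | Path) -> Recording:
    """Read a recording from a session fixture directory."""
    d = Path(directory)
    signal = np.load(d / "signal.npy").astype(float)
    channels = tuple(
        line.strip() for line in (d / "channels.txt").read_text().splitlines()
        if line.strip())
    events: list[tuple[int, str]] = []
    lines = (d / "events.tsv").read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        idx, label = line.split("\t")
        events.append((int(idx), label))
    meta = json.loads((d / "meta.json").read_text())
    fs = float(meta.pop("fs_hz"))
    reference = meta.pop("reference", "raw")
    return Recording(signal, fs, channels, events, reference, meta)


def read_edf(path: str | Path, *, channels: Sequence[str] | None = None,
             event_channel: str | None = None) -> Recording:
    """Import an EDF recording as a :class:`Recording` (signal in microvolts).

    Annotations become the event stream.  ``channels`` optionally restricts
    and orders the montage.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels is not None:
        raw.pick([c for c in channels])
    data = raw.get_data() * 1e6  # MNE stores volts
    events: list[tuple[int, str]] = []
    for ann in raw.annotations:
        sample = int(round(ann["onset"] * raw.info["sfreq"]))
        if 0 <= sample < data.shape[1]:
            events.append((sample, str(ann["description"])))
    return Recording(data, float(raw.info["sfreq"]), tuple(raw.ch_names),
                     events, reference="as-recorded", meta={"source": str(path)})
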