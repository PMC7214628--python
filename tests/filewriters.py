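"""Minimal synthetic EDF+ and BrainVision writers for reader round-trip tests.

These produce small, standard-conformant files from known arrays at test
time; they are fixture generators, not production writers.
"""

from __future__ import annotations

import numpy as np

PHYS_MIN, PHYS_MAX = -500.0, 500.0
DIG_MIN, DIG_MAX = -32768, 32767


def _pad(s: str, width: int) -> bytes:
    b = s.encode("ascii")
    assert len(b) <= width, (s, width)
    return b + b" " * (width - len(b))


def write_edf(path, data_uv: np.ndarray, fs: float,
              events: list[tuple[float, str]]) -> None:
    """Write an EDF+C file: continuous signals plus annotated events.

    ``data_uv`` is (n_channels, n_samples) in microvolts; the recording is
    chopped into 1-second records.  Each event is (onset_s, description).
    """
    C, T = data_uv.shape
    spr = int(round(fs))  # samples per 1 s record
    n_rec = T // spr
    assert n_rec * spr == T, "sample count must be a whole number of records"
    ns = C + 1  # plus the annotations channel
    ann_spr = 64  # 128 bytes of TAL space per record

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate 01-JAN-2020 X X X", 80),
        _pad("01.01.20", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("EDF+C", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    labels = [f"EEG ch{c:02d}" for c in range(C)] + ["EDF Annotations"]
    fields = [
        (16, labels),
        (80, [""] * ns),
        (8, ["uV"] * C + [""]),
        (8, [str(int(PHYS_MIN))] * C + ["-1"]),
        (8, [str(int(PHYS_MAX))] * C + ["1"]),
        (8, [str(DIG_MIN)] * ns),
        (8, [str(DIG_MAX)] * ns),
        (80, [""] * ns),
        (8, [str(spr)] * C + [str(ann_spr)]),
        (32, [""] * ns),
    ]
    for width, vals in fields:
        header += b"".join(_pad(v, width) for v in vals)

    scale = (DIG_MAX - DIG_MIN) / (PHYS_MAX - PHYS_MIN)
    digital = np.round((data_uv - PHYS_MIN) * scale + DIG_MIN).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_rec):
            for c in range(C):
                f.write(digital[c, r * spr:(r + 1) * spr].tobytes())
            tal = f"+{r}\x14\x14\x00".encode("ascii")
            for onset, desc in events:
                if r <= onset < r + 1:
                    tal += f"+{onset:g}\x14{desc}\x14\x00".encode("ascii")
            tal = tal.ljust(2 * ann_spr, b"\x00")
            assert len(tal) == 2 * ann_spr, "annotation record overflow"
            f.write(tal)


def write_brainvision(basepath, data_uv: np.ndarray, fs: float,
                      events: list[tuple[float, str]]) -> str:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg); returns the vhdr path.

    ``data_uv`` is (n_channels, n_samples); events are (onset_s, kind) and
    are written as Stimulus markers.
    """
    base = str(basepath)
    C, T = data_uv.shape
    stem = base.rsplit("/", 1)[-1]
    with open(base + ".vhdr", "w") as f:
        f.write("Brain Vision Data Exchange Header File Version 1.0\n")
        f.write("[Common Infos]\n")
        f.write(f"DataFile={stem}.eeg\nMarkerFile={stem}.vmrk\n")
        f.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
        f.write(f"NumberOfChannels={C}\n")
        f.write(f"SamplingInterval={1e6 / fs:g}\n")
        f.write("[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n")
        f.write("[Channel Infos]\n")
        for c in range(C):
            f.write(f"Ch{c + 1}=ch{c:02d},,1,uV\n")
    with open(base + ".vmrk", "w") as f:
        f.write("Brain Vision Data Exchange Marker File, Version 1.0\n")
        f.write("[Common Infos]\n")
        f.write(f"DataFile={stem}.eeg\n")
        f.write("[Marker Infos]\n")
        f.write("Mk1=New Segment,,1,1,0,20200101000000000000\n")
        for i, (onset, kind) in enumerate(events):
            pos = int(round(onset * fs)) + 1  # 1-based
            f.write(f"Mk{i + 2}=Stimulus,{kind},{pos},1,0\n")
    data_uv.astype("<f4").T.tofile(base + ".eeg")
    return base + ".vhdr"
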