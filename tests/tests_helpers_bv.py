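"""Helper: write a small synthetic BrainVision recording to disk.

Used by the end-to-end pipeline test; the recording carries an N1/P2-like
stimulus-locked response on a 15-channel standard-label montage so the
full load -> filter -> segment -> mark chain has something to find.
"""

import numpy as np

from toposep.synth import component_pattern, make_component_defaults, reduced_montage


def write_synthetic_brainvision(tmp_path, n_events=24, sfreq=500.0, stem="synthrec"):
    mon = reduced_montage(15)
    rng = np.random.default_rng(77)
    isi = int(0.9 * sfreq)
    n_samples = (n_events + 2) * isi
    data = rng.normal(0, 3.0, size=(len(mon), n_samples))

    comps = [c for c in make_component_defaults() if c.name in ("N1", "P2")]
    t = np.arange(-int(0.1 * sfreq), int(0.6 * sfreq)) / sfreq * 1000.0
    blip = np.zeros((len(mon), t.size))
    for c in comps:
        pat = component_pattern(c, mon)
        blip += (c.amplitude_uv * pat[:, None]
                 * np.exp(-0.5 * ((t - c.latency_ms) / (c.width_ms / 2.355)) ** 2))

    events = []
    for i in range(n_events):
        s = (i + 1) * isi
        events.append(s)
        data[:, s - int(0.1 * sfreq):s + int(0.6 * sfreq)] += blip

    vhdr = tmp_path / f"{stem}.vhdr"
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={len(mon)}",
        f"SamplingInterval={1e6 / sfreq:g}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(mon.labels, 1):
        lines.append(f"Ch{i}={lab},,1")
    vhdr.write_text("\n".join(lines) + "\n")

    mlines = ["Brain Vision Data Exchange Marker File, Version 1.0",
              "[Marker Infos]"]
    for i, s in enumerate(events, 1):
        mlines.append(f"Mk{i}=Stimulus,S  1,{s + 1},1,0")  # 1-based positions
    (tmp_path / f"{stem}.vmrk").write_text("\n".join(mlines) + "\n")
    data.astype("<f4").T.tofile(tmp_path / f"{stem}.eeg")
    return vhdr
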