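"""Shared fixtures: small point sets and a minimal FCS fixture writer."""

import numpy as np
import pytest

from samspec import EventMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_gaussians(rng):
    """Two well-separated isotropic Gaussians, 2000 points each, d=2."""
    a = rng.normal(0.0, 1.0, size=(2000, 2))
    b = rng.normal(12.0, 1.0, size=(2000, 2))
    truth = np.r_[np.ones(2000, dtype=int), np.full(2000, 2, dtype=int)]
    return EventMatrix(np.vstack([a, b])), truth


def write_fcs(path, values, channel_names):
    """Write a minimal FCS 3.0 file (float data, little endian) for tests."""
    values = np.asarray(values, dtype="<f4")
    n, d = values.shape
    delim = "/"
    keywords = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(d),
        "$TOT": str(n),
    }
    for i, name in enumerate(channel_names, start=1):
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}R"] = "262144"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in keywords.items()) + delim
    text_bytes = text.encode("ascii")
    header_len = 58
    text_start = header_len
    text_end = text_start + len(text_bytes) - 1
    data_start = text_end + 1
    data_end = data_start + values.nbytes - 1
    header = (
        b"FCS3.0    "
        + f"{text_start:8d}{text_end:8d}{data_start:8d}{data_end:8d}".encode()
        + b"       0       0"
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes)
        fh.write(values.tobytes())
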