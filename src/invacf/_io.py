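"""CSV serialisation helper: full-precision, round-trip-exact floats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def _float_repr(value) -> str:
    # shortest representation that round-trips to the same float64
    return repr(float(value))


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a frame so that reading it back reproduces every float exactly.

    pandas' default float formatting keeps only 15 significant digits, which
    breaks the bit-identity between staged and single-run pipelines.
    """
    frame.to_csv(path, index=False, float_format=_float_repr)


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a CSV with the exact (round-trip) float parser.

    The default pandas parser can be off by one ulp; staged pipeline reruns
    must reproduce single-run artifacts bit for bit.
    """
    return pd.read_csv(path, float_precision="round_trip", **kwargs)
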