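"""Shared plain-text table readers/writers.

Every table the pipeline writes starts with a comment header naming the
producing package version and the configuration hash, so any output file
can be traced to the run that made it.  Readers skip ``#`` comment lines.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str = "none",
                sep: str = "\t", index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# pdcscreen {__version__} config={config_hash}\n")
        df.to_csv(fh, sep=sep, index=index)
    return path


def read_table(path: str | Path, sep: str = "\t", **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", **kwargs)


def read_bed(path: str | Path, names: tuple[str, ...] = ("chrom", "start", "end")) -> pd.DataFrame:
    """Read a headerless BED-like file (extra columns get positional names)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    cols = list(names) + [f"col{i}" for i in range(len(names), df.shape[1])]
    df.columns = cols[: df.shape[1]]
    return df
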