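"""CSV I/O with a reproducibility metadata header.

Every file the pipeline writes starts with ``#``-prefixed comment lines
recording the package version, the master seed and a hash of the run
configuration, so any output table can be traced back to the exact run
that produced it.  Readers skip the comment lines transparently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_csv_with_metadata(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> Path:
    import wasatrial

    path = Path(path)
    meta = {"package": f"wasatrial {wasatrial.__version__}"}
    if metadata:
        meta.update(metadata)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, lineterminator="\n")
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping any metadata header lines."""
    return pd.read_csv(path, comment="#")
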