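"""Delimited-text I/O with provenance headers.

All pipeline outputs are UTF-8 CSV with '.' decimal separator and "NA"
as the missing-value marker.  Every file starts with a comment line
recording the tool version, a hash of the effective configuration and
the seed, so outputs are traceable to the run that produced them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, *, version: str, cfg_hash: str, seed) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# sednitrate {version} config={cfg_hash} seed={seed}\n")
        df.to_csv(fh, index=False, na_rep="NA")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", na_values=["NA"])
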