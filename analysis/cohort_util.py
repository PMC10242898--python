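"""Shared helper: load (or lazily regenerate) the simulated cohort."""

import importlib
import sys
from pathlib import Path

import pandas as pd

from cotfam.io import read_table

ROOT = Path(__file__).resolve().parents[1]


def load_cohort() -> pd.DataFrame:
    path = ROOT / "scratch" / "cohort.csv"
    if not path.exists():
        sys.path.insert(0, str(Path(__file__).parent))
        importlib.import_module("01_simulate_cohort").main()
    return read_table(path)
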