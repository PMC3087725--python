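"""Shared helpers for the analysis drivers."""
from pathlib import Path

import numpy as np

from admixcohort.marker_sets import MarkerSet


def load_markers(v, path) -> MarkerSet:
    """Read a one-rsid-per-line marker file against a variant table."""
    keep = set(Path(path).read_text().split())
    return MarkerSet(Path(path).stem,
                     np.flatnonzero(v["rsid"].isin(keep).to_numpy()), {})
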