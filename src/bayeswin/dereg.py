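"""Deregression of estimated breeding values (EBVs) into pseudo-phenotypes.

EBVs are shrunken towards the mean in proportion to their reliability r^2;
using them directly as a dependent variable double-shrinks marker effects.
Deregression removes the shrinkage: dEBV = EBV / r^2, with the standard
information weight

    w = (1 - h^2) / ((c + (1 - r^2) / r^2) * h^2)

where ``c`` is the fraction of genetic variance not captured by markers.
This is the single-animal form (no parent-average decomposition, which
would require a pedigree). The dEBVs enter the samplers unweighted by
default; weights are emitted for optional use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["deregress", "filter_by_accuracy"]


def deregress(records: pd.DataFrame, h2: float, c: float = 0.5) -> pd.DataFrame:
    """Deregress a table with columns ``animal``, ``ebv``, ``reliability``.

    Returns columns ``animal``, ``debv``, ``weight``. Records with zero
    reliability are rejected (deregression is undefined there).
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie in (0, 1)")
    if not 0.0 <= c < 1.0:
        raise ValueError("c must lie in [0, 1)")
    r2 = records["reliability"].to_numpy(dtype=float)
    if np.any(r2 <= 0.0) or np.any(r2 > 1.0):
        raise ValueError("reliability must lie in (0, 1]")
    debv = records["ebv"].to_numpy(dtype=float) / r2
    weight = (1.0 - h2) / ((c + (1.0 - r2) / r2) * h2)
    return pd.DataFrame({
        "animal": records["animal"].to_numpy(),
        "debv": debv,
        "weight": weight,
    })


def filter_by_accuracy(records: pd.DataFrame, min_accuracy: float = 0.60) -> pd.DataFrame:
    """Keep records whose EBV accuracy r = sqrt(r^2) is strictly above the cutoff."""
    r = np.sqrt(records["reliability"].to_numpy(dtype=float))
    keep = r > min_accuracy
    return records[keep].reset_index(drop=True)
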