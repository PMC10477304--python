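"""Broad per-sample microbiome measurements.

Richness, Shannon alpha diversity and human-read shedding are computed on
the raw (pre-processing) abundance data. Species relative abundance follows
the unique-relative-abundance (URA) idea: a species' score is the mean read
coverage over the most densely covered half of its positions (uniquely
mapped reads), and scores are normalized to sum to one across detected
species.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import UndefinedInputError


def richness(abundance_vector) -> int:
    """Number of strictly positive entries (missing entries count as absent)."""
    v = np.asarray(abundance_vector, dtype=float)
    return int(np.nansum(v > 0))


def shannon_diversity(abundance_vector, base: float | None = None) -> float:
    """Shannon index ``H = -sum p_i log p_i`` over normalized positive entries.

    Natural log by default; pass ``base`` for another convention. Raises
    :class:`UndefinedInputError` if no entry is positive.
    """
    v = np.asarray(abundance_vector, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size == 0:
        raise UndefinedInputError("Shannon diversity undefined for all-zero input")
    p = v / v.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def human_shedding(human_reads: int, total_reads: int) -> float:
    """Percentage of human reads among quality-passed reads."""
    if total_reads <= 0:
        raise UndefinedInputError("total_reads must be > 0")
    if not 0 <= human_reads <= total_reads:
        raise UndefinedInputError("need 0 <= human_reads <= total_reads")
    return 100.0 * human_reads / total_reads


def ura_score(coverage) -> float:
    """Mean coverage over the ceil(n/2) highest-coverage positions."""
    cov = np.asarray(coverage, dtype=float)
    if cov.size == 0:
        raise UndefinedInputError("coverage profile must be non-empty")
    k = int(np.ceil(cov.size / 2))
    top = np.sort(cov)[::-1][:k]
    return float(top.mean())


def ura_abundance(profiles: dict) -> pd.Series:
    """Relative abundance per species from coverage profiles.

    ``profiles`` maps species_id -> per-position coverage array. Scores are
    normalized to sum to 1 over species with a positive score; if every
    score is zero all species are reported absent (NaN).
    """
    scores = pd.Series({sp: ura_score(cov) for sp, cov in profiles.items()})
    total = scores[scores > 0].sum()
    if total == 0:
        return pd.Series(np.nan, index=scores.index)
    out = scores / total
    out[scores == 0] = 0.0
    return out
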