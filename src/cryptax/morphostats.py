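"""Per-character descriptive statistics and Tukey HSD comparisons.

Boxplot-style summaries use 2.5th/97.5th-percentile whiskers (covering
95% of the distribution).  Pairwise species comparisons use the
Tukey-Kramer form of the honestly-significant-difference test, with
adjusted p-values and simultaneous confidence intervals from the
studentized range distribution.
"""
from __future__ import annotations

import itertools
import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .errors import DegenerateVarianceError, InsufficientDataError
from .measurements import CHARACTERS, validate_measurement_table

logger = logging.getLogger(__name__)

WHISKER_COVERAGE = 95.0  # percent of the distribution spanned by whiskers


@lru_cache(maxsize=256)
def _q_critical(alpha: float, g: int, df: int) -> float:
    return float(studentized_range.ppf(1 - alpha, g, df))


def summarize_characters(table: pd.DataFrame) -> pd.DataFrame:
    """Boxplot summary per species and character.

    Returns a tidy frame with columns species, character, n, median, q1,
    q3, whisker_low, whisker_high.  Missing cells are dropped per
    character (and logged).
    """
    validate_measurement_table(table)
    half_tail = (100.0 - WHISKER_COVERAGE) / 2.0
    rows = []
    for species, group in table.groupby("species", sort=True):
        for character in CHARACTERS:
            values = group[character].dropna().to_numpy(dtype=float)
            if values.size < len(group):
                logger.info(
                    "species %r, character %s: dropped %d missing values",
                    species, character, len(group) - values.size,
                )
            if values.size == 0:
                continue
            rows.append(
                {
                    "species": species,
                    "character": character,
                    "n": values.size,
                    "median": float(np.median(values)),
                    "q1": float(np.percentile(values, 25)),
                    "q3": float(np.percentile(values, 75)),
                    "whisker_low": float(np.percentile(values, half_tail)),
                    "whisker_high": float(np.percentile(values, 100 - half_tail)),
                }
            )
    if not rows:
        raise InsufficientDataError("no data to summarize")
    return pd.DataFrame(rows)


def tukey_hsd(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer HSD over all species pairs, per character.

    For groups i, j with pooled SD s over g groups and N specimens, the
    simultaneous CI half-width is
    ``q_{alpha; g, N-g} / sqrt(2) * s * sqrt(1/n_i + 1/n_j)`` and the
    adjusted p-value is the studentized-range tail probability of the
    corresponding q statistic.  A pair is significant iff the adjusted
    p-value is below alpha, equivalently iff the CI excludes zero.
    """
    validate_measurement_table(table)
    if table["species"].nunique() < 2:
        raise InsufficientDataError("Tukey HSD requires at least 2 species")
    rows = []
    for character in CHARACTERS:
        sub = table[["species", character]].dropna()
        groups = {
            sp: g[character].to_numpy(dtype=float)
            for sp, g in sub.groupby("species", sort=True)
        }
        groups = {sp: v for sp, v in groups.items() if v.size >= 2}
        g = len(groups)
        if g < 2:
            logger.warning("character %s: fewer than 2 usable groups; skipped", character)
            continue
        n_total = sum(v.size for v in groups.values())
        df = n_total - g
        ss_within = sum((v.size - 1) * v.var(ddof=1) for v in groups.values())
        if ss_within <= 0:
            raise DegenerateVarianceError(
                f"character {character}: zero within-group variance in all groups"
            )
        s_pooled = np.sqrt(ss_within / df)
        q_crit = _q_critical(alpha, g, df)
        for sp_i, sp_j in itertools.combinations(sorted(groups), 2):
            vi, vj = groups[sp_i], groups[sp_j]
            diff = float(vi.mean() - vj.mean())
            se = s_pooled * np.sqrt(0.5 * (1.0 / vi.size + 1.0 / vj.size))
            half_width = q_crit * se
            q_stat = abs(diff) / se
            p_adj = float(studentized_range.sf(q_stat, g, df))
            rows.append(
                {
                    "character": character,
                    "species_a": sp_i,
                    "species_b": sp_j,
                    "mean_diff": diff,
                    "lower": diff - half_width,
                    "upper": diff + half_width,
                    "p_adj": p_adj,
                    "significant": bool(p_adj < alpha),
                }
            )
    return pd.DataFrame(rows)
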