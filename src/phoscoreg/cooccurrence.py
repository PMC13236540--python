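"""Within-protein pairwise co-occurrence patterns and the ratio statistic.

For a site pair (T1, T2) we count, over the differential datasets in which
BOTH sites carry a U or D call, the four directional patterns
nUU, nUD, nDU, nDD (first letter = T1).  The positive co-occurrence ratio is

    (nUU + nDD) / (nUD + nDU)

and the negative ratio is its inverse; a zero denominator with a nonzero
numerator yields +inf, 0/0 yields NaN (undefined) — sentinels, never
exceptions.  Datasets where either site is NR or absent contribute nothing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import pandas as pd

from .io_registry import Registry, SiteKey, UsageError

INFINITE = math.inf
UNDEFINED = math.nan

MATRIX_COLUMNS = [
    "site_i",
    "site_j",
    "nUU",
    "nUD",
    "nDU",
    "nDD",
    "concordant",
    "discordant",
    "positive_ratio",
    "negative_ratio",
]


@dataclass(frozen=True)
class PairPatternCounts:
    """Directional pattern counts for an ordered pair (anchor=T1, other=T2)."""

    anchor: SiteKey
    other: SiteKey
    nUU: int = 0
    nUD: int = 0
    nDU: int = 0
    nDD: int = 0
    n_conditions_concordant: int = 0
    n_conditions_discordant: int = 0
    n_studies_concordant: int = 0
    n_studies_discordant: int = 0

    @property
    def concordant(self) -> int:
        return self.nUU + self.nDD

    @property
    def discordant(self) -> int:
        return self.nUD + self.nDU

    @property
    def total(self) -> int:
        return self.concordant + self.discordant


@dataclass(frozen=True)
class CoOccurrenceRatio:
    anchor: SiteKey
    other: SiteKey
    polarity: str  # "positive" | "negative"
    ratio: float  # may be INFINITE or UNDEFINED


def _direction_series(calls: pd.DataFrame, site: SiteKey) -> pd.Series:
    mask = (
        (calls["gene_symbol"] == site.gene_symbol)
        & (calls["residue"] == site.residue)
        & (calls["position"] == site.position)
    )
    sub = calls[mask]
    return pd.Series(sub["direction"].to_numpy(), index=sub["dataset_id"].to_numpy())


def pair_pattern_counts(
    t1: SiteKey,
    t2: SiteKey,
    calls: pd.DataFrame,
    registry: Registry | None = None,
) -> PairPatternCounts:
    """Count U/D pattern frequencies for one ordered site pair.

    ``calls`` must be collapsed (one call per dataset-site, as produced by
    ``call_registry``).  With a registry, per-polarity distinct condition and
    study counts are filled in; without one they stay 0.
    """
    if t1 == t2:
        raise UsageError("pair_pattern_counts requires two distinct sites")
    d1 = _direction_series(calls, t1)
    d2 = _direction_series(calls, t2)
    common = d1.index.intersection(d2.index)
    a, b = d1.loc[common], d2.loc[common]
    both = (a != "NR") & (b != "NR")
    a, b = a[both], b[both]
    nUU = int(((a == "U") & (b == "U")).sum())
    nUD = int(((a == "U") & (b == "D")).sum())
    nDU = int(((a == "D") & (b == "U")).sum())
    nDD = int(((a == "D") & (b == "D")).sum())

    n_cond_c = n_cond_d = n_stud_c = n_stud_d = 0
    if registry is not None and len(a):
        conc_ds = a.index[(a == b)]
        disc_ds = a.index[(a != b)]
        meta = registry.datasets
        n_cond_c = len({meta[d].condition_id for d in conc_ds})
        n_cond_d = len({meta[d].condition_id for d in disc_ds})
        n_stud_c = len({meta[d].study_id for d in conc_ds})
        n_stud_d = len({meta[d].study_id for d in disc_ds})
    return PairPatternCounts(
        anchor=t1,
        other=t2,
        nUU=nUU,
        nUD=nUD,
        nDU=nDU,
        nDD=nDD,
        n_conditions_concordant=n_cond_c,
        n_conditions_discordant=n_cond_d,
        n_studies_concordant=n_stud_c,
        n_studies_discordant=n_stud_d,
    )


def cooccurrence_ratio(
    c: PairPatternCounts, polarity: str, pseudocount: float = 0.0
) -> CoOccurrenceRatio:
    """The co-occurrence ratio for one polarity (raw counts by default)."""
    if polarity not in ("positive", "negative"):
        raise UsageError(f"polarity must be positive/negative, got {polarity!r}")
    conc = c.concordant + pseudocount
    disc = c.discordant + pseudocount
    num, den = (conc, disc) if polarity == "positive" else (disc, conc)
    if den == 0:
        ratio = UNDEFINED if num == 0 else INFINITE
    else:
        ratio = num / den
    return CoOccurrenceRatio(anchor=c.anchor, other=c.other, polarity=polarity, ratio=ratio)


def cooccurrence_matrix(
    protein: str,
    calls: pd.DataFrame,
    registry: Registry | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Long-format pairwise co-occurrence table for every ordered site pair.

    Diagonal excluded; fewer than two sites yields an empty table.  The
    concordant count is symmetric under transpose; nUD and nDU swap.
    """
    protein = protein.upper()
    sub = calls[(calls["gene_symbol"] == protein) & calls["direction"].isin(["U", "D"])]
    sites = sorted(
        {SiteKey(protein, r, int(p)) for r, p in zip(sub["residue"], sub["position"])},
        key=lambda s: (s.position, s.residue),
    )
    rows = []
    for s1, s2 in itertools.permutations(sites, 2):
        counts = pair_pattern_counts(s1, s2, calls, registry)
        pos = cooccurrence_ratio(counts, "positive", pseudocount).ratio
        neg = cooccurrence_ratio(counts, "negative", pseudocount).ratio
        rows.append(
            {
                "site_i": str(s1),
                "site_j": str(s2),
                "nUU": counts.nUU,
                "nUD": counts.nUD,
                "nDU": counts.nDU,
                "nDD": counts.nDD,
                "concordant": counts.concordant,
                "discordant": counts.discordant,
                "positive_ratio": pos,
                "negative_ratio": neg,
            }
        )
    return pd.DataFrame(rows, columns=MATRIX_COLUMNS)
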