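"""Anchor-site vs PsOP co-regulation statistics and the high-confidence filter.

For an *anchor* phosphosite (e.g. a predominant Tau site) and each candidate
phosphosite on another protein (PsOP), the differential datasets of a
declared *universe* are cross-classified into a 2x2 contingency table:

    a  — neither site regulated
    b  — exactly one site regulated
    c  — both regulated, discordantly (U/D or D/U)   -> negative co-regulation
    d  — both regulated, concordantly (U/U or D/D)   -> positive co-regulation

with rows (a, b) / (c, d) and columns (a, c) / (b, d); n = a+b+c+d equals
the universe size.  A one-sided Fisher's exact test asks whether d (positive
tail) or c (negative tail) is larger than chance given the margins: the
p-value is the hypergeometric tail sum over all tables with the same margins
and d' >= d (resp. c' >= c), computed exactly via log-gamma arithmetic — no
normal approximation.

A pair is *classified* positive/negative when the corresponding tail p-value
is below alpha and the matching co-occurrence ratio exceeds 1; it is
*high-confidence* when additionally the winning-polarity support reaches at
least ``min_support_fraction`` of the anchor's regulated datasets and is
spread over at least ``min_conditions`` distinct experimental conditions and
``min_studies`` distinct studies — guards against a handful of studies or
one large multi-timepoint experiment dominating the evidence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cooccurrence import INFINITE, UNDEFINED, PairPatternCounts
from .io_registry import Registry, SiteKey, UsageError, ValidationError
from .regulation import ThresholdConfig

SCAN_COLUMNS = [
    "anchor",
    "psop_gene",
    "psop_site",
    "nUU",
    "nUD",
    "nDU",
    "nDD",
    "a",
    "b",
    "c",
    "d",
    "pos_ratio",
    "neg_ratio",
    "fet_p_pos",
    "fet_p_neg",
    "support_fraction",
    "n_conditions",
    "n_studies",
    "classification",
    "high_confidence",
    "flags",
]


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class CoRegulationStat:
    anchor: SiteKey
    psop: SiteKey
    counts: PairPatternCounts
    table: ContingencyTable
    positive_ratio: float
    negative_ratio: float
    fet_p_positive: float
    fet_p_negative: float
    support_fraction: float
    n_conditions: int
    n_studies: int
    classification: str  # "positive" | "negative" | "none"
    high_confidence: bool = False
    flags: tuple[str, ...] = field(default=())


# ---------------------------------------------------------------------------
# Fisher's exact test (one-sided), exact log-gamma arithmetic


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _hypergeom_tail(n: int, K: int, draws: int, k_min: int) -> float:
    """P(X >= k_min) for X ~ Hypergeometric(population n, successes K, draws)."""
    lo = max(0, draws - (n - K))
    hi = min(K, draws)
    if k_min <= lo:
        return 1.0
    if k_min > hi:
        return 0.0
    log_denom = _log_comb(n, draws)
    logs = [
        _log_comb(K, k) + _log_comb(n - K, draws - k) - log_denom
        for k in range(k_min, hi + 1)
    ]
    peak = max(logs)
    total = peak + math.log(sum(math.exp(v - peak) for v in logs))
    return min(1.0, math.exp(total))


def fisher_exact_one_sided(t: ContingencyTable, tail: str) -> float:
    """One-sided FET p-value on the a/b/c/d table.

    tail="concordant" sums hypergeometric probabilities over tables at the
    observed margins (rows (a, b)/(c, d), columns (a, c)/(b, d)) with
    d' >= d.  tail="discordant" is the same test after relabelling U<->D on
    the second site — which exchanges c and d while leaving a and b alone —
    so it sums over c' >= c with c in the (b, c) column.  This relabelling
    symmetry is what makes the two tails exact duals of one another; fixing
    one set of margins for both tails would make discordance undetectable
    whenever a dominates the table.  Returns p in (0, 1].
    """
    if tail not in ("concordant", "discordant"):
        raise UsageError(f"tail must be concordant/discordant, got {tail!r}")
    n = t.n
    if n == 0:
        return 1.0
    r2 = t.c + t.d  # row (c, d): datasets where both sites regulated
    if tail == "concordant":
        # d lives at the crossing of row 2 and column (b, d)
        return max(_hypergeom_tail(n, r2, t.b + t.d, t.d), math.ulp(0.0))
    return max(_hypergeom_tail(n, r2, t.b + t.c, t.c), math.ulp(0.0))


# ---------------------------------------------------------------------------
# contingency construction


def build_contingency(
    anchor: SiteKey,
    psop: SiteKey,
    calls: pd.DataFrame,
    universe: set[str] | list[str],
    cell_mode: str = "regulated",
) -> ContingencyTable:
    """Cross-classify every dataset of the universe into exactly one cell.

    cell_mode="regulated" (default): a = neither site regulated, b = exactly
    one regulated.  cell_mode="detected": a = neither site carries a call at
    all (not measured Class-1), b = every other dataset that is not c or d —
    a sensitivity variant for the ambiguity between "detected" and
    "regulated" in the cell definitions.
    """
    if anchor == psop:
        raise UsageError("anchor and psop must differ")
    if cell_mode not in ("regulated", "detected"):
        raise UsageError(f"cell_mode must be regulated/detected, got {cell_mode!r}")
    universe = set(universe)
    if not universe:
        raise UsageError("universe must be non-empty")

    def dirs(site: SiteKey) -> dict[str, str]:
        mask = (
            (calls["gene_symbol"] == site.gene_symbol)
            & (calls["residue"] == site.residue)
            & (calls["position"] == site.position)
            & calls["dataset_id"].isin(universe)
        )
        sub = calls[mask]
        return dict(zip(sub["dataset_id"], sub["direction"]))

    da, dp = dirs(anchor), dirs(psop)
    a = b = c = d = 0
    for ds in universe:
        xa, xp = da.get(ds), dp.get(ds)
        ra, rp = xa in ("U", "D"), xp in ("U", "D")
        if ra and rp:
            if xa == xp:
                d += 1
            else:
                c += 1
        elif cell_mode == "regulated":
            if ra or rp:
                b += 1
            else:
                a += 1
        else:  # detected
            if xa is None and xp is None:
                a += 1
            else:
                b += 1
    return ContingencyTable(a=a, b=b, c=c, d=d)


# ---------------------------------------------------------------------------
# corpus-wide scan


def _code_matrix(calls: pd.DataFrame, universe: list[str]) -> pd.DataFrame:
    """datasets x sites matrix of direction codes: U=1, D=-1, NR=0, absent=NaN."""
    sub = calls[calls["dataset_id"].isin(universe)].copy()
    sub["code"] = sub["direction"].map({"U": 1.0, "D": -1.0, "NR": 0.0})
    mat = sub.pivot_table(
        index="dataset_id",
        columns=["gene_symbol", "residue", "position"],
        values="code",
        aggfunc="first",
    )
    return mat.reindex(index=universe)


def coregulation_scan(
    anchor: SiteKey,
    calls: pd.DataFrame,
    registry: Registry,
    t: ThresholdConfig | None = None,
    universe: str = "anchor-measured",
    cell_mode: str = "regulated",
    support_denominator: str = "detected",
    include_same_protein: bool = True,
    fdr: bool = False,
) -> pd.DataFrame:
    """One CoRegulationStat row per candidate site co-measured with the anchor.

    The dataset universe is every differential dataset in which the anchor
    was measured (default) or the full differential corpus
    (universe="all").  Candidates are all sites with at least one U/D call
    inside the universe (other proteins, plus the anchor protein's other
    sites unless ``include_same_protein`` is False).

    The 10% support gate is evaluated against the anchor's *total
    detections*: by default the number of universe datasets in which the
    anchor carries a Class-1 call at all (``support_denominator =
    "detected"``); ``"regulated"`` restricts the denominator to datasets
    where the anchor was actually called U or D, a far laxer gate.
    ``fdr=True`` adds a Benjamini-Hochberg adjusted winning p-value column —
    a deviation from the raw p < alpha rule, off by default.
    """
    t = t or ThresholdConfig()
    if universe not in ("anchor-measured", "all"):
        raise UsageError(f"universe must be 'anchor-measured' or 'all', got {universe!r}")
    diff_ids = registry.differential_ids()
    if universe == "anchor-measured":
        m = registry.measurements
        mask = (
            (m["gene_symbol"] == anchor.gene_symbol)
            & (m["residue"] == anchor.residue)
            & (m["position"] == anchor.position)
        )
        ids = sorted(set(m[mask]["dataset_id"]) & set(diff_ids))
    else:
        ids = diff_ids
    if not ids:
        return pd.DataFrame(columns=SCAN_COLUMNS)

    mat = _code_matrix(calls, ids)
    anchor_key = (anchor.gene_symbol, anchor.residue, anchor.position)
    if anchor_key not in mat.columns:
        return pd.DataFrame(columns=SCAN_COLUMNS)
    if support_denominator not in ("detected", "regulated"):
        raise UsageError(
            f"support_denominator must be 'detected' or 'regulated', got {support_denominator!r}"
        )
    avec = mat[anchor_key].to_numpy()
    up_a, dn_a = avec == 1.0, avec == -1.0
    anchor_regulated = int(up_a.sum() + dn_a.sum())
    anchor_detected = int((~np.isnan(avec)).sum())
    if anchor_regulated == 0:
        return pd.DataFrame(columns=SCAN_COLUMNS)
    anchor_total = anchor_detected if support_denominator == "detected" else anchor_regulated

    cols = [
        k
        for k in mat.columns
        if k != anchor_key
        and (include_same_protein or k[0] != anchor.gene_symbol)
    ]
    if not cols:
        return pd.DataFrame(columns=SCAN_COLUMNS)
    M = mat[cols].to_numpy()
    Mu, Md = M == 1.0, M == -1.0
    nUU = (Mu & up_a[:, None]).sum(axis=0)
    nUD = (Md & up_a[:, None]).sum(axis=0)
    nDU = (Mu & dn_a[:, None]).sum(axis=0)
    nDD = (Md & dn_a[:, None]).sum(axis=0)
    conc, disc = nUU + nDD, nUD + nDU
    reg_a = (up_a | dn_a)[:, None]
    reg_m = Mu | Md
    n = len(ids)
    if cell_mode == "regulated":
        b_cell = (reg_a ^ reg_m).sum(axis=0)
        a_cell = n - b_cell - conc - disc
    elif cell_mode == "detected":
        detected = ~np.isnan(M)
        # anchor is measured everywhere in its own universe; a = neither
        # detected can only be nonzero under universe="all"
        anchor_det = ~np.isnan(avec)[:, None]
        a_cell = (~anchor_det & ~detected).sum(axis=0)
        b_cell = n - a_cell - conc - disc
    else:
        raise UsageError(f"cell_mode must be regulated/detected, got {cell_mode!r}")

    # per-candidate FET p-values and support metadata
    meta = registry.datasets
    conditions = np.array([meta[d].condition_id for d in ids])
    studies = np.array([meta[d].study_id for d in ids])
    rows = []
    for j, key in enumerate(cols):
        if not reg_m[:, j].any():
            continue  # never regulated inside the universe: not a candidate
        table = ContingencyTable(
            a=int(a_cell[j]), b=int(b_cell[j]), c=int(disc[j]), d=int(conc[j])
        )
        p_pos = fisher_exact_one_sided(table, "concordant")
        p_neg = fisher_exact_one_sided(table, "discordant")
        pos_ratio = _ratio(conc[j], disc[j])
        neg_ratio = _ratio(disc[j], conc[j])

        classification, flags = "none", []
        pos_ok = p_pos < t.alpha and _gt1(pos_ratio)
        neg_ok = p_neg < t.alpha and _gt1(neg_ratio)
        if pos_ok and neg_ok:
            classification = "positive" if p_pos <= p_neg else "negative"
            flags.append("both-significant")
        elif pos_ok:
            classification = "positive"
        elif neg_ok:
            classification = "negative"

        if classification == "positive":
            win = (Mu[:, j] & up_a) | (Md[:, j] & dn_a)
        elif classification == "negative":
            win = (Md[:, j] & up_a) | (Mu[:, j] & dn_a)
        else:
            win = np.zeros(n, dtype=bool)
        support = int(win.sum())
        n_cond = len(set(conditions[win]))
        n_stud = len(set(studies[win]))

        rows.append(
            {
                "anchor": str(anchor),
                "psop_gene": key[0],
                "psop_site": f"{key[1]}{key[2]}",
                "nUU": int(nUU[j]),
                "nUD": int(nUD[j]),
                "nDU": int(nDU[j]),
                "nDD": int(nDD[j]),
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "pos_ratio": pos_ratio,
                "neg_ratio": neg_ratio,
                "fet_p_pos": p_pos,
                "fet_p_neg": p_neg,
                "support_fraction": support / anchor_total,
                "n_conditions": n_cond,
                "n_studies": n_stud,
                "classification": classification,
                "high_confidence": False,
                "flags": ";".join(flags) if flags else "",
            }
        )
    stats = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    stats = apply_high_confidence_filter(stats, anchor_total, t)
    if fdr and len(stats):
        winning_p = np.where(
            stats["classification"] == "negative", stats["fet_p_neg"], stats["fet_p_pos"]
        )
        stats["fet_p_winning_bh"] = benjamini_hochberg(winning_p)
    stats.attrs["anchor_total_detections"] = anchor_total
    stats.attrs["anchor_regulated"] = anchor_regulated
    stats.attrs["universe_size"] = n
    return stats


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return UNDEFINED if num == 0 else INFINITE
    return float(num) / float(den)


def _gt1(ratio: float) -> bool:
    return not math.isnan(ratio) and ratio > 1.0


def apply_high_confidence_filter(
    stats: pd.DataFrame,
    anchor_total_detections: int,
    t: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Set the high_confidence flag on a scan table.

    A classified pair passes iff its winning-polarity p < alpha, its support
    fraction (winning-polarity datasets / anchor regulated datasets) is at
    least min_support_fraction, and the winning evidence spans at least
    min_conditions distinct conditions and min_studies distinct studies.
    Thresholds are boundary-inclusive ("at least").
    """
    t = t or ThresholdConfig()
    if anchor_total_detections <= 0:
        raise ValidationError("anchor_total_detections must be positive")
    stats = stats.copy()
    if not len(stats):
        stats["high_confidence"] = pd.Series(dtype=bool)
        return stats
    win_p = np.where(
        stats["classification"] == "negative", stats["fet_p_neg"], stats["fet_p_pos"]
    )
    win_ratio = np.where(
        stats["classification"] == "negative", stats["neg_ratio"], stats["pos_ratio"]
    )
    classified = stats["classification"].isin(["positive", "negative"]).to_numpy()
    ratio_ok = np.array([_gt1(r) for r in win_ratio])
    stats["high_confidence"] = (
        classified
        & (win_p < t.alpha)
        & ratio_ok
        & (stats["support_fraction"].to_numpy() >= t.min_support_fraction)
        & (stats["n_conditions"].to_numpy() >= t.min_conditions)
        & (stats["n_studies"].to_numpy() >= t.min_studies)
    )
    return stats


def high_confidence_stat(
    s: CoRegulationStat, anchor_total_detections: int, t: ThresholdConfig | None = None
) -> CoRegulationStat:
    """Record-level variant of :func:`apply_high_confidence_filter`."""
    t = t or ThresholdConfig()
    if anchor_total_detections <= 0:
        raise ValidationError("anchor_total_detections must be positive")
    if s.classification == "none":
        return CoRegulationStat(**{**s.__dict__, "high_confidence": False})
    win_p = s.fet_p_negative if s.classification == "negative" else s.fet_p_positive
    win_ratio = s.negative_ratio if s.classification == "negative" else s.positive_ratio
    ok = (
        win_p < t.alpha
        and _gt1(win_ratio)
        and s.support_fraction >= t.min_support_fraction
        and s.n_conditions >= t.min_conditions
        and s.n_studies >= t.min_studies
    )
    return CoRegulationStat(**{**s.__dict__, "high_confidence": ok})


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# shared PsOPs across anchors


def shared_psops(
    per_anchor: dict[str, set],
    polarity: str | None = None,
) -> tuple[pd.DataFrame, dict[str, set]]:
    """Pairwise overlap of high-confidence PsOP sets across anchors.

    Returns (pairwise table, per-anchor exclusive sets).  ``polarity`` is a
    label carried into the output only; callers pass the positive or
    negative PsOP sets they want compared.
    """
    if len(per_anchor) < 2:
        raise UsageError("shared_psops needs at least two anchors")
    anchors = sorted(per_anchor)
    rows = []
    for a1, a2 in itertools.combinations(anchors, 2):
        inter = per_anchor[a1] & per_anchor[a2]
        rows.append(
            {
                "anchor_a": a1,
                "anchor_b": a2,
                "polarity": polarity or "",
                "n_shared": len(inter),
                "shared": "|".join(sorted(str(s) for s in inter)),
            }
        )
    exclusives = {
        a: per_anchor[a] - set().union(*(per_anchor[b] for b in anchors if b != a))
        for a in anchors
    }
    return pd.DataFrame(rows), exclusives
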