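"""Hotspot overlap classification, typology tables and chi-square tests.

A venue is classified by which partnership types occur there: it is
"transactional-visited" if its reported peak-day maximum count of women
aged 14-24 engaging in transactional sex is at least 1 (likewise for
casual sex).  The four resulting categories — both, transactional only,
casual only, and exclusive sex work — partition the validated register.

Typology-by-subcounty distribution and the known-vs-new program
coverage split are compared with Pearson's chi-square test (no
continuity correction).  Because sparse typologies can produce expected
cell counts below 5, the test result carries a warning flag and an
optional fixed-margin Monte-Carlo p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import round_half_up
from .model import (
    Day,
    Geography,
    Group,
    Hotspot,
    HotspotStatus,
    LevelTwoRecord,
    RecordValidationError,
    Typology,
)

LOW_EXPECTED_THRESHOLD = 5.0


@dataclass(frozen=True)
class OverlapSummary:
    """Partition of validated hotspots by co-occurring partnership types."""

    n_total: int
    n_both: int
    n_transactional_only: int
    n_casual_only: int
    n_exclusive_sex_work: int
    percentages: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        parts = (self.n_both + self.n_transactional_only
                 + self.n_casual_only + self.n_exclusive_sex_work)
        if parts != self.n_total:
            raise RecordValidationError(
                f"overlap categories sum to {parts}, expected n_total={self.n_total}"
            )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float
    min_expected_count: float
    low_expected_warning: bool
    monte_carlo_p: Optional[float] = None


class ContingencyTable:
    """An r x c count table with labelled margins.

    Thin wrapper around a pandas DataFrame that validates nonnegative
    integer cells and exposes margins and within-column percentages.
    """

    def __init__(self, table: pd.DataFrame):
        values = table.to_numpy()
        if values.size == 0:
            raise RecordValidationError("contingency table must be non-empty")
        if (values < 0).any():
            raise RecordValidationError("contingency table cells must be nonnegative")
        self.table = table.astype(int)

    @property
    def row_labels(self) -> List[str]:
        return [str(x) for x in self.table.index]

    @property
    def column_labels(self) -> List[str]:
        return [str(x) for x in self.table.columns]

    @property
    def row_margins(self) -> pd.Series:
        return self.table.sum(axis=1)

    @property
    def column_margins(self) -> pd.Series:
        return self.table.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.table.to_numpy().sum())

    def column_percentages(self, decimals: int = 1) -> pd.DataFrame:
        margins = self.column_margins
        pct = self.table.divide(margins.where(margins > 0, other=np.nan), axis=1) * 100.0
        return pct.map(lambda x: np.nan if pd.isna(x) else round_half_up(float(x), decimals))


def _validated(register: Sequence[Hotspot]) -> List[Hotspot]:
    return [h for h in register if h.status == HotspotStatus.VALIDATED_ACTIVE]


def classify_overlap(level_two_records: Sequence[LevelTwoRecord]) -> OverlapSummary:
    """Partition validated venues by transactional/casual co-occurrence.

    Expects one record per validated hotspot (inactive records are
    skipped).  Presence means a peak-day maximum count of at least 1.
    """
    n_both = n_t = n_c = n_excl = 0
    n_total = 0
    for rec in level_two_records:
        if not rec.active:
            continue
        n_total += 1
        has_t = rec.count(Group.TRANSACTIONAL_14_24, Day.PEAK).max_count >= 1
        has_c = rec.count(Group.CASUAL_14_24, Day.PEAK).max_count >= 1
        if has_t and has_c:
            n_both += 1
        elif has_t:
            n_t += 1
        elif has_c:
            n_c += 1
        else:
            n_excl += 1
    pct = {}
    if n_total:
        pct = {
            "both": round_half_up(100.0 * n_both / n_total, 2),
            "transactional_only": round_half_up(100.0 * n_t / n_total, 2),
            "casual_only": round_half_up(100.0 * n_c / n_total, 2),
            "exclusive_sex_work": round_half_up(100.0 * n_excl / n_total, 2),
        }
    return OverlapSummary(
        n_total=n_total, n_both=n_both, n_transactional_only=n_t,
        n_casual_only=n_c, n_exclusive_sex_work=n_excl, percentages=pct,
    )


def typology_table(
    register: Sequence[Hotspot],
    geography: Geography,
    by: str = "subcounty",
) -> ContingencyTable:
    """Typology x geography counts over validated-active hotspots."""
    if by != "subcounty":
        raise RecordValidationError(f"unsupported grouping {by!r}; only 'subcounty'")
    hotspots = _validated(register)
    for h in hotspots:
        if h.typology is None:
            raise RecordValidationError(
                f"hotspot {h.id!r} has no typology; assign typologies before tabulating"
            )
    rows = [t.value for t in Typology]
    cols = [u.id for u in geography.units()
            if u.level.value == "subcounty"]
    table = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for h in hotspots:
        sc = geography.subcounty_of(h.zone_id)
        table.loc[h.typology.value, sc.id] += 1
    return ContingencyTable(table)


def pearson_chi_square(
    table: ContingencyTable,
    monte_carlo: bool = False,
    n_simulations: int = 2000,
    seed: Optional[int] = None,
) -> ChiSquareResult:
    """Pearson chi-square test of independence on a contingency table.

    Expected counts come from the margins; no continuity correction.  A
    warning flag is set when any expected count falls below 5, in which
    case a fixed-margin Monte-Carlo p-value (``monte_carlo=True``) is
    the more defensible significance measure.
    """
    counts = table.table.to_numpy()
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise RecordValidationError("chi-square requires at least a 2x2 table")
    if (table.row_margins == 0).any() or (table.column_margins == 0).any():
        raise RecordValidationError(
            "chi-square undefined with a zero row/column margin (expected count zero)"
        )
    res = stats.chi2_contingency(counts, correction=False)
    min_expected = float(res.expected_freq.min())
    mc_p: Optional[float] = None
    if monte_carlo:
        rng = np.random.default_rng(seed)
        sampler = stats.random_table(table.row_margins.to_numpy(),
                                     table.column_margins.to_numpy())
        sims = sampler.rvs(n_simulations, random_state=rng)
        expected = res.expected_freq
        sim_stats = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
        # add-one estimator, as in R's chisq.test(simulate.p.value=TRUE)
        mc_p = float((1 + (sim_stats >= res.statistic - 1e-9).sum()) / (n_simulations + 1))
    return ChiSquareResult(
        statistic=float(res.statistic),
        degrees_of_freedom=int(res.dof),
        p_value=float(res.pvalue),
        min_expected_count=min_expected,
        low_expected_warning=min_expected < LOW_EXPECTED_THRESHOLD,
        monte_carlo_p=mc_p,
    )


def chi_square_on_nonempty(
    table: ContingencyTable,
    monte_carlo: bool = False,
    n_simulations: int = 2000,
    seed: Optional[int] = None,
) -> Optional[ChiSquareResult]:
    """Chi-square after dropping all-zero rows/columns (they carry no
    information and make expected counts undefined); None if fewer than
    two informative rows or columns remain."""
    df = table.table
    trimmed = df.loc[df.sum(axis=1) > 0, df.columns[df.sum(axis=0) > 0]]
    if trimmed.shape[0] < 2 or trimmed.shape[1] < 2:
        return None
    return pearson_chi_square(ContingencyTable(trimmed), monte_carlo, n_simulations, seed)


@dataclass(frozen=True)
class KnownNewSplit:
    """Program coverage of the validated register: known vs newly identified."""

    n_total: int
    n_known: int
    n_new: int
    pct_known: float
    pct_new: float
    by_typology: pd.DataFrame  # columns: n_total, n_known, n_new, pct_new
    chi_square: Optional[ChiSquareResult]


def known_new_split(register: Sequence[Hotspot]) -> KnownNewSplit:
    """Split validated hotspots by prior program knowledge, overall and
    per typology, with the known-vs-new x typology chi-square."""
    hotspots = _validated(register)
    n_total = len(hotspots)
    n_known = sum(1 for h in hotspots if h.known_to_program)
    n_new = n_total - n_known
    rows = []
    for t in Typology:
        tot = sum(1 for h in hotspots if h.typology == t)
        known = sum(1 for h in hotspots if h.typology == t and h.known_to_program)
        rows.append({
            "typology": t.value, "n_total": tot, "n_known": known, "n_new": tot - known,
            "pct_new": round_half_up(100.0 * (tot - known) / tot, 1) if tot else float("nan"),
        })
    by_typology = pd.DataFrame(rows).set_index("typology")
    chi: Optional[ChiSquareResult] = None
    nonzero = by_typology[by_typology["n_total"] > 0]
    if len(nonzero) >= 2 and 0 < n_known < n_total:
        table = ContingencyTable(
            pd.DataFrame(
                {"known": nonzero["n_known"], "new": nonzero["n_new"]}
            ).T
        )
        chi = pearson_chi_square(table)
    return KnownNewSplit(
        n_total=n_total,
        n_known=n_known,
        n_new=n_new,
        pct_known=round_half_up(100.0 * n_known / n_total, 2) if n_total else float("nan"),
        pct_new=round_half_up(100.0 * n_new / n_total, 2) if n_total else float("nan"),
        by_typology=by_typology,
        chi_square=chi,
    )
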