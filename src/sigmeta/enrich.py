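"""Over-representation analysis of a gene set against GMT collections.

For each gene set, overlap with the query is tested on a 2x2 table over
a background universe with a one-sided Fisher exact test (hypergeometric
upper tail), followed by Benjamini-Hochberg adjustment across all tested
sets.  A set passes when all three reporting criteria hold:

    q <= 0.005,  set size <= 1000,  overlap percentage >= 2%.

Set sizes and overlaps are counted within the background, and the
overlap percentage denominator is the (background-restricted) set size.
The default background is the union of all collection members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

Q_CUT = 0.005
SET_SIZE_MAX = 1000
OVERLAP_MIN_PERCENT = 2.0


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id} has no members")


@dataclass(frozen=True)
class EnrichmentRow:
    set_id: str
    name: str
    overlap_count: int
    set_size: int
    overlap_percent: float
    p: float
    q: float
    passed: bool


def load_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: set id, description, then member symbols, tab-delimited.

    Duplicate members within a line are collapsed; symbols are upper-cased.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-delimited fields, "
                    f"got {len(fields)}"
                )
            members = frozenset(f.strip().upper() for f in fields[2:] if f.strip())
            sets.append(GeneSet(set_id=fields[0], name=fields[1], members=members))
    return sets


def bh_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
    if len(pvals) == 0:
        return []
    return list(multipletests(pvals, method="fdr_bh")[1])


def passes_criteria(
    q: float,
    set_size: int,
    overlap_percent: float,
    q_cut: float = Q_CUT,
    set_size_max: int = SET_SIZE_MAX,
    overlap_min_percent: float = OVERLAP_MIN_PERCENT,
) -> bool:
    """The three reporting criteria, as a pure function of (q, size, overlap%)."""
    return q <= q_cut and set_size <= set_size_max and overlap_percent >= overlap_min_percent


def enrich(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    background: Iterable[str] | None = None,
    q_cut: float = Q_CUT,
    set_size_max: int = SET_SIZE_MAX,
    overlap_min_percent: float = OVERLAP_MIN_PERCENT,
) -> list[EnrichmentRow]:
    """One-sided over-representation of ``query`` in each gene set.

    The 2x2 table is formed over ``background`` (default: the union of
    all set members); the query must lie within the background.  Sets
    with no member in the background are skipped with a warning.  Rows
    come back sorted by p ascending (ties by set id).
    """
    query_set = {g.upper() for g in query}
    if not query_set:
        raise ValueError("query gene set is empty")
    if background is None:
        bg: set[str] = set()
        for s in sets:
            bg |= s.members
    else:
        bg = {g.upper() for g in background}
    stray = query_set - bg
    if stray:
        raise ValueError(
            f"query genes absent from background: {sorted(stray)[:5]}"
            + ("..." if len(stray) > 5 else "")
        )
    n_bg = len(bg)
    n_query = len(query_set)

    tested: list[tuple[GeneSet, int, int, float]] = []
    for s in sets:
        members = s.members & bg
        if not members:
            log.warning("gene set %s has no member in background; skipped", s.set_id)
            continue
        overlap = len(query_set & members)
        # hypergeometric upper tail: P(X >= overlap)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(members), n_query))
        tested.append((s, overlap, len(members), min(p, 1.0)))
    if not tested:
        return []
    qvals = bh_fdr([t[3] for t in tested])
    rows = [
        EnrichmentRow(
            set_id=s.set_id,
            name=s.name,
            overlap_count=overlap,
            set_size=size,
            overlap_percent=100.0 * overlap / size,
            p=p,
            q=q,
            passed=passes_criteria(
                q, size, 100.0 * overlap / size, q_cut, set_size_max, overlap_min_percent
            ),
        )
        for (s, overlap, size, p), q in zip(tested, qvals)
    ]
    rows.sort(key=lambda r: (r.p, r.set_id))
    return rows


def enrichment_table(rows: Sequence[EnrichmentRow]):
    """Rows as a pandas DataFrame (column order mirrors EnrichmentRow)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "name": r.name,
                "overlap_count": r.overlap_count,
                "set_size": r.set_size,
                "overlap_percent": r.overlap_percent,
                "p": r.p,
                "q": r.q,
                "passed": r.passed,
            }
            for r in rows
        ]
    )
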