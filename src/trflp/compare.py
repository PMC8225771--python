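"""Matching experimental oTRFs against in silico profiles with taxonomic
rollup.

For every experimental oTRF label the in silico profile is searched two
ways: *exact* hits are IS TRF fragments whose size equals the label;
*window* hits are members of IS oTRF bins whose label lies within ±w bp.
Exact hits take precedence as the active set for taxonomy (when a
fragment of exactly that size exists in the reference digest it is the
best explanation of the peak); the windowed set is the fallback, and both
are always reported.  Taxon counts are numbers of distinct named phyla
and genera over the active set — the tool reports candidate sets, never a
single taxon call, because distinct taxa routinely share a fragment size.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .binning import OTRF, OTRFTable, Provenance, TRFMultiset
from .taxonomy import Lineage, parse_lineage  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)


@dataclass
class MatchResult:
    """Match of one experimental oTRF label against the in silico profile."""

    ex_label: int
    exact_is_trf_hits: list[Provenance]
    otrf_window_hits: list[Provenance]
    n_is_trf_fragments: int  # IS fragments at exactly the Ex label
    n_is_trf_sizes: int      # distinct IS TRF sizes within +- w
    n_is_otrf: int           # IS fragments in oTRF bins within +- w
    n_phyla: int
    n_genera: int
    active: str  # "exact" | "window" | "none"

    @property
    def active_hits(self) -> list[Provenance]:
        if self.active == "exact":
            return self.exact_is_trf_hits
        if self.active == "window":
            return self.otrf_window_hits
        return []


@dataclass
class ComparisonTable:
    """One row per experimental oTRF label, sorted by label."""

    rows: list[MatchResult]
    window: int = 2
    enzyme: Optional[str] = None

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "ex_otrf_bp": r.ex_label,
                    "n_is_trf": r.n_is_trf_fragments,
                    "n_is_otrf": r.n_is_otrf,
                    "n_phyla": r.n_phyla,
                    "n_genera": r.n_genera,
                    "top_taxa": _top_taxa_string(r),
                }
            )
        return pd.DataFrame(
            recs,
            columns=["ex_otrf_bp", "n_is_trf", "n_is_otrf",
                     "n_phyla", "n_genera", "top_taxa"],
        )


def rollup_taxa_counts(
    hits: Sequence[Provenance],
) -> tuple[int, int, dict[str, list[tuple[str, int]]]]:
    """Distinct-taxon counts over a hit set.

    Returns (n_phyla, n_genera, per-rank tallies).  NA ranks are excluded
    from the distinct counts; tallies are sorted by descending count then
    name, so the sum of a rank's tally equals the number of hits with a
    named value at that rank.
    """
    tallies: dict[str, list[tuple[str, int]]] = {}
    for rank in ("phylum", "genus"):
        counter = Counter(
            lin.get(rank) for _, lin in hits if lin.get(rank) is not None
        )
        tallies[rank] = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return len(tallies["phylum"]), len(tallies["genus"]), tallies


def _top_taxa_string(r: MatchResult, k: int = 3) -> str:
    if r.active == "none":
        return "no prediction"
    _, _, tallies = rollup_taxa_counts(r.active_hits)
    genera = tallies["genus"][:k]
    if not genera:
        return "NA"
    return ";".join(f"{name}({count})" for name, count in genera)


def match_ex_to_is(
    ex_table: Union[OTRFTable, Iterable[int]],
    is_trfs: TRFMultiset,
    is_otrfs: Sequence[OTRF],
    w: int = 2,
    *,
    ex_enzyme: Optional[str] = None,
    is_enzyme: Optional[str] = None,
) -> ComparisonTable:
    """Build the Ex-vs-IS comparison table.

    ``ex_table`` may be a binned experimental table or a bare iterable of
    Ex oTRF labels.  ``is_trfs`` must be the range-filtered IS multiset
    and ``is_otrfs`` the bins clustered from it, both from the same
    enzyme; an explicit enzyme mismatch is an error.
    """
    if isinstance(ex_table, OTRFTable):
        ex_enzyme = ex_enzyme or ex_table.enzyme
        labels = ex_table.labels
    else:
        labels = sorted(int(x) for x in ex_table)
    if ex_enzyme and is_enzyme and ex_enzyme != is_enzyme:
        raise ValueError(
            f"enzyme mismatch: experimental profile is {ex_enzyme}, "
            f"in silico profile is {is_enzyme}"
        )

    rows: list[MatchResult] = []
    for label in labels:
        exact = list(is_trfs.provenance.get(label, ()))
        n_exact = int(is_trfs.entries.get(label, 0))
        window_hits: list[Provenance] = []
        n_window = 0
        for bin_ in is_otrfs:
            if abs(bin_.label - label) <= w:
                window_hits.extend(bin_.provenance)
                n_window += int(bin_.weight)
        n_sizes = sum(1 for s in is_trfs.entries if abs(s - label) <= w)
        if exact or n_exact:
            active = "exact"
            active_hits = exact
        elif window_hits or n_window:
            active = "window"
            active_hits = window_hits
        else:
            active = "none"
            active_hits = []
        n_phyla, n_genera, _ = rollup_taxa_counts(active_hits)
        rows.append(
            MatchResult(
                ex_label=label,
                exact_is_trf_hits=exact,
                otrf_window_hits=window_hits,
                n_is_trf_fragments=n_exact,
                n_is_trf_sizes=n_sizes,
                n_is_otrf=n_window,
                n_phyla=n_phyla,
                n_genera=n_genera,
                active=active,
            )
        )
    rows.sort(key=lambda r: r.ex_label)
    return ComparisonTable(rows=rows, window=w, enzyme=ex_enzyme or is_enzyme)


def export_comparison(table: ComparisonTable, path: str | Path) -> None:
    """Write the comparison as TSV with fixed column order."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def export_comparison_long(table: ComparisonTable, path: str | Path) -> None:
    """Long-format export: one row per (Ex label, hit set, hit)."""
    rows = []
    for r in table.rows:
        for kind, hits in (("exact", r.exact_is_trf_hits),
                           ("window", r.otrf_window_hits)):
            for rid, lin in hits:
                rows.append(
                    {
                        "ex_otrf_bp": r.ex_label,
                        "hit_set": kind,
                        "record_id": rid,
                        "lineage": lin.to_string(),
                    }
                )
    pd.DataFrame(
        rows, columns=["ex_otrf_bp", "hit_set", "record_id", "lineage"]
    ).to_csv(path, sep="\t", index=False)
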