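"""Reference-amplicon digestion: tagged in silico amplicons, degeneracy-aware
restriction-site scanning, and labelled terminal fragments.

In T-RFLP only the fragment that retains the 5'-fluorophore of the forward
primer is detected, so for every reference sequence the observable is a
single terminal fragment: the distance from the 5' end of the tagged
amplicon to the first restriction cut (or the full amplicon length when no
site exists — an *unrestricted* fragment).

Degenerate bases make "is there a site here?" ambiguous.  Two semantics are
provided:

``guaranteed``
    every disambiguation of the window contains the site (the window's
    base set is a subset of the pattern's at every position);
``possible``
    at least one disambiguation does (non-empty intersection everywhere).

``guaranteed`` is the default: the primer tags contribute many N positions
and possible-semantics would manufacture cut sites inside them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .iupac import (
    IUPAC_SETS,
    SequenceError,
    clean_sequence,
    reverse_complement,
)
from .taxonomy import NA_LINEAGE, Lineage, parse_lineage

logger = logging.getLogger(__name__)

SEMANTICS = ("guaranteed", "possible")


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme: IUPAC recognition pattern plus top-strand cut offset.

    ``cut_offset`` is measured in bases from the 5' end of the recognition
    site on the top strand (AluI AG^CT -> pattern ``AGCT``, offset 2).
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", clean_sequence(self.site, name=self.name))
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError(
                f"{self.name}: cut_offset {self.cut_offset} outside "
                f"[0, {len(self.site)}]"
            )

    @property
    def is_palindromic(self) -> bool:
        """True when the pattern equals its own reverse complement
        (set-wise; IUPAC codes are canonical so string equality suffices)."""
        return self.site == reverse_complement(self.site)


@dataclass(frozen=True)
class Primer:
    """PCR primer; ``label`` names the 5' fluorophore, if any (e.g. FAM)."""

    name: str
    seq: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", clean_sequence(self.seq, name=self.name))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReferenceRecord:
    """One taxonomically annotated reference amplicon."""

    id: str
    lineage: Lineage
    seq: str


@dataclass(frozen=True)
class TaggedAmplicon:
    """fwd + insert + rc(rev): the molecule actually digested in silico."""

    record_id: str
    seq: str
    insert_len: int


@dataclass(frozen=True)
class TerminalFragment:
    """Labelled (5'-dye-side) fragment length for one record."""

    record_id: str
    length: int
    unrestricted: bool
    lineage: Lineage = NA_LINEAGE


@dataclass
class FragmentProfile:
    """In silico TRF profile: one terminal fragment per input record."""

    enzyme: str
    fragments: list[TerminalFragment]
    dataset_id: str = "dataset"

    def __len__(self) -> int:
        return len(self.fragments)


# ---------------------------------------------------------------------------
# reference I/O


def read_reference(
    fasta_path: str | Path,
    taxonomy_path: str | Path,
    *,
    permissive: bool = False,
) -> list[ReferenceRecord]:
    """Read a multi-FASTA plus a two-column taxonomy TSV (``id``, ``lineage``).

    Sequences are uppercased and U is mapped to T; non-IUPAC characters and
    duplicate FASTA ids are fatal.  A FASTA id absent from the taxonomy
    table is fatal unless ``permissive``, in which case the record gets an
    all-NA lineage.  Records are returned in file order.
    """
    import pandas as pd

    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str).fillna("")
    for col in ("id", "lineage"):
        if col not in tax.columns:
            raise ValueError(f"taxonomy table {taxonomy_path}: missing column {col!r}")
    if tax["id"].duplicated().any():
        dups = tax.loc[tax["id"].duplicated(), "id"].unique()
        logger.warning("taxonomy table: duplicated ids %s; keeping first", list(dups))
        tax = tax.drop_duplicates("id", keep="first")
    lineages = {row.id: parse_lineage(row.lineage) for row in tax.itertuples()}

    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        try:
            seq = clean_sequence(str(rec.seq), name=rec.id)
        except SequenceError:
            raise
        if rec.id in lineages:
            lineage = lineages[rec.id]
        elif permissive:
            lineage = NA_LINEAGE
        else:
            raise ValueError(
                f"FASTA id {rec.id!r} absent from taxonomy table "
                f"(pass permissive=True to assign NA lineage)"
            )
        records.append(ReferenceRecord(id=rec.id, lineage=lineage, seq=seq))
    return records


def dedup_records(
    records: Sequence[ReferenceRecord],
) -> tuple[list[ReferenceRecord], dict[str, str]]:
    """Drop exact sequence-string duplicates, keeping the first occurrence.

    Returns the kept records (input order) and a report mapping each
    removed id to the id of the identical record that was kept.
    """
    kept: list[ReferenceRecord] = []
    first_by_seq: dict[str, str] = {}
    removed: dict[str, str] = {}
    for rec in records:
        if rec.seq in first_by_seq:
            removed[rec.id] = first_by_seq[rec.seq]
        else:
            first_by_seq[rec.seq] = rec.id
            kept.append(rec)
    if removed:
        logger.info("dedup_records: removed %d duplicate sequences", len(removed))
    return kept, removed


# ---------------------------------------------------------------------------
# primer handling


def _scan_compatible(template: str, probe: str, start: int) -> Optional[int]:
    """Leftmost position >= start where ``probe`` is IUPAC-compatible with
    ``template`` (non-empty intersection at every aligned position)."""
    m = len(probe)
    probe_sets = [IUPAC_SETS[c] for c in probe]
    for i in range(start, len(template) - m + 1):
        ok = True
        for j in range(m):
            if probe_sets[j].isdisjoint(IUPAC_SETS[template[i + j]]):
                ok = False
                break
        if ok:
            return i
    return None


def tag_with_primers(insert: str, fwd: Primer, rev: Primer, *, record_id: str = "") -> TaggedAmplicon:
    """Flank ``insert`` with the forward primer and the reverse complement of
    the reverse primer, reproducing the amplicon structure whose length is
    insert + both primer lengths."""
    if not insert:
        raise ValueError("tag_with_primers: empty insert")
    insert = clean_sequence(insert, name=record_id or "insert")
    seq = fwd.seq + insert + reverse_complement(rev.seq)
    return TaggedAmplicon(record_id=record_id, seq=seq, insert_len=len(insert))


def insilico_pcr(
    record: ReferenceRecord, fwd: Primer, rev: Primer
) -> Optional[TaggedAmplicon]:
    """Primer-anchored in silico PCR.

    Finds the leftmost top-strand window compatible with ``fwd`` and the
    leftmost downstream window compatible with the bottom-strand ``rev``
    (equivalently, with rc(rev) on the top strand); the template between
    the two binding sites becomes the insert of the tagged amplicon.
    Returns ``None`` when either primer fails to bind in a consistent
    orientation (no-amplicon is a value, not an error).
    """
    template = record.seq
    i = _scan_compatible(template, fwd.seq, 0)
    if i is None:
        return None
    rc_rev = reverse_complement(rev.seq)
    j = _scan_compatible(template, rc_rev, i + len(fwd.seq))
    if j is None:
        return None
    insert = template[i + len(fwd.seq): j]
    seq = fwd.seq + insert + rc_rev
    return TaggedAmplicon(record_id=record.id, seq=seq, insert_len=len(insert))


# ---------------------------------------------------------------------------
# site finding and digestion


def _match_window(seq: str, i: int, pattern: str, guaranteed: bool) -> bool:
    for j, pc in enumerate(pattern):
        sset = IUPAC_SETS[seq[i + j]]
        pset = IUPAC_SETS[pc]
        if guaranteed:
            if not sset <= pset:
                return False
        else:
            if sset.isdisjoint(pset):
                return False
    return True


def find_sites(seq: str, enzyme: Enzyme, semantics: str = "guaranteed") -> list[int]:
    """Ordered 0-based start positions of recognition sites in ``seq``.

    The top strand is scanned against the pattern; when the pattern is not
    its own reverse complement the top strand is additionally scanned
    against rc(pattern), which finds bottom-strand sites reported at their
    top-strand start coordinate.  A sequence shorter than the site has no
    sites.
    """
    if semantics not in SEMANTICS:
        raise ValueError(f"unknown semantics {semantics!r}; expected one of {SEMANTICS}")
    guaranteed = semantics == "guaranteed"
    patterns = [enzyme.site]
    if not enzyme.is_palindromic:
        patterns.append(reverse_complement(enzyme.site))
    hits: set[int] = set()
    for pat in patterns:
        for i in range(len(seq) - len(pat) + 1):
            if _match_window(seq, i, pat, guaranteed):
                hits.add(i)
    return sorted(hits)


def terminal_fragment(
    tagged: TaggedAmplicon,
    enzyme: Enzyme,
    semantics: str = "guaranteed",
    *,
    lineage: Lineage = NA_LINEAGE,
) -> TerminalFragment:
    """Labelled terminal fragment of a tagged amplicon.

    Length is (first site start + cut offset); with no site the fragment is
    the whole amplicon, flagged unrestricted.
    """
    if not tagged.seq:
        raise ValueError("terminal_fragment: empty amplicon")
    sites = find_sites(tagged.seq, enzyme, semantics)
    if sites:
        return TerminalFragment(
            record_id=tagged.record_id,
            length=sites[0] + enzyme.cut_offset,
            unrestricted=False,
            lineage=lineage,
        )
    return TerminalFragment(
        record_id=tagged.record_id,
        length=len(tagged.seq),
        unrestricted=True,
        lineage=lineage,
    )


def digest_dataset(
    records: Iterable[ReferenceRecord],
    fwd: Primer,
    rev: Primer,
    enzyme: Enzyme,
    semantics: str = "guaranteed",
    *,
    dataset_id: str = "dataset",
) -> FragmentProfile:
    """Tag every record with the primer pair and digest it, carrying the
    record's lineage onto its terminal fragment.  One fragment per record."""
    fragments: list[TerminalFragment] = []
    for rec in records:
        tagged = tag_with_primers(rec.seq, fwd, rev, record_id=rec.id)
        fragments.append(
            terminal_fragment(tagged, enzyme, semantics, lineage=rec.lineage)
        )
    if not fragments:
        raise ValueError("digest_dataset: no input records")
    return FragmentProfile(enzyme=enzyme.name, fragments=fragments, dataset_id=dataset_id)


def write_fragments_tsv(profile: FragmentProfile, path: str | Path) -> None:
    """Write a fragment profile as TSV (record_id, length_bp, unrestricted, lineage)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "record_id": [f.record_id for f in profile.fragments],
            "length_bp": [f.length for f in profile.fragments],
            "unrestricted": [f.unrestricted for f in profile.fragments],
            "lineage": [f.lineage.to_string() for f in profile.fragments],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path: str | Path, *, enzyme: str = "", dataset_id: str = "dataset") -> FragmentProfile:
    """Read a fragment profile written by :func:`write_fragments_tsv`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"record_id": str})
    fragments = [
        TerminalFragment(
            record_id=str(r.record_id),
            length=int(r.length_bp),
            unrestricted=bool(r.unrestricted),
            lineage=parse_lineage(str(r.lineage)),
        )
        for r in df.itertuples()
    ]
    return FragmentProfile(enzyme=enzyme, fragments=fragments, dataset_id=dataset_id)
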