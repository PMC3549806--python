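"""Evolutionary profiles for a dimer template.

Two multiple sequence alignments — one per template chain — are turned into
a paired profile: rows of the two alignments are matched by a pairing key
(by default a source-organism tag), near-identical rows are purged, and at
every interface contact position the residue pairs observed across the
paired rows are tallied as single symbols.  Symbols default to group pairs
under a reduced amino-acid alphabet, which tolerates conservative
substitutions; raw residue-pair counting is available by passing
``scheme=None``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio import AlignIO, SeqIO

from .errors import EmptyTemplate, InsufficientPairs
from .potential import AMINO_ACIDS, GroupScheme

_GAPS = set("-.")
_STANDARD = set(AMINO_ACIDS)
_KEY_RE = re.compile(r"key=(\S+)")


@dataclass(frozen=True)
class MsaRow:
    row_id: str
    key: str
    seq: str

    def n_gaps(self) -> int:
        return sum(c in _GAPS for c in self.seq)


@dataclass
class Msa:
    """An alignment whose first-class citizen is the template row."""

    rows: list
    template_row: int = 0

    def __post_init__(self):
        lengths = {len(r.seq) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("aligned sequences have unequal lengths")

    @property
    def columns(self) -> int:
        return len(self.rows[0].seq) if self.rows else 0

    @property
    def template(self) -> MsaRow:
        return self.rows[self.template_row]

    @classmethod
    def from_fasta(cls, path, template_id=None, key_map=None) -> "Msa":
        """Read an aligned FASTA.

        The pairing key is taken from a ``key=<tag>`` field in the record
        description, or from ``key_map`` (row_id -> key).  The template row
        is the record with id ``template_id``, else the first record.
        ``path`` may also be an open text handle.
        """
        import contextlib

        rows = []
        template_row = 0
        with contextlib.ExitStack() as stack:
            if hasattr(path, "read"):
                source = path
            else:
                source = stack.enter_context(open(str(path)))
            for i, rec in enumerate(SeqIO.parse(source, "fasta")):
                key = ""
                m = _KEY_RE.search(rec.description)
                if m:
                    key = m.group(1)
                elif key_map and rec.id in key_map:
                    key = key_map[rec.id]
                rows.append(MsaRow(rec.id, key, str(rec.seq).upper()))
                if template_id is not None and rec.id == template_id:
                    template_row = i
        return cls(rows=rows, template_row=template_row)

    @classmethod
    def from_stockholm(cls, path, template_id=None, key_map=None) -> "Msa":
        aln = AlignIO.read(str(path), "stockholm")
        rows, template_row = [], 0
        for i, rec in enumerate(aln):
            key = key_map.get(rec.id, "") if key_map else ""
            rows.append(MsaRow(rec.id, key, str(rec.seq).upper()))
            if template_id is not None and rec.id == template_id:
                template_row = i
        return cls(rows=rows, template_row=template_row)


@dataclass
class ColumnMap:
    """Injective map from ungapped 0-based template position to column."""

    template_pos_to_column: dict

    def __getitem__(self, pos: int) -> int:
        return self.template_pos_to_column[pos]

    def __contains__(self, pos: int) -> bool:
        return pos in self.template_pos_to_column


@dataclass
class PairedProfile:
    msa_a: Msa
    msa_b: Msa
    row_pairs: list  # (row index in A, row index in B); template pair first
    colmap_a: ColumnMap
    colmap_b: ColumnMap
    n_dropped_unmatched: int = 0


@dataclass
class PairColumnCounts:
    """Residue-pair symbol tallies at one contact position.

    ``counts`` maps a symbol — a (group, group) index pair under a scheme,
    or a raw (aa, aa) pair — to its count over the paired rows.  The
    observed frequency f of a symbol is count / n_effective, and the
    pseudocount mixing weight is alpha = n_distinct - 1.
    """

    position_index: int
    counts: dict
    n_effective: int = field(init=False)
    n_distinct: int = field(init=False)

    def __post_init__(self):
        self.n_effective = sum(self.counts.values())
        self.n_distinct = sum(1 for v in self.counts.values() if v > 0)

    @property
    def alpha(self) -> float:
        return max(self.n_distinct - 1, 0)

    def f(self, symbol) -> float:
        if self.n_effective == 0:
            return 0.0
        return self.counts.get(symbol, 0) / self.n_effective


def row_identity(row: MsaRow, template: MsaRow) -> float:
    """Fraction identity over matched non-gap columns.

    Matches are counted over columns where both rows are non-gap and the
    denominator is the shorter ungapped length of the two rows.
    """
    matches = 0
    len_r = len_t = 0
    for x, y in zip(row.seq, template.seq):
        gx, gy = x in _GAPS, y in _GAPS
        len_r += not gx
        len_t += not gy
        if not gx and not gy and x == y:
            matches += 1
    denom = min(len_r, len_t)
    return matches / denom if denom else 0.0


def purge_similar(msa: Msa, threshold: float = 0.95) -> Msa:
    """Drop rows nearly identical to the template (identity > threshold).

    The template row itself is always retained.
    """
    template = msa.template
    kept, new_template = [], 0
    for i, row in enumerate(msa.rows):
        if i == msa.template_row:
            new_template = len(kept)
            kept.append(row)
        elif row_identity(row, template) <= threshold:
            kept.append(row)
    return Msa(rows=kept, template_row=new_template)


def map_columns(msa: Msa) -> ColumnMap:
    """Map each ungapped template position to its alignment column."""
    mapping, pos = {}, 0
    for col, c in enumerate(msa.template.seq):
        if c not in _GAPS:
            mapping[pos] = col
            pos += 1
    if not mapping:
        raise EmptyTemplate("template row contains only gaps")
    return ColumnMap(mapping)


def _dedupe_by_key(msa: Msa):
    """Best row per key (fewest gaps); template row excluded."""
    best: dict = {}
    for i, row in enumerate(msa.rows):
        if i == msa.template_row or not row.key:
            continue
        prev = best.get(row.key)
        if prev is None or row.n_gaps() < msa.rows[prev].n_gaps():
            if prev is not None:
                warnings.warn(
                    f"duplicate pairing key {row.key!r}; keeping row with fewest gaps"
                )
            best[row.key] = i
        elif prev is not None:
            warnings.warn(
                f"duplicate pairing key {row.key!r}; keeping row with fewest gaps"
            )
    return best


def pair_rows(msa_a: Msa, msa_b: Msa) -> PairedProfile:
    """Pair rows of the two alignments by pairing key.

    The two template rows are always paired with each other (the template's
    own contact pair is an observation).  Keys present in only one
    alignment are dropped; duplicates within one alignment keep the row
    with fewest gaps.
    """
    best_a = _dedupe_by_key(msa_a)
    best_b = _dedupe_by_key(msa_b)
    common = sorted(set(best_a) & set(best_b))
    dropped = (len(best_a) - len(common)) + (len(best_b) - len(common))
    row_pairs = [(msa_a.template_row, msa_b.template_row)]
    row_pairs += [(best_a[k], best_b[k]) for k in common]
    if len(row_pairs) == 1:
        warnings.warn(
            "no rows beyond the template pair could be paired; "
            "profile will rely on pseudocounts only",
            InsufficientPairs,
        )
    return PairedProfile(
        msa_a=msa_a, msa_b=msa_b, row_pairs=row_pairs,
        colmap_a=map_columns(msa_a), colmap_b=map_columns(msa_b),
        n_dropped_unmatched=dropped,
    )


def column_pair_counts(profile: PairedProfile, contact_pos,
                       scheme: GroupScheme | None,
                       position_index: int = 0) -> PairColumnCounts:
    """Tally residue-pair symbols at one contact position.

    ``contact_pos`` is (template position in chain A, template position in
    chain B), 0-based ungapped.  A paired row is skipped when either side
    shows a gap or a non-standard residue.  With a scheme the symbol is the
    (group, group) pair; with ``scheme=None`` it is the raw residue pair.
    """
    pos_a, pos_b = contact_pos
    col_a = profile.colmap_a[pos_a]
    col_b = profile.colmap_b[pos_b]
    counts: dict = {}
    for ia, ib in profile.row_pairs:
        x = profile.msa_a.rows[ia].seq[col_a]
        y = profile.msa_b.rows[ib].seq[col_b]
        if x not in _STANDARD or y not in _STANDARD:
            continue
        symbol = (x, y) if scheme is None else (scheme.group_of(x), scheme.group_of(y))
        counts[symbol] = counts.get(symbol, 0) + 1
    return PairColumnCounts(position_index=position_index, counts=counts)
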