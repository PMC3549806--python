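"""Dimer interface geometry: contact extraction, template QC, domain mapping.

A template is a co-crystallized two-chain structure.  Its interface is the
set of contact residue pairs: one residue from each chain with at least one
pair of heavy (non-hydrogen) atoms within the distance cutoff, 4.5 A by
default (inclusive).  The number of contact pairs R fixes the number of
rows of the pair position-specific scoring matrix built from the template.

Structures are read with gemmi (PDB and mmCIF); only the first model is
used, waters and non-polymer hetero groups are skipped, and for alternate
locations the highest-occupancy conformer of each atom is kept.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import gemmi
import numpy as np

from .errors import AnnotationConflict, ChainNotFound, EmptyChain


@dataclass(frozen=True, order=True)
class ResidueRef:
    """One residue identified by author numbering."""

    chain_id: str
    seq_num: int
    icode: str = ""
    aa: str = "X"


@dataclass(frozen=True)
class ContactPair:
    res_a: ResidueRef
    res_b: ResidueRef
    min_dist: float


@dataclass
class ContactMap:
    pairs: list
    cutoff: float

    @property
    def R(self) -> int:
        return len(self.pairs)

    def residues(self, side: str) -> list:
        """Distinct contact residues on side 'a' or 'b', in pair order."""
        seen, out = set(), []
        for p in self.pairs:
            r = p.res_a if side == "a" else p.res_b
            if r not in seen:
                seen.add(r)
                out.append(r)
        return out

    def to_tsv(self) -> str:
        lines = ["chain_a\tresnum_a\ticode_a\taa_a\tchain_b\tresnum_b\ticode_b\taa_b\tmin_dist"]
        for p in self.pairs:
            a, b = p.res_a, p.res_b
            lines.append(
                f"{a.chain_id}\t{a.seq_num}\t{a.icode}\t{a.aa}\t"
                f"{b.chain_id}\t{b.seq_num}\t{b.icode}\t{b.aa}\t{p.min_dist:.3f}"
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "cutoff": self.cutoff,
                "R": self.R,
                "pairs": [
                    {
                        "res_a": vars(p.res_a),
                        "res_b": vars(p.res_b),
                        "min_dist": p.min_dist,
                    }
                    for p in self.pairs
                ],
            },
            indent=1,
        )

    @classmethod
    def from_tsv(cls, text: str, cutoff: float = 4.5) -> "ContactMap":
        pairs = []
        for line in text.strip().splitlines()[1:]:
            f = line.split("\t")
            pairs.append(
                ContactPair(
                    ResidueRef(f[0], int(f[1]), f[2], f[3]),
                    ResidueRef(f[4], int(f[5]), f[6], f[7]),
                    float(f[8]),
                )
            )
        return cls(pairs=pairs, cutoff=cutoff)


@dataclass
class TemplateDimer:
    """A two-chain template with its interface contact map.

    ``chain_a_residues``/``chain_b_residues`` hold the ordered polymer
    residues of each chain so that contact pairs can be mapped onto
    0-based ungapped sequence positions via :meth:`contact_positions`.
    """

    id: str
    chain_a_id: str
    chain_b_id: str
    chain_a_seq: str
    chain_b_seq: str
    contact_map: ContactMap
    resolution: Optional[float] = None
    domains: Optional[list] = None
    chain_a_residues: list = field(default_factory=list)
    chain_b_residues: list = field(default_factory=list)

    def contact_positions(self) -> list:
        """0-based (position in chain A, position in chain B) per contact pair."""
        idx_a = {r: i for i, r in enumerate(self.chain_a_residues)}
        idx_b = {r: i for i, r in enumerate(self.chain_b_residues)}
        return [
            (idx_a[p.res_a], idx_b[p.res_b]) for p in self.contact_map.pairs
        ]


@dataclass
class QCCheck:
    name: str
    observed: object
    threshold: object
    passed: bool


@dataclass
class QCReport:
    passed: bool
    checks: list

    def to_json(self) -> str:
        return json.dumps(
            {"passed": self.passed, "checks": [vars(c) for c in self.checks]},
            indent=1, default=str,
        )


def load_structure(path) -> gemmi.Structure:
    """Read a PDB or mmCIF file (format detected from contents/extension)."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def _one_letter(resname: str) -> Optional[str]:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return None
    code = info.one_letter_code.upper()
    if not code.isalpha():
        return "X"
    return code


def _chain_residues(structure: gemmi.Structure, chain_id: str):
    """Standard amino-acid residues of a chain with heavy-atom coordinates.

    Returns (refs, coords, res_index) where coords is an (n_atoms, 3) array
    and res_index maps each atom row to its residue index.
    """
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainNotFound(f"chain {chain_id!r} not in structure")
    refs, xyz, res_idx = [], [], []
    for res in chain:
        if res.is_water():
            continue
        aa = _one_letter(res.name)
        if aa is None:
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and info.is_amino_acid():
                warnings.warn(f"skipping unmappable residue {res.name}")
            continue
        icode = res.seqid.icode.strip()
        ref = ResidueRef(chain_id, res.seqid.num, icode, aa)
        # highest-occupancy conformer per atom name
        best = {}
        for atom in res:
            if atom.is_hydrogen():
                continue
            prev = best.get(atom.name)
            if prev is None or atom.occ > prev.occ:
                best[atom.name] = atom
        if not best:
            continue
        ri = len(refs)
        refs.append(ref)
        for atom in best.values():
            xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
            res_idx.append(ri)
    if not refs:
        raise EmptyChain(f"chain {chain_id!r} has no standard residues")
    return refs, np.asarray(xyz), np.asarray(res_idx)


def extract_contacts(structure: gemmi.Structure, chain_a: str, chain_b: str,
                     cutoff: float = 4.5) -> ContactMap:
    """All inter-chain residue pairs with min heavy-atom distance <= cutoff.

    Pairs are ordered by (chain A residue, chain B residue) author numbering.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    refs_a, xyz_a, idx_a = _chain_residues(structure, chain_a)
    refs_b, xyz_b, idx_b = _chain_residues(structure, chain_b)
    # all-vs-all heavy atom distances, reduced to per-residue-pair minima
    d2 = ((xyz_a[:, None, :] - xyz_b[None, :, :]) ** 2).sum(axis=2)
    hit_a, hit_b = np.nonzero(d2 <= cutoff * cutoff)
    best: dict = {}
    for ai, bi in zip(hit_a, hit_b):
        key = (int(idx_a[ai]), int(idx_b[bi]))
        d = float(np.sqrt(d2[ai, bi]))
        if key not in best or d < best[key]:
            best[key] = d
    pairs = [
        ContactPair(refs_a[ia], refs_b[ib], best[(ia, ib)])
        for ia, ib in sorted(best)
    ]
    return ContactMap(pairs=pairs, cutoff=cutoff)


def load_dimer(path, chain_a: str, chain_b: str, cutoff: float = 4.5,
               domains=None, dimer_id: Optional[str] = None) -> TemplateDimer:
    """Parse a structure file and assemble a :class:`TemplateDimer`."""
    st = load_structure(path)
    return dimer_from_structure(st, chain_a, chain_b, cutoff=cutoff,
                                domains=domains, dimer_id=dimer_id or st.name)


def dimer_from_structure(st: gemmi.Structure, chain_a: str, chain_b: str,
                         cutoff: float = 4.5, domains=None,
                         dimer_id: Optional[str] = None) -> TemplateDimer:
    refs_a, _, _ = _chain_residues(st, chain_a)
    refs_b, _, _ = _chain_residues(st, chain_b)
    cmap = extract_contacts(st, chain_a, chain_b, cutoff=cutoff)
    resolution = st.resolution if st.resolution > 0 else None
    return TemplateDimer(
        id=dimer_id or st.name or "dimer",
        chain_a_id=chain_a,
        chain_b_id=chain_b,
        chain_a_seq="".join(r.aa for r in refs_a),
        chain_b_seq="".join(r.aa for r in refs_b),
        contact_map=cmap,
        resolution=resolution,
        domains=domains,
        chain_a_residues=refs_a,
        chain_b_residues=refs_b,
    )


def qc_template(dimer: TemplateDimer, min_chain_len: int = 36,
                min_pairs: int = 26, min_contact_res_per_chain: int = 6,
                max_resolution: float = 3.0,
                missing_resolution_passes: bool = False) -> QCReport:
    """Template quality control with strict literal thresholds.

    Defaults encode: resolution strictly below 3.0 A, each chain longer
    than 35 residues, more than 25 contact pairs, and more than 5 distinct
    contact residues contributed by each chain.
    """
    checks = []
    if dimer.resolution is None:
        checks.append(QCCheck("resolution", None, f"< {max_resolution}",
                              missing_resolution_passes))
    else:
        checks.append(QCCheck("resolution", dimer.resolution,
                              f"< {max_resolution}",
                              dimer.resolution < max_resolution))
    checks.append(QCCheck("chain_a_length", len(dimer.chain_a_seq),
                          f">= {min_chain_len}",
                          len(dimer.chain_a_seq) >= min_chain_len))
    checks.append(QCCheck("chain_b_length", len(dimer.chain_b_seq),
                          f">= {min_chain_len}",
                          len(dimer.chain_b_seq) >= min_chain_len))
    R = dimer.contact_map.R
    checks.append(QCCheck("min_pairs", R, f">= {min_pairs}", R >= min_pairs))
    for side, name in (("a", "contact_residues_a"), ("b", "contact_residues_b")):
        n = len(dimer.contact_map.residues(side))
        checks.append(QCCheck(name, n, f">= {min_contact_res_per_chain}",
                              n >= min_contact_res_per_chain))
    return QCReport(passed=all(c.passed for c in checks), checks=checks)


@dataclass(frozen=True)
class DomainAnnotation:
    """A (possibly cross-chain) domain: id plus residue ranges per chain."""

    domain_id: str
    ranges: tuple  # of (chain_id, start, end) inclusive author numbering

    def contains(self, ref: ResidueRef) -> bool:
        return any(
            c == ref.chain_id and s <= ref.seq_num <= e
            for c, s, e in self.ranges
        )


def _check_overlaps(domains):
    by_chain: dict = {}
    for dom in domains:
        for c, s, e in dom.ranges:
            by_chain.setdefault(c, []).append((s, e, dom.domain_id))
    for c, ranges in by_chain.items():
        ranges.sort()
        for (s1, e1, d1), (s2, e2, d2) in zip(ranges, ranges[1:]):
            if s2 <= e1 and d1 != d2:
                raise AnnotationConflict(
                    f"domains {d1} and {d2} overlap on chain {c}"
                )


def interacting_domains(contact_map: ContactMap, domains,
                        min_contact_residues: int = 4) -> list:
    """Domain pairs where each domain holds enough contact residues.

    A pair (domain on the A side, domain on the B side) is reported when
    each domain contains more than three (by default, >= 4) of its chain's
    distinct contact residues.  Cross-chain domains accumulate counts over
    all their chains.
    """
    _check_overlaps(domains)
    res_a = contact_map.residues("a")
    res_b = contact_map.residues("b")
    counts_a = {d.domain_id: sum(d.contains(r) for r in res_a) for d in domains}
    counts_b = {d.domain_id: sum(d.contains(r) for r in res_b) for d in domains}
    out = []
    for da in domains:
        na = counts_a[da.domain_id]
        if na < min_contact_residues:
            continue
        for db in domains:
            nb = counts_b[db.domain_id]
            if nb < min_contact_residues:
                continue
            out.append((da.domain_id, db.domain_id, na, nb))
    return out


def read_domains_tsv(path) -> list:
    """Domain annotation TSV: domain_id, chain_id, start, end (one range/row)."""
    by_id: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            dom, chain, start, end = line.split("\t")[:4]
            by_id.setdefault(dom, []).append((chain, int(start), int(end)))
    return [DomainAnnotation(d, tuple(r)) for d, r in by_id.items()]
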