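"""Deterministic synthetic fixtures for every input the toolkit consumes.

Real inputs to this toolkit come from crystallographic structures, homology
searches and expression compendia.  The generators here emulate their
statistical structure at toy scale so the whole pipeline runs end to end
offline:

* toy dimer structures whose designated contact pairs sit well inside the
  4.5 A cutoff and whose non-contacts sit well outside it (explicit
  separation margin, so the ground-truth contact map is unambiguous);
* paired alignments under a conservative-substitution model: interface
  columns mutate mostly within the 9 reduced amino-acid groups, mimicking
  the tolerance of interfaces for conservative changes;
* screening benchmarks where positives conserve the interface (up to
  within-group substitutions) and negatives lose most of it — unaligned or
  mutated across groups, the missing-binding-domain failure mode that
  motivates position-specific scoring.

All generators are pure functions of (arguments, seed): the same spec
yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import InfeasibleSpec
from .evaluate import HomologyHit
from .geometry import ContactMap, ContactPair, ResidueRef
from .potential import AMINO_ACIDS, MODIFIED_SCHEME

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# toy geometry constants: residue spacing along the chain, inter-chain
# separation for contacts vs non-contacts, intra-residue atom offsets
_SPACING = 8.0
_CONTACT_GAP = 4.0     # center-center distance of designated contact pairs
_FAR_GAP = 40.0        # chain separation for non-contact residues
_ATOM_OFFSET = 0.4     # max displacement of backbone atoms from the center


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic generators.

    Substitution rates apply at interface (contact) columns; non-contact
    columns substitute uniformly at ``background_sub_rate``.  The default
    benchmark has 20 positive and 20 negative designated candidate pairs,
    with negatives losing 70% of their interface.
    """

    seed: int = 0
    n_residues_per_chain: int = 40
    n_contacts: int = 30
    n_profile_rows: int = 50
    within_group_sub_rate: float = 0.3
    across_group_sub_rate: float = 0.05
    background_sub_rate: float = 0.3
    n_positive_candidates: int = 20
    n_negative_candidates: int = 20
    interface_ablation_fraction: float = 0.7
    resolution: float = 2.0

    def __post_init__(self):
        for name in ("within_group_sub_rate", "across_group_sub_rate",
                     "background_sub_rate", "interface_ablation_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_residues_per_chain", "n_contacts", "n_profile_rows",
                     "n_positive_candidates", "n_negative_candidates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ToyDimer:
    """A generated structure plus its ground truth."""

    pdb_text: str
    contact_map: ContactMap          # ground truth, independent of any parser
    seq_a: str
    seq_b: str
    contact_positions: list          # 0-based (pos in A, pos in B) per pair
    resolution: float


def _residue_atoms(aa: str, center):
    """Backbone + CB atom positions clustered within _ATOM_OFFSET of center."""
    x, y, z = center
    atoms = [
        ("N", "N", (x + _ATOM_OFFSET, y, z)),
        ("CA", "C", (x, y, z)),
        ("C", "C", (x - _ATOM_OFFSET, y, z)),
        ("O", "O", (x, y + _ATOM_OFFSET, z)),
    ]
    if aa != "G":
        atoms.append(("CB", "C", (x, y, z + _ATOM_OFFSET)))
    return atoms


def make_toy_dimer(spec: FixtureSpec) -> ToyDimer:
    """Emit a two-chain PDB with designated contacts and known ground truth.

    Chain A lies along the x axis; chain B residues sit either directly
    across their designated partner (contact, center gap 4.0 A) or far
    away (non-contact, 40 A).  All heavy-atom distances of designated
    pairs are below 4.5 A minus margin... specifically the minimum is
    ~3.2-4.0 A, while every non-designated inter-chain distance exceeds
    5.5 A.
    """
    n = spec.n_residues_per_chain
    if spec.n_contacts > n:
        raise InfeasibleSpec(
            f"{spec.n_contacts} contacts do not fit in chains of {n} residues"
        )
    rng = np.random.default_rng(spec.seed)
    seq_a = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    seq_b = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    idx_a = np.sort(rng.choice(n, size=spec.n_contacts, replace=False))
    idx_b = np.sort(rng.choice(n, size=spec.n_contacts, replace=False))
    partner_of_b = {int(j): int(i) for i, j in zip(idx_a, idx_b)}

    st = gemmi.Structure()
    st.name = "toydimer"
    st.resolution = spec.resolution
    model = gemmi.Model("1")
    serial = 1
    coords = {}  # (chain, pos) -> list of atom coordinate triples
    for chain_id, seq in (("A", seq_a), ("B", seq_b)):
        chain = gemmi.Chain(chain_id)
        for i, aa in enumerate(seq):
            if chain_id == "A":
                center = (_SPACING * i, 0.0, 0.0)
            elif i in partner_of_b:
                center = (_SPACING * partner_of_b[i], _CONTACT_GAP, 0.0)
            else:
                center = (_SPACING * i, _FAR_GAP, 0.0)
            res = gemmi.Residue()
            res.name = ONE_TO_THREE[aa]
            res.seqid = gemmi.SeqId(i + 1, " ")
            pts = []
            for name, element, pos in _residue_atoms(aa, center):
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(element)
                atom.pos = gemmi.Position(*pos)
                atom.occ = 1.0
                atom.b_iso = 20.0
                atom.serial = serial
                serial += 1
                res.add_atom(atom)
                pts.append(pos)
            coords[(chain_id, i)] = pts
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)

    pairs = []
    for i, j in zip(idx_a, idx_b):
        d = min(
            math.dist(p, q)
            for p in coords[("A", int(i))]
            for q in coords[("B", int(j))]
        )
        pairs.append(
            ContactPair(
                ResidueRef("A", int(i) + 1, "", seq_a[int(i)]),
                ResidueRef("B", int(j) + 1, "", seq_b[int(j)]),
                round(d, 6),
            )
        )
    return ToyDimer(
        pdb_text=st.make_pdb_string(),
        contact_map=ContactMap(pairs=pairs, cutoff=4.5),
        seq_a=seq_a,
        seq_b=seq_b,
        contact_positions=[(int(i), int(j)) for i, j in zip(idx_a, idx_b)],
        resolution=spec.resolution,
    )


def _substitute(aa: str, rng, within_rate: float, across_rate: float) -> str:
    """One interface-column substitution under the reduced-alphabet model."""
    u = rng.random()
    group = MODIFIED_SCHEME.groups[MODIFIED_SCHEME.group_of(aa)]
    if u < across_rate:
        others = [a for a in AMINO_ACIDS if a not in group]
        return str(rng.choice(others))
    if u < across_rate + within_rate:
        siblings = [a for a in sorted(group) if a != aa]
        return str(rng.choice(siblings)) if siblings else aa
    return aa


def _mutate_chain(seq: str, contact_cols: set, spec: FixtureSpec, rng) -> str:
    out = []
    for i, aa in enumerate(seq):
        if i in contact_cols:
            out.append(_substitute(aa, rng, spec.within_group_sub_rate,
                                   spec.across_group_sub_rate))
        elif rng.random() < spec.background_sub_rate:
            out.append(str(rng.choice([a for a in AMINO_ACIDS if a != aa])))
        else:
            out.append(aa)
    return "".join(out)


def make_paired_msas(dimer: ToyDimer, spec: FixtureSpec):
    """Aligned FASTA texts for the two chains with organism pairing keys.

    Interface columns follow the conservative-substitution model (mostly
    within-group changes); the rest of the sequence drifts uniformly.
    Rows are ungapped and tagged ``key=orgN`` consistently across the two
    files, with the template row first (``key=template``).
    """
    rng = np.random.default_rng(spec.seed + 1)
    cols_a = {i for i, _ in dimer.contact_positions}
    cols_b = {j for _, j in dimer.contact_positions}
    rows_a = [(f"templateA", "template", dimer.seq_a)]
    rows_b = [(f"templateB", "template", dimer.seq_b)]
    for k in range(spec.n_profile_rows):
        rows_a.append((f"hitA{k}", f"org{k}",
                       _mutate_chain(dimer.seq_a, cols_a, spec, rng)))
        rows_b.append((f"hitB{k}", f"org{k}",
                       _mutate_chain(dimer.seq_b, cols_b, spec, rng)))
    fa = "".join(f">{rid} key={key}\n{seq}\n" for rid, key, seq in rows_a)
    fb = "".join(f">{rid} key={key}\n{seq}\n" for rid, key, seq in rows_b)
    return fa, fb


def _identity(seq: str, template: str) -> float:
    return 100.0 * sum(a == b for a, b in zip(seq, template)) / len(template)


def _full_alignment(seq: str) -> dict:
    return {i: (i, aa) for i, aa in enumerate(seq)}


@dataclass
class ScreenBenchmark:
    hits_a: list
    hits_b: list
    labels: dict                      # (id_a, id_b) -> positive/negative
    designated_pairs: list            # [(id_a, id_b, label), ...]


def make_screen_benchmark(dimer: ToyDimer, spec: FixtureSpec) -> ScreenBenchmark:
    """Labelled hit tables for a screening run against the toy template.

    Positive candidate pairs conserve every contact position up to
    within-group substitution.  Negative pairs lose
    ``interface_ablation_fraction`` of contact positions in one of two
    ways, alternating between candidates: the missing-binding-domain mode
    (ablated positions unaligned) and the mutated-interface mode (ablated
    positions aligned but substituted across groups on one side — pairs a
    generic potential may still tolerate but the position-specific profile
    does not).  Candidate pairs arising from crossing one designated
    pair's A protein with another's B protein are left unannotated.
    """
    rng = np.random.default_rng(spec.seed + 2)
    contact_positions = dimer.contact_positions
    R = len(contact_positions)
    n_ablate = int(round(spec.interface_ablation_fraction * R))
    hits_a, hits_b = [], []
    labels, designated = {}, []

    def add_candidate(name, label, seq_a, seq_b, drop_a, drop_b):
        aln_a = {i: v for i, v in _full_alignment(seq_a).items() if i not in drop_a}
        aln_b = {i: v for i, v in _full_alignment(seq_b).items() if i not in drop_b}
        ev_a = 10.0 ** (-float(rng.uniform(10, 30)))
        ev_b = 10.0 ** (-float(rng.uniform(10, 30)))
        hits_a.append(HomologyHit("A", f"{name}_A", ev_a,
                                  _identity(seq_a, dimer.seq_a), aln_a))
        hits_b.append(HomologyHit("B", f"{name}_B", ev_b,
                                  _identity(seq_b, dimer.seq_b), aln_b))
        labels[(f"{name}_A", f"{name}_B")] = label
        designated.append((f"{name}_A", f"{name}_B", label))

    for k in range(spec.n_positive_candidates):
        sa = _mutate_chain(dimer.seq_a, {i for i, _ in contact_positions},
                           _interface_only(spec), rng)
        sb = _mutate_chain(dimer.seq_b, {j for _, j in contact_positions},
                           _interface_only(spec), rng)
        add_candidate(f"pos{k}", "positive", sa, sb, set(), set())

    for k in range(spec.n_negative_candidates):
        sa, sb = list(dimer.seq_a), list(dimer.seq_b)
        drop_a, drop_b = set(), set()
        ablated = rng.choice(R, size=n_ablate, replace=False)
        missing_domain = k % 2 == 0
        for r in ablated:
            pos_a, pos_b = contact_positions[int(r)]
            side_a = rng.random() < 0.5
            if missing_domain:  # unaligned interface position
                (drop_a if side_a else drop_b).add(pos_a if side_a else pos_b)
            else:  # cross-group mutation on one side, alignment intact
                if side_a:
                    sa[pos_a] = _cross_group(sa[pos_a], rng)
                else:
                    sb[pos_b] = _cross_group(sb[pos_b], rng)
        # background drift off the interface, as for positives
        bg = _background_only(spec)
        sa = _mutate_chain("".join(sa), {i for i, _ in contact_positions}, bg, rng)
        sb = _mutate_chain("".join(sb), {j for _, j in contact_positions}, bg, rng)
        add_candidate(f"neg{k}", "negative", sa, sb, drop_a, drop_b)

    return ScreenBenchmark(hits_a=hits_a, hits_b=hits_b, labels=labels,
                           designated_pairs=designated)


def _cross_group(aa: str, rng) -> str:
    group = MODIFIED_SCHEME.groups[MODIFIED_SCHEME.group_of(aa)]
    return str(rng.choice([a for a in AMINO_ACIDS if a not in group]))


def _interface_only(spec: FixtureSpec) -> FixtureSpec:
    """Positives: within-group interface drift, background drift elsewhere."""
    return FixtureSpec(
        seed=spec.seed,
        n_residues_per_chain=spec.n_residues_per_chain,
        n_contacts=spec.n_contacts,
        within_group_sub_rate=spec.within_group_sub_rate,
        across_group_sub_rate=0.0,
        background_sub_rate=spec.background_sub_rate,
    )


def _background_only(spec: FixtureSpec) -> FixtureSpec:
    return FixtureSpec(
        seed=spec.seed,
        n_residues_per_chain=spec.n_residues_per_chain,
        n_contacts=spec.n_contacts,
        within_group_sub_rate=0.0,
        across_group_sub_rate=0.0,
        background_sub_rate=spec.background_sub_rate,
    )


def make_expression_profiles(benchmark: ScreenBenchmark, spec: FixtureSpec,
                             n_conditions: int = 30):
    """Gene-expression profiles where interacting pairs co-express.

    Positive pairs share a latent condition response plus noise; proteins
    of negative pairs respond independently.  Returns (profiles dict of
    id -> ndarray, rows of (id_a, id_b, label)).
    """
    rng = np.random.default_rng(spec.seed + 3)
    profiles = {}
    rows = []
    for id_a, id_b, label in benchmark.designated_pairs:
        if label == "positive":
            latent = rng.normal(size=n_conditions)
            profiles[id_a] = latent + 0.5 * rng.normal(size=n_conditions)
            profiles[id_b] = latent + 0.5 * rng.normal(size=n_conditions)
        else:
            profiles[id_a] = rng.normal(size=n_conditions)
            profiles[id_b] = rng.normal(size=n_conditions)
        rows.append((id_a, id_b, label))
    return profiles, rows


def build_fixture_pssm(dimer: ToyDimer, spec: FixtureSpec, pot=None,
                       scheme=MODIFIED_SCHEME, beta: float = 5.0):
    """Run a toy dimer through the full pipeline; returns (TemplateDimer, PairPSSM).

    The structure text is re-parsed and contacts re-extracted rather than
    using the generator's ground truth, so this exercises the same code
    path as real inputs.
    """
    import io

    import gemmi as _gemmi

    from .core import build_pairpssm
    from .geometry import dimer_from_structure
    from .potential import bundled_potential
    from .profile import Msa, pair_rows, purge_similar

    st = _gemmi.read_pdb_string(dimer.pdb_text)
    st.setup_entities()
    tdimer = dimer_from_structure(st, "A", "B", dimer_id="toydimer")
    fa, fb = make_paired_msas(dimer, spec)
    msa_a = purge_similar(Msa.from_fasta(io.StringIO(fa)))
    msa_b = purge_similar(Msa.from_fasta(io.StringIO(fb)))
    profile = pair_rows(msa_a, msa_b)
    pot = pot or bundled_potential()
    pssm = build_pairpssm(tdimer, profile, pot, scheme=scheme, beta=beta)
    return tdimer, pssm


def hits_to_tsv(hits) -> str:
    """Serialize hits in the native TSV dialect read by ``read_hits_tsv``."""
    lines = []
    for h in hits:
        pairs = ",".join(f"{t}:{s}:{res}" for t, (s, res) in sorted(h.aligned_pairs.items()))
        lines.append(f"{h.template_chain}\t{h.subject_id}\t{h.evalue:.6g}\t"
                     f"{h.identity:.2f}\t{pairs}")
    return "\n".join(lines) + "\n"


def labels_to_tsv(labels: dict) -> str:
    return "".join(f"{a}\t{b}\t{lab}\n" for (a, b), lab in sorted(labels.items()))


def write_workspace(outdir, spec: FixtureSpec):
    """Emit a complete, self-consistent demo workspace to ``outdir``."""
    import shutil
    from importlib.resources import files
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dimer = make_toy_dimer(spec)
    (out / "dimer.pdb").write_text(dimer.pdb_text)
    (out / "contacts_truth.tsv").write_text(dimer.contact_map.to_tsv())
    fa, fb = make_paired_msas(dimer, spec)
    (out / "msa_a.fasta").write_text(fa)
    (out / "msa_b.fasta").write_text(fb)
    bench = make_screen_benchmark(dimer, spec)
    (out / "hits_a.tsv").write_text(hits_to_tsv(bench.hits_a))
    (out / "hits_b.tsv").write_text(hits_to_tsv(bench.hits_b))
    (out / "labels.tsv").write_text(labels_to_tsv(bench.labels))
    data = files("pairpssm") / "data"
    for name in ("synthetic_interface_potential.tsv",
                 "synthetic_interface_composition.tsv"):
        shutil.copy(str(data / name), out / name)
    profiles, rows = make_expression_profiles(bench, spec)
    cond = "\t".join(f"c{i}" for i in range(len(next(iter(profiles.values())))))
    lines = [f"gene\t{cond}"]
    for gid in sorted(profiles):
        vals = "\t".join(f"{v:.4f}" for v in profiles[gid])
        lines.append(f"{gid}\t{vals}")
    (out / "expression.tsv").write_text("\n".join(lines) + "\n")
    return out
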