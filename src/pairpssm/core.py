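"""Pair position-specific scoring matrix construction and energies.

For a template with R contact residue pairs, the general 20x20 empirical
potential is replaced by a position-specific matrix with one score table
per contact position.  A residue pair (i, j) at contact position r scores

    score_r(i, j) = ln( Q_ij / (P_i * P_j) )

where the target frequency Q_ij mixes the observed pair frequency f_ij in
the paired profile with a potential-derived pseudocount frequency

    g_ij = P_i * P_j * exp(S_ij),
    Q_ij = (alpha * f_ij + beta * g_ij) / (alpha + beta),

alpha = (number of distinct pair symbols in the column) - 1, beta = 5.
With no informative observations (alpha = 0) the score collapses to S_ij,
i.e. the pair PSSM degenerates to the general empirical matrix.

A candidate protein pair is scored by its specific interfacial energy (sum
of score_r over contact positions where both sides are aligned), which is
normalized by the template's self-energy; the normalized value is the
classification statistic (threshold 0.4-0.5).  The general interfacial
energy sums S over the same covered positions, for comparison.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import BuildError, DegenerateWeights, NormalizationUndefined
from .geometry import TemplateDimer
from .potential import AA_INDEX, AMINO_ACIDS, EmpiricalPotential, GroupScheme, SCHEMES
from .profile import PairColumnCounts, PairedProfile, column_pair_counts

DEFAULT_BETA = 5.0
DEFAULT_THRESHOLD = 0.4


def pseudocount_q(f_ij: float, g_ij: float, alpha: float, beta: float) -> float:
    """Data-dependent pseudocount mix of observed and prior frequencies."""
    if alpha + beta == 0:
        raise DegenerateWeights("alpha + beta must be positive")
    return (alpha * f_ij + beta * g_ij) / (alpha + beta)


def position_scores(counts: PairColumnCounts, pot: EmpiricalPotential,
                    scheme: Optional[GroupScheme],
                    beta: float = DEFAULT_BETA) -> np.ndarray:
    """20x20 log-ratio score table for one contact position.

    Rows index the chain-A residue, columns the chain-B residue, both in
    :data:`~pairpssm.potential.AMINO_ACIDS` order.  Observed frequencies
    are pooled at group-pair level under ``scheme`` (or taken raw when
    ``scheme`` is None); the pseudocount g and the null P stay at residue
    level.
    """
    if counts.n_effective == 0:
        warnings.warn("no effective observations; using pure pseudocount")
        alpha = 0.0
    else:
        alpha = float(counts.alpha)
    P = pot.P
    PP = np.outer(P, P)
    G = PP * np.exp(pot.S)
    F = np.zeros((20, 20))
    if counts.n_effective > 0:
        for ai, a in enumerate(AMINO_ACIDS):
            for bi, b in enumerate(AMINO_ACIDS):
                sym = (a, b) if scheme is None else (scheme.group_of(a), scheme.group_of(b))
                F[ai, bi] = counts.f(sym)
    Q = (alpha * F + beta * G) / (alpha + beta)
    return np.log(Q / PP)


@dataclass
class PositionEntry:
    """One contact position: the template's own pair and its score table."""

    template_pair: tuple  # (aa on chain A, aa on chain B)
    scores: np.ndarray  # (20, 20)


@dataclass
class PairPSSM:
    """Position-specific score tables for one dimer template."""

    template_id: str
    positions: list
    beta: float
    scheme_name: str
    S: np.ndarray  # the empirical potential behind the pseudocounts
    contact_positions: Optional[list] = None  # (pos in A, pos in B) per row
    self_energy: float = field(init=False)

    def __post_init__(self):
        self.self_energy = float(
            sum(
                p.scores[AA_INDEX[p.template_pair[0]], AA_INDEX[p.template_pair[1]]]
                for p in self.positions
            )
        )

    @property
    def R(self) -> int:
        return len(self.positions)

    def score(self, r: int, aa_a: str, aa_b: str) -> float:
        return float(self.positions[r].scores[AA_INDEX[aa_a], AA_INDEX[aa_b]])

    def general(self, aa_a: str, aa_b: str) -> float:
        return float(self.S[AA_INDEX[aa_a], AA_INDEX[aa_b]])

    def to_json(self) -> str:
        return json.dumps(
            {
                "template_id": self.template_id,
                "beta": self.beta,
                "scheme": self.scheme_name,
                "self_energy": self.self_energy,
                "contact_positions": self.contact_positions,
                "S": self.S.tolist(),
                "positions": [
                    {"template_pair": list(p.template_pair),
                     "scores": p.scores.tolist()}
                    for p in self.positions
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PairPSSM":
        obj = json.loads(text)
        pssm = cls(
            template_id=obj["template_id"],
            positions=[
                PositionEntry(tuple(p["template_pair"]),
                              np.asarray(p["scores"], dtype=float))
                for p in obj["positions"]
            ],
            beta=obj["beta"],
            scheme_name=obj["scheme"],
            S=np.asarray(obj["S"], dtype=float),
            contact_positions=[tuple(p) for p in obj["contact_positions"]]
            if obj.get("contact_positions") is not None else None,
        )
        return pssm

    def to_tsv(self) -> str:
        """Flat export: position, template pair, residue pair, score."""
        lines = ["position\ttemplate_a\ttemplate_b\taa_a\taa_b\tscore"]
        for r, p in enumerate(self.positions):
            ta, tb = p.template_pair
            for a in AMINO_ACIDS:
                for b in AMINO_ACIDS:
                    lines.append(
                        f"{r}\t{ta}\t{tb}\t{a}\t{b}\t"
                        f"{p.scores[AA_INDEX[a], AA_INDEX[b]]:.6f}"
                    )
        return "\n".join(lines) + "\n"


def build_pairpssm(dimer: TemplateDimer, profile: PairedProfile,
                   pot: EmpiricalPotential,
                   scheme: Optional[GroupScheme] = SCHEMES["modified"],
                   beta: float = DEFAULT_BETA) -> PairPSSM:
    """Build the pair PSSM for a template from its paired profile."""
    entries = []
    for r, ((pos_a, pos_b), pair) in enumerate(
        zip(dimer.contact_positions(), dimer.contact_map.pairs)
    ):
        if pos_a not in profile.colmap_a or pos_b not in profile.colmap_b:
            raise BuildError(
                f"contact position {r} ({pos_a}, {pos_b}) not covered by profile"
            )
        counts = column_pair_counts(profile, (pos_a, pos_b), scheme,
                                    position_index=r)
        table = position_scores(counts, pot, scheme, beta=beta)
        entries.append(PositionEntry((pair.res_a.aa, pair.res_b.aa), table))
    return PairPSSM(
        template_id=dimer.id,
        positions=entries,
        beta=beta,
        scheme_name=scheme.name if scheme is not None else "raw",
        S=pot.S.copy(),
        contact_positions=list(dimer.contact_positions()),
    )


@dataclass
class CandidateAlignmentPair:
    """A candidate protein pair aligned onto the two template chains.

    ``aln_a``/``aln_b`` map 0-based template positions to
    (candidate position, one-letter residue); template positions absent
    from the mapping are unaligned.
    """

    id_a: str
    id_b: str
    aln_a: dict
    aln_b: dict
    identity_a: float = 100.0
    identity_b: float = 100.0
    evalue_a: float = 0.0
    evalue_b: float = 0.0

    @property
    def same_protein(self) -> bool:
        return self.id_a == self.id_b


@dataclass
class EnergyResult:
    specific_energy: float
    normalized_energy: float
    general_energy: float
    covered_positions: int


def specific_energy(pssm: PairPSSM, cand: CandidateAlignmentPair,
                    dimer: Optional[TemplateDimer] = None) -> EnergyResult:
    """Interfacial energies of a candidate pair against the template.

    Contact positions where either side is unaligned contribute 0; the
    normalization by the template self-energy therefore penalizes
    candidates missing part of the interface (e.g. a lost binding domain).

    ``dimer`` supplies the template contact positions; when omitted, they
    are taken from the PSSM itself (stored at build time), falling back to
    contact-position-index keying (0..R-1 on both sides).
    """
    if pssm.self_energy <= 0:
        raise NormalizationUndefined(
            f"template {pssm.template_id} self-energy {pssm.self_energy:.3f} <= 0"
        )
    if dimer is not None:
        positions = dimer.contact_positions()
    elif pssm.contact_positions is not None:
        positions = pssm.contact_positions
    else:
        positions = [(r, r) for r in range(pssm.R)]
    spec = gen = 0.0
    covered = 0
    for r, (pos_a, pos_b) in enumerate(positions):
        hit_a = cand.aln_a.get(pos_a)
        hit_b = cand.aln_b.get(pos_b)
        if hit_a is None or hit_b is None:
            continue
        aa_a, aa_b = hit_a[1], hit_b[1]
        if aa_a not in AA_INDEX or aa_b not in AA_INDEX:
            continue
        covered += 1
        spec += pssm.score(r, aa_a, aa_b)
        gen += pssm.general(aa_a, aa_b)
    return EnergyResult(
        specific_energy=spec,
        normalized_energy=spec / pssm.self_energy,
        general_energy=gen,
        covered_positions=covered,
    )


def classify(result: EnergyResult, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """True when the normalized specific energy reaches the threshold."""
    return result.normalized_energy >= threshold
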