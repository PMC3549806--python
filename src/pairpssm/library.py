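"""Template-set curation and related-dimer analysis.

Two dimers sharing the same interacting domain pair are "related"; the
overlap of their interfaces under a residue correspondence (from an
external structural or sequence alignment) is measured by pair coverage

    PC = NCP_M**2 / (NCP_AB * NCP_A'B')

where NCP_M counts contact pairs of dimer A-B whose mapped residues are
also a contact pair of A'-B'.  Related pairs with PC >= 0.4 are taken to
share the same interaction type; confidence drops below ~30% minimum
sequence identity between the corresponding chains.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import EmptyCluster, UndefinedPC
from .geometry import ContactMap


@dataclass(frozen=True)
class ClusterMember:
    dimer_id: str
    n_contact_pairs: int
    resolution: float
    cluster_id: str = ""


@dataclass
class CorrespondenceMap:
    """Injective residue-position map from one chain to its counterpart."""

    pairs: dict

    def __post_init__(self):
        values = list(self.pairs.values())
        if len(set(values)) != len(values):
            raise ValueError("correspondence map must be injective")

    def get(self, key):
        return self.pairs.get(key)

    @classmethod
    def from_tsv(cls, path) -> "CorrespondenceMap":
        pairs = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                x, y = line.split("\t")[:2]
                pairs[int(x)] = int(y)
        return cls(pairs)


@dataclass
class PairCoverageResult:
    ncp_m: int
    ncp_ab: int
    ncp_apbp: int

    @property
    def pc(self) -> float:
        return self.ncp_m ** 2 / (self.ncp_ab * self.ncp_apbp)


def _pair_keys(cmap: ContactMap) -> set:
    return {(p.res_a.seq_num, p.res_b.seq_num) for p in cmap.pairs}


def pair_coverage(cp_ab: ContactMap, cp_apbp: ContactMap,
                  map_a: CorrespondenceMap,
                  map_b: CorrespondenceMap) -> PairCoverageResult:
    """Binding-site overlap of two related dimers.

    Contact pairs are matched through the per-chain correspondence maps
    (keyed by author residue numbers).  Raises :class:`UndefinedPC` when
    either interface is empty — the statistic is a missing value then,
    not zero.
    """
    if cp_ab.R == 0 or cp_apbp.R == 0:
        raise UndefinedPC("pair coverage undefined for an empty interface")
    target = _pair_keys(cp_apbp)
    ncp_m = 0
    for p in cp_ab.pairs:
        ma = map_a.get(p.res_a.seq_num)
        mb = map_b.get(p.res_b.seq_num)
        if ma is not None and mb is not None and (ma, mb) in target:
            ncp_m += 1
    return PairCoverageResult(ncp_m=ncp_m, ncp_ab=cp_ab.R, ncp_apbp=cp_apbp.R)


def same_interaction_type(pc: PairCoverageResult,
                          threshold: float = 0.4) -> bool:
    """True when pair coverage reaches the similarity threshold (inclusive)."""
    return pc.pc >= threshold


def min_pair_identity(identity_a: float, identity_b: float) -> float:
    """Sequence identity of a dimer pair: the minimum over the two chains.

    The less-conserved partner is the better indicator of interaction
    diversity.
    """
    return min(identity_a, identity_b)


def select_representative(members) -> ClusterMember:
    """Pick a cluster's representative dimer.

    Among members whose contact-pair count exceeds the cluster mean, the
    one with the best (smallest) resolution wins.  If no member exceeds
    the mean (e.g. all counts equal), fall back to smallest resolution
    overall.  Ties break on lexicographic dimer id.
    """
    members = list(members)
    if not members:
        raise EmptyCluster("cannot select a representative from no members")
    mean = sum(m.n_contact_pairs for m in members) / len(members)
    eligible = [m for m in members if m.n_contact_pairs > mean] or members
    return min(eligible, key=lambda m: (m.resolution, m.dimer_id))
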