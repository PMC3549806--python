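"""Empirical interfacial pair potentials and reduced amino-acid alphabets.

The scoring system mixes observed residue-pair frequencies with a prior
derived from a 20x20 empirical interfacial pair potential ``S`` and an
interface background composition ``P``.  Both are plain TSV inputs: the
matrix file has one-letter codes as header row and column, the composition
file is two columns (code, fraction).

The repository bundles a *synthetic* stand-in potential
(``data/synthetic_interface_potential.tsv``) constructed from group-level
base energies plus small per-residue offsets; supply a published interfacial
potential in the same format to work with real energies.  The bundled matrix
uses the log-propensity convention: larger (more positive) values mean the
pair is enriched at interfaces.
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Canonical residue order used for every 20x20 table in the package.
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class GroupScheme:
    """A partition of the 20 standard amino acids into 9 groups.

    Conservative substitutions stay within a group; counting residue pairs
    at group level tolerates them when estimating observed frequencies.
    """

    name: str
    groups: tuple[frozenset, ...]
    aa_to_group: dict = field(default=None, compare=False)

    def __post_init__(self):
        if len(self.groups) != 9:
            raise ValidationError(f"scheme {self.name!r} must have 9 groups")
        members = [a for g in self.groups for a in g]
        if sorted(members) != sorted(AMINO_ACIDS):
            raise ValidationError(
                f"scheme {self.name!r} is not a partition of the 20 amino acids"
            )
        object.__setattr__(
            self,
            "aa_to_group",
            {a: gi for gi, g in enumerate(self.groups) for a in g},
        )

    def group_of(self, aa: str) -> int:
        return self.aa_to_group[aa]


def _scheme(name, *parts):
    return GroupScheme(name, tuple(frozenset(p) for p in parts))


#: Environment-similarity classification of Saha et al.
SAHA_SCHEME = _scheme(
    "saha", "AV", "MLI", "GST", "PFYW", "C", "H", "RK", "DE", "NQ"
)

#: 9-group classification adjusted so within-group interfacial potentials
#: are tight (Ala regrouped with Gly, Val with the aliphatics, Pro with the
#: small polars, His with Arg, Lys alone).
MODIFIED_SCHEME = _scheme(
    "modified", "AG", "VMLI", "PST", "FYW", "C", "HR", "K", "DE", "NQ"
)

SCHEMES = {"saha": SAHA_SCHEME, "modified": MODIFIED_SCHEME}


@dataclass
class EmpiricalPotential:
    """A 20x20 interfacial pair potential with background composition.

    Attributes
    ----------
    S : ndarray, shape (20, 20)
        Pair potentials indexed by :data:`AMINO_ACIDS`; symmetric.
    P : ndarray, shape (20,)
        Interface background composition; positive, sums to 1.
    source : str
        Provenance note (file paths, symmetrization applied, ...).
    favorable_direction : str
        ``"positive"`` if larger S means more favorable binding (the
        log-propensity convention of the bundled stand-in), ``"negative"``
        for energy-like matrices where lower is more favorable.
    """

    S: np.ndarray
    P: np.ndarray
    source: str = ""
    favorable_direction: str = "positive"

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.S.shape != (20, 20):
            raise ValidationError("S must be 20x20")
        if self.P.shape != (20,):
            raise ValidationError("P must have 20 entries")
        if not np.allclose(self.S, self.S.T):
            raise ValidationError("S must be symmetric")
        if np.any(self.P <= 0):
            raise ValidationError("all composition entries must be positive")
        if abs(self.P.sum() - 1.0) > 1e-6:
            raise ValidationError(
                f"composition must sum to 1 (got {self.P.sum():.6f})"
            )

    def s(self, aa_i: str, aa_j: str) -> float:
        return float(self.S[AA_INDEX[aa_i], AA_INDEX[aa_j]])

    def p(self, aa: str) -> float:
        return float(self.P[AA_INDEX[aa]])


def load_potential(matrix_file, composition_file, favorable_direction="positive") -> EmpiricalPotential:
    """Load and validate a pair potential and composition from TSV files.

    An asymmetric matrix is symmetrized by averaging ``(S + S.T) / 2``; this
    is recorded in ``source``.
    """
    mat = pd.read_csv(matrix_file, sep="\t", index_col=0)
    mat.index = mat.index.astype(str).str.strip()
    mat.columns = mat.columns.astype(str).str.strip()
    missing = set(AMINO_ACIDS) - set(mat.index) | set(AMINO_ACIDS) - set(mat.columns)
    if missing:
        raise FormatError(f"matrix missing amino acids: {sorted(missing)}")
    S = mat.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)].to_numpy(dtype=float)

    comp = pd.read_csv(composition_file, sep="\t", header=None, names=["aa", "frac"])
    comp["aa"] = comp["aa"].astype(str).str.strip()
    comp = comp.set_index("aa")
    missing = set(AMINO_ACIDS) - set(comp.index)
    if missing:
        raise FormatError(f"composition missing amino acids: {sorted(missing)}")
    P = comp.loc[list(AMINO_ACIDS), "frac"].to_numpy(dtype=float)

    source = f"matrix={matrix_file}, composition={composition_file}"
    if not np.allclose(S, S.T):
        S = (S + S.T) / 2.0
        source += "; symmetrized by averaging"
    return EmpiricalPotential(S=S, P=P, source=source,
                              favorable_direction=favorable_direction)


def bundled_potential() -> EmpiricalPotential:
    """The synthetic stand-in potential shipped with the package."""
    data = importlib.resources.files("pairpssm") / "data"
    return load_potential(
        str(data / "synthetic_interface_potential.tsv"),
        str(data / "synthetic_interface_composition.tsv"),
    )


def _cell_values(S: np.ndarray, group_g, group_h):
    """Pool S over unordered residue combinations of two groups."""
    g = sorted(group_g)
    h = sorted(group_h)
    if set(g) == set(h):
        pairs = itertools.combinations_with_replacement(g, 2)
    else:
        pairs = itertools.product(g, h)
    return np.array([S[AA_INDEX[a], AA_INDEX[b]] for a, b in pairs])


def group_sd_table(pot: EmpiricalPotential, scheme: GroupScheme) -> np.ndarray:
    """9x9 table of within-cell spreads of the pair potential.

    Cell (g, h) is the population standard deviation of the potentials of
    all unordered residue combinations drawn from groups g and h.  A tight
    table means the classification is a faithful reduced alphabet for the
    potential: substituting within a group barely changes the pair energy.
    """
    n = len(scheme.groups)
    out = np.zeros((n, n))
    for gi in range(n):
        for hi in range(gi, n):
            vals = _cell_values(pot.S, scheme.groups[gi], scheme.groups[hi])
            sd = float(np.std(vals))  # population SD (ddof=0)
            out[gi, hi] = out[hi, gi] = sd
    return out


def compare_schemes(pot: EmpiricalPotential, low=0.3, high=0.5) -> dict:
    """Within-cell SD tables for both classifications plus banding counts.

    Bands follow the conventional coloring: below ``low``, between ``low``
    and ``high`` inclusive, and above ``high``.
    """
    report = {}
    for name, scheme in SCHEMES.items():
        table = group_sd_table(pot, scheme)
        tri = table[np.triu_indices_from(table)]
        report[name] = {
            "table": table,
            "bands": {
                "below": int(np.sum(tri < low)),
                "mid": int(np.sum((tri >= low) & (tri <= high))),
                "above": int(np.sum(tri > high)),
            },
            "max_sd": float(table.max()),
        }
    return report
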