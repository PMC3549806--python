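"""Candidate generation, ranking and evaluation statistics.

A template dimer A-B is used as a query against a target proteome: every
protein homologous to A (E-value at most 1e-3) crossed with every protein
homologous to B yields the candidate interolog pairs.  Scored candidates
are ranked and evaluated against gold-standard labels with average
precision (AP) and a normalized false-positive rank mass (FP):

    AP = (1/A) * sum_i i / T_i
    FP = (1/A) * sum_i (T_i - i) / (K - A)

where T_i is the rank of the i-th positive, A the number of positives and
K the list length.  MAP/MFP are means over templates.  A balanced
error-rate sweep locates the classification threshold, and gene-expression
profile correlation with a Welch t-test provides an orthogonal check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .core import CandidateAlignmentPair
from .errors import (EmptyClass, FPUndefined, NoEvaluableTemplates,
                     ValidationError)

POSITIVE, NEGATIVE, UNANNOTATED = "positive", "negative", "unannotated"


@dataclass
class HomologyHit:
    """One homology-search hit of a template chain against a target protein.

    ``aligned_pairs`` maps template positions (0-based) to
    (subject position, subject residue).
    """

    template_chain: str  # 'A' or 'B'
    subject_id: str
    evalue: float
    identity: float
    aligned_pairs: dict

    def __post_init__(self):
        if self.evalue < 0:
            raise ValidationError("evalue must be >= 0")
        if not 0 <= self.identity <= 100:
            raise ValidationError("identity must be in [0, 100]")


def read_hits_tsv(path) -> list:
    """Native hit table: chain, subject, evalue, identity, pairs.

    ``pairs`` is comma-separated ``tpos:spos:RES`` triples.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chain, subject, ev, ident, pairs = line.split("\t")[:5]
            aligned = {}
            for item in pairs.split(","):
                if not item:
                    continue
                t, s, res = item.split(":")
                aligned[int(t)] = (int(s), res)
            hits.append(HomologyHit(chain, subject, float(ev), float(ident), aligned))
    return hits


def hits_from_blast_tab(path, template_chain: str, subject_seqs: dict) -> list:
    """Parse 12-column BLAST tabular output (outfmt 6) into hits.

    Alignment coordinates are expanded assuming gapless segments between
    qstart..qend and sstart..send (tabular output carries no gap trace);
    subject residues come from ``subject_seqs`` (id -> sequence).
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            subject = f[1]
            ident = float(f[2])
            qstart, qend = int(f[6]), int(f[7])
            sstart, send = int(f[8]), int(f[9])
            evalue = float(f[10])
            if subject not in subject_seqs:
                continue
            seq = subject_seqs[subject]
            aligned = {}
            span = min(qend - qstart, send - sstart)
            for off in range(span + 1):
                spos = sstart - 1 + off
                if spos < len(seq):
                    aligned[qstart - 1 + off] = (spos, seq[spos])
            hits.append(HomologyHit(template_chain, subject, evalue, ident, aligned))
    return hits


def build_candidates(hits_a, hits_b, evalue_max: float = 1e-3) -> list:
    """Cartesian product of A-side and B-side hits passing the E-value filter.

    Pairs where both chains hit the same protein are allowed (homodimer-like
    candidates); they are flagged via ``CandidateAlignmentPair.same_protein``
    so downstream expression analysis can exclude them.
    """
    keep_a = [h for h in hits_a if h.evalue <= evalue_max]
    keep_b = [h for h in hits_b if h.evalue <= evalue_max]
    out = []
    for ha in keep_a:
        for hb in keep_b:
            out.append(
                CandidateAlignmentPair(
                    id_a=ha.subject_id, id_b=hb.subject_id,
                    aln_a=dict(ha.aligned_pairs), aln_b=dict(hb.aligned_pairs),
                    identity_a=ha.identity, identity_b=hb.identity,
                    evalue_a=ha.evalue, evalue_b=hb.evalue,
                )
            )
    return out


def apply_identity_limit(cands, limit: float) -> list:
    """Drop candidates where either chain identity exceeds the limit.

    Used to probe remote-homology performance (limits 95/50/40/30); the
    comparison is strictly greater, so identity exactly at the limit stays.
    """
    return [c for c in cands if c.identity_a <= limit and c.identity_b <= limit]


@dataclass
class RankedHitList:
    """Scored, labelled candidates sorted for evaluation.

    Ties in score rank negatives (and unannotated) before positives, so
    reported AP is pessimistic.  ``unannotated`` handling: "as_negative"
    keeps them in the list counted as negatives; "drop" removes them
    before ranking (the gold-negatives-only analysis).
    """

    entries: list = field(default_factory=list)  # (id pair, score, label)

    @classmethod
    def from_scored(cls, scored, unannotated: str = "as_negative") -> "RankedHitList":
        if unannotated not in ("as_negative", "drop"):
            raise ValueError("unannotated must be 'as_negative' or 'drop'")
        entries = list(scored)
        if unannotated == "drop":
            entries = [e for e in entries if e[2] != UNANNOTATED]
        entries.sort(key=lambda e: (-e[1], e[2] == POSITIVE))
        return cls(entries=entries)

    @property
    def K(self) -> int:
        return len(self.entries)

    @property
    def A(self) -> int:
        return sum(1 for e in self.entries if e[2] == POSITIVE)

    def positive_ranks(self) -> list:
        return [i + 1 for i, e in enumerate(self.entries) if e[2] == POSITIVE]


def average_precision(ranked: RankedHitList):
    """(AP, FP) of one template's ranked candidate list."""
    K, A = ranked.K, ranked.A
    if A == 0:
        raise NoEvaluableTemplates("hit list has no positives")
    if K == A:
        raise FPUndefined("hit list has no negatives; FP undefined")
    ranks = ranked.positive_ranks()
    ap = sum(i / t for i, t in enumerate(ranks, start=1)) / A
    fp = sum((t - i) / (K - A) for i, t in enumerate(ranks, start=1)) / A
    return ap, fp


def mean_metrics(per_template):
    """(MAP, MFP, M) over per-template (AP, FP) values."""
    per_template = list(per_template)
    if not per_template:
        raise NoEvaluableTemplates("no templates to average")
    aps = [x[0] for x in per_template]
    fps = [x[1] for x in per_template]
    return float(np.mean(aps)), float(np.mean(fps)), len(per_template)


@dataclass
class ErrorSweep:
    thresholds: list
    error_rates: list
    best_threshold: float
    min_error: float


def error_sweep(pos_scores, neg_scores, thresholds,
                literal_denominators: bool = False) -> ErrorSweep:
    """Balanced error rate over a threshold sweep.

    error(t) = (FN(t)/|pos| + FP(t)/|neg|) / 2 with a prediction positive
    iff score >= t.  ``literal_denominators=True`` swaps the denominators
    (FP/|pos| + FN/|neg|)/2 — a non-standard variant kept for comparison.
    Ties in the minimum resolve to the smallest threshold.
    """
    pos = np.asarray(list(pos_scores), dtype=float)
    neg = np.asarray(list(neg_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise EmptyClass("both score classes must be nonempty")
    thresholds = sorted(thresholds)
    errors = []
    for t in thresholds:
        fn = np.sum(pos < t)
        fp = np.sum(neg >= t)
        if literal_denominators:
            errors.append((fp / pos.size + fn / neg.size) / 2)
        else:
            errors.append((fn / pos.size + fp / neg.size) / 2)
    errors = [float(e) for e in errors]
    best = int(np.argmin(errors))  # argmin returns the first (smallest t)
    return ErrorSweep(thresholds=list(thresholds), error_rates=errors,
                      best_threshold=thresholds[best], min_error=errors[best])


@dataclass
class ExpressionTestResult:
    correlations: list
    null_correlations: list
    t_score: float
    p_value: float
    n_dropped_constant: int = 0


def _pair_correlations(pairs):
    rs, dropped = [], 0
    for x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            dropped += 1
            continue
        xs, ys = x[ok], y[ok]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            dropped += 1
            continue
        rs.append(float(stats.pearsonr(xs, ys)[0]))
    return rs, dropped


def expression_test(pairs, null_pairs) -> ExpressionTestResult:
    """Do predicted interactors co-express more than non-interacting pairs?

    Pearson r per pair on pairwise-complete observations, then a one-sided
    Welch two-sample t-test of mean r (predictions) vs mean r (null).
    Pairs with fewer than 3 complete observations or a constant profile
    are dropped and counted.  Self-pairs (the same gene twice) must be
    excluded by the caller: their correlation is identically 1.
    """
    rs, d1 = _pair_correlations(pairs)
    null_rs, d2 = _pair_correlations(null_pairs)
    if not rs or not null_rs:
        raise EmptyClass("need correlations in both the prediction and null sets")
    t, p = stats.ttest_ind(rs, null_rs, equal_var=False, alternative="greater")
    return ExpressionTestResult(
        correlations=rs, null_correlations=null_rs,
        t_score=float(t), p_value=float(p),
        n_dropped_constant=d1 + d2,
    )


def screen_and_rank(pssm, candidates, labels: dict, dimer=None,
                    unannotated: str = "as_negative",
                    use_general: bool = False) -> RankedHitList:
    """Score candidates with a pair PSSM and rank them for evaluation.

    ``labels`` maps (id_a, id_b) to positive/negative; unlisted pairs are
    unannotated.  ``use_general=True`` ranks by the general interfacial
    energy from the empirical matrix instead (the baseline).
    """
    from .core import specific_energy

    scored = []
    for cand in candidates:
        res = specific_energy(pssm, cand, dimer=dimer)
        score = res.general_energy if use_general else res.normalized_energy
        label = labels.get((cand.id_a, cand.id_b), UNANNOTATED)
        scored.append(((cand.id_a, cand.id_b), score, label))
    return RankedHitList.from_scored(scored, unannotated=unannotated)
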