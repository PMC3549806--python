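"""Screen candidate protein pairs and compare specific vs general energy.

Candidates (the cross product of per-chain homology hits at E <= 1e-3)
are scored by normalized specific interfacial energy; pairs at or above
0.4 are called interacting.  Positives conserve the template interface;
negatives either lost part of it (missing-domain mode) or carry
cross-group interface mutations a generic potential tolerates — ranking
by the position-specific energy separates them better.
"""

import numpy as np

from pairpssm import average_precision, build_candidates, screen_and_rank
from pairpssm.core import classify, specific_energy
from pairpssm.fixtures import (FixtureSpec, build_fixture_pssm,
                               make_screen_benchmark, make_toy_dimer)

spec = FixtureSpec(seed=7)
toy = make_toy_dimer(spec)
dimer, pssm = build_fixture_pssm(toy, spec)
bench = make_screen_benchmark(toy, spec)

candidates = build_candidates(bench.hits_a, bench.hits_b, evalue_max=1e-3)
print(f"candidates from {len(bench.hits_a)} x {len(bench.hits_b)} hits: "
      f"{len(candidates)}")

pos, neg = [], []
for cand in candidates:
    label = bench.labels.get((cand.id_a, cand.id_b))
    if label is None:
        continue
    res = specific_energy(pssm, cand, dimer=dimer)
    (pos if label == "positive" else neg).append(res.normalized_energy)
print(f"positives: mean normalized energy {np.mean(pos):.3f}, "
      f"{100 * np.mean(np.array(pos) >= 0.4):.0f}% called at threshold 0.4")
print(f"negatives: mean normalized energy {np.mean(neg):.3f}, "
      f"{100 * np.mean(np.array(neg) < 0.4):.0f}% rejected")

ranked_specific = screen_and_rank(pssm, candidates, bench.labels,
                                  dimer=dimer, unannotated="drop")
ranked_general = screen_and_rank(pssm, candidates, bench.labels,
                                 dimer=dimer, unannotated="drop",
                                 use_general=True)
ap_s, fp_s = average_precision(ranked_specific)
ap_g, fp_g = average_precision(ranked_general)
print(f"specific energy ranking: AP {ap_s:.3f}, FP {fp_s:.3f}")
print(f"general energy ranking:  AP {ap_g:.3f}, FP {fp_g:.3f}")
print("the gap comes from mutated-interface negatives: generic pair "
      "potentials cannot tell them from conserved interfaces")
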