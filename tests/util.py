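"""Shared test helpers and independent oracles.

The oracles here deliberately use naive enumeration so they stay independent
of the library's vectorised implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from lohtrack import (
    Genotype,
    LOHTract,
    PairedGenotypeTable,
    TERMINATORS,
    TractSet,
    TransitionType,
    classify_transition,
)

G = Genotype


def make_table(
    positions,
    germline,
    tissue,
    chrom: int = 1,
    patient: str = "P1",
    sample: str = "Td",
) -> PairedGenotypeTable:
    """Build a one-chromosome paired table from explicit call lists."""
    positions = list(positions)
    loci = pd.DataFrame(
        {
            "chrom": [chrom] * len(positions),
            "pos": positions,
            "variant_id": [f"v{i}" for i in range(len(positions))],
            "vtype": "SNP",
        }
    )
    return PairedGenotypeTable(
        patient=patient,
        loci=loci,
        germline=np.array([int(g) for g in germline], dtype=np.uint8),
        tissues={sample: np.array([int(t) for t in tissue], dtype=np.uint8)},
    )


def tract(start, end, chrom=1, arm="p", n_events=2, patient="P1", sample="Td",
          copy_state="neutral") -> LOHTract:
    return LOHTract(
        chrom=chrom, arm=arm, start=start, end=end, n_events=n_events,
        copy_state=copy_state, patient=patient, sample=sample,
    )


def tract_set(intervals, patient="P1", sample="Td", **kw) -> TractSet:
    return TractSet(
        patient=patient,
        sample=sample,
        tracts=[tract(s, e, patient=patient, sample=sample, **kw) for s, e in intervals],
    )


def oracle_scan(positions, transitions, min_events):
    """Brute-force enumeration of maximal terminator-free HET->HOM runs.

    Considers every (first event, last event) pair, checks that no
    terminating transition lies strictly between them and that the run can
    be extended in neither direction, then applies the support criterion.
    Returns [(start, end, n_events), ...] sorted by start.
    """
    n = len(transitions)
    events = [i for i in range(n) if transitions[i] == TransitionType.HET_TO_HOM]
    terms = [i for i in range(n) if TransitionType(int(transitions[i])) in TERMINATORS]

    def clear(i, j):  # no terminator strictly between locus indices i and j
        return not any(i < k < j for k in terms)

    runs = []
    for a_idx, a in enumerate(events):
        for b_idx in range(a_idx, len(events)):
            b = events[b_idx]
            if not clear(a, b):
                continue
            # maximality: no compatible event beyond either edge
            left_ext = any(clear(e, a) for e in events if e < a)
            right_ext = any(clear(b, e) for e in events if e > b)
            if left_ext or right_ext:
                continue
            count = sum(1 for e in events if a <= e <= b)
            if count >= min_events:
                runs.append((positions[a], positions[b], count))
    return sorted(set(runs))


def random_paired_vectors(rng, max_loci=50):
    """Random positions and paired genotype codes for oracle comparisons."""
    n = int(rng.integers(1, max_loci + 1))
    positions = np.sort(rng.choice(np.arange(1, 10 * max_loci), size=n, replace=False))
    germ = rng.integers(0, 4, size=n).astype(np.uint8)
    tiss = rng.integers(0, 4, size=n).astype(np.uint8)
    return positions, germ, tiss


def oracle_chi2_gof(n_member, n_total, p0):
    """Hand-rolled df=1 goodness-of-fit chi-square and p-value."""
    exp = [n_total * p0, n_total * (1 - p0)]
    obs = [n_member, n_total - n_member]
    stat = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
    return stat, float(chi2_dist.sf(stat, df=1))


def exact_overlap_probability(L, M, E):
    """Exact P(overlap) for two intervals of lengths L and M placed uniformly
    and independently on an eligible range of E positions, by enumeration of
    the first interval's start."""
    nA = E - L + 1
    nB = E - M + 1
    total = 0
    for a in range(1, nA + 1):
        lo = max(1, a - M + 1)
        hi = min(nB, a + L - 1)
        total += max(0, hi - lo + 1)
    return total / (nA * nB)


def relabel_alleles(codes):
    """Swap allele labels A<->B: AA<->BB, AB and NC fixed."""
    mapping = {0: 2, 1: 1, 2: 0, 3: 3}
    return np.array([mapping[int(c)] for c in codes], dtype=np.uint8)
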