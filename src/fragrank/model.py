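"""Probabilistic spectrum-molecule matching.

The generative model assumes each fragment's logRank depends only on the
bond type that produced it and on its parent's logRank (the root carries
logRank 0), and that peak logRanks are otherwise independent.  Training
therefore reduces to counting fragments per (bondType, logRank_pa) cell and
normalizing; the background (null) model is the logRank distribution of all
training peaks.  A match is scored by the log-likelihood ratio

    score = sum over non-root fragments of
            log P(logRank | bondType, logRank_pa) / P(logRank | null)

Peaks not explained by any fragment contribute a ratio of one and drop out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fraggraph import BOND_TYPE_LABELS, FragmentationGraph
from .spectra import (
    ABSENT_LOG_RANK,
    MAX_LOG_RANK,
    Spectrum,
    fragment_mz,
)

#: Default m/z window for matching a peak to a fragment, in Da.
FRAGMENT_TOLERANCE = 0.01

_BOND_INDEX = {b: i for i, b in enumerate(BOND_TYPE_LABELS)}
N_BOND_TYPES = len(BOND_TYPE_LABELS)  # 9
N_LOG_RANKS = 7  # l in 1..7 (7 = no matching peak)
N_PA = 8  # parent logRank in 0..7 (0 = root)


@dataclass
class AnnotatedGraph:
    """A fragmentation graph aligned to one spectrum.

    Parallel to ``fg.fragments``: ``log_rank`` (root entry is 0, absent
    fragments get 7), ``matched_peak`` (peak index or None) and
    ``log_rank_pa`` (0 for depth-1 fragments).  ``null_peaks`` lists the
    spectrum peak indices not matched by any fragment.
    """

    fg: FragmentationGraph
    spectrum_id: str
    log_rank: list[int]
    matched_peak: list[int | None]
    log_rank_pa: list[int]
    null_peaks: list[int]


def annotate(
    fg: FragmentationGraph,
    s: Spectrum,
    fragment_tolerance: float = FRAGMENT_TOLERANCE,
    seed: int = 0,
) -> AnnotatedGraph:
    """Match spectrum peaks to fragments within an m/z tolerance.

    Peaks are considered from the most intense down; each peak annotates at
    most one fragment and each fragment takes at most one peak.  When
    several fragments fall within tolerance of a peak, the lowest-depth one
    wins; equal-depth ties are resolved by a seeded uniform draw.  Fragments
    without a peak are annotated logRank 7; a fragment's logRank_pa is the
    smallest logRank among its minimum-depth parents (root = 0).
    """
    if s.log_ranks is None:
        raise ValueError(f"spectrum {s.id}: assign_log_ranks first")
    rng = np.random.default_rng(seed)
    n = len(fg.fragments)
    z = max(1, s.charge)
    frag_mzs = np.array(
        [fragment_mz(f.mass, z) for f in fg.fragments], dtype=float
    )
    sort_idx = np.argsort(frag_mzs[1:]) + 1  # root never matches a peak
    sorted_mzs = frag_mzs[sort_idx]

    log_rank = [ABSENT_LOG_RANK] * n
    log_rank[0] = 0
    matched_peak: list[int | None] = [None] * n
    taken = [False] * n

    rankable = [
        (s.ranks[k], k) for k in range(s.n_peaks) if s.log_ranks[k] is not None
    ]
    matched_peaks: set[int] = set()
    for _, k in sorted(rankable):
        mz = s.peaks[k].mz
        lo = np.searchsorted(sorted_mzs, mz - fragment_tolerance, side="left")
        hi = np.searchsorted(sorted_mzs, mz + fragment_tolerance, side="right")
        cands = [
            int(sort_idx[j]) for j in range(lo, hi) if not taken[sort_idx[j]]
        ]
        if not cands:
            continue
        min_depth = min(fg.fragments[c].depth for c in cands)
        best = sorted(c for c in cands if fg.fragments[c].depth == min_depth)
        chosen = best[0] if len(best) == 1 else int(rng.choice(best))
        taken[chosen] = True
        log_rank[chosen] = s.log_ranks[k]
        matched_peak[chosen] = k
        matched_peaks.add(k)

    log_rank_pa = [0] * n
    for i in range(1, n):
        parents = fg.fragments[i].parents
        log_rank_pa[i] = (
            min(log_rank[p] for p in parents) if parents else 0
        )

    null_peaks = [k for k in range(s.n_peaks) if k not in matched_peaks]
    return AnnotatedGraph(
        fg=fg,
        spectrum_id=s.id,
        log_rank=log_rank,
        matched_peak=matched_peak,
        log_rank_pa=log_rank_pa,
        null_peaks=null_peaks,
    )


@dataclass
class ScoringModel:
    """Conditional and null logRank tables.

    ``cond[b, p, l-1]`` = P(logRank = l | bondType b, logRank_pa p) over the
    nine bond-type labels and parent logRanks 0..7; ``null[l-1]`` =
    P(logRank = l | background).  ``counts`` keeps the raw training counts.
    """

    cond: np.ndarray  # (9, 8, 7)
    null: np.ndarray  # (7,)
    counts: np.ndarray  # (9, 8, 7)
    pseudocount: float
    fragment_tolerance: float = FRAGMENT_TOLERANCE
    rules_digest: str = ""
    metadata: dict = field(default_factory=dict)

    def cond_prob(self, bond_type: str, pa: int, log_rank: int) -> float:
        return float(self.cond[_BOND_INDEX[bond_type], pa, log_rank - 1])

    def null_prob(self, log_rank: int) -> float:
        return float(self.null[log_rank - 1])


def train(
    pairs: Sequence[tuple[FragmentationGraph, Spectrum]],
    pseudocount: float = 1.0,
    fragment_tolerance: float = FRAGMENT_TOLERANCE,
    seed: int = 0,
) -> ScoringModel:
    """Count-based maximum-likelihood fit of the conditional tables.

    ``cond[l | b, p] = (count(l,b,p) + pc) / (count(.,b,p) + 7 pc)``; a cell
    never observed falls back to the uniform pseudocount distribution.  The
    null row for logRanks 1..6 is the (smoothed) logRank distribution of all
    training peaks, scaled by the complement of the global probability that
    a fragment finds no peak, which becomes null[7].
    """
    if not pairs:
        raise ValueError("empty training set")
    counts = np.zeros((N_BOND_TYPES, N_PA, N_LOG_RANKS))
    peak_counts = np.zeros(MAX_LOG_RANK)
    n_absent = 0
    n_frag = 0
    digest = pairs[0][0].rules_digest
    for i, (fg, s) in enumerate(pairs):
        if fg.rules_digest != digest:
            raise ValueError(
                "training graphs were built with different rule tables"
            )
        ann = annotate(fg, s, fragment_tolerance, seed=seed + i)
        for j in range(1, len(fg.fragments)):
            frag = fg.fragments[j]
            b = _BOND_INDEX[frag.bond_type]
            counts[b, ann.log_rank_pa[j], ann.log_rank[j] - 1] += 1
            n_frag += 1
            if ann.log_rank[j] == ABSENT_LOG_RANK:
                n_absent += 1
        for lr in s.log_ranks:
            if lr is not None:
                peak_counts[lr - 1] += 1

    pc = pseudocount
    totals = counts.sum(axis=2, keepdims=True)
    denom = totals + N_LOG_RANKS * pc
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = (counts + pc) / denom
    # unobserved (b, p) cells with zero pseudocount: uniform fallback
    cond = np.where(denom > 0, cond, 1.0 / N_LOG_RANKS)

    if pc > 0:
        p_absent = (n_absent + pc) / (n_frag + 2 * pc)
        peak_frac = (peak_counts + pc) / (peak_counts.sum() + MAX_LOG_RANK * pc)
    else:
        p_absent = n_absent / n_frag if n_frag else 0.0
        peak_frac = (
            peak_counts / peak_counts.sum()
            if peak_counts.sum()
            else np.full(MAX_LOG_RANK, 1.0 / MAX_LOG_RANK)
        )
    null = np.concatenate([(1.0 - p_absent) * peak_frac, [p_absent]])

    return ScoringModel(
        cond=cond,
        null=null,
        counts=counts,
        pseudocount=pc,
        fragment_tolerance=fragment_tolerance,
        rules_digest=digest,
        metadata={"n_pairs": len(pairs), "n_fragments": int(n_frag)},
    )


def score(
    fg: FragmentationGraph,
    s: Spectrum,
    m: ScoringModel,
    seed: int = 0,
    annotated: AnnotatedGraph | None = None,
) -> float:
    """Log-likelihood-ratio score of a molecule-spectrum pair.

    Additive over non-root fragments; unmatched peaks contribute nothing.
    Raises if the null table has a zero entry for an observed logRank
    (retrain with a nonzero pseudocount).
    """
    ann = annotated or annotate(fg, s, m.fragment_tolerance, seed)
    total = 0.0
    for j in range(1, len(fg.fragments)):
        frag = fg.fragments[j]
        l = ann.log_rank[j]
        p_cond = m.cond_prob(frag.bond_type, ann.log_rank_pa[j], l)
        p_null = m.null_prob(l)
        if p_null == 0.0:
            raise ValueError(
                f"null probability of logRank {l} is zero; "
                "retrain with a nonzero pseudocount"
            )
        total += float(np.log(p_cond / p_null))
    return total


# ---------------------------------------------------------------------------
# Model file I/O


def save_model(m: ScoringModel, path) -> None:
    payload = {
        "cond": m.cond.tolist(),
        "null": m.null.tolist(),
        "counts": m.counts.tolist(),
        "pseudocount": m.pseudocount,
        "fragment_tolerance": m.fragment_tolerance,
        "rules_digest": m.rules_digest,
        "metadata": m.metadata,
        "bond_type_labels": list(BOND_TYPE_LABELS),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path, expected_rules_digest: str | None = None) -> ScoringModel:
    with open(path) as fh:
        payload = json.load(fh)
    if (
        expected_rules_digest is not None
        and payload.get("rules_digest") != expected_rules_digest
    ):
        raise ValueError(
            f"model at {path} was trained with rule digest "
            f"{payload.get('rules_digest')}, expected {expected_rules_digest}"
        )
    return ScoringModel(
        cond=np.array(payload["cond"]),
        null=np.array(payload["null"]),
        counts=np.array(payload["counts"]),
        pseudocount=payload["pseudocount"],
        fragment_tolerance=payload["fragment_tolerance"],
        rules_digest=payload.get("rules_digest", ""),
        metadata=payload.get("metadata", {}),
    )
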