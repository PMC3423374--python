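"""Mapping pseudogene-bearing contigs onto full-length reference genes.

Dinoflagellate mitochondrial genomes are dominated by gene fragments embedded
in unrelated flanking sequence. This module locates those fragments by local
alignment against the intact reference genes (both strands, several
non-overlapping matches per contig allowed), classifies how conserved each
match is, and summarises where on each gene the fragments come from as a
coverage profile with a formal uniformity ("no hot spot") test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._align import align_local
from .io import reverse_complement

__all__ = [
    "PseudogeneMatch",
    "CoverageProfile",
    "map_fragments",
    "classify_match",
    "coverage_profile",
]

#: classification thresholds, config-exposed
CONSERVED_MIN_IDENTITY = 90.0
DEGENERATE_MAX_IDENTITY = 60.0
MIN_MATCH_NT = 50
MIN_MATCH_IDENTITY = 40.0


@dataclass
class PseudogeneMatch:
    """One local alignment of a contig fragment onto a reference gene."""

    fragment: str
    gene: str
    fragment_interval: tuple[int, int]  # 1-based inclusive, on input strand
    gene_interval: tuple[int, int]  # 1-based inclusive
    gene_aa_interval: tuple[int, int]  # first/last aa touched on the gene
    orientation: str  # '+' or '-'
    identity_pct: float
    left_flank_nt: int
    right_flank_nt: int
    score: float
    conservation: str = ""

    def __post_init__(self) -> None:
        if not self.conservation:
            self.conservation = classify_match(self)


def classify_match(match: "PseudogeneMatch | float",
                   conserved_min: float = CONSERVED_MIN_IDENTITY,
                   degenerate_max: float = DEGENERATE_MAX_IDENTITY) -> str:
    """conserved (>= 90% identity), degenerate (< 60%) or intermediate."""
    identity = match if isinstance(match, (int, float)) else match.identity_pct
    if identity >= conserved_min:
        return "conserved"
    if identity < degenerate_max:
        return "degenerate"
    return "intermediate"


#: boundary convention: reported match ends sit on a run of this many
#: consecutive identities, so a chance flank match (even one reached over a
#: short gap) cannot drag the boundary
END_RUN = 10


def _trimmed_columns(hit, target: str, query: str):
    """Alignment columns as (kind, t_index, q_index), with noisy ends removed:
    the retained alignment starts and ends on END_RUN consecutive matches."""
    cols = []
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in hit.blocks:
        if prev_t is not None:
            cols.extend(("gap", t, None) for t in range(prev_t, t0))
            cols.extend(("gap", None, q) for q in range(prev_q, q0))
        for t, q in zip(range(t0, t1), range(q0, q1)):
            kind = "match" if target[t] == query[q] else "mismatch"
            cols.append((kind, t, q))
        prev_t, prev_q = t1, q1

    def clean_run_at(i: int) -> bool:
        window = cols[i:i + END_RUN]
        return len(window) == END_RUN and all(c[0] == "match" for c in window)

    start = 0
    while start + END_RUN <= len(cols) and not clean_run_at(start):
        start += 1
    end = len(cols)
    while end - END_RUN >= start and not all(
            c[0] == "match" for c in cols[end - END_RUN:end]):
        end -= 1
    if start + END_RUN > len(cols) or end - END_RUN < start:
        return []
    return cols[start:end]


def _search_strand(fragment: str, frag_id: str, gene: str, gene_id: str,
                   orientation: str, min_nt: int, min_identity: float,
                   min_score: float) -> list[PseudogeneMatch]:
    """All non-overlapping local matches of one fragment strand on one gene,
    found by best-hit recursion on the unmatched fragment remainder."""
    out: list[PseudogeneMatch] = []

    def recurse(sub: str, sub_off: int) -> None:
        if len(sub) < min_nt:
            return
        hit = align_local(gene, sub, kind="dna")
        cols = _trimmed_columns(hit, gene, sub)
        if not cols:
            return
        matches = sum(c[0] == "match" for c in cols)
        identity = 100.0 * matches / len(cols)
        t_idx = [c[1] for c in cols if c[1] is not None]
        q_idx = [c[2] for c in cols if c[2] is not None]
        t0, t1 = t_idx[0], t_idx[-1] + 1
        q0, q1 = q_idx[0], q_idx[-1] + 1
        hit = replace(hit, target_span=(t0, t1), query_span=(q0, q1),
                      identity_pct=identity)
        if hit.score >= min_score and (q1 - q0) >= min_nt \
                and hit.identity_pct >= min_identity:
            fs, fe = sub_off + q0 + 1, sub_off + q1  # 1-based on this strand
            if orientation == "-":
                n = len(fragment)
                fs, fe = n - fe + 1, n - fs + 1  # back to input-strand coords
            out.append(PseudogeneMatch(
                fragment=frag_id, gene=gene_id,
                fragment_interval=(fs, fe),
                gene_interval=(t0 + 1, t1),
                gene_aa_interval=(t0 // 3 + 1, (t1 - 1) // 3 + 1),
                orientation=orientation,
                identity_pct=hit.identity_pct,
                left_flank_nt=0, right_flank_nt=0,
                score=hit.score))
            recurse(sub[:q0], sub_off)
            recurse(sub[q1:], sub_off + q1)

    strand_seq = fragment if orientation == "+" else reverse_complement(fragment)
    recurse(strand_seq, 0)
    return out


def map_fragments(fragments: dict[str, str], reference_genes: dict[str, str],
                  min_nt: int = MIN_MATCH_NT,
                  min_identity: float = MIN_MATCH_IDENTITY,
                  min_score: float = 2.0 * MIN_MATCH_NT * 0.5,
                  ) -> list[PseudogeneMatch]:
    """Map every fragment onto the reference genes, both strands.

    A fragment region claimed by several genes keeps the highest-scoring
    match (ties: longer gene interval, then lexicographic gene name); a
    single fragment may carry matches to several genes as long as they do
    not overlap on the fragment. Flank lengths are the unmatched fragment
    ends outside the union of its accepted matches.
    """
    if not fragments or not reference_genes:
        raise ValueError("fragments and reference_genes must be non-empty")
    accepted: list[PseudogeneMatch] = []
    for frag_id, frag in fragments.items():
        candidates: list[PseudogeneMatch] = []
        for gene_id, gene in reference_genes.items():
            for orientation in "+-":
                candidates.extend(_search_strand(
                    frag, frag_id, gene, gene_id, orientation,
                    min_nt, min_identity, min_score))
        candidates.sort(key=lambda m: (-m.score,
                                       -(m.gene_interval[1] - m.gene_interval[0]),
                                       m.gene))
        chosen: list[PseudogeneMatch] = []
        for cand in candidates:
            s, e = cand.fragment_interval
            if any(not (e < c.fragment_interval[0] or s > c.fragment_interval[1])
                   for c in chosen):
                continue
            chosen.append(cand)
        if chosen:
            lo = min(c.fragment_interval[0] for c in chosen)
            hi = max(c.fragment_interval[1] for c in chosen)
            for c in chosen:
                c.left_flank_nt = lo - 1 if c.fragment_interval[0] == lo else 0
                c.right_flank_nt = (len(frag) - hi
                                    if c.fragment_interval[1] == hi else 0)
            chosen.sort(key=lambda m: m.fragment_interval)
        accepted.extend(chosen)
    return accepted


@dataclass
class CoverageProfile:
    """Per-position fragment-match depth along one reference gene."""

    gene: str
    depth: np.ndarray
    chi2: float
    dof: int
    p_value: float  # Monte Carlo under uniform fragment placement
    n_matches: int
    bins: int

    @property
    def uniform_not_rejected(self) -> bool:
        return bool(np.isnan(self.p_value)) or self.p_value >= 0.01


def _binned_chi2(depth: np.ndarray, bins: int) -> tuple[float, float]:
    edges = np.linspace(0, depth.size, bins + 1).astype(int)
    observed = np.array([depth[a:b].sum() for a, b in zip(edges, edges[1:])],
                        dtype=float)
    widths = np.diff(edges)
    expected = observed.sum() * widths / depth.size
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(observed.sum())


def coverage_profile(matches: list[PseudogeneMatch], gene_id: str,
                     gene_length: int, bins: int = 10,
                     n_monte_carlo: int = 999,
                     seed: int | None = 0) -> CoverageProfile:
    """Depth-of-coverage profile plus a uniformity test.

    The statistic is the chi-square of binned depth against the uniform
    expectation. Because the positions inside one fragment are not
    independent draws, the p-value is calibrated by Monte Carlo: matches of
    the observed lengths are re-placed uniformly at random along the gene
    ``n_monte_carlo`` times and the statistic recomputed (seeded). With zero
    matches the profile is all zeros and the test is undefined (p = NaN).
    """
    mine = [m for m in matches if m.gene == gene_id]
    depth = np.zeros(gene_length, dtype=int)
    lengths = []
    for m in mine:
        s, e = m.gene_interval
        depth[s - 1:e] += 1
        lengths.append(e - s + 1)
    if not mine:
        return CoverageProfile(gene_id, depth, float("nan"), bins - 1,
                               float("nan"), 0, bins)
    chi2, _ = _binned_chi2(depth, bins)
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_monte_carlo):
        sim = np.zeros(gene_length, dtype=int)
        for L in lengths:
            L = min(L, gene_length)
            start = rng.integers(0, gene_length - L + 1)
            sim[start:start + L] += 1
        sim_chi2, _ = _binned_chi2(sim, bins)
        if sim_chi2 >= chi2:
            hits += 1
    p = hits / (n_monte_carlo + 1)
    return CoverageProfile(gene_id, depth, chi2, bins - 1, p, len(mine), bins)


def matches_table(matches: list[PseudogeneMatch]):
    """Matches as a tidy DataFrame (one row per accepted local alignment)."""
    import pandas as pd

    rows = []
    for m in matches:
        rows.append({
            "fragment": m.fragment,
            "gene": m.gene,
            "fragment_start": m.fragment_interval[0],
            "fragment_end": m.fragment_interval[1],
            "gene_start": m.gene_interval[0],
            "gene_end": m.gene_interval[1],
            "aa_first": m.gene_aa_interval[0],
            "aa_last": m.gene_aa_interval[1],
            "orientation": m.orientation,
            "identity_pct": round(m.identity_pct, 2),
            "left_flank_nt": m.left_flank_nt,
            "right_flank_nt": m.right_flank_nt,
            "score": m.score,
            "conservation": m.conservation,
        })
    return pd.DataFrame(rows)
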