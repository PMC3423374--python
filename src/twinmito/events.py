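"""Detectors for gene-level structural events between related genomes:
fission of one gene into independently expressed parts, fusion of adjacent
genes into one reading frame, in-frame insertions retained in the mRNA,
intron interruptions, and trans-splice junctions of split genes.

All detectors are comparative: they take sequences (or annotated genomes)
and return typed event records with 1-based amino-acid coordinates, or
``None``/empty when the evidence does not meet the documented thresholds.
Alignment scoring is the shared configuration in :mod:`twinmito._align`.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._align import align_local, gapped_strings, percent_identity
from .io import AnnotatedGenome, spliced_sequence, translate

__all__ = [
    "FissionEvent",
    "FusionEvent",
    "InsertionEvent",
    "SpliceJunction",
    "detect_fission",
    "detect_fusions",
    "detect_inframe_insert",
    "detect_intron_interruption",
    "locate_trans_splice_junction",
    "IntronDecompositionError",
]


class IntronDecompositionError(ValueError):
    """cDNA cannot be decomposed into ordered exon matches on the locus."""


@dataclass
class FissionEvent:
    parent: str
    part_ids: tuple[str, str]
    part_spans: tuple[tuple[int, int], tuple[int, int]]  # 1-based aa on parent
    breakpoint: tuple[int, int]  # aa interval between the two parts


@dataclass
class FusionEvent:
    upstream: str
    downstream: str
    genome_id: str
    fused_feature: str
    no_internal_stop: bool
    initiator_retained: bool


@dataclass
class InsertionEvent:
    gene: str
    boundaries: dict[str, tuple[int, int]]  # per in-group member, 1-based aa
    insert_length_nt: dict[str, int]
    flank_identity_pct: tuple[float, float]  # before, after (first two members)
    insert_identity_pct: float


@dataclass
class SpliceJunction:
    gene: str
    junction_aa: tuple[int, int]  # (last aa of part 1, first aa of part 2)
    insert: str  # junction-inserted residues, possibly empty
    ambiguous_overlap: int = 0  # >0 when prefix and suffix claims overlap


# ---------------------------------------------------------------------------
# fission
# ---------------------------------------------------------------------------

def detect_fission(parent_protein: str,
                   candidate_proteins: dict[str, str],
                   parent_name: str = "parent",
                   min_part_coverage: float = 0.25,
                   min_joint_coverage: float = 0.80,
                   max_overlap_aa: int = 10) -> FissionEvent | None:
    """Recognise a gene split into two parts covering disjoint parent spans.

    Each candidate is locally aligned to the parent protein; an event is
    returned when exactly two candidates cover >= ``min_part_coverage`` of the
    parent each, jointly >= ``min_joint_coverage``, with span overlap at most
    ``max_overlap_aa`` residues.
    """
    if not parent_protein or not candidate_proteins:
        return None
    hits = []
    for name, prot in candidate_proteins.items():
        if not prot:
            continue
        hit = align_local(parent_protein, prot, kind="protein")
        span = hit.target_span
        coverage = (span[1] - span[0]) / len(parent_protein)
        if coverage >= min_part_coverage and hit.identity_pct >= 40.0:
            hits.append((name, span))
    if len(hits) != 2:
        return None
    hits.sort(key=lambda t: t[1][0])
    (name1, (s1, e1)), (name2, (s2, e2)) = hits
    overlap = e1 - s2  # 0-based half-open spans
    if overlap > max_overlap_aa:
        return None
    covered = len(set(range(s1, e1)) | set(range(s2, e2)))
    if covered / len(parent_protein) < min_joint_coverage:
        return None
    return FissionEvent(
        parent=parent_name,
        part_ids=(name1, name2),
        part_spans=((s1 + 1, e1), (s2 + 1, e2)),
        breakpoint=(min(e1, s2 + 1), max(e1, s2 + 1)),
    )


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def _protein_of(genome: AnnotatedGenome, feature) -> str:
    cds = spliced_sequence(genome, feature)
    prot = translate(cds, table=genome.translation_table, mode="open_frame")
    return prot.rstrip("*")  # internal stops kept — they are evidence


def detect_fusions(genome_fused: AnnotatedGenome,
                   genome_split: AnnotatedGenome,
                   min_part_coverage: float = 0.60,
                   max_overlap_aa: int = 10) -> list[FusionEvent]:
    """Find gene pairs separate in ``genome_split`` but fused into one reading
    frame in ``genome_fused``.

    For every pair of protein genes adjacent in the split genome, a single
    protein feature of the fused genome qualifies when the upstream protein
    aligns to its N-terminal region and the downstream protein to its
    C-terminal region, in order; the pair is rejected when the downstream
    gene also exists on its own in the fused genome. Evidence flags record
    the hallmarks of a fresh fusion: no stop codon between the two
    gene-derived regions, and a retained initiator methionine where the
    downstream part begins.
    """
    split_order = sorted(
        (f for f in genome_split.features
         if f.cls in ("protein", "rRNA", "tRNA", "orf")),
        key=lambda f: f.segments[0][0])
    events: list[FusionEvent] = []
    fused_proteins = {f.name: f for f in genome_fused.features
                      if f.cls in ("protein", "orf")}
    pairs = list(zip(split_order, split_order[1:]))
    if genome_split.topology == "circular" and len(split_order) > 1:
        pairs.append((split_order[-1], split_order[0]))
    for up_f, down_f in pairs:
        if up_f.cls not in ("protein", "orf") or down_f.cls not in ("protein", "orf"):
            continue
        up, down = up_f.name, down_f.name
        prot_up = _protein_of(genome_split, up_f)
        prot_down = _protein_of(genome_split, down_f)
        base = lambda n: n.rsplit(".", 1)[0]
        named = [f for n, f in fused_proteins.items()
                 if base(n) in (base(up), base(down), f"{base(up)}-{base(down)}")]
        candidates = named or list(fused_proteins.values())
        for cand in candidates:
            prot_cand = _protein_of(genome_fused, cand)
            if len(prot_cand) < 0.8 * (len(prot_up) + len(prot_down)):
                continue  # too short to hold both parts
            hit_up = align_local(prot_cand, prot_up, kind="protein")
            hit_dn = align_local(prot_cand, prot_down, kind="protein")
            cov_up = (hit_up.query_span[1] - hit_up.query_span[0]) / len(prot_up)
            cov_dn = (hit_dn.query_span[1] - hit_dn.query_span[0]) / len(prot_down)
            if cov_up < min_part_coverage or cov_dn < min_part_coverage:
                continue
            s_up, e_up = hit_up.target_span
            s_dn, e_dn = hit_dn.target_span
            if not (s_up < s_dn and e_up <= s_dn + max_overlap_aa):
                continue
            # downstream gene must not exist separately in the fused genome
            separate = False
            for other_name, other in fused_proteins.items():
                if other is cand:
                    continue
                prot_other = _protein_of(genome_fused, other)
                h = align_local(prot_other, prot_down, kind="protein")
                cov = (h.query_span[1] - h.query_span[0]) / len(prot_down)
                if cov >= 0.8 and h.identity_pct >= 80.0:
                    separate = True
                    break
            if separate:
                continue
            between = prot_cand[e_up:s_dn]
            init_pos = s_dn - (hit_dn.query_span[0])  # where downstream aa 1 sits
            initiator = (0 <= init_pos < len(prot_cand)
                         and prot_cand[init_pos] == "M")
            events.append(FusionEvent(
                upstream=up, downstream=down, genome_id=genome_fused.id,
                fused_feature=cand.name,
                no_internal_stop="*" not in prot_cand[: e_dn],
                initiator_retained=initiator))
            break
    return events


# ---------------------------------------------------------------------------
# in-frame insertion
# ---------------------------------------------------------------------------

def detect_inframe_insert(ingroup: dict[str, str],
                          outgroups: dict[str, str],
                          min_insert_aa: int = 10,
                          gene: str = "gene") -> InsertionEvent | None:
    """Find a contiguous region present in all in-group proteins but absent
    (gapped) from every outgroup.

    Sequences are amino acids; the first in-group member serves as the
    alignment reference, and boundaries are mapped onto the other members
    through pairwise global alignments. Reported nt lengths are 3x the aa
    lengths (the region is in-frame by construction of the coordinates).
    """
    if not outgroups:
        raise ValueError("at least one outgroup homolog is required "
                         "(insert polarity undecidable without it)")
    if len(ingroup) < 2:
        raise ValueError("at least two in-group homologs are required")
    names = list(ingroup)
    ref_name = names[0]
    ref = ingroup[ref_name]
    absent = [True] * len(ref)
    for out_seq in outgroups.values():
        a, b = gapped_strings(ref, out_seq, kind="protein", mode="global")
        ref_i = 0
        for col_a, col_b in zip(a, b):
            if col_a == "-":
                continue
            if col_b != "-":
                absent[ref_i] = False
            ref_i += 1
    runs = []
    start = None
    for i, flag in enumerate(absent + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    runs = [r for r in runs if r[1] - r[0] >= min_insert_aa]
    if not runs:
        return None
    ins_s, ins_e = max(runs, key=lambda r: r[1] - r[0])  # 0-based half-open on ref

    boundaries = {ref_name: (ins_s + 1, ins_e)}
    insert_len = {ref_name: 3 * (ins_e - ins_s)}
    member_cols = {}
    for name in names[1:]:
        a, b = gapped_strings(ref, ingroup[name], kind="protein", mode="global")
        # map ref residue index -> member residue index (last seen for gaps)
        ref_i = mem_i = 0
        start_mem = end_mem = None
        for col_a, col_b in zip(a, b):
            if col_a != "-" and ref_i == ins_s:
                start_mem = mem_i
            if col_a != "-" and ref_i == ins_e - 1:
                end_mem = mem_i if col_b != "-" else mem_i - 1
            if col_a != "-":
                ref_i += 1
            if col_b != "-":
                mem_i += 1
        if start_mem is None or end_mem is None:
            return None
        boundaries[name] = (start_mem + 1, end_mem + 1)
        insert_len[name] = 3 * (end_mem + 1 - start_mem)
        member_cols[name] = (a, b)
    # identities between the first two in-group members, inside vs outside
    other = names[1]
    a, b = member_cols[other]
    before_a = before_b = after_a = after_b = ins_a = ins_b = ""
    ref_i = 0
    for col_a, col_b in zip(a, b):
        region = ("before" if ref_i < ins_s else
                  "insert" if ref_i < ins_e else "after")
        if region == "before":
            before_a += col_a; before_b += col_b
        elif region == "insert":
            ins_a += col_a; ins_b += col_b
        else:
            after_a += col_a; after_b += col_b
        if col_a != "-":
            ref_i += 1
    if not ins_a:
        return None
    return InsertionEvent(
        gene=gene,
        boundaries=boundaries,
        insert_length_nt=insert_len,
        flank_identity_pct=(percent_identity(before_a, before_b),
                            percent_identity(after_a, after_b)),
        insert_identity_pct=percent_identity(ins_a, ins_b),
    )


# ---------------------------------------------------------------------------
# intron interruption
# ---------------------------------------------------------------------------

def _exact_anchors(locus: str, cdna: str, k: int = 16):
    """Maximal exact matches seeded on k-mers, as (cdna_pos, locus_pos, length)."""
    index: dict[str, list[int]] = {}
    for i in range(len(locus) - k + 1):
        index.setdefault(locus[i:i + k], []).append(i)
    anchors = []
    seen = set()
    for ci in range(len(cdna) - k + 1):
        for li in index.get(cdna[ci:ci + k], []):
            # extend left and right maximally
            c0, l0 = ci, li
            while c0 > 0 and l0 > 0 and cdna[c0 - 1] == locus[l0 - 1]:
                c0 -= 1
                l0 -= 1
            c1, l1 = ci + k, li + k
            while c1 < len(cdna) and l1 < len(locus) and cdna[c1] == locus[l1]:
                c1 += 1
                l1 += 1
            key = (c0, l0, c1 - c0)
            if key not in seen:
                seen.add(key)
                anchors.append(key)
    return anchors


def _chain_anchors(anchors):
    """Heaviest strictly colinear chain (weight = matched length)."""
    anchors = sorted(anchors, key=lambda a: (a[0], a[1]))
    best = [0.0] * len(anchors)
    prev = [-1] * len(anchors)
    for i, (ci, li, Li) in enumerate(anchors):
        best[i] = Li
        for j in range(i):
            cj, lj, Lj = anchors[j]
            if cj + Lj <= ci and lj + Lj <= li and best[j] + Li > best[i]:
                best[i] = best[j] + Li
                prev[i] = j
    if not anchors:
        return []
    end = max(range(len(anchors)), key=lambda i: best[i])
    chain = []
    while end != -1:
        chain.append(anchors[end])
        end = prev[end]
    return chain[::-1]


def detect_intron_interruption(locus: str, cdna: str,
                               min_intron: int = 20,
                               min_coverage: float = 0.90,
                               k: int = 16) -> list[tuple[int, int]]:
    """Locate introns as locus segments missing from the spliced cDNA.

    The cDNA is decomposed into a maximal colinear chain of exon matches on
    the locus; every chain gap where the locus side is at least ``min_intron``
    nt longer than the cDNA side is reported as an intron, with the exact
    splice point chosen to minimise exon mismatches. Intervals are 1-based
    inclusive locus coordinates. Raises :class:`IntronDecompositionError`
    when the chain covers less than ``min_coverage`` of the cDNA.
    """
    locus = locus.upper()
    cdna = cdna.upper().replace("U", "T")
    if len(cdna) > len(locus):
        raise IntronDecompositionError("cDNA longer than locus")
    chain = _chain_anchors(_exact_anchors(locus, cdna, k=k))
    if not chain:
        raise IntronDecompositionError("no exon matches found")
    covered = sum(L for _, _, L in chain)
    if covered / len(cdna) < min_coverage:
        raise IntronDecompositionError(
            f"exon chain covers only {100 * covered / len(cdna):.1f}% of cDNA")
    introns = []
    for (c0, l0, L0), (c1, l1, L1) in zip(chain, chain[1:]):
        ce, le = c0 + L0, l0 + L0
        dc, dl = c1 - ce, l1 - le
        if dl - dc < min_intron:
            continue
        cseg = cdna[ce:c1]
        intron_len = dl - dc
        best_i, best_mm = 0, None
        for i in range(dc + 1):
            left = sum(x != y for x, y in zip(cseg[:i], locus[le:le + i]))
            right = sum(x != y for x, y in
                        zip(cseg[i:], locus[l1 - (dc - i):l1]))
            mm = left + right
            if best_mm is None or mm < best_mm:
                best_mm, best_i = mm, i
        start = le + best_i + 1  # 1-based first intron base
        introns.append((start, start + intron_len - 1))
    return introns


# ---------------------------------------------------------------------------
# trans-splice junction
# ---------------------------------------------------------------------------

def _best_ungapped_offset(text: str, reference: str, anchor_end: bool,
                          min_overlap: int = 12) -> tuple[int, int]:
    """Best substitution-only placement of ``text`` against ``reference``.

    ``anchor_end=False``: text's start is placed inside the reference and the
    match runs to the reference end (prefix-of-text vs suffix-of-reference).
    ``anchor_end=True``: text's end placed so the match starts at reference
    start (suffix-of-text vs prefix-of-reference). Returns (offset, score)
    where score rewards matches (+1) and penalises mismatches (-1).
    """
    best = (0, -10**9)
    if not anchor_end:
        for a in range(0, len(reference) - min_overlap + 1):
            L = min(len(text), len(reference) - a)
            m = sum(x == y for x, y in zip(text[:L], reference[a:a + L]))
            score = 2 * m - L
            if score > best[1]:
                best = (a, score)
    else:
        for q in range(min_overlap, min(len(text), len(reference)) + 1):
            m = sum(x == y for x, y in zip(text[-q:], reference[:q]))
            score = 2 * m - q
            if score > best[1]:
                best = (q, score)
    return best


def locate_trans_splice_junction(part1_dna: str, part2_dna: str,
                                 transcript: str,
                                 gene: str = "gene") -> SpliceJunction:
    """Locate the junction of a trans-spliced transcript over its two gene
    pieces, tolerating substitutional editing but no indels.

    The maximal transcript prefix is matched against the 3' end of part 1 and
    the maximal suffix against the 5' start of part 2; whatever lies between
    is the junction insert. Coordinates are amino acids of the full protein,
    taking part 1 to encode complete codons from position 1 of the gene.
    """
    t = transcript.upper().replace("U", "T")
    p1 = part1_dna.upper()
    p2 = part2_dna.upper()
    a, _ = _best_ungapped_offset(t, p1, anchor_end=False)
    p = min(len(t), len(p1) - a)  # transcript prefix mapped into part 1
    q, _ = _best_ungapped_offset(t, p2, anchor_end=True)
    junction_last_aa = -(-len(p1) // 3)
    if p + q > len(t):
        return SpliceJunction(gene, (junction_last_aa, junction_last_aa + 1),
                              "", ambiguous_overlap=p + q - len(t))
    insert = t[p:len(t) - q]
    return SpliceJunction(gene, (junction_last_aa, junction_last_aa + 1), insert)
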