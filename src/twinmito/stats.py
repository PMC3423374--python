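"""Genome-level descriptive statistics for compact organellar genomes.

Everything is computed over the *sequenced* region only: for genomes stored as
``linear_gapped`` (physically circular molecules with one unsequenced gap) the
denominator of GC content and coding fraction is the stored sequence length,
matching how such genomes are normally tabulated.

Conventions (see docs/methods.md for rationale):

* gene classes counted as "coding": protein, rRNA, tRNA and annotated ORFs;
  intron features are counted inside their host gene's locus, so intronic
  nucleotides are coding-covered but excluded from spliced gene lengths;
* coverage is a position-set union, so overlapping genes are counted once;
* GC percentages exclude IUPAC ambiguity codes from numerator and denominator;
* spacers are measured between consecutive gene loci along the genome
  (cyclically for circular genomes, open across the gap otherwise); pairs at
  negative distance are reported as overlaps, not spacers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotatedGenome, GeneFeature, spliced_sequence

__all__ = [
    "GenomeStatistics",
    "gc_content",
    "coding_fraction",
    "intergenic_spacers",
    "codon_stats",
    "gene_length_summary",
    "summarize",
    "EmptySelectionError",
]

GENE_CLASSES = ("protein", "rRNA", "tRNA", "orf")


class EmptySelectionError(ValueError):
    """A GC selector matched no sequence positions."""


def _segment_positions(genome: AnnotatedGenome, feature: GeneFeature) -> np.ndarray:
    n = len(genome)
    idx = []
    for s, e in feature.segments:
        if s <= e:
            idx.append(np.arange(s - 1, e))
        else:  # wraps the origin
            idx.append(np.arange(s - 1, n))
            idx.append(np.arange(0, e))
    return np.concatenate(idx)


def _locus_positions(genome: AnnotatedGenome, feature: GeneFeature) -> np.ndarray:
    """Genomic positions of the full gene locus: the segments plus any gaps
    between consecutive segments (introns of a cis-spliced gene)."""
    segs = sorted(feature.segments, key=lambda p: p[0])
    if len(segs) > 1 and all(s <= e for s, e in segs):
        spliced = sum(e - s + 1 for s, e in segs)
        span = segs[-1][1] - segs[0][0] + 1
        # treat as one contiguous locus only when the segments nest inside a
        # plausible single span (cis-splicing), not for trans pieces
        if span >= spliced:
            lo, hi = segs[0][0], segs[-1][1]
            return np.arange(lo - 1, hi)
    return _segment_positions(genome, feature)


def _coverage_mask(genome: AnnotatedGenome,
                   classes: tuple[str, ...] = GENE_CLASSES) -> np.ndarray:
    mask = np.zeros(len(genome), dtype=bool)
    for f in genome.features:
        if f.cls in classes:
            mask[_locus_positions(genome, f)] = True
        elif f.cls == "intron":
            mask[_segment_positions(genome, f)] = True
    return mask


def gc_content(genome: AnnotatedGenome, selector: str = "total") -> float:
    """GC percent of the selected region class.

    ``selector`` is ``total``, ``intergenic``, or a gene class
    (``protein``/``rRNA``/``tRNA``/``orf``). Positions covered by several
    copies of a class are counted once, by genomic position.
    """
    seq = np.frombuffer(genome.sequence.encode(), dtype="S1")
    if selector == "total":
        mask = np.ones(len(genome), dtype=bool)
    elif selector == "intergenic":
        mask = ~_coverage_mask(genome)
    elif selector in GENE_CLASSES:
        mask = np.zeros(len(genome), dtype=bool)
        for f in genome.features_of_class(selector):
            mask[_segment_positions(genome, f)] = True
    else:
        raise ValueError(f"unknown selector {selector!r}")
    sel = seq[mask]
    gc = np.isin(sel, [b"G", b"C"]).sum()
    at = np.isin(sel, [b"A", b"T"]).sum()
    if gc + at == 0:
        raise EmptySelectionError(
            f"selector {selector!r} matches no unambiguous bases in {genome.id}")
    return 100.0 * gc / (gc + at)


def coding_fraction(genome: AnnotatedGenome) -> float:
    """Percent of sequenced positions covered by at least one gene locus."""
    if not genome.features:
        raise ValueError("genome has no features")
    return 100.0 * _coverage_mask(genome).mean()


def _gene_span(genome: AnnotatedGenome, feature: GeneFeature) -> tuple[int, int]:
    """(start, end) of the locus in genomic coordinates, 1-based; end may
    exceed the genome length for a wrapping locus (unwrapped coordinates)."""
    n = len(genome)
    segs = feature.segments
    if any(s > e for s, e in segs):  # wrapping feature
        s0 = min(s for s, e in segs)
        e0 = max(e for s, e in segs if s > e)
        return s0, n + e0
    return min(s for s, _ in segs), max(e for _, e in segs)


def intergenic_spacers(genome: AnnotatedGenome) -> dict:
    """Spacer lengths between consecutive gene loci plus overlap bookkeeping.

    Returns ``{"spacers": [(left_gene, right_gene, bp), ...], "mean": float,
    "overlaps": [(left_gene, right_gene, bp), ...]}``. Consecutive pairs are
    taken cyclically for circular genomes; for linear and linear_gapped
    genomes the pair across the ends/gap is not formed.
    """
    feats = [f for f in genome.features if f.cls in GENE_CLASSES]
    if len(feats) < 2:
        raise ValueError("need at least two gene features")
    n = len(genome)
    spans = sorted((( *_gene_span(genome, f), f.name) for f in feats),
                   key=lambda t: t[0])
    pairs = list(zip(spans, spans[1:]))
    if genome.topology == "circular":
        pairs.append((spans[-1], (spans[0][0] + n, spans[0][1] + n, spans[0][2])))
    spacers, overlaps = [], []
    for (s1, e1, n1), (s2, e2, n2) in pairs:
        gap = s2 - e1 - 1
        if gap >= 0:
            spacers.append((n1, n2, gap))
        else:
            overlaps.append((n1, n2, -gap))
    mean = float(np.mean([g for *_, g in spacers])) if spacers else 0.0
    return {"spacers": spacers, "mean": mean, "overlaps": overlaps}


def codon_stats(genome: AnnotatedGenome, include_orfs: bool = False) -> dict:
    """Codon usage, third-position A+T percent, and start/stop codon survey
    over complete protein-coding genes (fused genes count once; annotated
    ORFs excluded by default as potentially spurious)."""
    classes = ("protein", "orf") if include_orfs else ("protein",)
    feats = [f for f in genome.features if f.cls in classes and f.complete]
    if not feats:
        raise ValueError("no complete protein-coding features")
    usage: dict[str, int] = {}
    starts: dict[str, str] = {}
    stops: dict[str, str] = {}
    third = {"AT": 0, "GC": 0}
    for f in feats:
        cds = spliced_sequence(genome, f)
        if len(cds) % 3:
            warnings.warn(f"CDS length of {f.name} not divisible by 3; "
                          "excluded from codon statistics", stacklevel=2)
            continue
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        starts[f.name] = codons[0]
        stops[f.name] = codons[-1]
        for c in codons:
            usage[c] = usage.get(c, 0) + 1
            if c[2] in "AT":
                third["AT"] += 1
            elif c[2] in "GC":
                third["GC"] += 1
    total3 = third["AT"] + third["GC"]
    return {
        "usage": usage,
        "third_position_AT_pct": 100.0 * third["AT"] / total3 if total3 else float("nan"),
        "start_codons": starts,
        "stop_codons": stops,
        "alternative_starts": {g: c for g, c in starts.items() if c != "ATG"},
    }


def gene_length_summary(genome: AnnotatedGenome) -> tuple[float, float]:
    """(mean protein gene bp, mean all-gene bp) over spliced gene lengths."""
    n = len(genome)
    prot = [f.length(n) for f in genome.features if f.cls == "protein"]
    allg = [f.length(n) for f in genome.features if f.cls in GENE_CLASSES]
    if not allg:
        raise ValueError("no gene features")
    return (float(np.mean(prot)) if prot else float("nan"), float(np.mean(allg)))


@dataclass
class GenomeStatistics:
    """The full per-genome statistics block (one genome, sequenced region)."""

    genome_id: str
    total_bp: int
    gc_total_pct: float
    gc_by_class: dict[str, float]
    gene_counts: dict[str, int]
    coding_fraction_pct: float
    spacer_lengths: list[int]
    mean_spacer_bp: float
    overlap_pairs: list[tuple[str, str, int]]
    mean_protein_gene_bp: float
    mean_all_gene_bp: float
    third_position_AT_pct: float
    start_codons: dict[str, str] = field(default_factory=dict)
    stop_codons: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total_bp", self.total_bp),
            ("gc_total_pct", round(self.gc_total_pct, 2)),
            *[(f"gc_{k}_pct", round(v, 2)) for k, v in self.gc_by_class.items()],
            *[(f"n_{k}", v) for k, v in self.gene_counts.items()],
            ("coding_fraction_pct", round(self.coding_fraction_pct, 2)),
            ("mean_spacer_bp", round(self.mean_spacer_bp, 1)),
            ("n_spacers", len(self.spacer_lengths)),
            ("n_overlap_pairs", len(self.overlap_pairs)),
            ("overlap_pairs", ";".join(f"{a}|{b}" for a, b, _ in self.overlap_pairs)),
            ("mean_protein_gene_bp", round(self.mean_protein_gene_bp, 1)),
            ("mean_all_gene_bp", round(self.mean_all_gene_bp, 1)),
            ("third_position_AT_pct", round(self.third_position_AT_pct, 2)),
            ("alternative_start_codons",
             ";".join(f"{g}:{c}" for g, c in sorted(self.start_codons.items())
                      if c != "ATG")),
        ]
        return pd.DataFrame(rows, columns=["statistic", "value"]).assign(
            genome_id=self.genome_id)[["genome_id", "statistic", "value"]]


def summarize(genome: AnnotatedGenome) -> GenomeStatistics:
    """Compute the whole statistics block for one genome."""
    counts = {cls: len(genome.features_of_class(cls))
              for cls in ("protein", "rRNA", "tRNA", "orf", "intron")}
    counts["total_genes"] = sum(counts[c] for c in GENE_CLASSES)
    gc_by_class = {}
    for cls in ("rRNA", "tRNA", "protein", "orf"):
        try:
            gc_by_class[cls] = gc_content(genome, cls)
        except EmptySelectionError:
            continue
    try:
        gc_by_class["intergenic"] = gc_content(genome, "intergenic")
    except EmptySelectionError:
        pass
    sp = intergenic_spacers(genome)
    cs = codon_stats(genome)
    mean_prot, mean_all = gene_length_summary(genome)
    return GenomeStatistics(
        genome_id=genome.id,
        total_bp=len(genome),
        gc_total_pct=gc_content(genome, "total"),
        gc_by_class=gc_by_class,
        gene_counts=counts,
        coding_fraction_pct=coding_fraction(genome),
        spacer_lengths=[g for *_, g in sp["spacers"]],
        mean_spacer_bp=sp["mean"],
        overlap_pairs=sp["overlaps"],
        mean_protein_gene_bp=mean_prot,
        mean_all_gene_bp=mean_all,
        third_position_AT_pct=cs["third_position_AT_pct"],
        start_codons=cs["start_codons"],
        stop_codons=cs["stop_codons"],
    )
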