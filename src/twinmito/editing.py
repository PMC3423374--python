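"""Substitutional RNA-editing calls from paired genomic/cDNA sequences.

Dinoflagellate mitochondrial mRNAs differ from their encoding DNA by
single-base substitutions (mostly A->G at codon positions 1 and 2); this
module calls those sites from consensus sequence pairs, summarises the
substitution spectrum, and matches sites across species through a
codon-level homolog alignment.

Convention: edits are reported genomic -> transcript, and RNA bases are
mapped to the DNA alphabet internally (a U in the mRNA is reported as T),
so "A-to-G editing" means A in the DNA, G in the cDNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib
import pandas as pd

from ._align import gapped_strings
from .io import translate

__all__ = [
    "EditingSite",
    "call_editing_sites",
    "edit_spectrum",
    "conserved_editing_sites",
    "codon_homolog_map",
    "AlignmentIndelError",
]

BASES = "ACGT"
SUBSTITUTION_TYPES = [f"{a}>{b}" for a in BASES for b in BASES if a != b]


class AlignmentIndelError(ValueError):
    """The gene/transcript pair differs by an indel, not just substitutions."""


@dataclass
class EditingSite:
    gene: str
    cds_position: int  # 1-based nt index within the full CDS frame
    codon_index: int  # 1-based
    codon_position: int  # 1, 2 or 3
    genomic_base: str
    transcript_base: str
    aa_before: str
    aa_after: str
    synonymous: bool

    @property
    def substitution(self) -> str:
        return f"{self.genomic_base}>{self.transcript_base}"


def _clean(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _anchor(gene: str, transcript: str) -> tuple[int, int]:
    """Place the (possibly partial) transcript on the gene without gaps.

    The transcript is slid over the gene and anchored at the offset with the
    fewest mismatches; an infix edit-distance alignment (edlib) screens for
    indels: when the best substitution-only placement needs more changes than
    the unrestricted edit distance, the pair truly differs by an indel and
    the comparison is refused. Returns the 0-based gene offset of transcript
    position 0 and the compared length.
    """
    import numpy as np

    g = np.frombuffer(gene.encode(), dtype=np.uint8)
    t = np.frombuffer(transcript.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(g, len(t))
    mismatches = (windows != t).sum(axis=1)
    best = int(mismatches.argmin())
    k = edlib.align(transcript, gene, mode="HW", task="distance")["editDistance"]
    if int(mismatches[best]) > k:
        raise AlignmentIndelError(
            f"gene/transcript pair requires indels: best ungapped placement "
            f"has {int(mismatches[best])} mismatches but edit distance is {k}")
    return best, len(transcript)


def call_editing_sites(gene_cds: str, transcript_cds: str,
                       frame_offset: int = 0,
                       gene: str = "gene",
                       table: int = 1) -> list[EditingSite]:
    """Call substitution sites between a gene and its transcript.

    ``frame_offset`` is the 0-based position of ``gene_cds[0]`` within the
    full coding frame (0 when the full CDS is given); it controls codon
    numbering for partial RT-PCR fragments. An indel in the optimal
    alignment raises :class:`AlignmentIndelError` — editing handled here is
    substitutional only.
    """
    g = _clean(gene_cds)
    t = _clean(transcript_cds)
    if not g or not t:
        raise ValueError("empty sequence")
    if len(t) > len(g):
        raise AlignmentIndelError("transcript longer than gene segment")
    offset, span = _anchor(g, t)
    sites: list[EditingSite] = []
    for i in range(span):
        gb, tb = g[offset + i], t[i]
        if gb == tb:
            continue
        cds_pos = frame_offset + offset + i + 1
        codon_index = (cds_pos - 1) // 3 + 1
        codon_pos = (cds_pos - 1) % 3 + 1
        # reconstruct the codon around the site from the gene, then edit it
        codon_start_in_g = (offset + i) - (codon_pos - 1)
        codon_g = g[codon_start_in_g:codon_start_in_g + 3]
        if len(codon_g) == 3 and codon_start_in_g >= 0:
            codon_t = (codon_g[:codon_pos - 1] + tb + codon_g[codon_pos:])
            aa_before = translate(codon_g, table=table, mode="open_frame") or "?"
            aa_after = translate(codon_t, table=table, mode="open_frame") or "?"
        else:
            aa_before = aa_after = "?"
        sites.append(EditingSite(
            gene=gene, cds_position=cds_pos, codon_index=codon_index,
            codon_position=codon_pos, genomic_base=gb, transcript_base=tb,
            aa_before=aa_before, aa_after=aa_after,
            synonymous=(aa_before == aa_after != "?")))
    return sites


def edit_spectrum(sites: list[EditingSite]) -> pd.DataFrame:
    """Contingency table of the 12 substitution types x 3 codon positions."""
    table = pd.DataFrame(0, index=SUBSTITUTION_TYPES, columns=[1, 2, 3])
    for s in sites:
        table.loc[s.substitution, s.codon_position] += 1
    table.index.name = "substitution"
    table.columns.name = "codon_position"
    return table


def codon_homolog_map(cds_a: str, cds_b: str, table: int = 1) -> dict[int, int]:
    """Codon-level alignment of two homologous CDSs: 1-based codon index of A
    -> 1-based codon index of B, for codons aligned one-to-one.

    Built from a global alignment of the two translations, so codon
    correspondence is protein-homology-aware.
    """
    prot_a = translate(_clean(cds_a), table=table, mode="open_frame")
    prot_b = translate(_clean(cds_b), table=table, mode="open_frame")
    a, b = gapped_strings(prot_a, prot_b, kind="protein", mode="global")
    mapping: dict[int, int] = {}
    ia = ib = 0
    for ca, cb in zip(a, b):
        if ca != "-" and cb != "-":
            mapping[ia + 1] = ib + 1
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return mapping


def conserved_editing_sites(sites_a: list[EditingSite],
                            sites_b: list[EditingSite],
                            homolog_map: dict[int, int]
                            ) -> list[tuple[EditingSite, EditingSite]]:
    """Match editing sites across two species through a codon homolog map.

    Two sites pair when A's codon maps to B's codon, the within-codon
    position agrees, and the substitution type is identical. Sites at codons
    outside the map are excluded with a warning.
    """
    pairs = []
    b_index = {(s.codon_index, s.codon_position, s.substitution): s
               for s in sites_b}
    mapped_b_codons = set(homolog_map.values())
    for sa in sites_a:
        if sa.codon_index not in homolog_map:
            warnings.warn(f"site at codon {sa.codon_index} of {sa.gene} "
                          "outside homolog map; excluded", stacklevel=2)
            continue
        key = (homolog_map[sa.codon_index], sa.codon_position, sa.substitution)
        if key in b_index:
            pairs.append((sa, b_index[key]))
    for sb in sites_b:
        if sb.codon_index not in mapped_b_codons:
            warnings.warn(f"site at codon {sb.codon_index} of {sb.gene} "
                          "outside homolog map; excluded", stacklevel=2)
    return pairs


def sites_table(sites: list[EditingSite],
                conserved: set[int] | None = None) -> pd.DataFrame:
    """Per-site report: position, codon position, from, to, aa change."""
    rows = []
    for s in sites:
        rows.append({
            "gene": s.gene,
            "cds_position": s.cds_position,
            "codon_index": s.codon_index,
            "codon_position": s.codon_position,
            "from": s.genomic_base,
            "to": s.transcript_base,
            "aa_change": f"{s.aa_before}>{s.aa_after}",
            "synonymous": s.synonymous,
            "conserved": (s.cds_position in conserved) if conserved is not None
            else "",
        })
    return pd.DataFrame(rows, columns=["gene", "cds_position", "codon_index",
                                       "codon_position", "from", "to",
                                       "aa_change", "synonymous", "conserved"])
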