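"""Reading, writing and slicing annotated organellar genomes.

The central containers are :class:`AnnotatedGenome` and :class:`GeneFeature`.
Coordinates are 1-based inclusive throughout (GenBank convention); a segment
whose ``start > end`` wraps the origin and is only legal on a circular genome.

GenBank parsing and writing are delegated to Biopython's ``SeqIO``; this module
adds the domain model on top: gene-name normalisation, strand/splice/wrap-aware
sequence extraction, and translation with the two genetic codes that matter for
diatom mitochondria (table 1, universal; table 4, TGA -> Trp).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "AnnotatedGenome",
    "read_genome_annotation",
    "write_genome_annotation",
    "spliced_sequence",
    "translate",
    "feature_table",
    "write_feature_table",
    "normalize_gene_name",
    "InternalStopError",
    "CoordinateError",
    "GenomeParseError",
]

FEATURE_CLASSES = ("protein", "rRNA", "tRNA", "orf", "intron", "pseudogene")
TOPOLOGIES = ("circular", "linear", "linear_gapped")

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                           "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

#: default synonym table for cross-genome gene matching; callers may extend
GENE_SYNONYMS = {
    "rrnl": "rnl",
    "lsu": "rnl",
    "lsurrna": "rnl",
    "23srrna": "rnl",
    "rrns": "rns",
    "ssu": "rns",
    "ssurrna": "rns",
    "16srrna": "rns",
    "cytb": "cob",
    "coi": "cox1",
    "coxi": "cox1",
}


class GenomeParseError(ValueError):
    """Raised when a GenBank record cannot be mapped onto the domain model."""


class CoordinateError(ValueError):
    """Raised when a feature segment falls outside its genome."""


class InternalStopError(ValueError):
    """Raised when a complete CDS translates with an internal stop codon."""


def normalize_gene_name(raw: str, synonyms: dict[str, str] | None = None) -> str:
    """Canonicalise a gene symbol: lowercase, strip locus-tag prefixes and
    punctuation, then map through the synonym table."""
    name = raw.strip().lower()
    # strip a locus-tag style prefix such as "DbmtDNA_012_" or "kf_mt|"
    name = re.sub(r"^[a-z0-9]+[_|:](?=[a-z])", "", name)
    name = re.sub(r"[\s()\[\]]", "", name)
    table = dict(GENE_SYNONYMS)
    if synonyms:
        table.update({k.lower(): v for k, v in synonyms.items()})
    return table.get(name, name)


@dataclass
class GeneFeature:
    """One annotated genome element.

    ``segments`` are (start, end) 1-based inclusive pairs in reading order,
    i.e. the order in which they are concatenated to build the transcript;
    for a minus-strand feature each segment still has start <= end on the
    forward strand (unless it wraps the origin) and the extracted sequence is
    reverse-complemented after concatenation.
    """

    name: str
    cls: str
    strand: str
    segments: list[tuple[int, int]]
    complete: bool = True
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cls not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.cls!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.segments:
            raise ValueError(f"feature {self.name!r} has no segments")
        self.segments = [(int(s), int(e)) for s, e in self.segments]

    def length(self, genome_length: int | None = None) -> int:
        """Spliced length in nucleotides (wrapping segments need the genome
        length to be resolvable)."""
        total = 0
        for s, e in self.segments:
            if s <= e:
                total += e - s + 1
            else:
                if genome_length is None:
                    raise CoordinateError(
                        f"wrapping segment in {self.name!r} requires genome length")
                total += (genome_length - s + 1) + e
        return total


@dataclass
class AnnotatedGenome:
    """A (possibly gapped) circular or linear DNA sequence plus features.

    ``sequence`` holds the sequenced portion only; for ``linear_gapped``
    genomes the unsequenced gap is *outside* the stored sequence and every
    statistic downstream is computed over the sequenced region.
    """

    id: str
    topology: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    translation_table: int = 1

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTRYSWKMBDHVN")
        if bad:
            raise GenomeParseError(
                f"unknown residue characters in {self.id!r}: {sorted(bad)}")
        self.validate()

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature ids in {self.id!r}: {dupes}")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.segments:
                if not (1 <= s <= n and 1 <= e <= n):
                    raise CoordinateError(
                        f"feature {f.name!r} segment ({s},{e}) outside [1,{n}]")
                if s > e and self.topology != "circular":
                    raise CoordinateError(
                        f"feature {f.name!r} wraps the origin on non-circular "
                        f"genome {self.id!r}")

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def features_of_class(self, *classes: str) -> list[GeneFeature]:
        return [f for f in self.features if f.cls in classes]


def _classify(biofeature: SeqFeature, name: str) -> str | None:
    t = biofeature.type
    if t == "CDS":
        if biofeature.qualifiers.get("pseudo") or biofeature.qualifiers.get("pseudogene"):
            return "pseudogene"
        return "orf" if re.fullmatch(r"orf\d*[a-z]?", name) else "protein"
    if t == "rRNA":
        return "rRNA"
    if t == "tRNA":
        return "tRNA"
    if t == "intron":
        return "intron"
    return None


def _feature_name(biofeature: SeqFeature, synonyms: dict[str, str] | None) -> str | None:
    for key in ("gene", "product", "label", "locus_tag", "note"):
        if key in biofeature.qualifiers:
            return normalize_gene_name(str(biofeature.qualifiers[key][0]), synonyms)
    return None


def read_genome_annotation(path: str | Path,
                           topology: str | None = None,
                           synonyms: dict[str, str] | None = None,
                           keep_classes: Sequence[str] = FEATURE_CLASSES,
                           ) -> AnnotatedGenome:
    """Read one GenBank flat-file record into an :class:`AnnotatedGenome`.

    Topology is taken from the LOCUS line unless overridden (use
    ``topology="linear_gapped"`` for a physically circular genome with an
    unsequenced gap). Duplicate gene names are disambiguated with ``.2``,
    ``.3`` ... suffixes so the genome invariant holds; rearrangement code
    re-collapses these when matching genes across genomes.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # malformed record
        raise GenomeParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    if topology is None:
        topology = record.annotations.get("topology", "linear")
        if topology not in TOPOLOGIES:
            topology = "linear"
    table = 1
    features: list[GeneFeature] = []
    seen: dict[str, int] = {}
    for bf in record.features:
        name = _feature_name(bf, synonyms)
        if name is None:
            if bf.type in ("CDS", "rRNA", "tRNA", "intron"):
                raise GenomeParseError(
                    f"unnamed {bf.type} feature at {bf.location} in {record.id}")
            continue
        cls = _classify(bf, name)
        if cls is None or cls not in keep_classes:
            continue
        if bf.location is None:
            raise GenomeParseError(f"feature {name!r} has malformed coordinates")
        if "transl_table" in bf.qualifiers:
            table = int(bf.qualifiers["transl_table"][0])
        strand = "-" if bf.location.strand == -1 else "+"
        parts = list(bf.location.parts)
        if strand == "-":
            # Biopython keeps parts in genomic order; reading order for a
            # minus-strand join is the reverse
            parts = parts[::-1]
        segments = [(int(p.start) + 1, int(p.end)) for p in parts]
        segments = _merge_wrap(segments, len(record.seq), topology)
        seen[name] = seen.get(name, 0) + 1
        uname = name if seen[name] == 1 else f"{name}.{seen[name]}"
        complete = not (bf.location.start.__class__.__name__.startswith("Before")
                        or bf.location.end.__class__.__name__.startswith("After"))
        features.append(GeneFeature(uname, cls, strand, segments, complete,
                                    qualifiers={"source_type": bf.type}))
    return AnnotatedGenome(record.id or record.name, topology, str(record.seq),
                           features, translation_table=table)


def _merge_wrap(segments: list[tuple[int, int]], n: int, topology: str
                ) -> list[tuple[int, int]]:
    """Collapse a join(x..n, 1..y) pair from a circular record into one
    wrapping segment (x, y)."""
    if topology != "circular" or len(segments) < 2:
        return segments
    out = list(segments)
    i = 0
    while i < len(out) - 1:
        (s1, e1), (s2, e2) = out[i], out[i + 1]
        if e1 == n and s2 == 1 and s1 > 1:
            out[i:i + 2] = [(s1, e2)]
        else:
            i += 1
    return out


_TYPE_BY_CLASS = {"protein": "CDS", "orf": "CDS", "pseudogene": "CDS",
                  "rRNA": "rRNA", "tRNA": "tRNA", "intron": "intron"}


def write_genome_annotation(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write the genome back out as a GenBank flat file (round-trip safe for
    the fields the domain model stores)."""
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description="")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = (
        "circular" if genome.topology == "circular" else "linear")
    n = len(genome.sequence)
    strand_num = {"+": 1, "-": -1}
    for f in genome.features:
        locs = []
        for s, e in f.segments:
            if s <= e:
                locs.append(SimpleLocation(s - 1, e, strand=strand_num[f.strand]))
            else:  # wrapping
                locs.append(SimpleLocation(s - 1, n, strand=strand_num[f.strand]))
                locs.append(SimpleLocation(0, e, strand=strand_num[f.strand]))
        if f.strand == "-":
            locs = locs[::-1]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.name]}
        if f.cls in ("protein", "orf"):
            quals["transl_table"] = [str(genome.translation_table)]
        if f.cls == "pseudogene":
            quals["pseudo"] = [""]
        record.features.append(SeqFeature(loc, type=_TYPE_BY_CLASS[f.cls],
                                          qualifiers=quals))
    SeqIO.write([record], str(path), "genbank")


def _segment_text(genome: AnnotatedGenome, s: int, e: int) -> str:
    seq = genome.sequence
    if s <= e:
        return seq[s - 1:e]
    if genome.topology != "circular":
        raise CoordinateError(
            f"segment ({s},{e}) wraps the origin on non-circular genome {genome.id!r}")
    return seq[s - 1:] + seq[:e]


def reverse_complement(dna: str) -> str:
    return dna.translate(COMPLEMENT)[::-1]


def spliced_sequence(genome: AnnotatedGenome, feature: GeneFeature) -> str:
    """Concatenate the feature's segments in reading order; minus-strand
    features are reverse-complemented. Circular wrap is handled."""
    parts = [_segment_text(genome, s, e) for s, e in feature.segments]
    seq = "".join(parts)
    return reverse_complement(seq) if feature.strand == "-" else seq


def translate(cds: str, table: int = 1, mode: str = "standard",
              complete: bool = True) -> str:
    """Translate a CDS.

    ``standard`` mode requires a length divisible by 3 and raises
    :class:`InternalStopError` if a complete CDS contains a premature stop;
    a single trailing stop codon is trimmed from the returned protein.
    ``open_frame`` mode (dinoflagellate host genes, which lack canonical
    start/stop codons) translates from the first base, trims a trailing
    partial codon, and maps stops to ``*`` without complaint.
    """
    cds = cds.upper().replace("U", "T")
    if mode not in ("standard", "open_frame"):
        raise ValueError(f"unknown translation mode {mode!r}")
    if mode == "standard" and len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if mode == "open_frame":
        cds = cds[:len(cds) - len(cds) % 3]
    codon_table = CodonTable.unambiguous_dna_by_id[table]
    aa = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if codon in codon_table.stop_codons:
            aa.append("*")
        else:
            aa.append(codon_table.forward_table.get(codon, "X"))
    protein = "".join(aa)
    if mode == "standard":
        if protein.endswith("*"):
            protein = protein[:-1]
        if complete and "*" in protein:
            pos = protein.index("*") + 1
            raise InternalStopError(
                f"internal stop at codon {pos} under table {table}")
    return protein


def feature_table(genome: AnnotatedGenome) -> pd.DataFrame:
    """One row per feature: genome_id, name, cls, strand, segments, length."""
    rows = []
    for f in genome.features:
        rows.append({
            "genome_id": genome.id,
            "name": f.name,
            "cls": f.cls,
            "strand": f.strand,
            "segments": ";".join(f"{s}..{e}" for s, e in f.segments),
            "length": f.length(len(genome)),
        })
    return pd.DataFrame(rows, columns=["genome_id", "name", "cls", "strand",
                                       "segments", "length"])


def write_feature_table(genome: AnnotatedGenome, path: str | Path) -> None:
    feature_table(genome).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]],
                path: str | Path) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
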